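"""Normalization and differential-expression statistics for two-factor counts.

Implements TMM (trimmed mean of M-values) normalization factors, log2-CPM
expression (the PCA substrate), a per-gene negative-binomial log-linear model
for a crossed two-factor design with interaction (likelihood-ratio tests,
Cox-Reid adjusted-profile-likelihood dispersion), the conditional NB exact
test for pairwise group comparisons, Benjamini-Hochberg FDR and the
fold-change / FDR / mean-count DEG filters.

The NB parameterization throughout is ``var = mu + phi * mu**2`` with phi the
dispersion; fold-changes are reported in log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)

__all__ = [
    "CountMatrix",
    "NormFactors",
    "DEResult",
    "TMMNormalizer",
    "TwoFactorDE",
    "tmm_factors",
    "log_normalized_expression",
    "fit_two_factor_glm",
    "pairwise_exact_test",
    "bh_fdr",
    "filter_degs",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class CountMatrix:
    """Genes x samples integer counts with two-factor sample annotations.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes as rows, sample IDs as columns.
    samples : DataFrame
        One row per sample with columns ``sample_id``, ``factor_a``,
        ``factor_b`` and optionally ``replicate``.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        samples = samples.reset_index(drop=True).copy()
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        for col in ("sample_id", "factor_a", "factor_b"):
            if col not in samples.columns:
                raise ValueError(f"sample table lacks required column {col!r}")
        if samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        missing = set(counts.columns) - set(samples["sample_id"])
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        samples = (
            samples.set_index("sample_id").loc[list(counts.columns)].reset_index()
        )
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0):
            raise ValueError("counts must be >= 0")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        self.samples = samples

    @property
    def gene_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.counts.columns.to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(float)

    def group_mask(self, factor_a: str | None = None, factor_b: str | None = None):
        m = np.ones(len(self.samples), dtype=bool)
        if factor_a is not None:
            m &= (self.samples["factor_a"] == factor_a).to_numpy()
        if factor_b is not None:
            m &= (self.samples["factor_b"] == factor_b).to_numpy()
        return m

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.counts.shape
        return f"CountMatrix({g} genes x {s} samples)"


@dataclass
class NormFactors:
    """Per-sample TMM factors and library sizes; unit geometric mean."""

    factors: np.ndarray
    library_sizes: np.ndarray
    sample_ids: np.ndarray
    reference_sample: str = ""

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError("normalization factors must be finite and positive")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


class DEResult:
    """Per-gene, per-contrast differential-expression statistics.

    Holds a long-format table with columns ``gene_id``, ``contrast``,
    ``logFC`` (log2), ``pvalue``, ``fdr``, ``status`` ("tested" or
    "not_tested"); FDR is computed within each contrast over tested genes
    only. ``dispersion`` carries the per-gene phi-hat used by the tests.
    """

    def __init__(self, gene_ids: np.ndarray, dispersion: np.ndarray | float = np.nan):
        self.gene_ids = np.asarray(gene_ids)
        if np.isscalar(dispersion):
            dispersion = np.full(len(self.gene_ids), float(dispersion))
        self.dispersion = np.asarray(dispersion, dtype=float)
        self._frames: dict[str, pd.DataFrame] = {}

    @property
    def contrasts(self) -> list[str]:
        return list(self._frames)

    def add_contrast(
        self,
        name: str,
        logfc: np.ndarray,
        pvalue: np.ndarray,
        tested: np.ndarray | None = None,
    ) -> None:
        if name in self._frames:
            raise ValueError(f"duplicate contrast name {name!r}")
        n = len(self.gene_ids)
        logfc = np.asarray(logfc, dtype=float)
        pvalue = np.asarray(pvalue, dtype=float)
        if logfc.shape != (n,) or pvalue.shape != (n,):
            raise ValueError("logFC/p-value length must match gene_ids")
        tested = (
            np.ones(n, dtype=bool) if tested is None else np.asarray(tested, bool)
        )
        ok = pvalue[tested]
        if np.any(~((ok > 0) & (ok <= 1))):
            raise ValueError("tested p-values must lie in (0, 1]")
        fdr = np.full(n, np.nan)
        if tested.any():
            fdr[tested] = bh_fdr(pvalue[tested])
        self._frames[name] = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "contrast": name,
                "logFC": logfc,
                "pvalue": np.where(tested, pvalue, np.nan),
                "fdr": fdr,
                "status": np.where(tested, "tested", "not_tested"),
            }
        )

    def contrast(self, name: str) -> pd.DataFrame:
        if name not in self._frames:
            raise ValueError(
                f"unknown contrast {name!r}; available: {self.contrasts}"
            )
        return self._frames[name].set_index("gene_id")

    def to_frame(self) -> pd.DataFrame:
        if not self._frames:
            return pd.DataFrame(
                columns=["gene_id", "contrast", "logFC", "pvalue", "fdr", "status"]
            )
        return pd.concat(self._frames.values(), ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DEResult":
        """Rebuild from a long-format table written by :meth:`to_frame`."""
        gene_ids = frame["gene_id"].unique()
        out = cls(gene_ids)
        for name, sub in frame.groupby("contrast", sort=False):
            sub = sub.set_index("gene_id").reindex(gene_ids)
            tested = (sub["status"] == "tested").to_numpy()
            out.add_contrast(
                str(name),
                sub["logFC"].to_numpy(),
                np.where(tested, sub["pvalue"].to_numpy(), 1.0),
                tested,
            )
        return out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | int | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference sample, per-gene log2 ratios of
    library-size-adjusted counts (M-values) are doubly trimmed — ``trim_m``
    on M and ``trim_a`` on average log abundance — and averaged with
    inverse-asymptotic-variance weights; the exponentiated mean is the
    sample's factor. Factors are rescaled to unit geometric mean. The default
    reference is the sample whose upper-quartile count fraction is closest to
    the mean across samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    y = mat.to_numpy(dtype=float)
    sample_ids = np.asarray(mat.columns)
    lib = y.sum(axis=0)
    zero_cols = np.where(lib == 0)[0]
    if zero_cols.size:
        raise ValueError(
            f"sample {sample_ids[zero_cols[0]]!r} has all-zero counts"
        )

    if reference is None:
        with np.errstate(invalid="ignore"):
            f75 = np.array(
                [np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])]
            )
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(reference, str):
        ref = int(np.where(sample_ids == reference)[0][0])
    else:
        ref = int(reference)

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref], trim_m, trim_a)

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(factors, lib, sample_ids, str(sample_ids[ref]))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        logger.warning("TMM: no genes usable for a sample pair; factor set to 1")
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # effectively identical samples
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        logger.warning("TMM: trimming removed all genes; factor set to 1")
        return 1.0
    f = np.nansum(m[sel] / w[sel]) / np.nansum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def log_normalized_expression(
    counts: CountMatrix | pd.DataFrame,
    factors: NormFactors,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2(CPM + prior) on TMM-effective library sizes.

    Counts are scaled per million of the effective library size
    (library size x TMM factor); the positive ``prior_count`` keeps the log
    finite. This is the substrate for PCA of samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    y = mat.to_numpy(dtype=float)
    eff = factors.effective_library_sizes
    if eff.shape[0] != y.shape[1]:
        raise ValueError("normalization factors do not match sample count")
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    cpm = y / eff[None, :] * 1e6
    return pd.DataFrame(
        np.log2(cpm + prior_count), index=mat.index, columns=mat.columns
    )


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style TMM normalizer.

    ``fit`` computes per-sample TMM factors from a :class:`CountMatrix` (or a
    genes x samples DataFrame); ``transform`` returns log2(CPM + prior) on
    effective library sizes.

    Attributes
    ----------
    factors_ : ndarray
        Per-sample TMM factors, unit geometric mean.
    library_sizes_ : ndarray
        Column sums of the fitted counts.
    reference_sample_ : str
        ID of the reference sample used for the pairwise trimmed means.
    """

    def __init__(
        self, trim_m: float = 0.30, trim_a: float = 0.05, prior_count: float = 0.5
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior_count = prior_count

    def fit(self, X, y=None):
        nf = tmm_factors(X, self.trim_m, self.trim_a)
        self.factors_ = nf.factors
        self.library_sizes_ = nf.library_sizes
        self.reference_sample_ = nf.reference_sample
        self.norm_factors_ = nf
        return self

    def transform(self, X):
        return log_normalized_expression(X, self.norm_factors_, self.prior_count)


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes; shared design matrix)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood, var = mu + phi mu^2, phi per gene."""
    r = 1.0 / phi[:, None]
    mu = np.maximum(mu, 1e-300)
    return np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(mu / (mu + r))
        + r * np.log(r / (r + mu)),
        axis=1,
    )


def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-gene NB log-linear models by IRLS, vectorized across genes.

    y is genes x samples, x the shared samples x p design matrix, offset the
    per-sample log effective library size. Returns (beta, mu).
    """
    g, s = y.shape
    eta = np.log(np.maximum(y, 0.5))
    mu = np.exp(eta)
    phi_col = phi[:, None]
    beta = np.zeros((g, x.shape[1]))
    for _ in range(max_iter):
        w = mu / (1.0 + phi_col * mu)  # working weights for log link
        z = (eta - offset[None, :]) + (y - mu) / mu
        xw = x[None, :, :] * w[:, :, None]
        a = np.einsum("gsp,sq->gpq", xw, x)
        b = np.einsum("gsp,gs->gp", xw, z)
        a[:, np.arange(x.shape[1]), np.arange(x.shape[1])] += 1e-10
        beta_new = np.linalg.solve(a, b[..., None])[..., 0]
        eta_new = np.clip(offset[None, :] + beta_new @ x.T, -50.0, 50.0)
        delta = np.max(np.abs(eta_new - eta))
        eta, beta = eta_new, beta_new
        mu = np.exp(eta)
        if delta < tol:
            break
    return beta, mu


def _cox_reid_adjustment(
    x: np.ndarray, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """0.5 * logdet(X' W X) per gene — the Cox-Reid profile adjustment."""
    w = mu / (1.0 + phi[:, None] * mu)
    xw = x[None, :, :] * w[:, :, None]
    a = np.einsum("gsp,sq->gpq", xw, x)
    a[:, np.arange(x.shape[1]), np.arange(x.shape[1])] += 1e-12
    sign, logdet = np.linalg.slogdet(a)
    return 0.5 * logdet


def _design_matrices(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict]:
    """Full (A*B) and additive (A+B) treatment-coded design matrices."""
    a_levels = list(pd.unique(samples["factor_a"]))
    b_levels = list(pd.unique(samples["factor_b"]))
    a_dum = np.column_stack(
        [(samples["factor_a"] == lv).to_numpy(float) for lv in a_levels[1:]]
    )
    b_dum = np.column_stack(
        [(samples["factor_b"] == lv).to_numpy(float) for lv in b_levels[1:]]
    )
    inter = np.column_stack(
        [
            a_dum[:, i] * b_dum[:, j]
            for i in range(a_dum.shape[1])
            for j in range(b_dum.shape[1])
        ]
    )
    ones = np.ones((len(samples), 1))
    x_full = np.hstack([ones, a_dum, b_dum, inter])
    x_add = np.hstack([ones, a_dum, b_dum])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(
            "two-factor design with interaction is not full rank; "
            "some factor-A x factor-B cells are empty or aliased"
        )
    info = {
        "a_levels": a_levels,
        "b_levels": b_levels,
        "n_a": a_dum.shape[1],
        "n_b": b_dum.shape[1],
        "df_interaction": inter.shape[1],
    }
    return x_full, x_add, info


def estimate_common_dispersion(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Cox-Reid adjusted-profile-likelihood common dispersion.

    Maximizes the summed per-gene profile likelihood, each penalized by the
    Cox-Reid 0.5*logdet term, over a single shared phi.
    """

    def neg_apl(log_phi: float) -> float:
        phi = np.full(y.shape[0], np.exp(log_phi))
        _, mu = _nb_irls(y, x, offset, phi)
        apl = _nb_loglik(y, mu, phi) - _cox_reid_adjustment(x, mu, phi)
        return -float(np.sum(apl))

    res = optimize.minimize_scalar(
        neg_apl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def _moderated_dispersions(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    prior_weight: float = 10.0,
    grid_size: int = 25,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> np.ndarray:
    """Per-gene dispersions shrunk toward the common value.

    Maximizes, per gene, APL_g(phi) + prior_weight * mean_g' APL_g'(phi) on a
    log-spaced grid — a weighted-likelihood moderation toward the common
    dispersion.
    """
    grid = np.exp(np.linspace(np.log(bounds[0]), np.log(bounds[1]), grid_size))
    apl = np.empty((y.shape[0], grid_size))
    for i, phi_val in enumerate(grid):
        phi = np.full(y.shape[0], phi_val)
        _, mu = _nb_irls(y, x, offset, phi)
        apl[:, i] = _nb_loglik(y, mu, phi) - _cox_reid_adjustment(x, mu, phi)
    score = apl + prior_weight * apl.mean(axis=0)[None, :]
    return grid[np.argmax(score, axis=1)]


def fit_two_factor_glm(
    counts: CountMatrix,
    factors: NormFactors | None = None,
    dispersion: float | str = "common",
) -> DEResult:
    """Likelihood-ratio tests for interaction and main effects, per gene.

    Fits per-gene NB log-linear models with offsets equal to the log
    effective library size. The interaction p-value comes from the LRT of
    the full (A*B) against the additive (A+B) model; main-effect tests
    compare the additive model against single-factor models. ``dispersion``
    is ``"common"`` (Cox-Reid adjusted-profile-likelihood shared estimate),
    ``"moderated"`` (per-gene, shrunk toward the common value), or a fixed
    positive float.

    Genes with all-zero counts are flagged ``not_tested`` and excluded from
    the FDR denominator. The interaction contrast's logFC is the (first)
    interaction coefficient in log2 units.
    """
    y = counts.values.astype(float)
    if factors is None:
        factors = tmm_factors(counts)
    offset = np.log(factors.effective_library_sizes)
    x_full, x_add, info = _design_matrices(counts.samples)
    cells = counts.samples.groupby(["factor_a", "factor_b"]).size()
    if (cells >= 2).sum() < 2:
        raise ValueError("need >=2 replicates in >=2 design cells")

    tested = y.sum(axis=1) > 0
    yt = y[tested]

    if dispersion == "common":
        phi_common = estimate_common_dispersion(yt, x_full, offset)
        phi = np.full(yt.shape[0], phi_common)
    elif dispersion == "moderated":
        phi = _moderated_dispersions(yt, x_full, offset)
    else:
        phi_val = float(dispersion)
        if phi_val <= 0:
            raise ValueError("fixed dispersion must be > 0")
        phi = np.full(yt.shape[0], phi_val)

    beta_full, mu_full = _nb_irls(yt, x_full, offset, phi)
    _, mu_add = _nb_irls(yt, x_add, offset, phi)
    ll_full = _nb_loglik(yt, mu_full, phi)
    ll_add = _nb_loglik(yt, mu_add, phi)
    lrt_int = np.maximum(2.0 * (ll_full - ll_add), 0.0)
    p_int = stats.chi2.sf(lrt_int, df=info["df_interaction"])

    # main effects tested within the additive model
    ones = np.ones((len(counts.samples), 1))
    x_a_only = x_add[:, : 1 + info["n_a"]]
    x_b_only = np.hstack([ones, x_add[:, 1 + info["n_a"]:]])
    beta_add, _ = _nb_irls(yt, x_add, offset, phi)
    _, mu_b_only = _nb_irls(yt, x_b_only, offset, phi)
    _, mu_a_only = _nb_irls(yt, x_a_only, offset, phi)
    ll_b_only = _nb_loglik(yt, mu_b_only, phi)
    ll_a_only = _nb_loglik(yt, mu_a_only, phi)
    p_main_a = stats.chi2.sf(
        np.maximum(2.0 * (ll_add - ll_b_only), 0.0), df=info["n_a"]
    )
    p_main_b = stats.chi2.sf(
        np.maximum(2.0 * (ll_add - ll_a_only), 0.0), df=info["n_b"]
    )

    n = y.shape[0]
    phi_all = np.full(n, np.nan)
    phi_all[tested] = phi
    result = DEResult(counts.gene_ids, phi_all)

    def expand(vals: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(n, fill)
        out[tested] = vals
        return out

    p_floor = np.nextafter(0.0, 1.0)
    i_int = 1 + info["n_a"] + info["n_b"]
    result.add_contrast(
        "interaction",
        expand(beta_full[:, i_int] / _LN2, 0.0),
        expand(np.maximum(p_int, p_floor), 1.0),
        tested,
    )
    result.add_contrast(
        "main_a",
        expand(beta_add[:, 1] / _LN2, 0.0),
        expand(np.maximum(p_main_a, p_floor), 1.0),
        tested,
    )
    result.add_contrast(
        "main_b",
        expand(beta_add[:, 1 + info["n_a"]] / _LN2, 0.0),
        expand(np.maximum(p_main_b, p_floor), 1.0),
        tested,
    )
    return result


class TwoFactorDE(BaseEstimator):
    """Two-factor NB differential expression as a scikit-learn estimator.

    ``fit`` takes a :class:`CountMatrix`, computes TMM factors, estimates the
    dispersion, runs the interaction / main-effect likelihood-ratio tests and
    (optionally) pairwise exact tests for the four cell-vs-cell contrasts.

    Parameters
    ----------
    dispersion : "common", "moderated" or float
        Dispersion handling for the NB model.
    pairwise : bool
        Also run conditional exact tests between the four design cells
        (treatment within each A level, A contrast within each B level).

    Attributes
    ----------
    results_ : DEResult
        Per-gene statistics per contrast.
    norm_factors_ : NormFactors
        TMM factors used as offsets.
    dispersion_ : ndarray
        Per-gene fitted dispersion.
    """

    def __init__(self, dispersion: float | str = "common", pairwise: bool = True):
        self.dispersion = dispersion
        self.pairwise = pairwise

    def fit(self, X: CountMatrix, y=None):
        if not isinstance(X, CountMatrix):
            raise TypeError("TwoFactorDE.fit expects a CountMatrix")
        self.norm_factors_ = tmm_factors(X)
        self.results_ = fit_two_factor_glm(X, self.norm_factors_, self.dispersion)
        self.dispersion_ = self.results_.dispersion
        if self.pairwise:
            self._add_pairwise(X)
        return self

    def _add_pairwise(self, cm: CountMatrix) -> None:
        a_levels = list(pd.unique(cm.samples["factor_a"]))
        b_levels = list(pd.unique(cm.samples["factor_b"]))
        phi = np.where(np.isfinite(self.dispersion_), self.dispersion_, 0.1)
        for a in a_levels:
            g1 = cm.sample_ids[cm.group_mask(factor_a=a, factor_b=b_levels[0])]
            g2 = cm.sample_ids[cm.group_mask(factor_a=a, factor_b=b_levels[1])]
            p, lfc = pairwise_exact_test(cm, self.norm_factors_, g1, g2, phi)
            self.results_.add_contrast(f"{a}:{b_levels[1]}_vs_{b_levels[0]}", lfc, p)
        for b in b_levels:
            g1 = cm.sample_ids[cm.group_mask(factor_a=a_levels[0], factor_b=b)]
            g2 = cm.sample_ids[cm.group_mask(factor_a=a_levels[1], factor_b=b)]
            p, lfc = pairwise_exact_test(cm, self.norm_factors_, g1, g2, phi)
            self.results_.add_contrast(f"{b}:{a_levels[1]}_vs_{a_levels[0]}", lfc, p)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def _conditional_nb_logpmf(t: int, r1: float, r2: float) -> np.ndarray:
    """log pmf of S1 | S1 + S2 = t for independent NB(r1, p), NB(r2, p).

    The conditional law is beta-binomial(t, r1, r2); it is evaluated through
    the pmf ratio recurrence, which stays accurate for the huge r values that
    arise as the dispersion tends to zero (where it converges to the
    binomial(t, r1/(r1+r2)) conditional of Poisson counts).
    """
    a = np.arange(t)
    log_ratio = (
        np.log(t - a) - np.log(a + 1.0) + np.log(a + r1) - np.log(t - 1.0 - a + r2)
    )
    logpmf = np.concatenate([[0.0], np.cumsum(log_ratio)])
    return logpmf - special.logsumexp(logpmf)


def _minlike_two_sided(logpmf: np.ndarray, observed: int) -> float:
    """Two-sided exact p: total probability of outcomes no more likely than
    the observed one (relative tie tolerance 1e-7)."""
    pmf = np.exp(logpmf)
    cutoff = pmf[observed] * (1.0 + 1e-7)
    return float(min(pmf[pmf <= cutoff].sum(), 1.0))


def pairwise_exact_test(
    counts: CountMatrix | pd.DataFrame,
    factors: NormFactors,
    group1,
    group2,
    dispersion: float | np.ndarray = 0.1,
    prior_count: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional NB exact test between two sample groups, per gene.

    Counts are scaled to a common effective library size (pseudo-counts),
    summed within each group and rounded; the two-sided p-value is the
    minimum-likelihood tail probability of the group-1 sum conditional on the
    total, under NB sums with sizes ``n_i / phi``. logFC (log2) compares
    group-2 to group-1 pseudo-count means with a ``prior_count`` offset.

    As phi -> 0 with equal library sizes this reproduces the conditional
    binomial two-sided exact test.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    ids = list(mat.columns)
    idx1 = [ids.index(s) for s in group1]
    idx2 = [ids.index(s) for s in group2]
    if set(idx1) & set(idx2):
        raise ValueError("groups overlap")
    if not idx1 or not idx2:
        raise ValueError("both groups must be non-empty")

    y = mat.to_numpy(dtype=float)
    eff = factors.effective_library_sizes
    sel = idx1 + idx2
    common = np.exp(np.mean(np.log(eff[sel])))
    pseudo = y[:, sel] * (common / eff[sel])[None, :]
    n1, n2 = len(idx1), len(idx2)
    s1 = np.rint(pseudo[:, :n1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo[:, n1:].sum(axis=1)).astype(np.int64)

    phi = np.broadcast_to(
        np.atleast_1d(np.asarray(dispersion, dtype=float)), (y.shape[0],)
    )
    if np.any(phi <= 0):
        raise ValueError("dispersion must be > 0")

    pvals = np.ones(y.shape[0])
    for g in range(y.shape[0]):
        t = int(s1[g] + s2[g])
        if t == 0:
            continue
        r1, r2 = n1 / phi[g], n2 / phi[g]
        logpmf = _conditional_nb_logpmf(t, r1, r2)
        pvals[g] = _minlike_two_sided(logpmf, int(s1[g]))

    m1 = s1 / n1 + prior_count
    m2 = s2 / n2 + prior_count
    logfc = np.log2(m2 / m1)
    return pvals, logfc


# ---------------------------------------------------------------------------
# FDR and DEG filters
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    de: DEResult,
    counts: CountMatrix,
    contrast: str,
    group1_mask: np.ndarray,
    group2_mask: np.ndarray,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    mean_count_threshold: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Up/down DEG lists under fold-change, FDR and mean-count rules.

    A gene is *up* when logFC > log2(fc_threshold), FDR < fdr_threshold and
    both groups' mean raw counts exceed mean_count_threshold; *down* is
    symmetric with logFC < -log2(fc_threshold). All inequalities are strict.
    """
    if fc_threshold <= 0 or fdr_threshold < 0 or mean_count_threshold < 0:
        raise ValueError("thresholds must be positive")
    tab = de.contrast(contrast)
    y = counts.values.astype(float)
    mean1 = y[:, np.asarray(group1_mask, bool)].mean(axis=1)
    mean2 = y[:, np.asarray(group2_mask, bool)].mean(axis=1)
    means_ok = pd.Series(
        (mean1 > mean_count_threshold) & (mean2 > mean_count_threshold),
        index=counts.gene_ids,
    )
    tested = tab["status"] == "tested"
    fdr_ok = tested & (tab["fdr"] < fdr_threshold)
    lfc = tab["logFC"]
    cut = np.log2(fc_threshold)
    up = tab.index[fdr_ok & (lfc > cut) & means_ok.reindex(tab.index)]
    down = tab.index[fdr_ok & (lfc < -cut) & means_ok.reindex(tab.index)]
    return list(up), list(down)
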