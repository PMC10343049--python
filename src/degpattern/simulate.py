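"""Seeded synthetic-data generators for every stage of the pipeline.

The study's raw inputs (RNA-seq counts from a two-factor co-culture /
treatment design, cytokine-array spot densities, qPCR Ct values) are not
publicly deposited, so each downstream stage is exercised on simulated data
with the statistical structure the analysis assumes:

* counts: per-gene negative-binomial draws, ``var = mu + phi * mu**2``, with
  log-uniform library sizes and planted main/interaction effects organised
  into profile clusters;
* profiles: well-separated cluster centroids plus isotropic noise, a direct
  fixture for the consensus-clustering stage;
* spot panels: duplicate spots per analyte = true level + background + noise,
  with negative-control spots carrying background only;
* Ct tables: target Ct shifted by -log2(relative expression) against a
  reference gene.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimDesign",
    "SimTruth",
    "simulate_counts",
    "simulate_profiles",
    "simulate_spot_panel",
    "simulate_ct",
    "default_effect_templates",
]

_LN2 = np.log(2.0)


def default_effect_templates(n_clusters: int, magnitude: float = 2.0) -> np.ndarray:
    """Distinct per-cluster (main_A, main_B, interaction) log2 effect vectors.

    Sign/axis patterns scaled by ``magnitude`` guarantee mutually separable
    planted differential profiles.
    """
    patterns = []
    base = [
        (0.0, 0.0, 1.0),
        (0.0, 0.0, -1.0),
        (0.0, 1.0, 1.0),
        (1.0, 0.0, -1.0),
        (1.0, 1.0, 1.0),
        (0.0, -1.0, 1.0),
        (-1.0, 0.0, -1.0),
        (1.0, -1.0, -1.0),
    ]
    for i in range(n_clusters):
        if i < len(base):
            patterns.append(base[i])
        else:  # extend deterministically beyond the hand-set patterns
            signs = [1.0 if (i >> b) & 1 else -1.0 for b in range(3)]
            patterns.append(tuple(s * (1.0 + i / 8.0) for s in signs))
    return magnitude * np.asarray(patterns, dtype=float)


@dataclass
class SimDesign:
    """Parameters of the two-factor count simulation.

    Effects are log2 fold-changes; baselines are on the natural-log scale.
    """

    n_genes: int = 1000
    factor_a_levels: tuple[str, ...] = ("WT", "APP")
    factor_b_levels: tuple[str, ...] = ("PBS", "LPS")
    replicates_per_cell: int = 3
    baseline_log_mean_range: tuple[float, float] = (np.log(5.0), np.log(500.0))
    dispersion: float | tuple[float, float] = 0.1
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_profile_clusters: int = 4
    cluster_effect_templates: np.ndarray | None = None
    fraction_null: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.factor_a_levels) < 2 or len(self.factor_b_levels) < 2:
            raise ValueError("each factor needs >=2 levels")
        if self.replicates_per_cell <= 0:
            raise ValueError("replicates_per_cell must be positive")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must lie in [0, 1]")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be a positive interval")
        disp = self.dispersion
        if np.isscalar(disp):
            if disp <= 0:
                raise ValueError("dispersion must be > 0")
        else:
            shape, scale = disp
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma dispersion parameters must be > 0")
        if self.n_profile_clusters < 1:
            raise ValueError("n_profile_clusters must be >= 1")
        if self.cluster_effect_templates is None:
            self.cluster_effect_templates = default_effect_templates(
                self.n_profile_clusters
            )
        tmpl = np.asarray(self.cluster_effect_templates, dtype=float)
        if tmpl.shape[0] != self.n_profile_clusters:
            raise ValueError("one effect template required per cluster")
        if self.n_profile_clusters > 1:
            for i, j in itertools.combinations(range(tmpl.shape[0]), 2):
                if np.allclose(tmpl[i], tmpl[j]):
                    raise ValueError("cluster templates must be distinct")
        self.cluster_effect_templates = tmpl


@dataclass
class SimTruth:
    """Ground truth paired with a simulated data object."""

    cluster_labels: np.ndarray  # -1 for null genes
    true_logfc: pd.DataFrame | None = None  # genes x contrasts, log2
    dispersion: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _two_factor_design(design: SimDesign) -> pd.DataFrame:
    rows = []
    for a in design.factor_a_levels:
        for b in design.factor_b_levels:
            for r in range(1, design.replicates_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{a}_{b}_r{r}",
                        "factor_a": a,
                        "factor_b": b,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(design: SimDesign) -> tuple["CountMatrix", SimTruth]:
    """Draw a two-factor NB count matrix with planted effect clusters.

    Gene means are ``library_size * exp(baseline + X @ effects)`` with the
    design matrix holding factor-A, factor-B and interaction indicators for
    the non-reference levels; counts are NB with ``var = mu + phi * mu**2``.
    A fraction of genes is null (all effects zero); the rest carry the log2
    effect template of their planted cluster on the first non-reference
    coefficients of each term.

    Returns the count matrix together with a :class:`SimTruth` carrying
    cluster labels, true per-contrast log2 fold-changes, dispersions and
    library sizes.
    """
    from .de import CountMatrix  # local import to avoid a cycle

    meta = _two_factor_design(design)
    n_samples = len(meta)
    root = np.random.default_rng(np.random.SeedSequence(design.seed))

    baselines = root.uniform(*design.baseline_log_mean_range, size=design.n_genes)
    lo, hi = design.library_size_range
    lib_sizes = np.exp(root.uniform(np.log(lo), np.log(hi), size=n_samples))

    if np.isscalar(design.dispersion):
        phi = np.full(design.n_genes, float(design.dispersion))
    else:
        shape, scale = design.dispersion
        phi = root.gamma(shape, scale, size=design.n_genes)
        phi = np.maximum(phi, 1e-8)

    n_null = int(round(design.fraction_null * design.n_genes))
    labels = np.full(design.n_genes, -1, dtype=int)
    n_alt = design.n_genes - n_null
    if n_alt > 0:
        alt_idx = root.choice(design.n_genes, size=n_alt, replace=False)
        labels[alt_idx] = root.integers(0, design.n_profile_clusters, size=n_alt)

    # log2 effects per gene on (first non-reference A, B, A:B) coefficients
    eff = np.zeros((design.n_genes, 3))
    for g in np.where(labels >= 0)[0]:
        eff[g] = design.cluster_effect_templates[labels[g], :3]

    a1 = (meta["factor_a"] == design.factor_a_levels[1]).to_numpy(float)
    b1 = (meta["factor_b"] == design.factor_b_levels[1]).to_numpy(float)
    x = np.column_stack([a1, b1, a1 * b1])  # samples x 3

    log_mu = (
        baselines[:, None]
        + _LN2 * eff @ x.T
        + np.log(lib_sizes)[None, :]
        - np.log(np.mean(lib_sizes))
    )
    mu = np.exp(log_mu)

    counts = np.empty((design.n_genes, n_samples), dtype=np.int64)
    gene_streams = np.random.SeedSequence(design.seed).spawn(design.n_genes + 1)
    for g in range(design.n_genes):
        rng = np.random.default_rng(gene_streams[g + 1])
        r = 1.0 / phi[g]
        p = r / (r + mu[g])
        counts[g] = rng.negative_binomial(r, p)

    gene_ids = np.array([f"gene{g:05d}" for g in range(design.n_genes)])
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=meta["sample_id"].to_numpy()),
        meta,
    )

    # true log2FC for the four cell-vs-cell contrasts used downstream
    a0, a1n = design.factor_a_levels[:2]
    b0, b1n = design.factor_b_levels[:2]
    a, b, ab = eff[:, 0], eff[:, 1], eff[:, 2]
    true_logfc = pd.DataFrame(
        {
            f"{a0}:{b1n}_vs_{b0}": b,
            f"{a1n}:{b1n}_vs_{b0}": b + ab,
            f"{b0}:{a1n}_vs_{a0}": a,
            f"{b1n}:{a1n}_vs_{a0}": a + ab,
            "interaction": ab,
        },
        index=gene_ids,
    )
    truth = SimTruth(
        cluster_labels=labels,
        true_logfc=true_logfc,
        dispersion=phi,
        library_sizes=lib_sizes,
        extra={"baseline_log_mean": baselines, "mu": mu},
    )
    return cm, truth


def simulate_profiles(
    n_per_cluster: int,
    n_clusters: int,
    separation: float,
    n_contrasts: int = 4,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Planted-cluster differential profiles: centroids plus isotropic noise.

    Centroids are ``separation``-scaled signed axis vectors, so any two are at
    least ``separation * sqrt(2)`` apart; at most ``2 * n_contrasts`` distinct
    centroids are representable.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if n_clusters > 2 * n_contrasts:
        raise ValueError(
            f"cannot place {n_clusters} centroids with n_contrasts={n_contrasts}; "
            f"max is {2 * n_contrasts}"
        )
    centroids = np.zeros((n_clusters, n_contrasts))
    for g in range(n_clusters):
        axis, sign = divmod(g, 2)
        centroids[g, axis] = separation * (1.0 if sign == 0 else -1.0)

    rng = np.random.default_rng(np.random.SeedSequence([seed, n_clusters]))
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    x = centroids[labels] + noise_sd * rng.standard_normal(
        (labels.size, n_contrasts)
    )
    profiles = pd.DataFrame(
        x,
        index=[f"gene{i:04d}" for i in range(labels.size)],
        columns=[f"contrast{c + 1}" for c in range(n_contrasts)],
    )
    truth = SimTruth(cluster_labels=labels, extra={"centroids": centroids})
    return profiles, truth


def simulate_spot_panel(
    analytes: list[str],
    true_levels: dict[str, dict[str, float] | list[float]],
    background: float = 50.0,
    noise_sd: float = 5.0,
    n_replicates: int = 3,
    n_controls: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy duplicate-spot cytokine panel with negative-control rows.

    ``true_levels`` maps group label -> per-analyte level (dict or list in
    ``analytes`` order). Each analyte row carries two spot densities
    (level + background + noise); rows with ``analyte == "NEG"`` carry the
    background-only control spots.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (group tests need >=2)")
    if n_controls < 2:
        raise ValueError("n_controls must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    rows = []
    for group, levels in true_levels.items():
        if not isinstance(levels, dict):
            levels = dict(zip(analytes, levels))
        for a in analytes:
            if levels[a] < 0:
                raise ValueError(f"negative true level for {a!r} in group {group!r}")
        for rep in range(1, n_replicates + 1):
            rep_id = f"{group}_rep{rep}"
            for a in analytes:
                s = levels[a] + background + noise_sd * rng.standard_normal(2)
                rows.append(
                    {
                        "replicate_id": rep_id,
                        "group": group,
                        "analyte": a,
                        "spot1": max(s[0], 0.0),
                        "spot2": max(s[1], 0.0),
                    }
                )
            for _ in range(n_controls // 2 + n_controls % 2):
                s = background + noise_sd * rng.standard_normal(2)
                rows.append(
                    {
                        "replicate_id": rep_id,
                        "group": group,
                        "analyte": "NEG",
                        "spot1": max(s[0], 0.0),
                        "spot2": max(s[1], 0.0),
                    }
                )
    return pd.DataFrame(rows)


def simulate_ct(
    groups: list[str],
    true_log2_ratios: dict[str, float],
    reference_ct: float = 18.0,
    delta_ct_base: float = 4.0,
    noise_sd: float = 0.0,
    n_per_group: int = 3,
    seed: int = 0,
    target: str = "target",
    reference: str = "GAPDH",
) -> pd.DataFrame:
    """Tidy qPCR Ct table (sample_id, group, gene, ct).

    Target Ct is the reference-implied Ct (``reference_ct + delta_ct_base``)
    minus the group's log2 relative expression, plus noise; the calibrator
    group should have ratio 1 so the comparative-Ct recovery is unbiased.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not groups:
        raise ValueError("groups must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    rows = []
    for group in groups:
        ratio = true_log2_ratios[group]
        for i in range(1, n_per_group + 1):
            sid = f"{group}_s{i}"
            ref_ct = reference_ct + noise_sd * rng.standard_normal()
            tgt_ct = (
                reference_ct
                + delta_ct_base
                - ratio
                + noise_sd * rng.standard_normal()
            )
            rows.append(
                {"sample_id": sid, "group": group, "gene": reference, "ct": ref_ct}
            )
            rows.append(
                {"sample_id": sid, "group": group, "gene": target, "ct": tgt_ct}
            )
    return pd.DataFrame(rows)
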