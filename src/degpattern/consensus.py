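"""Differential profiles and reproducibility-based k-means cluster selection.

Genes with a significant genotype x treatment interaction (FDR below a
cutoff, default 0.2) are summarised as *differential profiles*: one entry per
pairwise contrast equal to logFC x (-log p), each column divided by its
standard deviation. k-means is run with several random initializations for
each candidate k; for every pair of runs a co-clustering distance is
computed from the overlap of their same-cluster gene-pair sets, and the
largest k whose mean pairwise distance falls below a tolerance (default
1e-5) is selected — the granularity at which the clustering is perfectly
reproducible across initializations.

The distance between runs A and B with co-clustered pair sets P_A, P_B is

    d = 1 - 0.5 * (|P_A & P_B| / |P_A| + |P_A & P_B| / |P_B|),

which is 0 for identical partitions (up to label names) and 1 for
partitions sharing no co-clustered pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .de import DEResult

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringRun",
    "ReproducibilityCurve",
    "ConsensusKMeans",
    "build_profiles",
    "kmeans_run",
    "coclustered_pairs",
    "clustering_distance",
    "reproducibility_sweep",
    "select_k",
    "final_clustering",
]


def build_profiles(
    de: DEResult,
    contrasts: list[str],
    fdr_cutoff: float = 0.2,
    selection_contrast: str = "interaction",
) -> pd.DataFrame:
    """SD-normalized logFC x (-log p) profile matrix for interaction genes.

    Rows are the genes with ``selection_contrast`` FDR below ``fdr_cutoff``;
    each column c holds logFC(g, c) * (-ln p(g, c)), divided by the column's
    sample standard deviation (columns with zero SD are left unscaled, with a
    warning). The choice of logarithm bases is immaterial: any per-column
    rescaling cancels in the SD normalization.
    """
    sel_tab = de.contrast(selection_contrast)
    selected = sel_tab.index[
        (sel_tab["status"] == "tested") & (sel_tab["fdr"] < fdr_cutoff)
    ]
    if len(selected) < 2:
        raise ValueError(
            f"only {len(selected)} genes with {selection_contrast} FDR < "
            f"{fdr_cutoff}; raise the cutoff to build profiles"
        )
    cols = {}
    for c in contrasts:
        tab = de.contrast(c).loc[selected]
        entry = tab["logFC"].to_numpy() * (-np.log(tab["pvalue"].to_numpy()))
        entry = np.nan_to_num(entry, nan=0.0)
        sd = np.std(entry, ddof=1)
        if sd > 0:
            entry = entry / sd
        else:
            logger.warning("profile column %r has zero SD; left unscaled", c)
        cols[c] = entry
    return pd.DataFrame(cols, index=selected)


@dataclass
class ClusteringRun:
    """One seeded k-means partition of the profile rows."""

    k: int
    seed: int
    labels: np.ndarray
    converged: bool
    n_iter: int
    inertia: float
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size and self.labels.max() >= self.k:
            raise ValueError("label out of range for k")


def kmeans_run(
    profiles: pd.DataFrame | np.ndarray,
    k: int,
    seed: int,
    init: str = "k-means++",
    max_iter: int = 300,
) -> ClusteringRun:
    """A single seeded k-means (Lloyd) run on the profile matrix.

    ``init`` is ``"k-means++"`` (default) or ``"random"`` (k distinct data
    rows); iterations stop when assignments are stable or at ``max_iter``.
    Deterministic given (profiles, k, seed).
    """
    x = np.asarray(profiles, dtype=float)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} out of range for {x.shape[0]} rows")
    km = KMeans(
        n_clusters=k,
        init=init,
        n_init=1,
        max_iter=max_iter,
        tol=0.0,
        algorithm="lloyd",
        random_state=seed,
    ).fit(x)
    return ClusteringRun(
        k=k,
        seed=seed,
        labels=km.labels_.astype(int),
        converged=km.n_iter_ < max_iter,
        n_iter=int(km.n_iter_),
        inertia=float(km.inertia_),
        centers=km.cluster_centers_,
    )


def coclustered_pairs(run: ClusteringRun) -> set[tuple[int, int]]:
    """Unordered index pairs (i < j) assigned to the same cluster."""
    pairs = set()
    labels = run.labels
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((int(members[i]), int(members[j])))
    return pairs


def _pair_counts(labels_a: np.ndarray, labels_b: np.ndarray):
    """(|P_A|, |P_B|, |P_A & P_B|) via the label contingency table."""

    def n_pairs(counts: np.ndarray) -> float:
        return float(np.sum(counts * (counts - 1) // 2))

    na = n_pairs(np.bincount(labels_a))
    nb = n_pairs(np.bincount(labels_b))
    joint = labels_a.astype(np.int64) * (labels_b.max() + 1) + labels_b
    nab = n_pairs(np.bincount(joint))
    return na, nb, nab


def clustering_distance(run_a: ClusteringRun, run_b: ClusteringRun) -> float:
    """Co-clustering reproducibility distance between two runs, in [0, 1].

    1 minus the mean of the two fractions of shared co-clustered pairs
    relative to each run's own co-clustered pairs. Invariant to cluster
    relabeling and symmetric. All-singleton partitions have no co-clustered
    pairs; the distance is 0 if both runs are all-singleton, else 1.
    """
    la, lb = np.asarray(run_a.labels), np.asarray(run_b.labels)
    if la.shape != lb.shape:
        raise ValueError("runs cover different gene sets")
    na, nb, nab = _pair_counts(la, lb)
    if na == 0 or nb == 0:
        logger.warning("all-singleton clustering in distance computation")
        return 0.0 if na == nb == 0 else 1.0
    return 1.0 - 0.5 * (nab / na + nab / nb)


@dataclass
class ReproducibilityCurve:
    """Mean pairwise co-clustering distance per candidate k."""

    distances: dict[int, float]
    n_init: int
    tolerance: float = 1e-5
    selected_k: int | None = None
    runs: dict[int, list[ClusteringRun]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.distances),
                "mean_distance": list(self.distances.values()),
                "selected": [k == self.selected_k for k in self.distances],
            }
        )


def _run_seed(base_seed: int, k: int, init_index: int) -> int:
    """Stable per-run seed schedule from (base_seed, k, init_index)."""
    return int(
        np.random.SeedSequence([base_seed, k, init_index]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def reproducibility_sweep(
    profiles: pd.DataFrame | np.ndarray,
    k_range=range(2, 21),
    n_init: int = 10,
    base_seed: int = 0,
    init: str = "k-means++",
    tolerance: float = 1e-5,
    keep_runs: bool = True,
) -> ReproducibilityCurve:
    """Mean pairwise run distance for each k over n_init seeded runs.

    For each k in ``k_range`` (default 2..20), ``n_init`` (default 10)
    independent k-means runs are compared pairwise and the distance averaged
    over all C(n_init, 2) pairs. Deterministic given ``base_seed``.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2 to form run pairs")
    x = np.asarray(profiles, dtype=float)
    ks = list(k_range)
    if max(ks) > x.shape[0]:
        raise ValueError(
            f"max k ({max(ks)}) exceeds number of profile rows ({x.shape[0]})"
        )
    distances: dict[int, float] = {}
    all_runs: dict[int, list[ClusteringRun]] = {}
    for k in ks:
        runs = [
            kmeans_run(x, k, _run_seed(base_seed, k, i), init=init)
            for i in range(n_init)
        ]
        ds = [
            clustering_distance(runs[i], runs[j])
            for i in range(n_init)
            for j in range(i + 1, n_init)
        ]
        distances[k] = float(np.mean(ds))
        if keep_runs:
            all_runs[k] = runs
    curve = ReproducibilityCurve(
        distances=distances, n_init=n_init, tolerance=tolerance, runs=all_runs
    )
    curve.selected_k = select_k(curve, tolerance)
    return curve


def select_k(curve: ReproducibilityCurve, tolerance: float = 1e-5) -> int | None:
    """Largest k whose mean pairwise distance is below the tolerance.

    Returns ``None`` (with a log report) when no k qualifies.
    """
    ok = [k for k, d in curve.distances.items() if d < tolerance]
    if not ok:
        logger.info(
            "no k in %s reaches mean distance < %g (min observed %g)",
            sorted(curve.distances),
            tolerance,
            min(curve.distances.values()),
        )
        return None
    return max(ok)


def final_clustering(
    profiles: pd.DataFrame | np.ndarray,
    curve: ReproducibilityCurve,
    k_selected: int | None = None,
) -> tuple[ClusteringRun, pd.DataFrame]:
    """Consensus run at the selected k plus per-cluster mean profiles.

    Among the sweep's runs at ``k_selected`` the one with minimal
    within-cluster sum of squares is taken; ties break toward the earliest
    initialization.
    """
    if k_selected is None:
        k_selected = curve.selected_k
    if k_selected is None:
        raise ValueError("no reproducible k was selected")
    if k_selected not in curve.runs:
        raise ValueError(f"k={k_selected} has no stored runs in the curve")
    runs = curve.runs[k_selected]
    best = min(range(len(runs)), key=lambda i: (runs[i].inertia, i))
    run = runs[best]
    x = np.asarray(profiles, dtype=float)
    means = np.vstack([x[run.labels == c].mean(axis=0) for c in range(run.k)])
    cols = (
        list(profiles.columns)
        if isinstance(profiles, pd.DataFrame)
        else [f"c{i}" for i in range(x.shape[1])]
    )
    table = pd.DataFrame(means, columns=cols)
    table.insert(0, "cluster", np.arange(run.k))
    table.insert(1, "n_genes", np.bincount(run.labels, minlength=run.k))
    return run, table


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Reproducibility-selected k-means, scikit-learn style.

    ``fit(X)`` sweeps k over ``k_range`` with ``n_init`` seeded k-means runs
    each, computes the mean pairwise co-clustering distance per k, selects
    the largest k below ``tolerance`` and stores the minimal-inertia run at
    that k.

    Attributes
    ----------
    curve_ : ReproducibilityCurve
        Mean distance per k and the selection.
    selected_k_ : int or None
        The chosen granularity (None when no k is reproducible).
    labels_ : ndarray
        Labels of the consensus run (only when a k was selected).
    cluster_means_ : DataFrame
        Per-cluster mean profile table.
    """

    def __init__(
        self,
        k_range=range(2, 21),
        n_init: int = 10,
        tolerance: float = 1e-5,
        init: str = "k-means++",
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_init = n_init
        self.tolerance = tolerance
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        self.curve_ = reproducibility_sweep(
            X,
            k_range=self.k_range,
            n_init=self.n_init,
            base_seed=self.random_state,
            init=self.init,
            tolerance=self.tolerance,
        )
        self.selected_k_ = self.curve_.selected_k
        if self.selected_k_ is not None:
            run, table = final_clustering(X, self.curve_)
            self.consensus_run_ = run
            self.labels_ = run.labels
            self.cluster_means_ = table
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        if self.selected_k_ is None:
            raise ValueError("no reproducible k; no labels available")
        return self.labels_
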