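"""File formats, run configuration and the end-to-end pipeline driver.

Matrix files are genes-as-rows TSV/CSV with a mandatory header of sample
IDs (MatrixMarket MTX with row/column label sidecars is also read); sample
metadata, spot panels and Ct tables are tidy TSV/CSV. A pipeline run is
described by a validated :class:`RunConfig` (YAML-loadable) and produces a
JSON :class:`RunManifest` with per-file sha256 checksums, so a rerun with
identical config and seeds can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .consensus import (
    ConsensusKMeans,
    build_profiles,
)
from .de import CountMatrix, DEResult, TwoFactorDE, filter_degs
from .simulate import SimDesign, simulate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_sep(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    return "," if fmt == "csv" else "\t"


def read_metadata(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_infer_sep(path, fmt))
    for col in ("sample_id", "factor_a", "factor_b"):
        if col not in meta.columns:
            raise ValueError(f"metadata {path} lacks required column {col!r}")
    return meta


def read_counts(
    path: str | Path,
    metadata: str | Path | pd.DataFrame,
    fmt: str | None = None,
) -> CountMatrix:
    """Read a genes x samples count matrix plus sample metadata.

    ``fmt`` is tsv, csv or mtx (inferred from the suffix when omitted). MTX
    input expects ``<stem>.rows.txt`` and ``<stem>.cols.txt`` label sidecars
    next to the matrix file.
    """
    path = Path(path)
    if fmt is None and path.suffix.lower() == ".mtx":
        fmt = "mtx"
    if fmt == "mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        rows = Path(str(path)[: -len(path.suffix)] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(path.suffix)] + ".cols.txt").read_text().split()
        counts = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        counts = pd.read_csv(path, sep=_infer_sep(path, fmt), index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID {dup!r} in {path}")
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    return CountMatrix(counts, metadata)


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(meta_path, sep="\t", index=False)


def write_mtx(cm: CountMatrix, path: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    path = Path(path)
    mmwrite(str(path), csr_matrix(cm.values))
    stem = str(path)[: -len(path.suffix)] if path.suffix else str(path)
    Path(stem + ".rows.txt").write_text("\n".join(cm.gene_ids) + "\n")
    Path(stem + ".cols.txt").write_text("\n".join(cm.sample_ids) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(500, gt=0)
    replicates_per_cell: int = Field(3, gt=0)
    n_profile_clusters: int = Field(4, ge=1)
    fraction_null: float = Field(0.7, ge=0.0, le=1.0)
    dispersion: float = Field(0.1, gt=0)


class RunConfig(BaseModel):
    """Validated parameters for an end-to-end run (YAML-loadable)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    seed: int = 0
    counts: str | None = None  # paths; when absent, data are simulated
    metadata: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    fdr_cutoff: float = Field(0.2, gt=0, le=1)
    fc_threshold: float = Field(2.0, gt=0)
    fdr_threshold: float = Field(0.05, gt=0, le=1)
    mean_count_threshold: float = Field(2.0, ge=0)
    k_min: int = Field(2, ge=2)
    k_max: int = Field(20, ge=2)
    n_init: int = Field(10, ge=2)
    tolerance: float = Field(1e-5, gt=0)
    dispersion_mode: str = "common"
    out_dir: str = "degpattern_out"

    @model_validator(mode="after")
    def _check(self):
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if (self.counts is None) != (self.metadata is None):
            raise ValueError("counts and metadata must be given together")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class RunManifest(BaseModel):
    config: RunConfig
    version: str = __version__
    seeds: dict[str, int] = {}
    outputs: dict[str, str] = {}  # path -> sha256
    selected_k: int | None = None
    n_up: int | None = None
    n_down: int | None = None
    started: str = ""
    finished: str = ""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunManifest:
    """simulate/load -> TMM -> two-factor DE -> profiles -> consensus k.

    Persists intermediates under ``config.out_dir`` and returns a manifest
    with checksums. Any stage failure aborts with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config, started=datetime.now(timezone.utc).isoformat()
    )
    seeds = {s: stage_seed(config.seed, s) for s in ("simulate", "cluster")}
    manifest.seeds = seeds

    stage = "load"
    try:
        if config.counts is not None:
            cm = read_counts(config.counts, config.metadata)
        else:
            stage = "simulate"
            design = SimDesign(
                n_genes=config.simulate.n_genes,
                replicates_per_cell=config.simulate.replicates_per_cell,
                n_profile_clusters=config.simulate.n_profile_clusters,
                fraction_null=config.simulate.fraction_null,
                dispersion=config.simulate.dispersion,
                seed=seeds["simulate"],
            )
            cm, truth = simulate_counts(design)
            write_counts(cm, out / "counts.tsv", out / "metadata.tsv")
            truth_payload = {
                "cluster_labels": truth.cluster_labels.tolist(),
                "library_sizes": truth.library_sizes.tolist(),
            }
            (out / "truth.json").write_text(json.dumps(truth_payload))

        stage = "differential_expression"
        de = TwoFactorDE(dispersion=config.dispersion_mode).fit(cm)
        res: DEResult = de.results_
        res.to_frame().to_csv(out / "de_results.csv", index=False)

        stage = "deg_filter"
        b_levels = list(pd.unique(cm.samples["factor_b"]))
        pair_contrasts = [c for c in res.contrasts if "_vs_" in c]
        primary = pair_contrasts[0]
        a_of_primary = primary.split(":")[0]
        up, down = filter_degs(
            res,
            cm,
            primary,
            cm.group_mask(factor_a=a_of_primary, factor_b=b_levels[0]),
            cm.group_mask(factor_a=a_of_primary, factor_b=b_levels[1]),
            config.fc_threshold,
            config.fdr_threshold,
            config.mean_count_threshold,
        )
        pd.DataFrame(
            {
                "gene_id": up + down,
                "direction": ["up"] * len(up) + ["down"] * len(down),
            }
        ).to_csv(out / "degs.csv", index=False)
        manifest.n_up, manifest.n_down = len(up), len(down)

        stage = "profiles"
        profiles = build_profiles(res, pair_contrasts, config.fdr_cutoff)
        if config.k_max > len(profiles):
            raise ValueError(
                f"k_max={config.k_max} exceeds the {len(profiles)} selected "
                "profile genes"
            )
        profiles.to_csv(out / "profiles.csv", index_label="gene_id")

        stage = "consensus_clustering"
        ck = ConsensusKMeans(
            k_range=range(config.k_min, config.k_max + 1),
            n_init=config.n_init,
            tolerance=config.tolerance,
            random_state=seeds["cluster"],
        ).fit(profiles)
        ck.curve_.to_frame().to_csv(out / "reproducibility.csv", index=False)
        manifest.selected_k = ck.selected_k_
        if ck.selected_k_ is not None:
            pd.DataFrame(
                {"gene_id": profiles.index, "cluster": ck.labels_}
            ).to_csv(out / "clusters.csv", index=False)
            ck.cluster_means_.to_csv(out / "cluster_means.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest
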