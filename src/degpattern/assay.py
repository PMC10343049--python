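"""Cytokine-array densitometry and comparative-Ct qPCR quantification.

Antibody arrays print each capture antibody in duplicate; an analyte's level
on one array is the mean of its two spot densities after subtracting the
mean negative-control (background) density, clamped at zero. Group
comparisons use the pooled-variance two-tailed Student's t-test (two groups)
or one-way ANOVA (two or more); fold-change is the ratio of group mean
levels.

qPCR relative expression uses the comparative-Ct method: per sample
dCt = Ct_target - Ct_reference (reference gene, e.g. GAPDH), ddCt subtracts
the calibrator group's mean dCt, and relative expression is 2**(-ddCt),
summarised per group as mean +/- SEM.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spot_level", "quantify_panel", "group_compare", "ddct"]


def spot_level(duplicates, negative_controls) -> float:
    """Background-subtracted analyte level from a duplicate spot pair.

    The mean negative-control density is subtracted from each spot; the level
    is the mean of the two corrected spots, clamped at zero (pixel densities
    cannot support negative abundance).
    """
    dup = np.asarray(duplicates, dtype=float)
    neg = np.asarray(negative_controls, dtype=float)
    if dup.shape != (2,):
        raise ValueError("exactly 2 duplicate spots required")
    if neg.size < 2:
        raise ValueError("need >=2 negative-control spots")
    if np.any(dup < 0) or np.any(neg < 0):
        raise ValueError("spot densities must be >= 0")
    background = neg.mean()
    return float(max(np.mean(dup - background), 0.0))


def quantify_panel(panel: pd.DataFrame, neg_label: str = "NEG") -> pd.DataFrame:
    """Per-replicate analyte levels from a tidy duplicate-spot panel.

    ``panel`` has columns replicate_id, group, analyte, spot1, spot2; rows
    with ``analyte == neg_label`` are the negative-control spots of that
    replicate array. Returns a tidy table (replicate_id, group, analyte,
    level).
    """
    required = {"replicate_id", "group", "analyte", "spot1", "spot2"}
    if not required <= set(panel.columns):
        raise ValueError(f"panel lacks columns {sorted(required - set(panel.columns))}")
    rows = []
    for rep_id, sub in panel.groupby("replicate_id", sort=False):
        negs = sub[sub["analyte"] == neg_label][["spot1", "spot2"]].to_numpy().ravel()
        if negs.size < 2:
            raise ValueError(f"replicate {rep_id!r} has <2 negative-control spots")
        group = sub["group"].iloc[0]
        for _, r in sub[sub["analyte"] != neg_label].iterrows():
            rows.append(
                {
                    "replicate_id": rep_id,
                    "group": group,
                    "analyte": r["analyte"],
                    "level": spot_level((r["spot1"], r["spot2"]), negs),
                }
            )
    return pd.DataFrame(rows)


def group_compare(
    levels_by_group: dict[str, np.ndarray],
    test: str = "t",
    control_group: str | None = None,
    welch: bool = False,
) -> dict:
    """Fold-change and significance test across replicate groups.

    ``test`` is ``"t"`` (pooled-variance two-tailed Student's t, exactly two
    groups; Welch with ``welch=True``) or ``"anova"`` (one-way F, >=2
    groups). Fold-change is mean(other)/mean(control); with both means zero
    it is NaN with an ``undefined`` flag, with a zero control mean it is
    reported as infinity.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in levels_by_group.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has <2 replicates")
    names = list(groups)
    if control_group is None:
        control_group = names[0]
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly two groups")
        other = [g for g in names if g != control_group][0]
        stat, p = stats.ttest_ind(
            groups[other], groups[control_group], equal_var=not welch
        )
    elif test == "anova":
        stat, p = stats.f_oneway(*groups.values())
        other = [g for g in names if g != control_group][0]
    else:
        raise ValueError(f"unknown test {test!r}")

    mc = groups[control_group].mean()
    mt = groups[other].mean()
    undefined = mc == 0 and mt == 0
    if undefined:
        fc = np.nan
    elif mc == 0:
        fc = np.inf
    else:
        fc = mt / mc
    return {
        "statistic": float(stat),
        "pvalue": float(p),
        "fold_change": float(fc),
        "undefined_fold_change": undefined,
        "control_group": control_group,
        "comparison_group": other,
        "test": test,
    }


def compare_panel(
    levels: pd.DataFrame, control_group: str, test: str = "t"
) -> pd.DataFrame:
    """Per-analyte group comparison of quantified array levels."""
    rows = []
    for analyte, sub in levels.groupby("analyte", sort=False):
        by_group = {
            g: s["level"].to_numpy() for g, s in sub.groupby("group", sort=False)
        }
        res = group_compare(by_group, test=test, control_group=control_group)
        res["analyte"] = analyte
        rows.append(res)
    return pd.DataFrame(rows)


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str = "GAPDH",
    calibrator_group: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Comparative-Ct (2^-ddCt) relative expression.

    ``table`` is tidy qPCR data (sample_id, group, gene, ct). Per sample,
    dCt = Ct_target - Ct_reference; ddCt subtracts the calibrator group's
    mean dCt; relative expression is 2**(-ddCt). Samples missing either Ct
    are dropped with a warning. Returns (per-sample table, per-group
    mean +/- SEM summary).
    """
    wide = table.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct", aggfunc="mean"
    ).reset_index()
    for gene in (target, reference):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    missing = wide[[target, reference]].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} sample(s) with missing Ct",
            stacklevel=2,
        )
        wide = wide[~missing]
    if calibrator_group is None:
        calibrator_group = wide["group"].iloc[0]
    if not (wide["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")

    wide = wide.copy()
    wide["dct"] = wide[target] - wide[reference]
    cal_mean = wide.loc[wide["group"] == calibrator_group, "dct"].mean()
    wide["ddct"] = wide["dct"] - cal_mean
    wide["rel_expr"] = 2.0 ** (-wide["ddct"])

    summary = (
        wide.groupby("group", sort=False)["rel_expr"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    per_sample = wide[["sample_id", "group", "dct", "ddct", "rel_expr"]]
    return per_sample, summary
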