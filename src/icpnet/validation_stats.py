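"""Validation-arm statistics: ΔΔCt relative quantification and morphometry.

qPCR fold changes use the classical 2^−ΔΔCt model (amplification
efficiency fixed at 2 per cycle): per individual, ΔCt = mean Ct(target) −
mean Ct(reference) over the triplicate, and the fold change is
2^−(ΔCt − mean ΔCt of the calibrator group), so the calibrator group's
geometric-mean fold is exactly 1.  Group comparisons use one-way ANOVA
with Dunnett many-to-one post-tests against the control group, run on the
ΔCt scale (closer to normal than the fold scale).

Morphometry: capillaries per villus is the ratio of total capillaries to
total terminal villi over a placenta's 50 fields (ratio of totals, not a
mean of per-field ratios); immune-cell burden is the mean count per field
per placenta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MARKERS = ("cd45", "cd3", "cd19")

#: Fixed stream for the multivariate-t integration inside the Dunnett test;
#: keeps the adjusted p-values reproducible run to run.
_DUNNETT_SEED = 845216


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------


@dataclass
class DdctResult:
    per_individual: pd.DataFrame  # individual, group, gene, delta_ct, fold
    per_group: pd.DataFrame  # gene, group, mean_fold, sd_fold, n
    anova: dict  # gene -> AnovaDunnettResult (on the ΔCt scale)


def ddct_fold_change(
    records: pd.DataFrame,
    reference_gene: str = "GAPDH",
    calibrator_group: str = "healthy",
    run_anova: bool = True,
    control_group: str | None = None,
) -> DdctResult:
    """Relative expression per individual and per group via 2^−ΔΔCt.

    ``records`` columns: individual, group, gene, replicate, ct (three
    replicates per individual and gene).  The reference gene must be
    measured for every individual.
    """
    mean_ct = (
        records.groupby(["individual", "group", "gene"], sort=True)["ct"]
        .agg(["mean", "count"])
        .reset_index()
    )
    if not (mean_ct["count"] == 3).all():
        bad = mean_ct.loc[mean_ct["count"] != 3]
        raise ValueError(
            f"expected 3 Ct replicates per (individual, gene); first offender: "
            f"{bad.iloc[0]['individual']}/{bad.iloc[0]['gene']}"
        )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("individual")["mean"]
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    missing = sorted(set(targets["individual"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for individual(s) {missing[:5]}"
        )
    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        delta_ct = sub["mean"].to_numpy() - ref.loc[sub["individual"]].to_numpy()
        sub = sub.assign(delta_ct=delta_ct)
        calib = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if calib.empty:
            raise ValueError(f"no calibrator-group ({calibrator_group!r}) records for {gene!r}")
        fold = np.power(2.0, -(delta_ct - calib.mean()))
        rows.append(sub.assign(fold=fold))
    per_individual = (
        pd.concat(rows, ignore_index=True)[
            ["individual", "group", "gene", "delta_ct", "fold"]
        ]
        if rows
        else pd.DataFrame(columns=["individual", "group", "gene", "delta_ct", "fold"])
    )
    per_group = (
        per_individual.groupby(["gene", "group"], sort=True)["fold"]
        .agg(mean_fold="mean", sd_fold="std", n="count")
        .reset_index()
    )
    anova = {}
    if run_anova and not per_individual.empty:
        control = calibrator_group if control_group is None else control_group
        for gene, sub in per_individual.groupby("gene", sort=True):
            by_group = {
                g: s["delta_ct"].to_numpy() for g, s in sub.groupby("group", sort=True)
            }
            anova[gene] = anova_dunnett(by_group, control)
    return DdctResult(per_individual=per_individual, per_group=per_group, anova=anova)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett
# ---------------------------------------------------------------------------


@dataclass
class AnovaDunnettResult:
    f_stat: float
    p_value: float
    comparisons: dict[str, float]  # group -> Dunnett-adjusted p vs control

    def stars(self) -> dict[str, str]:
        return {g: significance_stars(p) for g, p in self.comparisons.items()}


def anova_dunnett(values_by_group: dict, control_group: str) -> AnovaDunnettResult:
    """One-way ANOVA F test plus Dunnett many-to-one comparisons.

    The family-wise Dunnett adjustment integrates the multivariate-t
    distribution numerically (fixed internal seed, so results are
    deterministic to the integrator's tolerance, about 1e-3 on p).
    """
    if control_group not in values_by_group:
        raise ValueError(f"control group {control_group!r} not among groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(v.var(ddof=1) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in every group; ANOVA undefined")
    samples = list(groups.values())
    means = [v.mean() for v in samples]
    if np.ptp(means) == 0:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = stats.f_oneway(*samples)
    treat_names = [g for g in sorted(groups) if g != control_group]
    res = stats.dunnett(
        *[groups[g] for g in treat_names],
        control=groups[control_group],
        alternative="two-sided",
        rng=np.random.default_rng(_DUNNETT_SEED),
    )
    comparisons = {g: float(p) for g, p in zip(treat_names, res.pvalue)}
    return AnovaDunnettResult(
        f_stat=float(f_stat), p_value=float(p_value), comparisons=comparisons
    )


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------


@dataclass
class MorphometryResult:
    per_placenta: pd.DataFrame  # placenta, group, value
    per_group: pd.DataFrame  # group, mean, sd, n
    anova: AnovaDunnettResult | None
    excluded: list[str]


def _summarize(
    per_placenta: pd.DataFrame, control_group: str, run_anova: bool
) -> MorphometryResult:
    per_group = (
        per_placenta.groupby("group", sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    anova = None
    if run_anova:
        by_group = {
            g: s["value"].to_numpy() for g, s in per_placenta.groupby("group", sort=True)
        }
        anova = anova_dunnett(by_group, control_group)
    return MorphometryResult(
        per_placenta=per_placenta, per_group=per_group, anova=anova, excluded=[]
    )


def capillaries_per_villus(
    records: pd.DataFrame, control_group: str = "healthy", run_anova: bool = True
) -> MorphometryResult:
    """Σ capillaries / Σ terminal villi over each placenta's fields.

    Placentas with zero total villi are excluded with a warning.
    """
    totals = records.groupby(["placenta", "group"], sort=True)[
        ["capillaries", "villi"]
    ].sum().reset_index()
    zero = totals["villi"] == 0
    excluded = sorted(totals.loc[zero, "placenta"])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} placenta(s) with zero total villi: "
            f"{excluded[:5]}",
            stacklevel=2,
        )
    kept = totals[~zero]
    per_placenta = kept.assign(value=kept["capillaries"] / kept["villi"])[
        ["placenta", "group", "value"]
    ]
    result = _summarize(per_placenta, control_group, run_anova)
    result.excluded = excluded
    return result


def mean_cells_per_field(
    records: pd.DataFrame,
    marker: str,
    control_group: str = "healthy",
    run_anova: bool = True,
) -> MorphometryResult:
    """Arithmetic mean count per field for one immune marker, per placenta."""
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    per_placenta = (
        records.groupby(["placenta", "group"], sort=True)[marker]
        .mean()
        .reset_index()
        .rename(columns={marker: "value"})
    )
    return _summarize(per_placenta, control_group, run_anova)
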