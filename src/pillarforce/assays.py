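"""Levamisole paralysis time-courses and plate respirometry (OCR) analysis.

Levamisole, a cholinergic agonist, paralyzes worms with intact postsynaptic
excitation-contraction coupling; resistant strains paralyze more slowly.
Cohorts are scored every 10 minutes, and observation stops at the first
scored time by which every reference-strain worm is paralyzed.  Curves are
compared with a two-way repeated-measures (split-plot) ANOVA: worm as
subject, strain as the between factor, time as the within factor.

Oxygen consumption rate (OCR) runs follow the standard three-phase plate
protocol: basal cycles, maximal cycles after FCCP uncoupling, and
non-mitochondrial cycles after sodium azide (plan 5/9/5).  To avoid unstable
transitions, only the final 3 / 7 / 2 cycles of each phase enter statistics.
Per-well phase values are means of retained cycles normalized to worms per
well; spare respiratory capacity is maximal minus basal (reported even when
negative).  Strains/conditions are compared by one-way ANOVA with Tukey's
multiple-comparison test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ALPHA, MixedAnovaResult, OneWayAnovaResult, mixed_design_anova, one_way_anova
from .synthetic import OCRRun, OCRWell, ParalysisCohort

__all__ = [
    "ParalysisResult",
    "paralysis_curve",
    "DEFAULT_RETENTION",
    "select_ocr_cycles",
    "OCRSummary",
    "summarize_ocr",
    "ocr_group_test",
    "ContrastResult",
    "prednisone_contrast",
]


# ---------------------------------------------------------------------------
# Levamisole paralysis


@dataclass
class ParalysisResult:
    """Paralysis fractions on the scored grid, truncated at the stop time."""

    times_min: np.ndarray
    fractions: dict  # label -> fraction paralyzed per scored time
    n_per_cohort: dict
    stop_time_min: float | None  # first time all reference worms paralyzed
    open_ended: bool  # reference never fully paralyzed within horizon
    anova: MixedAnovaResult | None

    def __post_init__(self) -> None:
        for label, frac in self.fractions.items():
            frac = np.asarray(frac)
            if np.any(frac < 0) or np.any(frac > 1):
                raise ValueError(f"fractions out of [0, 1] for {label}")
            if np.any(np.diff(frac) < 0):
                raise ValueError(f"paralysis fractions must be non-decreasing ({label})")


def paralysis_curve(
    cohort: ParalysisCohort,
    reference: ParalysisCohort,
    horizon_min: float = 360.0,
    with_anova: bool = True,
) -> ParalysisResult:
    """Score both cohorts on the common 10-min grid up to reference saturation.

    Scoring stops at the first grid time at which the reference cohort is
    fully paralyzed; if that never happens within ``horizon_min`` the result
    is flagged open-ended and the full horizon is reported.
    """
    if cohort.score_interval_min != reference.score_interval_min:
        raise ValueError("cohorts must be scored on the same grid")
    dt = reference.score_interval_min
    grid = np.arange(dt, horizon_min + 0.5 * dt, dt)
    ref_counts = reference.counts_at(grid)
    full = np.flatnonzero(ref_counts == reference.n_worms)
    if len(full):
        stop_idx = int(full[0])
        grid = grid[: stop_idx + 1]
        stop_time = float(grid[-1])
        open_ended = False
    else:
        stop_time = None
        open_ended = True

    labels = [cohort.label or "test", reference.label or "reference"]
    fractions = {
        labels[0]: cohort.fractions_at(grid),
        labels[1]: reference.fractions_at(grid),
    }
    anova = None
    if with_anova and cohort.n_worms == reference.n_worms and len(grid) >= 2:
        status = {
            labels[0]: (cohort.latent_times_min[:, None] <= grid[None, :]).astype(float),
            labels[1]: (reference.latent_times_min[:, None] <= grid[None, :]).astype(float),
        }
        anova = mixed_design_anova(status)
    return ParalysisResult(
        times_min=grid,
        fractions=fractions,
        n_per_cohort={labels[0]: cohort.n_worms, labels[1]: reference.n_worms},
        stop_time_min=stop_time,
        open_ended=open_ended,
        anova=anova,
    )


# ---------------------------------------------------------------------------
# OCR cycle selection and summary


DEFAULT_RETENTION = (3, 7, 2)  # final basal / maximal / non-mito cycles kept
_PHASE_ORDER = ("basal", "maximal", "nonmito")


def select_ocr_cycles(run: OCRRun, retain: tuple[int, int, int] = DEFAULT_RETENTION) -> OCRRun:
    """Keep only the final ``retain`` cycles of each phase in each well.

    Order-preserving and idempotent: applying the selection to an already
    selected run is a no-op.  A phase shorter than its retention count is an
    error naming the phase.
    """
    new_wells = []
    for well in run.wells:
        phases = np.asarray(well.phases)
        keep = np.zeros(len(phases), dtype=bool)
        for phase, n_keep in zip(_PHASE_ORDER, retain):
            idx = np.flatnonzero(phases == phase)
            if len(idx) < n_keep:
                raise ValueError(
                    f"phase {phase!r} has {len(idx)} cycles, cannot retain {n_keep}"
                )
            keep[idx[-n_keep:]] = True
        new_wells.append(
            OCRWell(
                label=well.label,
                worms_per_well=well.worms_per_well,
                values=well.values[keep],
                phases=tuple(phases[keep]),
            )
        )
    return OCRRun(wells=tuple(new_wells), plan=tuple(retain))


@dataclass
class OCRSummary:
    """Per-well normalized phase values and per-group mean/s.e.m./n."""

    wells: pd.DataFrame  # label, well, basal, maximal, nonmito, spare, mito_basal
    groups: pd.DataFrame  # label, metric, mean, sem, n


def summarize_ocr(
    run: OCRRun,
    retain: tuple[int, int, int] = DEFAULT_RETENTION,
) -> OCRSummary:
    """Per-well phase values: mean of retained cycles / worms per well.

    Spare capacity = maximal - basal; mitochondrial basal = basal - nonmito
    is carried as a secondary column.  Values may be negative and are
    reported as computed.
    """
    selected = select_ocr_cycles(run, retain)
    rows = []
    for i, well in enumerate(selected.wells):
        phases = np.asarray(well.phases)
        vals = {}
        for phase in _PHASE_ORDER:
            vals[phase] = float(
                well.values[phases == phase].mean() / well.worms_per_well
            )
        rows.append(
            {
                "label": well.label,
                "well": i,
                "basal": vals["basal"],
                "maximal": vals["maximal"],
                "nonmito": vals["nonmito"],
                "spare": vals["maximal"] - vals["basal"],
                "mito_basal": vals["basal"] - vals["nonmito"],
            }
        )
    wells = pd.DataFrame(rows)
    metrics = ["basal", "maximal", "nonmito", "spare", "mito_basal"]
    groups = (
        wells.melt(id_vars="label", value_vars=metrics, var_name="metric")
        .groupby(["label", "metric"])["value"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return OCRSummary(wells=wells, groups=groups)


def ocr_group_test(summary: OCRSummary, metric: str = "basal") -> OneWayAnovaResult:
    """One-way ANOVA with Tukey HSD across labels for one OCR metric."""
    groups = {
        label: grp[metric].to_numpy() for label, grp in summary.wells.groupby("label")
    }
    return one_way_anova(groups, with_tukey=True)


# ---------------------------------------------------------------------------
# Drug-rescue contrast


@dataclass
class ContrastResult:
    anova: OneWayAnovaResult | None
    rescue: bool | None  # None when the design cannot decide rescue
    mutant_vs_reference_p: float | None
    treated_vs_reference_p: float | None
    note: str = ""


def prednisone_contrast(
    summary: OCRSummary,
    reference: str,
    mutant: str,
    treated: str,
    metric: str = "basal",
) -> ContrastResult:
    """Rescue test across {reference, mutant, mutant+drug} well groups.

    Rescue is declared when the mutant differs from the reference (Tukey
    adjusted p < alpha) while the treated group does not.  With fewer than
    three groups present, falls back to a plain pairwise comparison and
    leaves the rescue verdict undecided.
    """
    present = [
        g for g in (reference, mutant, treated) if g in set(summary.wells["label"])
    ]
    groups = {
        label: grp[metric].to_numpy()
        for label, grp in summary.wells.groupby("label")
        if label in present
    }
    if len(groups) < 3:
        if len(groups) == 2:
            from .stats import welch_ttest

            a, b = (groups[g] for g in groups)
            res = welch_ttest(a, b)
            return ContrastResult(
                anova=None,
                rescue=None,
                mutant_vs_reference_p=res.p_value,
                treated_vs_reference_p=None,
                note="fewer than 3 groups; plain pairwise comparison reported",
            )
        raise ValueError("need at least 2 groups")

    anova = one_way_anova(groups, with_tukey=True)
    tk = anova.tukey

    def pair_p(a, b):
        row = tk[
            ((tk["group1"] == a) & (tk["group2"] == b))
            | ((tk["group1"] == b) & (tk["group2"] == a))
        ]
        return float(row["p_adj"].iloc[0])

    p_mut = pair_p(reference, mutant)
    p_trt = pair_p(reference, treated)
    rescue = (p_mut < ALPHA) and (p_trt >= ALPHA)
    return ContrastResult(
        anova=anova,
        rescue=rescue,
        mutant_vs_reference_p=p_mut,
        treated_vs_reference_p=p_trt,
    )
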