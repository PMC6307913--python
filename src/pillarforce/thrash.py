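"""Body-bend counting and aggregation for the thrashing (swim) assay.

A worm dropped into buffer thrashes side to side; one body bend is one full
cycle — a rightward bend followed by a leftward bend.  Counting is automated
with hysteresis-thresholded sign changes of the head-bend angle: a bend is
scored when the angle rises above ``+h`` and subsequently falls below ``-h``,
with ``h`` a fixed fraction (default 20%) of the series' amplitude envelope.
The hysteresis band prevents noise-driven double counting near zero
crossings; partial cycles (a rightward excursion with no leftward return) do
not count, matching manual scoring conventions.

The assay design is 10 worms x 5 repeated 10-s windows x 3 biological
replicates = 150 records per condition; bars are means with s.e.m. over all
records, compared pairwise with Welch t-tests, or with a two-way ANOVA
(strain x temperature) plus Tukey contrasts for the temperature-sensitivity
design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import tukey_hsd, welch_ttest
from .synthetic import ThrashSeries, gen_thrash_series

__all__ = [
    "count_bends",
    "ThrashDesign",
    "simulate_thrash_table",
    "aggregate_thrash",
    "TemperatureContrast",
    "temperature_contrast",
]

DEFAULT_HYSTERESIS_FRAC = 0.2
DEFAULT_SMOOTH_S = 1.0 / 6.0


def count_bends(
    series,
    window_s: float = 10.0,
    hysteresis_frac: float = DEFAULT_HYSTERESIS_FRAC,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> int:
    """Number of completed body bends in the first ``window_s`` seconds.

    ``series`` is a :class:`ThrashSeries` or a ``(time_s, angle_rad)`` pair.
    The angle is lightly smoothed (moving average over ``smooth_s``), the
    hysteresis band is ``hysteresis_frac`` of the smoothed amplitude
    envelope, and a bend is one +band excursion followed by one -band
    excursion.  A flat series, or one that never leaves the band, scores 0.
    """
    if isinstance(series, ThrashSeries):
        t, angle = series.time_s, series.angle_rad
    else:
        t, angle = series
    t = np.asarray(t, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if len(t) < 2:
        raise ValueError("series too short")
    dt = t[1] - t[0]
    if t[-1] - t[0] + dt < window_s - 1e-9:
        raise ValueError(
            f"series covers {t[-1] - t[0] + dt:.2f} s, shorter than the "
            f"{window_s} s window"
        )
    n_win = int(round(window_s / dt))
    x = angle[:n_win]

    if smooth_s > 0:
        k = max(int(round(smooth_s / dt)), 1)
        if k > 1:
            kernel = np.ones(k) / k
            x = np.convolve(x, kernel, mode="same")

    envelope = np.max(np.abs(x))
    if envelope == 0:
        return 0
    h = hysteresis_frac * envelope

    bends = 0
    state = "seek_up"
    for v in x:
        if state == "seek_up" and v > h:
            state = "seek_down"
        elif state == "seek_down" and v < -h:
            bends += 1
            state = "seek_up"
    return bends


# ---------------------------------------------------------------------------
# Design aggregation


@dataclass(frozen=True)
class ThrashDesign:
    """The assay's sampling design (defaults: 10 x 5 x 3 = 150 per bar)."""

    n_worms: int = 10
    repeats: int = 5
    replicates: int = 3

    @property
    def records_per_condition(self) -> int:
        return self.n_worms * self.repeats * self.replicates


def simulate_thrash_table(
    conditions: list[dict],
    design: ThrashDesign = ThrashDesign(),
    worm_sd_hz: float = 0.2,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the full assay table by generating and counting angle series.

    ``conditions`` is a list of dicts each holding a ``frequency_hz`` entry
    plus arbitrary metadata columns (strain, treatment, day, temperature...).
    Per worm a frequency offset ~ N(0, worm_sd_hz) models between-animal
    variability; each 10-s repeat is an independently noised series counted
    with :func:`count_bends`.
    """
    root = np.random.SeedSequence([int(seed), 606])
    streams = root.spawn(len(conditions))
    rows = []
    for cond, stream in zip(conditions, streams):
        meta = {k: v for k, v in cond.items() if k != "frequency_hz"}
        f0 = cond["frequency_hz"]
        rng = np.random.default_rng(stream)
        for rep in range(design.replicates):
            for worm in range(design.n_worms):
                f_worm = max(f0 + rng.normal(0.0, worm_sd_hz), 0.0) if worm_sd_hz else f0
                for repeat in range(design.repeats):
                    sub = int(rng.integers(0, 2**31 - 1))
                    ts = gen_thrash_series(
                        f_worm, duration_s=10.0, noise_sigma=noise_sigma, seed=sub
                    )
                    rows.append(
                        {
                            **meta,
                            "replicate": rep + 1,
                            "worm_id": f"w{rep + 1}-{worm + 1}",
                            "repeat": repeat + 1,
                            "count": count_bends(ts),
                        }
                    )
    return pd.DataFrame(rows)


def aggregate_thrash(
    table: pd.DataFrame,
    design: ThrashDesign = ThrashDesign(),
    by: tuple[str, ...] = ("strain", "treatment", "day"),
) -> pd.DataFrame:
    """Per-condition mean, s.e.m. and record count over all design records.

    Every condition must carry the complete design
    (``n_worms * repeats * replicates`` records); incomplete cells raise an
    explicit error listing them rather than being silently dropped.
    """
    keys = [k for k in by if k in table.columns]
    if not keys:
        raise ValueError("no grouping columns present in the table")
    expected = design.records_per_condition
    counts = table.groupby(keys, sort=True).size()
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(
            "incomplete design: expected "
            f"{expected} records per condition, got {bad.to_dict()}"
        )
    out = (
        table.groupby(keys, sort=True)["count"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
            n="count",
        )
        .reset_index()
    )
    return out


def thrash_pairwise(table: pd.DataFrame, key: str, a, b, value: str = "count"):
    """Welch t-test between two condition levels of ``key``."""
    return welch_ttest(
        table.loc[table[key] == a, value], table.loc[table[key] == b, value]
    )


# ---------------------------------------------------------------------------
# Temperature-sensitivity contrast


@dataclass(frozen=True)
class TemperatureContrast:
    anova: pd.DataFrame  # two-way ANOVA table (type II SS)
    interaction_p: float
    temperature_effect: float  # mean(25C) - mean(20C), all strains pooled
    tukey: pd.DataFrame  # Tukey HSD across strain x temperature cells


def temperature_contrast(table: pd.DataFrame) -> TemperatureContrast:
    """Two-way ANOVA (strain x temperature) with Tukey-adjusted contrasts.

    ``table`` needs columns ``strain``, ``temperature`` and ``count`` and at
    least two levels of each factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("strain", "temperature", "count"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["strain"].nunique() < 2 or table["temperature"].nunique() < 2:
        raise ValueError("both factors need at least two levels")

    model = smf.ols("count ~ C(strain) * C(temperature)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    interaction_row = [i for i in anova.index if ":" in i][0]
    interaction_p = float(anova.loc[interaction_row, "PR(>F)"])

    temps = sorted(table["temperature"].unique())
    temp_effect = float(
        table.loc[table["temperature"] == temps[-1], "count"].mean()
        - table.loc[table["temperature"] == temps[0], "count"].mean()
    )
    cells = {
        f"{s}@{t}": grp["count"].to_numpy()
        for (s, t), grp in table.groupby(["strain", "temperature"])
    }
    return TemperatureContrast(
        anova=anova,
        interaction_p=interaction_p,
        temperature_effect=temp_effect,
        tukey=tukey_hsd(cells),
    )
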