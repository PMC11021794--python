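"""Per-cell growth rates, population growth timeseries, lysis frequencies,
and replicate-level comparisons.

A cell's elongation rate is the OLS slope of log length against time over its
track (birth to terminal event), the standard single-cell proxy for growth
rate in mother-machine experiments.  Lysis frequency is the number of lysis
events per lineage per hour within an observation window.  Replicate-level
condition comparisons use Welch's t-test on per-replicate summaries: the
replicate, not the cell, is the unit of inference (cells within a device are
not independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthEstimate", "LysisSummary", "WelchResult",
    "elongation_rate", "cell_growth_estimates", "growth_timeseries",
    "window_rate_summary", "lysis_frequency", "compare_replicates",
]


@dataclass(frozen=True)
class GrowthEstimate:
    cell_id: str
    rate_per_min: float
    r_squared: float
    n_frames: int
    t_mid: float


@dataclass(frozen=True)
class LysisSummary:
    condition: str
    window_min: tuple[float, float]
    n_lineages: int
    n_events: int
    frequency: float        # events / lineage / h (the reported statistic)
    cell_hours: float       # total observed lineage-time in the window
    rate_per_cell_hour: float  # events / cell-hour: unbiased estimate of the
                               # underlying per-cell lysis rate

    def poisson_ci(self, level: float = 0.95):
        """Exact (Garwood) CI for the per-cell-hour lysis rate."""
        a = 1.0 - level
        k = self.n_events
        lo = 0.0 if k == 0 else stats.chi2.ppf(a / 2, 2 * k) / 2 / self.cell_hours
        hi = stats.chi2.ppf(1 - a / 2, 2 * k + 2) / 2 / self.cell_hours
        return lo, hi


@dataclass(frozen=True)
class WelchResult:
    difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: float
    p_value: float


def elongation_rate(times_min, lengths_um, cell_id: str = "") -> GrowthEstimate:
    """OLS slope of ln(length) vs time for one track segment.

    Requires >= 3 frames; lengths must be positive.  With zero residual
    variance (exact exponential input) r^2 is 1 by convention.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(lengths_um, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 frames to estimate an elongation rate")
    if np.any(y <= 0):
        raise ValueError("lengths must be positive")
    ly = np.log(y)
    res = stats.linregress(t, ly)
    r2 = 1.0 if np.allclose(ly, res.intercept + res.slope * t) else res.rvalue ** 2
    return GrowthEstimate(cell_id, float(res.slope), float(r2), len(t),
                          float(0.5 * (t[0] + t[-1])))


def cell_growth_estimates(observations: pd.DataFrame, assignments: pd.DataFrame,
                          split_times: tuple[float, ...] = (),
                          min_frames: int = 3) -> pd.DataFrame:
    """Per-cell elongation rates from tracked observations.

    ``assignments`` maps observation rows to cell ids (tracker or ground
    truth).  Tracks crossing any time in ``split_times`` (typically the
    treatment boundaries) are split there, so each estimate reflects a single
    treatment regime.  Segments with fewer than ``min_frames`` frames are
    dropped.  Returns a tidy frame: cell_id, segment, t_mid, rate_per_min,
    r_squared, n_frames.
    """
    merged = observations.merge(assignments, on=["trench_id", "frame", "rank"])
    edges = sorted(split_times)

    def segment_of(t: float) -> int:
        return int(np.searchsorted(edges, t, side="right"))

    merged = merged.assign(segment=merged["time_min"].map(segment_of))
    rows = []
    for (cid, seg), g in merged.groupby(["cell_id", "segment"], sort=False):
        if len(g) < min_frames:
            continue
        est = elongation_rate(g["time_min"], g["length_um"], cid)
        rows.append((cid, seg, est.t_mid, est.rate_per_min, est.r_squared,
                     est.n_frames))
    return pd.DataFrame(rows, columns=["cell_id", "segment", "t_mid",
                                       "rate_per_min", "r_squared", "n_frames"])


def growth_timeseries(estimates: pd.DataFrame, window_width: float = 20.0,
                      t_grid=None) -> pd.DataFrame:
    """Sliding-window mean and s.d. of per-cell rates against time.

    Each estimate enters every window containing its mid-track time.  Empty
    windows yield NaN, not zero.  Returns time, mean_rate, sd_rate, n_cells.
    """
    if t_grid is None:
        lo, hi = estimates["t_mid"].min(), estimates["t_mid"].max()
        t_grid = np.arange(math.floor(lo), math.ceil(hi) + 1, window_width / 2)
    t_mid = estimates["t_mid"].to_numpy()
    rate = estimates["rate_per_min"].to_numpy()
    rows = []
    half = window_width / 2
    for t in np.asarray(t_grid, dtype=float):
        sel = (t_mid >= t - half) & (t_mid < t + half)
        if sel.sum() == 0:
            rows.append((t, np.nan, np.nan, 0))
        else:
            rows.append((t, float(rate[sel].mean()),
                         float(rate[sel].std(ddof=1)) if sel.sum() > 1 else np.nan,
                         int(sel.sum())))
    return pd.DataFrame(rows, columns=["time_min", "mean_rate", "sd_rate", "n_cells"])


def window_rate_summary(estimates: pd.DataFrame, window: tuple[float, float],
                        ) -> float:
    """Mean per-cell rate for estimates whose mid-time falls in ``window``
    (the per-replicate summary plotted for the 250-300 min comparison)."""
    lo, hi = window
    sel = estimates[(estimates["t_mid"] >= lo) & (estimates["t_mid"] <= hi)]
    if len(sel) == 0:
        raise ValueError(f"no growth estimates in window {window}")
    return float(sel["rate_per_min"].mean())


def lysis_frequency(lineage: pd.DataFrame, window: tuple[float, float],
                    frame_interval: float = 1.0, condition: str = "",
                    ) -> LysisSummary:
    """Lysis events per lineage per hour within a time window.

    A lineage is counted if it is alive at any point in the window; an event
    is counted when a lineage's fate is ``lysed`` and its disappearance time
    (one frame after it was last seen) falls inside the window.  The
    ``frequency`` denominator is lineages x window-hours; ``rate_per_cell_hour``
    divides instead by summed lineage-time in the window, which estimates the
    per-cell lysis rate directly.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive width")
    birth_t = lineage["birth_frame"].to_numpy() * frame_interval
    end_t = (lineage["last_frame"].to_numpy() + 1) * frame_interval
    alive = (birth_t < hi) & (end_t > lo)
    n_lineages = int(alive.sum())
    if n_lineages == 0:
        raise ValueError(f"no lineages alive in window {window}")
    lysed = (lineage["fate"].to_numpy() == "lysed") & (end_t >= lo) & (end_t < hi)
    n_events = int(lysed.sum())
    window_h = (hi - lo) / 60.0
    cell_hours = float(np.sum(np.minimum(end_t[alive], hi)
                              - np.maximum(birth_t[alive], lo))) / 60.0
    return LysisSummary(condition, (lo, hi), n_lineages, n_events,
                        n_events / (n_lineages * window_h), cell_hours,
                        n_events / cell_hours)


def compare_replicates(values_a, values_b) -> WelchResult:
    """Welch two-sample t-test on replicate-level summaries.

    Returns the mean difference (a - b), its confidence interval at 95%, the
    Welch t statistic, Welch-Satterthwaite degrees of freedom, and p-value.
    Identical groups give difference 0 and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    diff = float(a.mean() - b.mean())
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    df = float(res.df)
    if se == 0:
        return WelchResult(diff, diff, diff, float("nan"), df, 1.0)
    tcrit = stats.t.ppf(0.975, df)
    return WelchResult(diff, diff - tcrit * se, diff + tcrit * se,
                       float(res.statistic), df, float(res.pvalue))
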