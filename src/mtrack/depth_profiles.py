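"""Day/night time-at-depth analysis of PSAT binned summaries.

Pop-off archival tags transmit, per pre-programmed 3/6/12-h period, the
proportion of time spent in each of 12 depth bins plus an 8-point
depth–temperature profile.  This module flags periods day or night by solar
elevation, aggregates heterogeneous tag programmes onto a common bin set,
fills transmission gaps with a local-linear smoother, and compares
period-maximum depths between transiting and area-restricted behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import ModeSequence
from .capture_effects import PeriodContrast, rank_sum_contrast

logger = logging.getLogger(__name__)

#: common-bin default (m).  A documented package default — the common bin
#: set is tag-programme dependent and should be configured per data set.
DEFAULT_COMMON_BINS = (0.0, 1.0, 10.0, 50.0, 100.0, 200.0, 300.0, 2000.0)

TRANSIT_MODES = (1, 2)
ARB_MODES = (3, 4)


@dataclass(frozen=True)
class DepthSummary:
    """One binned time-at-depth record as a PSAT reports it."""
    animal_id: str
    period_start: pd.Timestamp
    period_hours: float            # 3, 6 or 12
    bin_edges: tuple               # 13 strictly increasing edges from 0 (m)
    proportions: tuple             # 12 proportions summing to 1

    def __post_init__(self):
        if self.period_hours not in (3.0, 6.0, 12.0, 3, 6, 12):
            raise ValueError("summary period must be 3, 6 or 12 hours")
        edges = np.asarray(self.bin_edges, float)
        if len(edges) != 13 or np.any(np.diff(edges) <= 0):
            raise ValueError("need 13 strictly increasing bin edges")
        p = np.asarray(self.proportions, float)
        if len(p) != 12 or np.any(p < -1e-12):
            raise ValueError("need 12 non-negative proportions")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {p.sum():.8f}, not 1")

    @property
    def period_end(self) -> pd.Timestamp:
        return self.period_start + pd.Timedelta(hours=float(self.period_hours))


@dataclass(frozen=True)
class PDTRecord:
    """8-point depth/mean-temperature profile for one summary period."""
    animal_id: str
    period_start: pd.Timestamp
    period_hours: float
    depths_m: tuple
    temps_c: tuple

    def __post_init__(self):
        d = np.asarray(self.depths_m, float)
        if len(d) != 8 or len(self.temps_c) != 8:
            raise ValueError("PDT records carry exactly 8 depth/temperature points")
        if np.any(np.diff(d) < 0):
            raise ValueError("PDT depths must be non-decreasing")


# ---------------------------------------------------------------------------
# solar day/night flag
# ---------------------------------------------------------------------------

def solar_elevation_deg(time_utc, lon, lat) -> float:
    """Solar elevation (degrees, geometric horizon, no refraction) at a UTC
    time and position, via the standard low-accuracy NOAA/Spencer series
    (declination and equation of time from the fractional-year Fourier
    expansion; accuracy well under 0.5 degrees)."""
    ts = pd.Timestamp(time_utc)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    doy = ts.dayofyear
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    lon180 = (float(lon) + 180.0) % 360.0 - 180.0
    tst = hour * 60.0 + eqtime + 4.0 * lon180          # true solar time, min
    ha = np.radians(tst / 4.0 - 180.0)                 # hour angle
    phi = np.radians(float(lat))
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


def day_night_flag(time_utc, lon, lat) -> str:
    """'day' iff the sun is above the geometric horizon at (lon, lat)."""
    return "day" if solar_elevation_deg(time_utc, lon, lat) > 0.0 else "night"


# ---------------------------------------------------------------------------
# aggregation onto common bins
# ---------------------------------------------------------------------------

def _map_to_common(summary: DepthSummary, common: np.ndarray) -> np.ndarray:
    """Fold a summary's 12 bins into the common bins by exact containment."""
    out = np.zeros(len(common) - 1)
    edges = np.asarray(summary.bin_edges, float)
    for b in range(12):
        lo, hi = edges[b], edges[b + 1]
        p = summary.proportions[b]
        if p == 0 and not np.any((common <= lo) & (lo < np.roll(common, -1))):
            continue
        # the common bin whose interval contains [lo, hi)
        j = int(np.searchsorted(common, lo, side="right")) - 1
        if j < 0 or j >= len(out) or hi > common[j + 1] + 1e-9:
            if p == 0:
                continue  # empty bins outside the common range are harmless
            raise ValueError(
                f"summary bin [{lo}, {hi}] m of {summary.animal_id} @ "
                f"{summary.period_start} straddles a common-bin edge"
            )
        out[j] += p
    return out


def aggregate_tad(summaries: list[DepthSummary], common_bins=DEFAULT_COMMON_BINS,
                  flags: list[str] | None = None) -> pd.DataFrame:
    """Time-weighted mean time-at-depth per day/night flag on common bins.

    ``flags`` gives 'day'/'night' per summary (default: all pooled under
    'all').  Each returned row is renormalized to sum to 1.
    """
    common = np.asarray(common_bins, float)
    if np.any(np.diff(common) <= 0):
        raise ValueError("common bins must be strictly increasing")
    if flags is None:
        flags = ["all"] * len(summaries)
    if len(flags) != len(summaries):
        raise ValueError("one flag per summary required")
    acc: dict[str, np.ndarray] = {}
    wsum: dict[str, float] = {}
    for s, f in zip(summaries, flags):
        v = _map_to_common(s, common)
        w = float(s.period_hours)
        acc[f] = acc.get(f, 0.0) + w * v
        wsum[f] = wsum.get(f, 0.0) + w
    rows = {}
    for f in acc:
        v = acc[f] / wsum[f]
        total = v.sum()
        rows[f] = v / total if total > 0 else v
    cols = [f"{common[i]:g}-{common[i+1]:g}m" for i in range(len(common) - 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def flag_summaries(summaries: list[DepthSummary], lon: float, lat: float) -> list[str]:
    """Day/night flag per summary from solar elevation at the period
    midpoint, at a representative position (e.g. the smoothed track
    location)."""
    out = []
    for s in summaries:
        mid = s.period_start + pd.Timedelta(hours=float(s.period_hours) / 2.0)
        out.append(day_night_flag(mid, lon, lat))
    return out


# ---------------------------------------------------------------------------
# gap interpolation
# ---------------------------------------------------------------------------

def _local_linear(t_obs, y_obs, t_eval, bandwidth):
    """Tricube-weighted local-linear fit evaluated at ``t_eval``."""
    out = np.empty(len(t_eval))
    for i, t0 in enumerate(t_eval):
        d = np.abs(t_obs - t0)
        h = max(bandwidth, np.partition(d, min(2, len(d) - 1))[min(2, len(d) - 1)] + 1e-9)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        if w.sum() <= 0:
            out[i] = np.nan
            continue
        W = w / w.sum()
        tb = np.sum(W * t_obs)
        yb = np.sum(W * y_obs)
        sxx = np.sum(W * (t_obs - tb) ** 2)
        slope = np.sum(W * (t_obs - tb) * (y_obs - yb)) / sxx if sxx > 1e-12 else 0.0
        out[i] = yb + slope * (t0 - tb)
    return out


def interpolate_gaps(series: pd.DataFrame, bandwidth_periods: float = 5.0):
    """Fill missing summary periods by per-bin local-linear smoothing.

    ``series``: rows indexed by period time (numeric, in periods or days),
    one column per depth bin, NaN rows/cells where the tag did not report.
    Filled rows are clipped to be non-negative and renormalized onto the
    simplex.  Returns ``(filled, was_missing)``; a bin observed in fewer
    than 2 periods is left empty and flagged.
    """
    t = series.index.to_numpy(float)
    filled = series.copy().astype(float)
    was_missing = series.isna()
    for col in series.columns:
        y = series[col].to_numpy(float)
        obs = np.isfinite(y)
        miss = ~obs
        if not miss.any():
            continue
        if obs.sum() < 2:
            logger.warning("bin %s observed in <2 periods; left empty", col)
            continue
        step = np.median(np.diff(np.sort(t))) if len(t) > 1 else 1.0
        filled.loc[miss, col] = _local_linear(
            t[obs], y[obs], t[miss], bandwidth_periods * step
        )
    vals = np.clip(filled.to_numpy(float), 0.0, None)
    sums = np.nansum(vals, axis=1)
    ok = sums > 0
    vals[ok] = vals[ok] / sums[ok, None]
    filled.iloc[:, :] = vals
    return filled, was_missing


# ---------------------------------------------------------------------------
# mode-conditioned maximum depth
# ---------------------------------------------------------------------------

def max_depth_by_mode(period_table: pd.DataFrame, modes: ModeSequence,
                      include_mode4: bool = True) -> PeriodContrast:
    """Rank-sum contrast of period-maximum depths, transiting vs ARB.

    ``period_table`` needs columns ``t_start, t_end, max_depth_m``; each
    period is assigned the behavioural class covering the majority of it
    (ties to transit).  ``include_mode4=False`` drops error-dominated
    fast-ARB periods from the ARB group.
    """
    step = modes.step_days
    mt = modes.df["t"].to_numpy(float)
    mm = modes.df["mode"].to_numpy()
    arb_set = ARB_MODES if include_mode4 else (3,)
    transit_depths, arb_depths = [], []
    for rec in period_table.itertuples(index=False):
        a, b = float(rec.t_start), float(rec.t_end)
        starts = np.maximum(mt, a)
        ends = np.minimum(mt + step, b)
        overlap = np.clip(ends - starts, 0.0, None)
        w_arb = overlap[np.isin(mm, arb_set)].sum()
        w_tr = overlap[np.isin(mm, TRANSIT_MODES)].sum()
        if w_arb == 0 and w_tr == 0:
            continue
        if w_arb > w_tr:
            arb_depths.append(rec.max_depth_m)
        else:
            transit_depths.append(rec.max_depth_m)  # ties -> transit
    if not transit_depths or not arb_depths:
        raise ValueError("one behaviour group has no depth periods")
    return rank_sum_contrast(np.asarray(transit_depths), np.asarray(arb_depths))
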