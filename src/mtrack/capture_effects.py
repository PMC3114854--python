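"""Post-release (capture/tagging) effect analyses.

Tagged animals often behave atypically immediately after release.  This
module quantifies that alteration from classified trajectories:

* time from release to the first area-restricted-behaviour (ARB) step,
  summarized by a Kaplan–Meier product-limit curve with Greenwood variance
  and log–log confidence bands, and its 50:50 crossing day;
* early-vs-late movement contrasts (e.g. travel speed in the first 10 days
  against all later days) via the Wilcoxon rank-sum test with a
  Hodges–Lehmann location-shift estimate;
* northward alignment of early headings;
* seasonal return-to-capture classification (did the animal circle back to
  within a radius of its release point, split by early/late-season tagging).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .behavior import ModeSequence, StepSeries
from .core_data import haversine_km
from .ctcrw import RegularTrack

logger = logging.getLogger(__name__)

ARB_MODES = (3, 4)


# ---------------------------------------------------------------------------
# time to first ARB
# ---------------------------------------------------------------------------

def first_arb_times(sequences: dict[str, ModeSequence],
                    include_mode4: bool = True) -> pd.DataFrame:
    """Per-animal first-ARB event table.

    The event is the start time of the first classified ARB step (modes 3
    and 4, or mode 3 only when ``include_mode4`` is False); animals that
    never enter ARB are right-censored at their last classified step.
    Returns columns ``animal_id, time, observed``.
    """
    arb_set = ARB_MODES if include_mode4 else (3,)
    rows = []
    for aid, seq in sequences.items():
        df = seq.df[seq.df["mode"] != 0]
        if df.empty:
            logger.warning("animal %s has no classified steps; excluded", aid)
            continue
        hit = df[df["mode"].isin(arb_set)]
        if len(hit):
            rows.append((aid, float(hit["t"].iloc[0]), True))
        else:
            rows.append((aid, float(df["t"].iloc[-1] + seq.step_days), False))
    return pd.DataFrame(rows, columns=["animal_id", "time", "observed"])


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log–log 95% CI."""
    times: np.ndarray        # event-time grid (days)
    survival: np.ndarray     # S(t), non-increasing, S(0)=1 implied
    variance: np.ndarray     # Greenwood
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray


def km_estimator(events: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier estimate of the time-to-first-ARB distribution.

    ``events`` needs ``time`` and ``observed`` columns; times must be
    non-negative.  The survival estimate comes from the product-limit
    formula; Greenwood's formula gives the variance and the 95% CI is on the
    log(-log S) scale, clipped to [0, 1].
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    t = events["time"].to_numpy(float)
    if np.any(t < 0):
        raise ValueError("negative event times")
    obs = events["observed"].to_numpy(bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=obs)
    table = kmf.event_table  # indexed by time: removed, observed, censored, at_risk
    times = table.index.to_numpy(float)
    d = table["observed"].to_numpy(float)
    n = table["at_risk"].to_numpy(float)
    c = table["censored"].to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy(float)
    # Greenwood: Var[S] = S^2 * sum d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
        gw = surv**2 * np.cumsum(terms)
        # log-log (complementary log-log) interval
        se_loglog = np.sqrt(np.cumsum(terms)) / np.abs(np.log(np.where(surv > 0, surv, np.nan)))
        z = stats.norm.ppf(0.975)
        lo = surv ** np.exp(z * se_loglog)
        hi = surv ** np.exp(-z * se_loglog)
    lo = np.where(surv <= 0, 0.0, np.where(np.isfinite(lo), lo, np.where(surv >= 1, 1.0, np.nan)))
    hi = np.where(surv <= 0, 0.0, np.where(np.isfinite(hi), hi, 1.0))
    return KMCurve(
        times=times, survival=surv, variance=np.nan_to_num(gw),
        ci_lower=np.clip(np.nan_to_num(lo, nan=1.0), 0.0, 1.0),
        ci_upper=np.clip(np.nan_to_num(hi, nan=1.0), 0.0, 1.0),
        at_risk=n, events=d, censored=c,
    )


def median_crossing(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5 (the 50:50 day), or None."""
    below = curve.survival <= 0.5
    if not below.any():
        return None
    return float(curve.times[np.argmax(below)])


# ---------------------------------------------------------------------------
# rank-based contrasts
# ---------------------------------------------------------------------------

@dataclass
class PeriodContrast:
    """Early-vs-late two-sample contrast."""
    early_stat: float        # early-window mean
    late_stat: float         # late-window mean
    statistic: float         # Mann-Whitney U (x vs y)
    p_value: float
    hl_shift: float          # Hodges-Lehmann estimate of x - y location shift
    n_early: int
    n_late: int


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.median(np.subtract.outer(x, y)))


def rank_sum_contrast(x, y) -> PeriodContrast:
    """Two-sided Wilcoxon rank-sum test with Hodges–Lehmann shift.

    Exact null distribution for small untied samples; otherwise the normal
    approximation with tie correction.  All values tied across both samples
    gives p = 1 and shift 0 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return PeriodContrast(float(x.mean()), float(y.mean()),
                              statistic=len(x) * len(y) / 2.0, p_value=1.0,
                              hl_shift=0.0, n_early=len(x), n_late=len(y))
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and min(len(x), len(y)) <= 25 and len(x) + len(y) <= 30) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return PeriodContrast(
        early_stat=float(x.mean()), late_stat=float(y.mean()),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        hl_shift=hodges_lehmann(x, y), n_early=len(x), n_late=len(y),
    )


def exact_rank_sum_p(x, y) -> float:
    """Brute-force two-sided rank-sum p by enumerating all rank assignments.

    Independent oracle for small samples (n + m <= ~12); not used by the
    analysis path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    nm = len(pooled)
    mean_u = n * (nm - n) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(nm), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def early_late_speed(steps: StepSeries | list[StepSeries],
                     split_days: float = 10.0) -> PeriodContrast:
    """Pooled-across-animals early (t < split) vs late (t >= split) speed
    contrast.  Speeds from low-confidence steps are excluded."""
    if isinstance(steps, StepSeries):
        steps = [steps]
    early, late = [], []
    for s in steps:
        df = s.df
        ok = np.isfinite(df["speed_kmh"].to_numpy(float))
        if "valid" in df:
            # the first step's speed is usable even though its turn is not;
            # only low-confidence positions disqualify a speed
            pass
        t = df["t"].to_numpy(float)[ok]
        v = df["speed_kmh"].to_numpy(float)[ok]
        early.append(v[t < split_days])
        late.append(v[t >= split_days])
    early = np.concatenate(early) if early else np.array([])
    late = np.concatenate(late) if late else np.array([])
    if len(early) < 2:
        raise ValueError("early window is empty or too small (check split_days)")
    if len(late) < 2:
        raise ValueError("late window is empty or too small")
    return rank_sum_contrast(early, late)


def early_late_turn(steps: StepSeries | list[StepSeries],
                    split_days: float = 10.0) -> PeriodContrast:
    """Early-vs-late contrast of absolute turning angles (radians)."""
    if isinstance(steps, StepSeries):
        steps = [steps]
    early, late = [], []
    for s in steps:
        df = s.df[s.df["valid"]]
        t = df["t"].to_numpy(float)
        a = np.abs(df["turn_rad"].to_numpy(float))
        early.append(a[t < split_days])
        late.append(a[t >= split_days])
    early = np.concatenate(early)
    late = np.concatenate(late)
    if len(early) < 2 or len(late) < 2:
        raise ValueError("a window is empty or too small")
    return rank_sum_contrast(early, late)


@dataclass
class HeadingAlignment:
    mean_northward: float    # mean of cos(bearing), +1 = due north
    t_statistic: float
    p_value: float
    n: int


def heading_alignment(steps: StepSeries | list[StepSeries],
                      window_days: float = 10.0) -> HeadingAlignment:
    """Mean northward component of step headings within the first
    ``window_days``, with a one-sample t-test against 0."""
    if isinstance(steps, StepSeries):
        steps = [steps]
    comp = []
    for s in steps:
        df = s.df
        ok = np.isfinite(df["heading_rad"].to_numpy(float))
        t = df["t"].to_numpy(float)[ok]
        h = df["heading_rad"].to_numpy(float)[ok]
        comp.append(np.cos(h[t < window_days]))
    comp = np.concatenate(comp) if comp else np.array([])
    if len(comp) < 5:
        raise ValueError("need at least 5 headings in the window")
    if np.ptp(comp) == 0:
        # degenerate: identical headings
        tt, p = np.inf if comp[0] != 0 else 0.0, 0.0 if comp[0] != 0 else 1.0
    else:
        tt, p = stats.ttest_1samp(comp, 0.0)
    return HeadingAlignment(float(comp.mean()), float(tt), float(p), len(comp))


# ---------------------------------------------------------------------------
# return-to-capture classification
# ---------------------------------------------------------------------------

@dataclass
class ReturnStatus:
    departed: bool
    returned: bool
    early_season: bool
    max_distance_km: float
    final_distance_km: float


def return_classifier(track: RegularTrack, release: tuple,
                      release_date=None, radius_km: float = 500.0,
                      departure_km: float = 100.0,
                      season_split: str = "03-01") -> ReturnStatus:
    """Did the animal leave the release vicinity and later circle back?

    ``departed``: distance from the release point exceeded ``departure_km``
    at some time.  ``returned``: after first exceeding ``departure_km``, the
    distance later fell back below ``radius_km``.  ``early_season``: release
    calendar date strictly before ``season_split`` (month-day, default
    1 March; the austral-summer tagging season convention).
    """
    lon = track.df["lon"].to_numpy(float)
    lat = track.df["lat"].to_numpy(float)
    dist = haversine_km((lon, lat), (np.full_like(lon, release[0]), np.full_like(lat, release[1])))
    beyond = dist > departure_km
    departed = bool(beyond.any())
    returned = False
    if departed:
        first = int(np.argmax(beyond))
        # must have been beyond the *return* radius before coming back when
        # the radius exceeds the departure threshold
        thresh = max(radius_km, departure_km)
        far = dist[first:] > thresh
        if far.any():
            first_far = first + int(np.argmax(far))
            returned = bool((dist[first_far:] < radius_km).any() and dist[first_far:].min() < radius_km)
        else:
            returned = False
    early = False
    if release_date is not None:
        rd = pd.Timestamp(release_date)
        sm, sd_ = (int(p) for p in season_split.split("-"))
        early = (rd.month, rd.day) < (sm, sd_)
    return ReturnStatus(
        departed=departed, returned=returned, early_season=early,
        max_distance_km=float(dist.max()), final_distance_km=float(dist[-1]),
    )
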