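"""Four-mode pseudo-behaviour classification of regularized 12-h steps.

Each 12-h step of a regularized track yields a speed (great-circle
displacement / 12 h) and a relative turning angle (signed difference of
consecutive bearings).  Speeds are modelled by two gamma densities
(slow/fast) and turning angles by two zero-mean wrapped-Cauchy densities
(directed/tortuous); the four behavioural modes are the Cartesian product:

    1 slow-transit  = slow  × directed
    2 fast-transit  = fast  × directed
    3 slow-ARB      = slow  × tortuous   (ARB = area-restricted behaviour)
    4 fast-ARB      = fast  × tortuous   (error-dominated; advisory flag)

Parameters are fitted per animal by EM over the product mixture; steps are
then labelled by the maximum of the four component likelihoods (equal
priors — the classifier reports likelihoods, not posterior probabilities).
Mode 4, fast-yet-tortuous movement, is biologically implausible over 12-h
scales and mostly flags segments dominated by location error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_data import haversine_km, initial_bearing_rad
from .ctcrw import RegularTrack

logger = logging.getLogger(__name__)

MODE_NAMES = {1: "slow-transit", 2: "fast-transit", 3: "slow-ARB", 4: "fast-ARB"}
#: (speed component, angle component) per mode; 0 = slow/directed, 1 = fast/tortuous
_MODE_COMPONENTS = {1: (0, 0), 2: (1, 0), 3: (0, 1), 4: (1, 1)}

_SPEED_EPS = 1e-6      # km/h floor so gamma densities stay finite
_MIN_WEIGHT = 1e-3     # degenerate-component threshold


@dataclass
class StepSeries:
    """Per-step movement metrics of a 12-h regularized track.

    ``df`` columns: t (step start, days), speed_kmh, turn_rad (NaN on the
    first step), heading_rad, valid.
    """
    df: pd.DataFrame
    step_days: float = 0.5

    def __len__(self):
        return len(self.df)

    @property
    def valid(self) -> pd.DataFrame:
        return self.df[self.df["valid"]]


@dataclass
class MixtureParams:
    """Fitted movement-density parameters (gamma speeds, wrapped-Cauchy
    turning angles, product-mixture weights ordered mode 1..4)."""
    speed_slow: tuple      # (shape, rate)
    speed_fast: tuple
    rho_directed: float    # wrapped-Cauchy concentration, mean 0
    rho_tortuous: float
    weights: tuple         # 4-simplex
    loglik: float = np.nan
    degenerate: bool = False

    def __post_init__(self):
        ms = self.speed_slow[0] / self.speed_slow[1]
        mf = self.speed_fast[0] / self.speed_fast[1]
        if mf <= ms:
            raise ValueError("fast speed component mean must exceed slow mean")
        if not (self.rho_directed > self.rho_tortuous):
            raise ValueError("directed concentration must exceed tortuous")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")

    @property
    def speed_mean_kmh(self) -> tuple:
        return (self.speed_slow[0] / self.speed_slow[1],
                self.speed_fast[0] / self.speed_fast[1])


@dataclass
class ModeSequence:
    """Per-step mode labels (0 = unassigned) with per-mode log-likelihoods.

    Mode 4 carries an error-dominated advisory flag.
    """
    df: pd.DataFrame       # t, mode, loglik_1..loglik_4, error_dominated
    step_days: float = 0.5

    def __len__(self):
        return len(self.df)

    @property
    def modes(self) -> np.ndarray:
        return self.df["mode"].to_numpy()


# ---------------------------------------------------------------------------
# step metrics
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, float)
    w = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return w


def step_metrics(track: RegularTrack) -> StepSeries:
    """Speeds, turning angles and headings from consecutive grid positions.

    A step is invalid when either bounding position is low-confidence, or
    (for the turning angle) when it is the first step of the series.
    """
    df = track.df
    if len(df) < 3:
        raise ValueError("need at least 3 grid positions")
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    t = df["t"].to_numpy(float)
    dt_h = np.diff(t) * 24.0
    dist = haversine_km((lon[:-1], lat[:-1]), (lon[1:], lat[1:]))
    speed = dist / dt_h
    heading = initial_bearing_rad((lon[:-1], lat[:-1]), (lon[1:], lat[1:]))
    turn = np.full(len(speed), np.nan)
    turn[1:] = wrap_angle(np.diff(heading))
    low = df["low_confidence"].to_numpy(bool) if "low_confidence" in df else np.zeros(len(df), bool)
    valid = ~(low[:-1] | low[1:])
    valid &= np.isfinite(speed)
    valid[0] = False  # turning angle undefined on the first step
    out = pd.DataFrame({
        "t": t[:-1], "speed_kmh": speed, "turn_rad": turn,
        "heading_rad": heading, "valid": valid,
    })
    return StepSeries(df=out, step_days=float(np.median(np.diff(t))))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _gamma_logpdf(x, shape, rate):
    return stats.gamma.logpdf(x, a=shape, scale=1.0 / rate)


def _wc_logpdf(theta, rho):
    """Wrapped-Cauchy(mu=0, rho) log-density."""
    return np.log(1.0 - rho * rho) - np.log(2.0 * np.pi) - np.log1p(
        rho * rho - 2.0 * rho * np.cos(theta)
    )


def _weighted_gamma_ml(x, w):
    """Weighted gamma ML via the standard log-moment Newton iteration."""
    w = w / w.sum()
    m = float(np.sum(w * x))
    mlog = float(np.sum(w * np.log(x)))
    s = np.log(m) - mlog
    if s <= 0:
        return 1e6, 1e6 / m  # effectively degenerate at the mean
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        num = np.log(k) - special.digamma(k) - s
        den = 1.0 / k - special.polygamma(1, k)
        k_new = k - num / den
        if not np.isfinite(k_new) or k_new <= 0:
            break
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    return float(k), float(k / m)


def _weighted_wc_ml(theta, w):
    """Weighted ML of the wrapped-Cauchy concentration (mean fixed at 0)."""
    w = w / w.sum()

    def nll(rho):
        return -float(np.sum(w * _wc_logpdf(theta, rho)))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def _component_logliks(speed, turn, params: MixtureParams) -> np.ndarray:
    """n×4 per-step per-mode log-likelihoods (no mixture weights)."""
    speed = np.maximum(speed, _SPEED_EPS)
    g = np.column_stack([
        _gamma_logpdf(speed, *params.speed_slow),
        _gamma_logpdf(speed, *params.speed_fast),
    ])
    c = np.column_stack([
        _wc_logpdf(turn, params.rho_directed),
        _wc_logpdf(turn, params.rho_tortuous),
    ])
    ll = np.empty((len(speed), 4))
    for mode, (si, ai) in _MODE_COMPONENTS.items():
        ll[:, mode - 1] = g[:, si] + c[:, ai]
    return ll


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _em_once(speed, turn, init, max_iter=500, tol=1e-8):
    """One EM run from an explicit init; returns (params-tuple, loglik path)."""
    sp_slow, sp_fast, rho_d, rho_t, w = init
    n = len(speed)
    ll_path = []
    prev = -np.inf
    for _ in range(max_iter):
        params = _RawParams(sp_slow, sp_fast, rho_d, rho_t, w)
        comp = _component_logliks(speed, turn, params)
        logw = np.log(np.maximum(w, 1e-300))
        joint = comp + logw
        norm = special.logsumexp(joint, axis=1)
        ll = float(norm.sum())
        ll_path.append(ll)
        r = np.exp(joint - norm[:, None])
        # M-step
        w = r.mean(axis=0)
        w = np.maximum(w, 1e-12)
        w = w / w.sum()
        r_slow = r[:, 0] + r[:, 2]
        r_fast = r[:, 1] + r[:, 3]
        r_dir = r[:, 0] + r[:, 1]
        r_tor = r[:, 2] + r[:, 3]
        x = np.maximum(speed, _SPEED_EPS)
        if r_slow.sum() > 1e-8:
            sp_slow = _weighted_gamma_ml(x, r_slow)
        if r_fast.sum() > 1e-8:
            sp_fast = _weighted_gamma_ml(x, r_fast)
        if r_dir.sum() > 1e-8:
            rho_d = _weighted_wc_ml(turn, r_dir)
        if r_tor.sum() > 1e-8:
            rho_t = _weighted_wc_ml(turn, r_tor)
        if ll - prev < tol * max(1.0, abs(ll)) and len(ll_path) > 2:
            break
        prev = ll
    return (sp_slow, sp_fast, rho_d, rho_t, w), ll_path


@dataclass
class _RawParams:
    """Unvalidated parameter bundle used inside EM (labels may be swapped)."""
    speed_slow: tuple
    speed_fast: tuple
    rho_directed: float
    rho_tortuous: float
    weights: np.ndarray


def _relabel(raw, ll):
    """Impose the ordering invariants (fast mean > slow mean, directed rho >
    tortuous rho), permuting mixture weights to match."""
    sp_a, sp_b = raw[0], raw[1]
    rho_a, rho_b = raw[2], raw[3]
    w = np.asarray(raw[4], float).copy()
    swap_speed = sp_b[0] / sp_b[1] < sp_a[0] / sp_a[1]
    if swap_speed:
        sp_a, sp_b = sp_b, sp_a
        w = w[[1, 0, 3, 2]]
    swap_angle = rho_b > rho_a
    if swap_angle:
        rho_a, rho_b = rho_b, rho_a
        w = w[[2, 3, 0, 1]]
    if sp_b[0] / sp_b[1] <= sp_a[0] / sp_a[1]:
        sp_b = (sp_b[0] * 1.0 + 1e-9, sp_b[1])  # pathological equality
    if rho_a <= rho_b:
        rho_a = min(rho_b + 1e-9, 0.9999)
    degenerate = bool(np.any(w < _MIN_WEIGHT))
    return MixtureParams(
        speed_slow=tuple(sp_a), speed_fast=tuple(sp_b),
        rho_directed=float(rho_a), rho_tortuous=float(rho_b),
        weights=tuple(w), loglik=float(ll), degenerate=degenerate,
    )


def fit_movement_mixture(steps: StepSeries, n_restarts: int = 20,
                         seed: int = 0, max_iter: int = 500,
                         tol: float = 1e-8) -> MixtureParams:
    """EM fit of the 4-component product mixture to valid steps.

    Runs ``n_restarts`` seeded random initializations (quantile-anchored)
    and keeps the best likelihood.  A fit with any mixture weight below
    1e-3 is flagged degenerate — the study system itself showed 2-4
    distinguishable modes per animal, so collapsed components are expected
    for some tracks.
    """
    v = steps.valid
    if len(v) < 30:
        raise ValueError("need at least 30 valid steps to fit the mixture")
    speed = np.maximum(v["speed_kmh"].to_numpy(float), _SPEED_EPS)
    turn = v["turn_rad"].to_numpy(float)

    if np.ptp(speed) < 1e-9 and np.ptp(turn) < 1e-9:
        # all steps identical: nothing to separate
        m = float(speed.mean())
        params = MixtureParams(
            speed_slow=(1e6, 1e6 / max(m, _SPEED_EPS)),
            speed_fast=(2e6, 1e6 / max(m, _SPEED_EPS)),  # mean 2m > m
            rho_directed=0.5, rho_tortuous=0.0,
            weights=(1.0, 0.0, 0.0, 0.0), loglik=np.nan, degenerate=True,
        )
        logger.warning("degenerate step series: all speeds and turns identical")
        return params

    rng = np.random.default_rng(seed)
    q25, q75 = np.quantile(speed, [0.25, 0.75])
    med = np.median(speed)
    lo, hi = speed[speed <= med], speed[speed > med]
    best = None
    best_ll = -np.inf
    for restart in range(max(1, n_restarts)):
        if restart <= 1:
            # deterministic anchors: median split of speeds; canonical or
            # turn-threshold-derived angle structure
            ms, mf = float(max(lo.mean(), _SPEED_EPS)), float(hi.mean())
            sds, sdf = max(lo.std(), 1e-2), max(hi.std(), 1e-2)
            rho_init = (0.7, 0.1) if restart == 0 else (0.9, 0.02)
        else:
            ms = q25 * rng.uniform(0.5, 1.5)
            mf = max(q75 * rng.uniform(0.5, 1.5), ms * 1.5)
            sds = sdf = max(speed.std(), 1e-3)
            rho_init = (float(rng.uniform(0.5, 0.95)), float(rng.uniform(0.0, 0.3)))
        k_s = min(max((ms / sds) ** 2, 0.2), 1e4)
        k_f = min(max((mf / sdf) ** 2, 0.2), 1e4)
        if restart == 1:
            # weight anchor from a crude tortuosity split
            f_tort = float(np.clip(np.mean(np.abs(turn) > 1.0), 0.05, 0.95))
            w0 = np.array([(1 - f_tort) / 2, (1 - f_tort) / 2, f_tort / 2, f_tort / 2])
        else:
            w0 = np.full(4, 0.25)
        init = (
            (k_s, k_s / ms), (k_f, k_f / mf),
            rho_init[0], rho_init[1],
            w0,
        )
        raw, ll_path = _em_once(speed, turn, init, max_iter=max_iter, tol=tol)
        if np.any(np.diff(ll_path) < -1e-6 * np.maximum(1.0, np.abs(ll_path[:-1]))):
            logger.warning("EM log-likelihood decreased; numerical issue in restart")
        if ll_path[-1] > best_ll:
            best_ll = ll_path[-1]
            best = raw
    params = _relabel(best, best_ll)
    if params.degenerate:
        logger.warning(
            "mixture fit degenerate (weights %s); fewer than 4 modes supported",
            np.round(params.weights, 4),
        )
    return params


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_steps(steps: StepSeries, params: MixtureParams) -> ModeSequence:
    """Assign each valid step the argmax of the four component likelihoods
    (equal priors; mixture weights are used only in fitting).  Ties break
    toward the lower mode number (transit)."""
    df = steps.df
    speed = df["speed_kmh"].to_numpy(float)
    turn = df["turn_rad"].to_numpy(float)
    valid = df["valid"].to_numpy(bool)
    ll = np.full((len(df), 4), np.nan)
    if valid.any():
        ll[valid] = _component_logliks(speed[valid], turn[valid], params)
    # argmax with lower-mode tie-break: argmax returns the first maximum
    mode = np.zeros(len(df), dtype=int)
    if valid.any():
        mode[valid] = np.argmax(np.round(ll[valid], 12), axis=1) + 1
    out = pd.DataFrame({
        "t": df["t"].to_numpy(),
        "mode": mode,
        "loglik_1": ll[:, 0], "loglik_2": ll[:, 1],
        "loglik_3": ll[:, 2], "loglik_4": ll[:, 3],
        "error_dominated": mode == 4,
    })
    return ModeSequence(df=out, step_days=steps.step_days)


def _runs(labels: np.ndarray):
    """(value, start, length) runs of a 1-D label array."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j - i))
        i = j
    return runs


def smooth_modes(modes: ModeSequence, min_run_steps: int = 2) -> ModeSequence:
    """Absorb mode runs shorter than ``min_run_steps`` into the flanking
    majority mode (the longer flank wins; ties go to the left flank).
    Unassigned steps (mode 0) act as boundaries.  Iterated to a fixed point,
    so the operation is idempotent; ``min_run_steps=1`` is the identity."""
    if min_run_steps < 1:
        raise ValueError("min_run_steps must be >= 1")
    labels = modes.df["mode"].to_numpy().copy()
    if min_run_steps == 1:
        return ModeSequence(df=modes.df.copy(), step_days=modes.step_days)
    for _ in range(len(labels)):
        runs = [r for r in _runs(labels)]
        changed = False
        for idx, (val, start, length) in enumerate(runs):
            if val == 0 or length >= min_run_steps:
                continue
            left = runs[idx - 1] if idx > 0 and runs[idx - 1][0] != 0 else None
            right = runs[idx + 1] if idx + 1 < len(runs) and runs[idx + 1][0] != 0 else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and left[2] >= right[2]):
                new = left[0]
            else:
                new = right[0]
            labels[start:start + length] = new
            changed = True
            break  # recompute runs after each absorption
        if not changed:
            break
    df = modes.df.copy()
    df["mode"] = labels
    df["error_dominated"] = labels == 4
    return ModeSequence(df=df, step_days=modes.step_days)


# ---------------------------------------------------------------------------
# bout statistics
# ---------------------------------------------------------------------------

@dataclass
class BoutStats:
    bout_days: np.ndarray        # ARB bout durations
    interval_days: np.ndarray    # gaps between consecutive ARB bouts
    n_modes: int                 # distinct modes observed


def bout_statistics(modes: ModeSequence, step_days: float | None = None) -> BoutStats:
    """ARB bout durations and inter-bout intervals, treating modes {3, 4} as
    a single ARB class; durations are run length × step size (days)."""
    sd = step_days if step_days is not None else modes.step_days
    labels = modes.df["mode"].to_numpy()
    assigned = labels[labels != 0]
    arb = np.isin(assigned, (3, 4)).astype(int)
    runs = _runs(arb)
    bouts = [length * sd for val, _, length in runs if val == 1]
    intervals = []
    seen_first_bout = False
    pending_gap = None
    for val, _, length in runs:
        if val == 1:
            if seen_first_bout and pending_gap is not None:
                intervals.append(pending_gap)
            seen_first_bout = True
            pending_gap = None
        else:
            if seen_first_bout:
                pending_gap = length * sd
    return BoutStats(
        bout_days=np.asarray(bouts, float),
        interval_days=np.asarray(intervals, float),
        n_modes=int(len(np.unique(assigned))),
    )
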