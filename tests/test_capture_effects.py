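"""Kaplan-Meier first-ARB analysis, rank-based contrasts, returns."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtrack.behavior import ModeSequence
from mtrack.capture_effects import (
    early_late_speed,
    first_arb_times,
    heading_alignment,
    hodges_lehmann,
    km_estimator,
    median_crossing,
    rank_sum_contrast,
    return_classifier,
)
from mtrack.behavior import StepSeries

from conftest import make_track


def seq_from_modes(modes, animal_id="A"):
    df = pd.DataFrame({"t": np.arange(len(modes)) * 0.5, "mode": modes})
    return ModeSequence(df=df)


def events(times, observed):
    return pd.DataFrame({"animal_id": [f"A{i}" for i in range(len(times))],
                         "time": times, "observed": observed})


def km_hand_lifetable(times, observed):
    """Independent product-limit computation straight from the definition."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    observed = np.asarray(observed, bool)[order]
    uniq = np.unique(times[observed])
    s = 1.0
    out = {}
    for u in uniq:
        n_at_risk = np.sum(times >= u)
        d = np.sum((times == u) & observed)
        s *= 1.0 - d / n_at_risk
        out[u] = s
    return out


class TestFirstArbTimes:
    def test_arb_from_first_step(self):
        tab = first_arb_times({"A": seq_from_modes([3, 1, 1])})
        assert tab["time"].iloc[0] == 0.0 and bool(tab["observed"].iloc[0])

    def test_all_transit_censored_at_end(self):
        tab = first_arb_times({"A": seq_from_modes([1] * 60)})
        assert tab["time"].iloc[0] == pytest.approx(30.0)
        assert not bool(tab["observed"].iloc[0])

    def test_sixteen_day_onset_fixture(self):
        # transit for 32 half-day steps, then ARB: onset exactly day 16
        tab = first_arb_times({"A": seq_from_modes([2] * 32 + [3] * 8)})
        assert tab["time"].iloc[0] == pytest.approx(16.0)

    def test_mode4_exclusion_option(self):
        seq = seq_from_modes([1, 4, 1, 3])
        with_m4 = first_arb_times({"A": seq}, include_mode4=True)
        without = first_arb_times({"A": seq}, include_mode4=False)
        assert with_m4["time"].iloc[0] == 0.5
        assert without["time"].iloc[0] == 1.5


class TestKMEstimator:
    def test_two_events_no_censoring(self):
        curve = km_estimator(events([1.0, 2.0], [True, True]))
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_event_censor_event(self):
        # hand product-limit: S(1) = 2/3; at t=3 the only remaining subject
        # fails, so S(3) = 2/3 * (1 - 1/1) = 0
        curve = km_estimator(events([1.0, 2.0, 3.0], [True, False, True]))
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_survival_is_one(self):
        curve = km_estimator(events([5.0, 7.0, 9.0], [False] * 3))
        assert np.all(curve.survival == 1.0)

    def test_matches_hand_lifetable_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            t = np.round(rng.exponential(10, n), 1) + 0.1
            obs = rng.uniform(size=n) < 0.7
            if not obs.any():
                continue
            curve = km_estimator(events(t, obs))
            hand = km_hand_lifetable(t, obs)
            got = dict(zip(curve.times, curve.survival))
            for u, s in hand.items():
                assert got[u] == pytest.approx(s, abs=1e-12)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        curve = km_estimator(events(t, [True] * 40))
        for u, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > u), abs=1e-12)

    def test_greenwood_variance_hand_check(self):
        curve = km_estimator(events([1.0, 2.0, 3.0], [True, False, True]))
        v = dict(zip(curve.times, curve.variance))
        # at t=1: S=2/3, var = S^2 * d/(n(n-d)) = (4/9) * 1/(3*2)
        assert v[1.0] == pytest.approx((4 / 9) * (1 / 6))

    def test_ci_clipped_to_unit_interval(self):
        rng = np.random.default_rng(2)
        curve = km_estimator(events(rng.exponential(5, 30),
                                    rng.uniform(size=30) < 0.6))
        assert np.all(curve.ci_lower >= 0) and np.all(curve.ci_upper <= 1)
        assert np.all(curve.ci_lower <= curve.survival + 1e-12)
        assert np.all(curve.ci_upper >= curve.survival - 1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimator(events([-1.0, 2.0], [True, True]))


class TestMedianCrossing:
    def test_none_when_survival_stays_high(self):
        curve = km_estimator(events([1.0] + [50.0] * 9, [True] + [False] * 9))
        assert median_crossing(curve) is None

    def test_two_subject_example(self):
        curve = km_estimator(events([1.0, 2.0], [True, True]))
        assert median_crossing(curve) == 1.0

    def test_time_rescaling_equivariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(16, 50)
        obs = [True] * 50
        c1 = median_crossing(km_estimator(events(t, obs)))
        c2 = median_crossing(km_estimator(events(t * 3.0, obs)))
        assert c2 == pytest.approx(3.0 * c1)

    def test_exponential_onset_median_16(self):
        """Crossing day concentrates near the generating median (16 d)."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            t = rng.exponential(16.0 / np.log(2.0), 200)
            c = median_crossing(km_estimator(events(t, [True] * 200)))
            hits += 13.0 <= c <= 19.0
        assert hits >= 45


class TestRankSum:
    def test_identical_samples(self):
        c = rank_sum_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.hl_shift == 0.0
        assert c.p_value > 0.9

    def test_all_tied_convention(self):
        c = rank_sum_contrast([2.0, 2.0], [2.0, 2.0, 2.0])
        assert c.p_value == 1.0 and c.hl_shift == 0.0

    def test_matches_exhaustive_enumeration_for_small_samples(self):
        """p-value agrees with brute-force enumeration of rank assignments
        for every untied sample-size pair with n+m <= 10."""
        rng = np.random.default_rng(5)
        for n, m in [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 8), (5, 5)]:
            x = rng.normal(0, 1, n)
            y = rng.normal(0.8, 1, m)
            c = rank_sum_contrast(x, y)
            # independent enumeration oracle
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mean_u = n * m / 2.0
            u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
            count = total = 0
            for comb in itertools.combinations(range(n + m), n):
                u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
                count += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
                total += 1
            assert c.p_value == pytest.approx(count / total, abs=1e-10)

    def test_hodges_lehmann_on_shifted_samples(self):
        x = np.array([5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0])
        assert hodges_lehmann(x, y) == 4.0

    def test_power_at_study_speed_contrast(self):
        """Early-vs-late speed contrast effect size rejects at alpha=0.001
        nearly always at n=200 per group."""
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(100):
            x = rng.normal(1.97, 1.20, 200)
            y = rng.normal(1.28, 0.93, 200)
            rejections += rank_sum_contrast(x, y).p_value <= 1e-3
        assert rejections >= 95

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_contrast([1.0], [2.0, 3.0])


def make_step_series(t, speed, turn=None, heading=None):
    n = len(t)
    df = pd.DataFrame({
        "t": t, "speed_kmh": speed,
        "turn_rad": np.zeros(n) if turn is None else turn,
        "heading_rad": np.zeros(n) if heading is None else heading,
        "valid": True,
    })
    df.loc[0, "valid"] = False
    return StepSeries(df=df)


class TestEarlyLate:
    def test_equal_speeds_zero_shift(self):
        s = make_step_series(np.arange(40) * 0.5, np.full(40, 1.5))
        c = early_late_speed(s, 10.0)
        assert c.hl_shift == 0.0

    def test_zero_split_rejected(self):
        s = make_step_series(np.arange(40) * 0.5, np.full(40, 1.5))
        with pytest.raises(ValueError):
            early_late_speed(s, 0.0)

    def test_hl_shift_recovers_simulated_contrast(self):
        rng = np.random.default_rng(7)
        shifts = []
        for _ in range(10):
            t = np.arange(160) * 0.5
            speed = np.where(t < 10.0, rng.normal(1.97, 1.20, 160),
                             rng.normal(1.28, 0.93, 160))
            c = early_late_speed(make_step_series(t, np.abs(speed)), 10.0)
            shifts.append(c.hl_shift)
        assert 0.4 <= np.mean(shifts) <= 1.0


class TestHeadingAlignment:
    def test_due_north(self):
        s = make_step_series(np.arange(10) * 0.5, np.ones(10), heading=np.zeros(10))
        a = heading_alignment(s, 10.0)
        assert a.mean_northward == pytest.approx(1.0)

    def test_due_east(self):
        s = make_step_series(np.arange(10) * 0.5, np.ones(10),
                             heading=np.full(10, np.pi / 2))
        a = heading_alignment(s, 10.0)
        assert a.mean_northward == pytest.approx(0.0, abs=1e-12)

    def test_uniform_headings_near_zero(self):
        rng = np.random.default_rng(8)
        means = []
        for _ in range(20):
            s = make_step_series(np.arange(1000) * 0.001, np.ones(1000),
                                 heading=rng.uniform(-np.pi, np.pi, 1000))
            means.append(heading_alignment(s, 10.0).mean_northward)
        # SE of the pooled mean over 20000 headings is 0.005
        assert abs(np.mean(means)) < 0.015

    def test_too_few_headings_rejected(self):
        s = make_step_series(np.arange(3) * 0.5, np.ones(3))
        with pytest.raises(ValueError):
            heading_alignment(s, 10.0)


class TestReturnClassifier:
    def test_homebody_never_departs(self):
        track = make_track(np.arange(10) * 0.5,
                           180.0 + np.linspace(0, 0.3, 10), np.full(10, -30.0))
        st = return_classifier(track, (180.0, -30.0))
        assert not st.departed and not st.returned

    def test_out_and_back_loop(self):
        # out to ~800 km and back to ~200 km
        lat = np.concatenate([np.linspace(-30, -37.2, 20), np.linspace(-37.2, -31.8, 20)])
        track = make_track(np.arange(40) * 0.5, np.full(40, 180.0), lat)
        st = return_classifier(track, (180.0, -30.0))
        assert st.departed and st.returned
        assert st.max_distance_km == pytest.approx(800, rel=0.01)

    def test_one_way_departure_not_returned(self):
        lat = np.linspace(-30, -40, 30)
        track = make_track(np.arange(30) * 0.5, np.full(30, 180.0), lat)
        st = return_classifier(track, (180.0, -30.0))
        assert st.departed and not st.returned

    def test_season_split_boundary(self):
        track = make_track(np.arange(5) * 0.5, np.full(5, 180.0), np.full(5, -30.0))
        early = return_classifier(track, (180.0, -30.0), release_date="2006-02-28")
        late = return_classifier(track, (180.0, -30.0), release_date="2006-03-01")
        assert early.early_season and not late.early_season
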