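"""Product-limit estimation, landmark proportions, medians, log-rank."""

import numpy as np
import pytest

from bsi_stewardship.survival import km_fit, km_median, km_proportion_at, log_rank


def brute_force_product_limit(durations, events, t):
    """Independent oracle: S(t) as the literal product over event times."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    s = 1.0
    for ti in sorted(set(durations[events])):
        if ti > t:
            break
        n_i = np.sum(durations >= ti)
        d_i = np.sum((durations == ti) & events)
        s *= 1.0 - d_i / n_i
    return s


def brute_force_log_rank(da, ea, db, eb):
    """Independent oracle: explicit hypergeometric tally per event time."""
    da, ea = np.asarray(da, float), np.asarray(ea, bool)
    db, eb = np.asarray(db, float), np.asarray(eb, bool)
    o_minus_e = v = 0.0
    for t in sorted(set(np.concatenate([da[ea], db[eb]]))):
        na = np.sum(da >= t)
        nb = np.sum(db >= t)
        d_a = np.sum((da == t) & ea)
        d_b = np.sum((db == t) & eb)
        n, d = na + nb, d_a + d_b
        o_minus_e += d_a - d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v if v > 0 else 0.0


class TestKMFit:
    def test_hand_product_limit(self):
        """Durations (1+, 2, 3, 3, 4+): S(2) = 3/4, S(3) = 3/4 * 1/3 = 1/4."""
        curve = km_fit([1, 2, 3, 3, 4], [False, True, True, True, False])
        assert curve.survival_at(2.0)[0] == pytest.approx(0.75)
        assert curve.survival_at(3.0)[0] == pytest.approx(0.25)

    def test_no_censoring_reduces_to_empirical_survivor(self):
        curve = km_fit([2, 3, 3], [True, True, True])
        assert curve.survival_at(2.0)[0] == pytest.approx(2 / 3)
        assert curve.survival_at(3.0)[0] == 0.0

    def test_all_censored_is_flat_one(self):
        curve = km_fit([1, 2, 3], [False, False, False])
        assert curve.survival_at(10.0)[0] == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit([], [])

    def test_survival_non_increasing_and_bounded(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(1, 40)
            curve = km_fit(rng.exponential(30, n), rng.random(n) < 0.7)
            assert np.all(np.diff(curve.survival) <= 1e-15)
            assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 31))
            dur = np.round(rng.exponential(24, n), 1)  # rounding forces ties
            ev = rng.random(n) < 0.7
            curve = km_fit(dur, ev)
            for t in np.unique(dur):
                assert curve.survival_at(t)[0] == pytest.approx(
                    brute_force_product_limit(dur, ev, t), abs=1e-12
                )

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        dur = np.round(rng.exponential(24, 200), 1)
        ev = rng.random(200) < 0.6
        curve = km_fit(dur, ev)
        kmf = lifelines.KaplanMeierFitter().fit(dur, ev)
        for t in curve.times:
            assert curve.survival_at(t)[0] == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLandmarkProportion:
    def test_all_events_before_landmark(self):
        curve = km_fit([10.0] * 5, [True] * 5)
        p, lo, hi, extr = km_proportion_at(curve, 24.0)
        assert p == 1.0 and extr

    def test_degenerate_ci(self):
        curve = km_fit([10.0] * 5, [True] * 5)
        p, lo, hi, _ = km_proportion_at(curve, 10.0)
        assert (p, hi) == (1.0, 1.0)

    def test_non_decreasing_in_time(self):
        rng = np.random.default_rng(5)
        curve = km_fit(rng.exponential(30, 100), rng.random(100) < 0.8)
        props = [km_proportion_at(curve, t)[0] for t in np.linspace(0, 200, 50)]
        assert np.all(np.diff(props) >= -1e-15)

    def test_exponential_cohort_matches_closed_form(self):
        """Exponential event times with P(T <= 24) = 0.9 recover that
        landmark within Monte-Carlo error at n = 5000."""
        lam = -np.log(0.1) / 24.0
        rng = np.random.default_rng(11)
        t = np.minimum(rng.exponential(1 / lam, 5000), 240.0)
        ev = t < 240.0
        p, lo, hi, _ = km_proportion_at(km_fit(t, ev), 24.0)
        assert p == pytest.approx(0.9, abs=0.02)
        assert lo < 0.9 < hi


class TestMedian:
    def test_plain_median(self):
        median, _ = km_median(km_fit([1, 2, 3], [True] * 3))
        assert median == 2.0

    def test_absent_when_curve_stays_above_half(self):
        median, ci = km_median(km_fit([5, 6, 7, 8], [True, False, False, False]))
        assert median is None

    def test_exponential_cohort_matches_closed_form(self):
        lam = 0.03
        rng = np.random.default_rng(13)
        t = rng.exponential(1 / lam, 4000)
        median, (lo, hi) = km_median(km_fit(t, np.ones_like(t, bool)))
        expected = np.log(2) / lam
        assert median == pytest.approx(expected, rel=0.05)
        assert lo < expected < hi


class TestLogRank:
    def test_identical_samples_give_null(self):
        chi2, p = log_rank([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert (chi2, p) == (0.0, 1.0)

    def test_hand_tally_two_by_two(self):
        """A events {1,2}, B events {3,4}: exhaustive hypergeometric tally."""
        chi2, p = log_rank([1, 2], [True, True], [3, 4], [True, True])
        expected = brute_force_log_rank([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert chi2 == pytest.approx(49 / 17, abs=1e-10)  # (7/6)^2 / (17/36)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(17)
        da, db = rng.exponential(20, 50), rng.exponential(30, 60)
        ea, eb = rng.random(50) < 0.8, rng.random(60) < 0.8
        assert log_rank(da, ea, db, eb)[0] == pytest.approx(log_rank(db, eb, da, ea)[0])

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(19)
        da, db = rng.exponential(20, 40), rng.exponential(35, 40)
        ea = eb = np.ones(40, bool)
        c1 = log_rank(da, ea, db, eb)[0]
        c2 = log_rank(da * 7.3, ea, db * 7.3, eb)[0]
        assert c1 == pytest.approx(c2)

    def test_no_events_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = log_rank([1, 2], [0, 0], [3, 4], [0, 0])
        assert p == 1.0

    def test_matches_brute_force_on_random_censored_samples(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            na, nb = rng.integers(3, 25, 2)
            da = np.round(rng.exponential(20, na), 0)
            db = np.round(rng.exponential(25, nb), 0)
            ea, eb = rng.random(na) < 0.7, rng.random(nb) < 0.7
            if not (ea.any() or eb.any()):
                continue
            assert log_rank(da, ea, db, eb)[0] == pytest.approx(
                brute_force_log_rank(da, ea, db, eb), abs=1e-10
            )

    def test_matches_lifelines(self):
        stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(29)
        da, db = rng.exponential(20, 80), rng.exponential(32, 90)
        ea, eb = rng.random(80) < 0.7, rng.random(90) < 0.7
        chi2, p = log_rank(da, ea, db, eb)
        ref = stats.logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-9)
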