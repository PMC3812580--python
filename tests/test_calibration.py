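"""Drop-session segmentation, feature extraction, the height regression,
and the hit/thrust profile statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sonimotion.calibration import (
    Trial,
    fit_calibration,
    profile_strain_types,
    residual_sd_for_adj_r2,
    segment_trials,
    trial_feature,
    trial_feature_used,
    welch_t,
)
from sonimotion.synth import PROTOCOL_HEIGHTS_CM, gen_drop_session, gen_profile_reps


def make_trial(sums, onset=0, spacing=10, height=None):
    sums = np.asarray(sums, dtype=float)
    t = onset + np.arange(len(sums)) * spacing
    return Trial(onset_ms=onset, t_ms=t, sums=sums, drop_height_cm=height)


class TestSegmentation:
    def test_single_burst(self):
        t = np.arange(0, 500, 100)
        res = segment_trials(t, np.full(5, 1200.0))
        assert res.n_trials == 1
        assert res.trials[0].n_samples == 5
        assert res.n_discarded == 0

    def test_lone_echo_discarded(self):
        """A reading 700 ms after the burst is rebound, not data."""
        t = np.array([0, 100, 200, 900])
        res = segment_trials(t, np.full(4, 1200.0))
        assert res.n_trials == 1
        assert res.trials[0].n_samples == 3
        assert res.n_discarded == 1

    def test_echo_train_discarded_together(self):
        t = np.array([0, 100, 800, 900, 1000])
        res = segment_trials(t, np.full(5, 1200.0))
        assert (res.n_trials, res.n_discarded) == (1, 3)

    def test_onset_gap_opens_new_trial(self):
        t = np.array([0, 100, 2200, 2300])
        res = segment_trials(t, np.full(4, 1200.0))
        assert res.n_trials == 2
        assert res.trials[1].onset_ms == 2200

    def test_empty_input(self):
        res = segment_trials([], [])
        assert (res.n_trials, res.n_discarded) == (0, 0)

    def test_protocol_session_recovers_all_trials(self):
        session = gen_drop_session(seed=11)
        r = session.readings
        res = segment_trials(r["t_ms"].to_numpy(), r["sum"].to_numpy())
        assert res.n_trials == 45
        assert res.n_discarded == session.n_echo_readings

    @given(st.lists(st.integers(1, 3000), min_size=1, max_size=60))
    def test_partition_conserves_readings(self, gaps):
        t = np.cumsum(gaps)
        res = segment_trials(t, np.full(len(t), 1000.0))
        retained = sum(tr.n_samples for tr in res.trials)
        assert retained + res.n_discarded == len(t)

    @given(st.lists(st.integers(1, 3000), min_size=1, max_size=60),
           st.integers(100, 900), st.integers(0, 900))
    def test_wider_ricochet_gap_never_drops_more(self, gaps, g1, extra):
        t = np.cumsum(gaps)
        s = np.full(len(t), 1000.0)
        g2 = min(g1 + extra, 1999)
        n1 = sum(tr.n_samples for tr in segment_trials(t, s, ricochet_gap_ms=g1).trials)
        n2 = sum(tr.n_samples for tr in segment_trials(t, s, ricochet_gap_ms=g2).trials)
        assert n2 >= n1


class TestTrialFeature:
    @pytest.mark.parametrize(
        "sums, expected",
        [([1200], 1200.0), ([1500] * 12, 1500.0), ([1000, 2000, 3000], 2000.0)],
    )
    def test_examples(self, sums, expected):
        assert trial_feature(make_trial(sums)) == pytest.approx(expected)

    def test_cap_at_ten_samples(self):
        sums = [1000.0] * 10 + [9999.0] * 5
        mean, used = trial_feature_used(make_trial(sums))
        assert used == 10
        assert mean == pytest.approx(1000.0)

    def test_empty_trial_errors(self):
        with pytest.raises(ValueError):
            trial_feature(make_trial([]))


class TestFitCalibration:
    def test_exact_line_recovery(self):
        a, b = 7.0, 2.5
        trials = [make_trial([a + b * d], height=d) for d in (0.0, 1.0, 2.0)]
        fit = fit_calibration(trials)
        assert fit.slope == pytest.approx(b, abs=1e-9)
        assert fit.intercept == pytest.approx(a, abs=1e-9)

    def test_noiseless_protocol_recovers_calibration_line(self):
        session = gen_drop_session(seed=3, residual_sd=0.0, ricochet_prob=0.0)
        r = session.readings
        res = segment_trials(r["t_ms"].to_numpy(), r["sum"].to_numpy(),
                             heights=r["height_cm"].to_numpy())
        fit = fit_calibration(res.trials)
        assert fit.slope == pytest.approx(3.00, abs=1e-9)
        assert fit.intercept == pytest.approx(1208.29, abs=1e-9)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 45

    def test_singular_design_rejected(self):
        trials = [make_trial([1500.0], height=100.0) for _ in range(5)]
        with pytest.raises(ValueError):
            fit_calibration(trials)

    def test_fit_statistics_are_consistent(self):
        rng = np.random.default_rng(5)
        trials = [
            make_trial([1208.29 + 3.0 * d + rng.normal(0, 100)], height=d)
            for d in np.repeat(PROTOCOL_HEIGHTS_CM, 5)
        ]
        fit = fit_calibration(trials)
        # with one regressor, F = t_slope^2
        assert fit.f_stat == pytest.approx(fit.t_slope**2, rel=1e-9)
        assert fit.adj_r2 <= 1

    def test_recovery_bias_shrinks_with_noise(self):
        """Slope bias goes to zero as the residual scale does."""
        errs = []
        for sd in (200.0, 20.0, 0.0):
            slopes = []
            for seed in range(5):
                s = gen_drop_session(seed=seed, residual_sd=sd, ricochet_prob=0.0)
                r = s.readings
                res = segment_trials(r["t_ms"].to_numpy(), r["sum"].to_numpy(),
                                     heights=r["height_cm"].to_numpy())
                slopes.append(fit_calibration(res.trials).slope)
            errs.append(abs(np.mean(slopes) - 3.00))
        assert errs[2] < 1e-9
        assert errs[2] <= errs[1] <= errs[0] + 1e-9


class TestWelch:
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=15),
        st.lists(st.floats(-50, 50), min_size=2, max_size=15),
    )
    def test_matches_textbook_formula_via_scipy(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, df = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        assert df == pytest.approx(ref.df, rel=1e-9)

    def test_equal_variance_equal_n_gives_pooled_df(self):
        a = [0.0, 1.0, 2.0, 3.0]
        b = [10.0, 11.0, 12.0, 13.0]
        _, df = welch_t(a, b)
        assert df == pytest.approx(2 * len(a) - 2)

    def test_degenerate_zero_variance(self):
        t, df = welch_t([5.0, 5.0], [5.0, 5.0])
        assert t == 0.0
        assert df == 2.0


class TestProfiles:
    def test_identical_reps_give_zero_t_and_zero_width(self):
        rep = np.column_stack([np.arange(0, 50, 5), np.linspace(2000, 1000, 10)])
        cmp_ = profile_strain_types([rep.copy(), rep.copy()], [rep.copy(), rep.copy()])
        assert np.all(cmp_.tests["t"] == 0.0)
        assert np.allclose(cmp_.hit.ci_lo, cmp_.hit.mean)
        assert np.allclose(cmp_.hit.ci_hi, cmp_.hit.mean)

    def test_ci_brackets_mean(self):
        cmp_ = profile_strain_types(
            gen_profile_reps("hit", n_reps=20, seed=1),
            gen_profile_reps("thrust", n_reps=20, seed=2),
        )
        for prof in (cmp_.hit, cmp_.thrust):
            assert np.all(prof.ci_lo <= prof.mean + 1e-12)
            assert np.all(prof.mean <= prof.ci_hi + 1e-12)

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(0)
        t_grid = np.arange(0, 50, 5)

        def iid_reps(n):
            return [
                np.column_stack([t_grid, 1500 + rng.normal(0, 100, len(t_grid))])
                for _ in range(n)
            ]

        small = profile_strain_types(iid_reps(25), iid_reps(25)).hit
        large = profile_strain_types(iid_reps(100), iid_reps(100)).hit
        w_small = np.mean(small.ci_hi - small.ci_lo)
        w_large = np.mean(large.ci_hi - large.ci_lo)
        assert 1.6 < w_small / w_large < 2.6  # expect ~2 for a 4x sample

    def test_thrust_exceeds_hit_at_the_delay_bin(self):
        """At the 5 ms bin thrust reads higher: hit - thrust t is negative
        and conventionally significant on the synthetic repetition sets."""
        cmp_ = profile_strain_types(
            gen_profile_reps("hit", n_reps=59, seed=10),
            gen_profile_reps("thrust", n_reps=59, seed=11),
        )
        row = cmp_.tests[cmp_.tests["bin_start_ms"] == 5].iloc[0]
        assert row["t"] < 0
        assert abs(row["t"]) > 2
        # recommendation sits below the thrust mean at that bin
        i = np.nonzero(cmp_.thrust.bin_starts_ms == 5)[0][0]
        assert cmp_.recommended_stage2_threshold == pytest.approx(cmp_.thrust.ci_lo[i])

    def test_too_few_reps_rejected(self):
        rep = np.column_stack([[0, 5], [2000, 1800]])
        with pytest.raises(ValueError):
            profile_strain_types([rep], [rep, rep])


def test_residual_sd_matches_target_adj_r2():
    """The derived noise scale lands the fit's adjusted R-squared near its
    target on average over seeds."""
    sd = residual_sd_for_adj_r2(0.56, PROTOCOL_HEIGHTS_CM, reps=5)
    vals = []
    for seed in range(30):
        s = gen_drop_session(seed=seed, residual_sd=sd, ricochet_prob=0.0)
        r = s.readings
        res = segment_trials(r["t_ms"].to_numpy(), r["sum"].to_numpy(),
                             heights=r["height_cm"].to_numpy())
        vals.append(fit_calibration(res.trials).adj_r2)
    assert np.mean(vals) == pytest.approx(0.56, abs=0.08)
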