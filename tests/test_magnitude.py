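"""Magnitude pipeline: exclusion rule, profiles, Friedman, BH, fits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icmspsych import magnitude as mg
from icmspsych.core_io import ValidationError, trials_to_frame
from icmspsych.synthetic import (
    MagnitudeDesign,
    SyntheticConfig,
    gen_magnitude_dataset,
)

FREQS9 = [20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0, 250.0, 300.0]


def make_frame(rows):
    return pd.DataFrame(rows, columns=["electrode", "day", "block",
                                       "frequency_Hz", "amplitude_uA",
                                       "duration_s", "response"])


class TestExcludeFirstBlock:
    def test_six_blocks_nine_freqs_retain_45(self):
        rows = [(1, 1, b, f, 60.0, 1.0, 1.0)
                for b in range(1, 7) for f in FREQS9]
        out = mg.exclude_first_block(make_frame(rows))
        assert len(out) == 45
        assert set(out["block"]) == {2, 3, 4, 5, 6}

    def test_minimum_block_rule_not_literal_one(self):
        rows = [(1, 1, b, 100.0, 60.0, 1.0, 1.0) for b in (3, 4, 5)]
        out = mg.exclude_first_block(make_frame(rows))
        assert set(out["block"]) == {4, 5}

    def test_single_block_set_empties_with_warning(self):
        rows = [(1, 1, 1, f, 60.0, 1.0, 1.0) for f in FREQS9]
        with pytest.warns(UserWarning, match="single"):
            out = mg.exclude_first_block(make_frame(rows))
        assert out.empty

    def test_removes_one_block_per_set_on_complete_designs(self):
        rows = [(e, d, b, f, 60.0, 1.0, 1.0)
                for e in (1, 2) for d in (10, 20)
                for b in range(1, 4) for f in FREQS9]
        out = mg.exclude_first_block(make_frame(rows))
        # 4 sets x 9 trials per block removed
        assert len(out) == len(rows) - 4 * 9


class TestComputeProfiles:
    def test_constant_responses_have_zero_sem(self):
        rows = [(1, 1, b, 100.0, 60.0, 1.0, 2.0) for b in (1, 2, 3)]
        prof = mg.compute_profiles(make_frame(rows))
        assert prof.loc[0, "mean"] == 2.0
        assert prof.loc[0, "sem"] == 0.0
        assert prof.loc[0, "n"] == 3

    def test_mean_and_sem_match_hand_computation(self):
        rows = [(1, 1, b, 100.0, 60.0, 1.0, r)
                for b, r in enumerate([1, 2, 3, 4, 5], start=1)]
        prof = mg.compute_profiles(make_frame(rows))
        assert prof.loc[0, "mean"] == pytest.approx(3.0)
        # sd({1..5}) = sqrt(2.5); SEM = sqrt(2.5)/sqrt(5) ~ 0.7071
        assert prof.loc[0, "sem"] == pytest.approx(np.sqrt(2.5 / 5))

    def test_untested_frequencies_absent_no_imputation(self):
        rows = [(1, 1, 1, f, 60.0, 1.0, 1.0) for f in (20.0, 100.0, 300.0)]
        prof = mg.compute_profiles(make_frame(rows))
        assert len(prof) == 3
        assert set(prof["frequency_Hz"]) == {20.0, 100.0, 300.0}


class TestFriedman:
    def test_identical_responses_give_zero_statistic(self):
        data = np.full((5, 9), 2.0)
        q, p = mg.friedman_test(data)
        assert q == pytest.approx(0.0)
        assert p > 0.99

    def test_strictly_monotone_responses_maximal_statistic(self):
        # responses increase with frequency in every one of 5 blocks
        data = np.tile(np.arange(1.0, 10.0), (5, 1))
        q, p = mg.friedman_test(data)
        # maximal Q for n=5, k=9: n*(k-1) = 40 when ranks agree across blocks
        assert q == pytest.approx(5 * 8)
        assert p < 0.001

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            data = rng.normal(size=(6, 5))
            q, p = mg.friedman_test(data)
            q2, p2 = stats.friedmanchisquare(*data.T)
            assert q == pytest.approx(q2)
            assert p == pytest.approx(p2)

    def test_exact_p_matches_full_enumeration_oracle(self):
        """3 blocks x 3 treatments: p equals the tail over all (3!)^3 rankings."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            data = rng.normal(size=(3, 3))
            q_obs, p_exact = mg.friedman_test(data, method="exact")
            # independent oracle: enumerate rank assignments directly
            perms = list(itertools.permutations([1, 2, 3]))
            stats_all = []
            for combo in itertools.product(perms, repeat=3):
                ranks = np.array(combo, dtype=float)
                rs = ranks.sum(axis=0)
                stats_all.append(12 / (3 * 3 * 4) * (rs ** 2).sum() - 3 * 3 * 4)
            oracle = np.mean([s >= q_obs - 1e-9 for s in stats_all])
            assert p_exact == pytest.approx(oracle)

    def test_invariant_to_monotone_transform_within_blocks(self):
        rng = np.random.default_rng(2)
        data = rng.random(size=(4, 6)) + 0.5
        q1, _ = mg.friedman_test(data)
        q2, _ = mg.friedman_test(np.exp(3 * data))
        assert q1 == pytest.approx(q2)

    def test_too_small_design_rejected(self):
        with pytest.raises(ValidationError):
            mg.friedman_test(np.ones((1, 5)))


class TestFriedmanScreen:
    def test_modulated_vs_flat_electrodes_separated(self):
        """Frequency-modulated electrodes screen significant; flat do not."""
        cfg = SyntheticConfig(noise_sd=0.2, first_block_bias=0.0,
                              n_electrodes_per_category=3)
        trials, labels = gen_magnitude_dataset(
            cfg, MagnitudeDesign(n_blocks=6), seed=5)
        df = trials_to_frame(trials)
        # add flat electrodes: constant mean, same noise
        rng = np.random.default_rng(6)
        flat_rows = []
        for e in range(100, 105):
            for b in range(1, 7):
                for f in FREQS9:
                    flat_rows.append((e, 100, b, f, 60.0, 1.0,
                                      2.0 * np.exp(rng.normal(0, 0.2))))
        df = pd.concat([df, make_frame(flat_rows)], ignore_index=True)
        screen = mg.friedman_screen(mg.exclude_first_block(df))
        sig = set(screen.table.loc[screen.table.significant, "electrode"])
        assert set(labels) <= sig  # every modulated electrode detected

    def test_incomplete_blocks_dropped_and_undefined_flagged(self):
        rows = [(1, 1, b, f, 60.0, 1.0, b * f)
                for b in (1, 2) for f in (20.0, 100.0)]
        rows += [(2, 1, 1, 20.0, 60.0, 1.0, 1.0)]  # one trial only
        screen = mg.friedman_screen(make_frame(rows))
        t = screen.table.set_index("electrode")
        assert not np.isnan(t.loc[1, "statistic"])
        assert np.isnan(t.loc[2, "statistic"])
        assert not t.loc[2, "significant"]


class TestBHAdjust:
    def test_all_ones_give_zero_critical_p(self):
        mask, crit = mg.bh_adjust(np.ones(10))
        assert crit == 0.0
        assert not mask.any()

    def test_worked_example_first_four_significant(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
        mask, crit = mg.bh_adjust(p, alpha=0.05)
        assert list(mask) == [True, True, True, True, False]
        assert crit == pytest.approx(0.04)

    def test_single_p_at_alpha_boundary(self):
        mask, crit = mg.bh_adjust([0.04], alpha=0.05)
        assert mask[0] and crit == pytest.approx(0.04)

    def test_empty_input(self):
        mask, crit = mg.bh_adjust([])
        assert mask.size == 0 and crit == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=25))
    def test_matches_brute_force_step_up(self, p_list):
        p = np.array(p_list)
        mask, crit = mg.bh_adjust(p, alpha=0.05)
        # brute force: evaluate every step-up threshold directly
        m = len(p)
        sp = np.sort(p)
        passing = [sp[i] for i in range(m) if sp[i] <= (i + 1) / m * 0.05]
        expected_crit = max(passing) if passing else 0.0
        assert crit == pytest.approx(expected_crit)
        assert np.array_equal(mask, p <= expected_crit) or not passing


class TestAmplitudeFit:
    def test_noiseless_line_recovered(self):
        amps = np.arange(20.0, 81.0, 10.0)
        rows = [(1, 1, 1, 100.0, a, 1.0, 0.05 * a - 0.5) for a in amps]
        fit = mg.fit_amplitude_linear(make_frame(rows), normalize=False)
        assert fit.slope == pytest.approx(0.05)
        assert fit.intercept == pytest.approx(-0.5)

    def test_three_point_fit_matches_normal_equations(self):
        x = np.array([20.0, 50.0, 80.0])
        y = np.array([1.0, 2.5, 2.9])
        rows = [(1, 1, 1, 100.0, a, 1.0, r) for a, r in zip(x, y)]
        fit = mg.fit_amplitude_linear(make_frame(rows), normalize=False)
        X = np.column_stack([x, np.ones(3)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0])
        assert fit.intercept == pytest.approx(beta[1])

    def test_single_amplitude_rejected(self):
        rows = [(1, 1, 1, 100.0, 60.0, 1.0, r) for r in (1.0, 2.0)]
        with pytest.raises(ValidationError):
            mg.fit_amplitude_linear(make_frame(rows))

    def test_cross_set_data_normalized_by_set_median(self):
        # two sets rating the same physical series on different scales
        amps = np.arange(20.0, 81.0, 10.0)
        rows = [(1, 1, 1, 100.0, a, 1.0, 0.05 * a) for a in amps]
        rows += [(1, 8, 1, 100.0, a, 1.0, 0.5 * a) for a in amps]
        fit = mg.fit_amplitude_linear(make_frame(rows))
        single = mg.fit_amplitude_linear(make_frame(rows[:7]), normalize=True)
        assert fit.slope == pytest.approx(single.slope)


class TestDurationFit:
    DUR = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0, 1.5, 2.0])

    def test_noiseless_logistic_recovered(self):
        true = (3.0, 0.4, 4.0)
        y = true[0] / (1 + np.exp(-true[2] * (self.DUR - true[1])))
        rows = [(1, 1, 1, 100.0, 60.0, d, r) for d, r in zip(self.DUR, y)]
        fit = mg.fit_duration_logistic(make_frame(rows))
        assert fit.asymptote == pytest.approx(true[0], rel=1e-6)
        assert fit.midpoint == pytest.approx(true[1], rel=1e-6)
        assert fit.rate == pytest.approx(true[2], rel=1e-6)

    def test_parameters_recovered_from_noisy_data(self):
        rng = np.random.default_rng(7)
        true = (3.0, 0.4, 4.0)
        durs = np.tile(self.DUR, 40)
        y = true[0] / (1 + np.exp(-true[2] * (durs - true[1])))
        y = y * np.exp(rng.normal(0, 0.1, size=y.size))
        rows = [(1, 1, 1, 100.0, 60.0, d, r) for d, r in zip(durs, y)]
        fit = mg.fit_duration_logistic(make_frame(rows))
        assert fit.asymptote == pytest.approx(true[0], rel=0.1)
        assert fit.midpoint == pytest.approx(true[1], abs=0.1)
        assert fit.rate == pytest.approx(true[2], rel=0.25)

    def test_three_durations_rejected(self):
        rows = [(1, 1, 1, 100.0, 60.0, d, 1.0) for d in (0.1, 0.5, 1.0)]
        with pytest.raises(ValidationError):
            mg.fit_duration_logistic(make_frame(rows))


class TestShapeInvariance:
    def _frame(self, shape_by_amp, n_reps=10, noise=0.15, seed=8):
        rng = np.random.default_rng(seed)
        rows = []
        for amp, shape in shape_by_amp.items():
            for f, mean in shape.items():
                for _ in range(n_reps):
                    rows.append((1, 1, 1, f, amp, 1.0,
                                 mean * np.exp(rng.normal(0, noise))))
        return make_frame(rows)

    def test_identical_conditions_give_high_p(self):
        shape = {20.0: 3.0, 100.0: 2.0, 300.0: 1.0}
        df = self._frame({50.0: shape, 80.0: shape}, noise=0.0)
        _, p = mg.shape_invariance_test(df)
        assert p > 0.9

    def test_pure_gain_change_not_flagged(self):
        shape = {20.0: 3.0, 100.0: 2.0, 300.0: 1.0}
        doubled = {f: 2 * v for f, v in shape.items()}
        df = self._frame({50.0: shape, 80.0: doubled})
        _, p = mg.shape_invariance_test(df)
        assert p > 0.05

    def test_shape_change_flagged(self):
        low_peak = {20.0: 3.0, 100.0: 2.0, 300.0: 0.5}
        high_peak = {20.0: 0.5, 100.0: 2.0, 300.0: 3.0}
        df = self._frame({50.0: low_peak, 80.0: high_peak})
        _, p = mg.shape_invariance_test(df)
        assert p < 0.05

    def test_zero_median_condition_rejected(self):
        df = self._frame({50.0: {20.0: 0.0, 100.0: 0.0},
                          80.0: {20.0: 1.0, 100.0: 2.0}}, noise=0.0)
        with pytest.raises(ValidationError):
            mg.shape_invariance_test(df)


class TestGroupMedianTest:
    def test_large_offset_groups_highly_significant(self):
        rng = np.random.default_rng(9)
        rows = []
        for e, (cat, offset) in enumerate([("LFP", 0.0), ("IFP", 5.0),
                                           ("HFP", 10.0)]):
            for i in range(50):
                rows.append((e, 1, 1, 100.0, 60.0, 1.0,
                             offset + rng.random()))
        labels = {0: "LFP", 1: "IFP", 2: "HFP"}
        res = mg.group_median_test(make_frame(rows), labels)
        assert res.p_value < 0.001
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_identical_constant_groups_zero_statistic(self):
        rows = [(e, 1, 1, 100.0, 60.0, 1.0, 2.0)
                for e in (0, 1) for _ in range(5)]
        res = mg.group_median_test(make_frame(rows), {0: "LFP", 1: "HFP"})
        assert res.statistic == 0.0

    def test_empty_group_rejected(self):
        rows = [(0, 1, 1, 100.0, 60.0, 1.0, 2.0)]
        with pytest.raises(ValidationError):
            mg.group_median_test(make_frame(rows), {0: "LFP"})


class TestBiasSensitivity:
    def test_exclusion_removes_first_block_bias(self):
        """Profiles with block 1 included are biased upward; exclusion fixes it."""
        cfg = SyntheticConfig(noise_sd=0.0, first_block_bias=1.0,
                              n_electrodes_per_category=1)
        trials, labels = gen_magnitude_dataset(cfg, seed=10)
        df = trials_to_frame(trials)
        arch_means = {e: None for e in labels}
        from icmspsych.synthetic import default_archetypes
        arches = default_archetypes()
        with_b1 = mg.compute_profiles(df)
        without = mg.compute_profiles(mg.exclude_first_block(df))
        for e, cat in labels.items():
            truth = arches[cat].mean_intensity(
                without[without.electrode == e]["frequency_Hz"].to_numpy())
            err_with = np.abs(
                with_b1[with_b1.electrode == e]["mean"].to_numpy() - truth).max()
            err_without = np.abs(
                without[without.electrode == e]["mean"].to_numpy() - truth).max()
            assert err_without < err_with
            assert err_without == pytest.approx(0.0, abs=1e-9)


class TestNormalityGate:
    def test_gate_separates_normal_from_heavy_tailed(self):
        rng = np.random.default_rng(12)
        assert mg.is_normal_anderson(rng.normal(size=500))
        assert not mg.is_normal_anderson(rng.exponential(size=500))
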