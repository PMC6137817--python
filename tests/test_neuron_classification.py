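import itertools

import numpy as np
import pytest

import corridor_neuro as cn
from corridor_neuro.neuron_classification import _signed_rank
from corridor_neuro.trace_processing import DffTrace, FilterSpec

from conftest import make_spatial


def exact_signed_rank_p(diffs):
    """Independent oracle: two-sided signed-rank p by full sign enumeration."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0) and len(set(np.abs(d))) == len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_null = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    w_null = np.array(w_null)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return float(np.mean((w_null <= lo) | (w_null >= hi)))


def pre_post_matrix(n_trials, pre_val, post_val, noise_sd=0.0, seed=0, n_bins=60):
    """Trials x bins matrix (2-cm bins over [0, 120)): pre window bins 30-39,
    post window bins 40-49."""
    rng = np.random.default_rng(seed)
    m = rng.normal(0.0, noise_sd, size=(n_trials, n_bins)) if noise_sd else np.zeros((n_trials, n_bins))
    m[:, 30:40] += pre_val
    m[:, 40:50] += post_val
    return m


class TestTaskResponsive:
    def test_null_identity_not_responsive(self, geometry):
        sp = make_spatial(pre_post_matrix(20, 0.5, 0.5))
        res = cn.classify_task_responsive(sp, geometry)
        assert not res.responsive
        assert res.p_value == 1.0

    def test_shifted_increase_flagged(self, geometry):
        sp = make_spatial(pre_post_matrix(50, 0.0, 0.5, noise_sd=0.05, seed=1))
        res = cn.classify_task_responsive(sp, geometry)
        assert res.responsive
        assert res.direction == "increase"
        assert res.p_value < 1e-6
        assert res.r_post_mean > res.r_pre_mean

    def test_decrease_direction(self, geometry):
        sp = make_spatial(pre_post_matrix(50, 0.5, 0.0, noise_sd=0.05, seed=2))
        res = cn.classify_task_responsive(sp, geometry)
        assert res.responsive and res.direction == "decrease"

    def test_signed_rank_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=10)
            while np.any(d == 0) or len(set(np.abs(d))) != len(d):
                d = rng.normal(0.3, 1.0, size=10)
            p_impl = _signed_rank(d, np.zeros_like(d))
            p_oracle = exact_signed_rank_p(d)
            assert p_impl == pytest.approx(p_oracle, abs=1e-9)

    def test_null_calibration_1000_neurons(self, geometry):
        # flagged fraction under the global null stays near nominal alpha
        flagged = 0
        for i in range(1000):
            sp = make_spatial(pre_post_matrix(40, 0.0, 0.0, noise_sd=0.1, seed=100 + i))
            flagged += cn.classify_task_responsive(sp, geometry).responsive
        assert flagged / 1000 <= 0.005

    def test_underpowered_below_minimum_trials(self, geometry):
        sp = make_spatial(pre_post_matrix(5, 0.0, 1.0, noise_sd=0.01, seed=4))
        res = cn.classify_task_responsive(sp, geometry)
        assert res.underpowered
        assert not res.responsive  # 2 * 0.5^5 > 0.001: unattainable


@pytest.fixture(scope="module")
def recovery():
    specs = [
        cn.NeuronSpec(category="corridor", peak_rate=6.0),
        cn.NeuronSpec(category="locomotion", peak_rate=8.0),
        cn.NeuronSpec(category="lick", peak_rate=12.0),
        cn.NeuronSpec(category="reward_zone", anchor_pos=88.0, peak_rate=8.0),
        cn.NeuronSpec(category="untuned"),
    ]
    bundle = cn.simulate_session(
        lick_policy=cn.LickPolicy(mode="uniform", rate=0.05),
        neuron_specs=specs, n_trials=40, seed=42,
    )
    dff = cn.compute_dff(bundle.fluorescence, bundle.calcium.frame_rate)
    return bundle, cn.classify_neurons(bundle, dff, seed=1)


class TestAssignCategory:
    @pytest.mark.parametrize(
        "idx,expected",
        [(0, "corridor"), (1, "locomotion"), (2, "lick"), (3, "reward_zone")],
    )
    def test_planted_category_recovered(self, recovery, idx, expected):
        _, labels = recovery
        assert labels.loc[idx, "category"] == expected

    def test_untuned_not_responsive(self, recovery):
        _, labels = recovery
        assert not labels.loc[4, "task_responsive"]
        assert labels.loc[4, "category"] == "other"

    def test_not_responsive_means_no_category(self, geometry, small_bundle, small_dff):
        res = cn.classify_task_responsive(
            make_spatial(pre_post_matrix(20, 0.2, 0.2)), geometry
        )
        cat, ambiguous = cn.assign_category(res, small_dff, small_bundle, 1)
        assert cat == "other" and not ambiguous


class TestLickResponseTest:
    def test_planted_lick_neuron_significant(self):
        bundle = cn.simulate_session(
            lick_policy=cn.LickPolicy(mode="uniform", rate=0.05),
            neuron_specs=[cn.NeuronSpec(category="lick", peak_rate=15.0)],
            n_trials=40, seed=5,
        )
        dff = cn.compute_dff(bundle.fluorescence, 40.0)
        res = cn.lick_response_test(dff, bundle, neuron=0, seed=6)
        assert not res.skipped
        assert res.mean_licking > res.mean_non_licking
        assert res.p_value < 0.001

    def test_lick_independent_neuron_null_calibration(self):
        # across independent null sessions the p-values stay unremarkable:
        # none significant at the classification alpha, at most one below 0.05
        ps = []
        for seed in (7, 17, 27, 37, 47):
            bundle = cn.simulate_session(
                lick_policy=cn.LickPolicy(mode="uniform", rate=0.05),
                neuron_specs=[cn.NeuronSpec(category="untuned", baseline_rate=2.0)],
                n_trials=40, seed=seed,
            )
            dff = cn.compute_dff(bundle.fluorescence, 40.0)
            res = cn.lick_response_test(dff, bundle, neuron=0, seed=seed + 1)
            assert not res.skipped
            ps.append(res.p_value)
        assert min(ps) >= 0.001
        assert sum(p < 0.05 for p in ps) <= 1

    def test_no_corridor_licks_skipped(self):
        bundle = cn.simulate_session(
            lick_policy=cn.LickPolicy(mode="none"),
            neuron_specs=[cn.NeuronSpec(category="untuned")],
            n_trials=10, seed=9,
        )
        dff = cn.compute_dff(bundle.fluorescence, 40.0)
        res = cn.lick_response_test(dff, bundle, neuron=0, seed=10)
        assert res.skipped
        assert np.isnan(res.p_value)


class TestRewardLocation:
    def test_planted_reward_zone_flagged(self, phase2_bundle):
        dff = cn.compute_dff(phase2_bundle.fluorescence, 40.0)
        labels = cn.classify_neurons(phase2_bundle, dff, seed=1)
        assert labels.loc[0, "reward_location"] is True or labels.loc[0, "reward_location"] == True  # noqa: E712

    def test_grating_offset_neuron_excluded(self, phase2_bundle):
        # responds only at the cued wall transition -> fails the uncued test
        dff = cn.compute_dff(phase2_bundle.fluorescence, 40.0)
        labels = cn.classify_neurons(phase2_bundle, dff, seed=1)
        assert labels.loc[1, "p_cued"] < 0.001
        assert labels.loc[1, "p_uncued"] > 0.001
        assert not labels.loc[1, "reward_location"]

    def test_untuned_not_flagged(self, phase2_bundle):
        dff = cn.compute_dff(phase2_bundle.fluorescence, 40.0)
        labels = cn.classify_neurons(phase2_bundle, dff, seed=1)
        assert not labels.loc[2, "reward_location"]

    def test_one_sided_direction_required(self, geometry):
        # strong *decrease* must not be flagged (test is R_post > R_pre)
        cued = make_spatial(pre_post_matrix(20, 1.0, 0.0, noise_sd=0.02, seed=11))
        uncued = make_spatial(pre_post_matrix(20, 1.0, 0.0, noise_sd=0.02, seed=12))
        flag, p_c, p_u = cn.classify_reward_location(cued, uncued, geometry)
        assert flag is False
        assert p_c > 0.5 and p_u > 0.5

    def test_too_few_uncued_trials_undetermined(self, geometry):
        cued = make_spatial(pre_post_matrix(20, 0.0, 1.0, noise_sd=0.02, seed=13))
        uncued = make_spatial(pre_post_matrix(4, 0.0, 1.0, noise_sd=0.02, seed=14))
        flag, _, _ = cn.classify_reward_location(cued, uncued, geometry)
        assert flag is None


class TestGainModulated:
    def _profile(self, peak_center_cm, bin_width=2.0, n_bins=80, n_trials=10, scale=1.0):
        m = np.zeros((n_trials, n_bins))
        centers = bin_width * (np.arange(n_bins) + 0.5)
        m[:] = scale * np.exp(-0.5 * ((centers - peak_center_cm) / 5.0) ** 2)
        return make_spatial(m, bin_width=bin_width, frame="treadmill")

    def test_treadmill_anchored_recovered(self, gain_bundle):
        dff = cn.compute_dff(gain_bundle.fluorescence, 40.0)
        labels = cn.classify_neurons(gain_bundle, dff, seed=1)
        assert labels.loc[0, "gain_modulated"]
        assert 75.0 <= labels.loc[0, "peak_gain1_cm"] < 100.0
        assert 75.0 <= labels.loc[0, "peak_gain075_cm"] < 100.0

    def test_virtual_anchored_not_flagged(self, gain_bundle):
        # anchored at 80 cm *virtual* = ~107 cm treadmill under gain 0.75
        dff = cn.compute_dff(gain_bundle.fluorescence, 40.0)
        labels = cn.classify_neurons(gain_bundle, dff, seed=1)
        assert not labels.loc[1, "gain_modulated"]
        assert labels.loc[1, "peak_gain075_cm"] > 100.0

    def test_boundary_lower_edge_inclusive(self, geometry):
        # peak exactly at onset - 5 = 75 cm treadmill -> flagged
        flag, pk1, _ = cn.classify_gain_modulated(
            self._profile(75.0), self._profile(75.0), geometry
        )
        assert pk1 == 75.0
        assert flag is True

    def test_boundary_upper_edge_exclusive(self, geometry):
        # peak at onset + 20 = 100 cm treadmill -> outside the window
        flag, pk1, _ = cn.classify_gain_modulated(
            self._profile(101.0), self._profile(85.0), geometry
        )
        assert flag is False

    def test_invariant_to_response_scaling(self, geometry):
        a = cn.classify_gain_modulated(self._profile(85.0), self._profile(90.0), geometry)
        b = cn.classify_gain_modulated(
            self._profile(85.0, scale=7.3), self._profile(90.0, scale=0.01), geometry
        )
        assert a == b

    def test_requires_treadmill_frame(self, geometry):
        sp = make_spatial(np.ones((4, 10)), frame="virtual")
        with pytest.raises(ValueError, match="treadmill"):
            cn.classify_gain_modulated(sp, sp, geometry)

    def test_all_missing_profile_undetermined(self, geometry):
        sp = make_spatial(np.full((4, 80), np.nan), frame="treadmill")
        flag, pk1, pk075 = cn.classify_gain_modulated(sp, sp, geometry)
        assert flag is None and np.isnan(pk1)


@pytest.fixture(scope="module")
def variable_speed_bundle():
    # strong speed variability -> position and time alignments separate
    return cn.simulate_session(
        lick_policy=cn.LickPolicy(mode="none"),
        n_trials=20, seed=15, speed_sigma=0.6,
    )


class TestDistanceTimeConsistency:
    def _craft_dff(self, bundle, kind):
        t = bundle.frames["time_s"].to_numpy()
        v = bundle.frames["virtual_cm"].to_numpy()
        out = np.zeros(bundle.n_frames)
        for tr in bundle.trials:
            sl = bundle.trial_frame_slice(tr)
            if kind == "position":
                out[sl] = np.exp(-0.5 * ((v[sl] - 85.0) / 6.0) ** 2)
            else:
                tt = t[sl] - t[sl][0]
                out[sl] = np.exp(-0.5 * ((tt - 3.0) / 0.5) ** 2)
        return DffTrace(out[None, :], np.array([1.0]), FilterSpec())

    def test_position_locked_more_consistent_in_distance(self, variable_speed_bundle):
        dff = self._craft_dff(variable_speed_bundle, "position")
        cv_d, cv_t = cn.distance_time_consistency(dff, variable_speed_bundle, 0)
        assert cv_d < cv_t

    def test_time_locked_more_consistent_in_time(self, variable_speed_bundle):
        dff = self._craft_dff(variable_speed_bundle, "time")
        cv_d, cv_t = cn.distance_time_consistency(dff, variable_speed_bundle, 0)
        assert cv_t < cv_d

    def test_too_few_trials_rejected(self, small_bundle, small_dff):
        with pytest.raises(ValueError, match="trials"):
            cn.distance_time_consistency(small_dff, small_bundle, 0)
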