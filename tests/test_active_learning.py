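"""Active-learning components: thresholds, step checks, sampling, the loop."""

import numpy as np
import pytest

from msalnamd import (ALConfig, UQThresholds, broaden_training_set,
                      build_initial_set, check_step, compute_thresholds,
                      make_lvc_model, normal_mode_data,
                      probability_uncertain_points, run_al, spawn_gapmd,
                      threshold_from_deviations, wigner_sample)
from msalnamd.descriptors_model import TrainConfig
from msalnamd.surface_hopping import Trajectory
from msalnamd.units import FS_TO_AU_TIME

DT = 0.1 * FS_TO_AU_TIME


class TestThresholds:
    def test_hand_median_mad(self):
        med, mad, thr = threshold_from_deviations([0.1, 0.2, 0.3, 0.4, 0.5])
        assert med == pytest.approx(0.3)
        assert mad == pytest.approx(0.1)
        assert thr == pytest.approx(0.6)

    def test_constant_deviations(self):
        med, mad, thr = threshold_from_deviations([0.25] * 7)
        assert mad == 0.0 and thr == pytest.approx(0.25)

    def test_identical_models_give_zero(self, trained_main, lvc_1atom_2state):
        geoms = [lvc_1atom_2state.ref_coords + 0.01 * i for i in range(5)]
        thr = compute_thresholds(trained_main, trained_main, geoms,
                                 lvc_1atom_2state.elements)
        np.testing.assert_array_equal(thr.thresholds, 0.0)

    def test_empty_validation_rejected(self, trained_main,
                                       lvc_1atom_2state):
        with pytest.raises(ValueError):
            compute_thresholds(trained_main, trained_main, [],
                               lvc_1atom_2state.elements)

    def test_threshold_invariant(self):
        thr = UQThresholds(thresholds=[0.6], medians=[0.3], mads=[0.1])
        assert thr.thresholds[0] >= thr.medians[0] >= 0


class TestCheckStep:
    thr = UQThresholds(thresholds=[0.01, 0.02], medians=[0.005, 0.01],
                       mads=[0.001, 0.003])

    def test_negative_gap_detected_first(self):
        # inverted ordering AND huge uncertainty: negative gap wins
        v = check_step([0.0, -0.01], [5.0, 5.0], 0, self.thr)
        assert v == "negative_gap"

    def test_uncertain_current(self):
        v = check_step([0.0, 0.1], [0.0101 * 1.01, 0.1], 0, self.thr)
        assert v == "uncertain_current"

    def test_uncertain_adjacent(self):
        v = check_step([0.0, 0.1], [0.0, 0.1 + 0.021], 0, self.thr)
        assert v == "uncertain_adjacent"

    def test_ok(self):
        assert check_step([0.0, 0.1], [0.001, 0.101], 0, self.thr) == "ok"

    def test_middle_state_checks_both_neighbors(self):
        thr = UQThresholds(thresholds=[0.01] * 3, medians=[0.0] * 3,
                           mads=[0.0] * 3)
        assert check_step([0.0, 0.1, 0.05], [0.0, 0.1, 0.05], 1,
                          thr) == "negative_gap"


def synthetic_monitored_trajectory(p_aux_shift=0.0, n=50, dt=10.0):
    """Trajectory with a V-shaped gap minimum mid-way, plus aux energies."""
    times = dt * np.arange(n)
    e = np.zeros((n, 2))
    gap = 0.05 + 0.001 * np.abs(np.arange(n) - n // 2)
    e[:, 1] = gap
    aux = e.copy()
    aux[:, 1] += p_aux_shift
    return Trajectory(
        times=times, coords=np.zeros((n, 1, 3)),
        velocities=np.zeros((n, 1, 3)),
        active_state=np.ones(n, dtype=int), energies=e,
        kinetic=np.zeros(n), aux_energies=aux,
    )


class TestProbabilityUncertainPoints:
    def test_identical_aux_gives_nothing(self):
        traj = synthetic_monitored_trajectory(0.0)
        assert probability_uncertain_points(traj) == []

    def test_disagreeing_aux_is_flagged(self):
        traj = synthetic_monitored_trajectory(-0.045)  # much smaller aux gap
        pts = probability_uncertain_points(traj, tol=0.10)
        assert len(pts) == 1

    def test_cap_is_respected(self):
        trajs = [synthetic_monitored_trajectory(-0.045) for _ in range(40)]
        pts = probability_uncertain_points(trajs, cap=15, seed=1)
        assert len(pts) == 15

    def test_seeded_subset_determinism(self):
        trajs = [synthetic_monitored_trajectory(-0.045) for _ in range(40)]
        a = probability_uncertain_points(trajs, cap=15, seed=5)
        b = probability_uncertain_points(trajs, cap=15, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


def completed_trajectory(n=20, n_states=2):
    return Trajectory(
        times=np.arange(float(n)), coords=np.zeros((n, 1, 3)),
        velocities=np.zeros((n, 1, 3)),
        active_state=np.ones(n, dtype=int),
        energies=np.zeros((n, n_states)), kinetic=np.zeros(n),
    )


class TestSpawnGapMD:
    def test_even_branch_split(self):
        trajs = [completed_trajectory() for _ in range(50)]
        spawns = spawn_gapmd(trajs, n_states=2, seed=0)
        branches = [b for _, _, b in spawns]
        assert len(spawns) == 50
        assert branches.count("upper") == 25
        assert branches.count("lower") == 25

    def test_uncertain_at_step_zero_is_skipped(self):
        bad = completed_trajectory()
        bad.verdict = "uncertain_current"
        bad.stop_step = 0
        spawns = spawn_gapmd([bad], n_states=2, seed=0)
        assert spawns == []

    def test_two_state_pair_is_always_01(self):
        trajs = [completed_trajectory() for _ in range(10)]
        assert all(p == (0, 1) for _, p, _ in spawn_gapmd(trajs, 2, seed=3))

    def test_spawn_uses_certain_steps_only(self):
        t = completed_trajectory(n=30)
        t.verdict = "uncertain_adjacent"
        t.stop_step = 5
        for seed in range(10):
            spawns = spawn_gapmd([t], n_states=2, seed=seed)
            # the chosen step's coordinates come from the certain prefix
            assert len(spawns) == 1


class TestBroadening:
    def test_doubles_and_labels_with_reference(self, trained_main,
                                               lvc_1atom_2state, labeled_500):
        from msalnamd import eval_adiabatic

        sub = labeled_500[:10]
        out = broaden_training_set(sub, trained_main, lvc_1atom_2state,
                                   seed=4)
        assert len(out) == 20
        for rec in out.records[10:]:
            assert rec.tag == "broadening"
            ref = eval_adiabatic(lvc_1atom_2state, rec.coords)
            np.testing.assert_array_equal(rec.energies, ref.energies)

    def test_seeded_determinism(self, trained_main, lvc_1atom_2state,
                                labeled_500):
        sub = labeled_500[:5]
        a = broaden_training_set(sub, trained_main, lvc_1atom_2state, seed=9)
        b = broaden_training_set(sub, trained_main, lvc_1atom_2state, seed=9)
        for ra, rb in zip(a.records[5:], b.records[5:]):
            np.testing.assert_array_equal(ra.coords, rb.coords)


class TestBuildInitialSet:
    def test_stop_fraction_one_stops_at_two_batches(self, lvc_1atom_2state):
        nm = normal_mode_data(lvc_1atom_2state)
        data, hist = build_initial_set(nm, lvc_1atom_2state, batch=20,
                                       stop_fraction=1.0, seed=1)
        assert len(hist) == 2
        assert len(data) == 40

    def test_size_bookkeeping(self, lvc_1atom_2state):
        nm = normal_mode_data(lvc_1atom_2state)
        data, hist = build_initial_set(nm, lvc_1atom_2state, batch=25,
                                       stop_fraction=0.10, seed=2,
                                       max_batches=4)
        assert len(data) == 25 * len(hist)

    def test_cv_history_decreases_in_median(self, lvc_1atom_2state):
        """CV error history is non-increasing in the median across seeds."""
        nm = normal_mode_data(lvc_1atom_2state)
        firsts, lasts = [], []
        for seed in (0, 1, 2):
            _, hist = build_initial_set(nm, lvc_1atom_2state, batch=30,
                                        stop_fraction=0.0, seed=seed,
                                        max_batches=3)
            firsts.append(hist[0])
            lasts.append(hist[-1])
        assert np.median(lasts) <= np.median(firsts)


class TestRunAL:
    def test_exact_reference_converges_immediately(self, lvc_1atom_2state,
                                                   labeled_500):
        """With main == aux == a perfect wrapper, nothing is ever uncertain
        and AL converges at iteration 1."""
        from msalnamd.active_learning import ALMonitor, ALState
        from msalnamd.surface_hopping import propagate_tsh

        class OracleWrapper:
            """Presents the analytic oracle through the ML-model interface."""

            def __init__(self, model, elements):
                self.model = model
                self.elements = elements
                self.n_states = model.n_states

            def evaluate(self, coords):
                return self.model.evaluate(coords)

            def energies(self, coords):
                return self.model.evaluate(coords).energies

        m = lvc_1atom_2state
        wrapper = OracleWrapper(m, m.elements)
        thr = compute_thresholds_like_zero = UQThresholds(
            thresholds=[1e-12, 1e-12], medians=[0, 0], mads=[0, 0]
        )
        monitor = ALMonitor(wrapper, thr)
        nm = normal_mode_data(m)
        ic = wigner_sample(nm, 1, seed=0)[0]
        ic.state = 1
        traj = propagate_tsh(ic, wrapper, dt=DT, max_time=100 * DT, seed=0,
                             al_monitor=monitor)
        assert traj.verdict == "completed"
        np.testing.assert_array_equal(traj.uq, 0.0)

    def test_al_loop_smoke(self, lvc_1atom_2state):
        """Two iterations of the full loop run, record provenance, and keep
        thresholds immutable."""
        nm = normal_mode_data(lvc_1atom_2state)
        cfg = ALConfig(
            n_states=2, n_tsh=4, initial_state=1, dt=DT, max_time=150 * DT,
            gapmd_max_time=100 * DT, batch=20, max_iterations=2,
            train_schedule=TrainConfig(epochs=300, patience=300), seed=3,
        )
        state = run_al(nm, lvc_1atom_2state, cfg)
        assert state.iteration <= 2
        assert state.thresholds is not None
        assert len(state.history) >= 1
        # training set grows across non-final iterations
        n_train = [h["n_train"] for h in state.history]
        assert all(b > a for a, b in zip(n_train, n_train[1:]))
        # provenance: every non-initial record carries exactly one tag
        tags = {r.tag for r in state.training_set if r.tag != "initial"}
        allowed = {"negative_gap", "uncertain_current", "uncertain_adjacent",
                   "probability", "gapmd-negative_gap",
                   "gapmd-uncertain_current", "gapmd-uncertain_adjacent"}
        assert tags <= allowed
        assert all(r.tag is not None for r in state.training_set)

    def test_convergence_ratio_excludes_gapmd(self):
        """The recorded ratio counts only ML-TSH trajectories."""
        # synthesized from the history bookkeeping: ratio = completed / n_tsh
        from msalnamd.active_learning import ALState

        st = ALState(iteration=1, training_set=None, main_model=None,
                     aux_model=None, thresholds=None,
                     history=[{"convergence_ratio": 0.75}])
        assert st.convergence_ratio == 0.75
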