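"""Descriptors and the multi-state ML potential."""

import numpy as np
import pytest

from msalnamd import (DescriptorConfig, DisplacementConfig, LossWeights,
                      MultiStateModel, TrainConfig, compute_loss, featurize,
                      train)
from msalnamd.descriptors_model import fit_self_atomic_energies
from msalnamd.training_data import TrainingRecord, TrainingSet
from msalnamd._mlp import MLP


@pytest.fixture(scope="module")
def symfun():
    return DescriptorConfig(elements=("H", "C", "O"))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestSymmetryFunctions:
    def test_beyond_cutoff_features_vanish(self, symfun):
        coords = np.array([[0.0, 0, 0], [0, 0, 30.0]])  # Bohr, ~15.9 A apart
        desc = featurize(coords, ["C", "C"], symfun)
        np.testing.assert_array_equal(desc, 0.0)

    def test_rotation_translation_invariance(self, symfun, rng):
        coords = np.array([[0.0, 0, 0], [2.1, 0.3, -0.2], [0.5, 2.2, 0.8]])
        elements = ["C", "O", "H"]
        base = featurize(coords, elements, symfun)
        for _ in range(5):
            r = random_rotation(rng)
            moved = coords @ r.T + rng.standard_normal(3)
            np.testing.assert_allclose(
                featurize(moved, elements, symfun), base, atol=1e-10
            )

    def test_same_element_permutation_invariance(self, symfun):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
        a = featurize(coords, ["C", "H", "H"], symfun)
        swapped = coords[[0, 2, 1]]
        b = featurize(swapped, ["C", "H", "H"], symfun)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_allclose(np.sort(a[1:], axis=0),
                                   np.sort(b[1:], axis=0), atol=1e-12)

    def test_unsupported_element_rejected(self, symfun):
        with pytest.raises(ValueError, match="not in supported set"):
            featurize(np.zeros((1, 3)), ["Xx"], symfun)

    def test_jacobian_matches_finite_differences(self, symfun, rng):
        coords = np.array([[0.0, 0, 0], [2.3, 0.4, 0], [0.2, 2.7, 1.0]])
        elements = ["C", "O", "H"]
        desc, jac = symfun.featurize_with_jacobian(coords, elements)
        eps = 1e-6
        for a in range(3):
            for c in range(3):
                xp, xm = coords.copy(), coords.copy()
                xp[a, c] += eps
                xm[a, c] -= eps
                fd = (featurize(xp, elements, symfun)
                      - featurize(xm, elements, symfun)) / (2 * eps)
                np.testing.assert_allclose(jac[:, :, a, c], fd, atol=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DescriptorConfig(angular_cutoff=6.0)  # exceeds radial cutoff
        with pytest.raises(ValueError):
            DescriptorConfig(radial_cutoff=-1.0)


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        e = [np.array([0.0, 0.1]), np.array([0.05, 0.2, 0.4])]
        f = [np.zeros((2, 1, 3)), np.ones((3, 2, 3))]
        loss = compute_loss(e, f, e, f, LossWeights())
        assert loss.total == loss.energy == loss.force == loss.gap == 0.0

    def test_hand_computed_example(self):
        e_ref = [np.array([0.0, 0.1])]
        e_ml = [np.array([0.01, 0.13])]
        loss = compute_loss(e_ml, None, e_ref, None,
                            LossWeights(1.0, 0.0, 1.0))
        assert loss.energy == pytest.approx(0.0005)
        assert loss.gap == pytest.approx(0.0004)
        assert loss.total == pytest.approx(0.0009)

    def test_gap_weight_linearity(self):
        e_ref = [np.array([0.0, 0.1, 0.25])]
        e_ml = [np.array([0.02, 0.08, 0.3])]
        l1 = compute_loss(e_ml, None, e_ref, None, LossWeights(1.0, 0.0, 1.0))
        l2 = compute_loss(e_ml, None, e_ref, None, LossWeights(1.0, 0.0, 2.0))
        assert l2.total - l2.energy == pytest.approx(2 * (l1.total - l1.energy))

    def test_mismatched_state_counts_rejected(self):
        with pytest.raises(ValueError, match="state counts"):
            compute_loss([np.array([0.0, 1.0])], None, [np.array([0.0])],
                         None, LossWeights())


def _zero_weight_model(descriptor, elements=("C",), n_states=2):
    rng = np.random.default_rng(0)
    nets = {}
    for e in descriptor.site_elements(list(elements)):
        net = MLP((descriptor.dim + 1, 8, 1), rng)
        net.weights = [np.zeros_like(w) for w in net.weights]
        net.biases = [np.zeros_like(b) for b in net.biases]
        nets[e] = net
    return MultiStateModel(descriptor=descriptor, networks=nets,
                           sae={e: 1.5 for e in elements},
                           n_states_trained=n_states)


class TestPrediction:
    def test_zero_network_returns_self_atomic_energies(self):
        desc = DisplacementConfig(ref_coords=np.zeros((1, 3)))
        model = _zero_weight_model(desc)
        e = model.predict_states(np.ones((1, 3)), ["C"], [0, 1, 2])
        np.testing.assert_allclose(e, 1.5)

    def test_zero_network_zero_forces(self):
        desc = DisplacementConfig(ref_coords=np.zeros((1, 3)))
        model = _zero_weight_model(desc)
        f = model.predict_forces(np.ones((1, 3)), ["C"], [0, 1])
        np.testing.assert_array_equal(f, 0.0)

    def test_state_order_swap(self, trained_main, lvc_1atom_2state):
        x = lvc_1atom_2state.ref_coords + 0.05
        e01 = trained_main.predict_states(x, lvc_1atom_2state.elements, [0, 1])
        e10 = trained_main.predict_states(x, lvc_1atom_2state.elements, [1, 0])
        np.testing.assert_allclose(e01, e10[::-1], atol=1e-14)

    def test_state_feature_reaches_output(self):
        desc = DisplacementConfig(ref_coords=np.zeros((1, 3)))
        rng = np.random.default_rng(42)
        nets = {"SYS": MLP((desc.dim + 1, 16, 1), rng)}
        model = MultiStateModel(descriptor=desc, networks=nets,
                                sae={"C": 0.0}, n_states_trained=2)
        e = model.predict_states(0.3 * np.ones((1, 3)), ["C"], [0, 1])
        assert abs(e[1] - e[0]) > 1e-6

    def test_forces_match_finite_differences(self, trained_main,
                                             lvc_1atom_2state, rng):
        elements = lvc_1atom_2state.elements
        x = lvc_1atom_2state.ref_coords + 0.1 * rng.standard_normal((1, 3))
        f = trained_main.predict_forces(x, elements, [0, 1])
        eps = 1e-4
        for c in range(3):
            xp, xm = x.copy(), x.copy()
            xp[0, c] += eps
            xm[0, c] -= eps
            fd = -(trained_main.predict_states(xp, elements, [0, 1])
                   - trained_main.predict_states(xm, elements, [0, 1])) / (2 * eps)
            np.testing.assert_allclose(f[:, 0, c], fd, rtol=1e-4, atol=1e-9)

    def test_net_force_vanishes_with_invariant_descriptors(self, rng):
        """Translation invariance of symmetry functions implies zero total
        force for any network."""
        desc = DescriptorConfig(elements=("C", "H"))
        rng_net = np.random.default_rng(7)
        nets = {e: MLP((desc.dim + 1, 16, 1), rng_net) for e in ("C", "H")}
        model = MultiStateModel(descriptor=desc, networks=nets,
                                sae={"C": 0.0, "H": 0.0}, n_states_trained=1)
        coords = np.array([[0.0, 0, 0], [2.2, 0.1, 0.3], [0.1, 2.5, -0.4]])
        f = model.predict_forces(coords, ["C", "H", "H"], [0])
        np.testing.assert_allclose(f.sum(axis=1), 0.0, atol=1e-8)

    def test_extrapolation_warns_not_raises(self, trained_main,
                                            lvc_1atom_2state, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="msalnamd.descriptors_model"):
            e = trained_main.predict_states(
                lvc_1atom_2state.ref_coords, lvc_1atom_2state.elements, [5]
            )
        assert np.isfinite(e).all()
        assert any("extrapolat" in r.message for r in caplog.records)


class TestTraining:
    def test_smoke_benchmark_mae(self, trained_main, lvc_1atom_2state, rng):
        """500 Wigner-labeled points on the 1-atom 2-state surface give
        sub-mHa validation energy errors."""
        from msalnamd import eval_adiabatic, normal_mode_data, wigner_sample

        nm = normal_mode_data(lvc_1atom_2state)
        test = wigner_sample(nm, 150, seed=99)
        errs = []
        for s in test:
            ref = eval_adiabatic(lvc_1atom_2state, s.coords).energies
            pred = trained_main.predict_states(
                s.coords, lvc_1atom_2state.elements, [0, 1]
            )
            errs.append(np.abs(pred - ref))
        mae = np.mean(errs, axis=0)
        assert np.all(mae < 1e-3), mae

    def test_seeded_determinism(self, labeled_500):
        sched = TrainConfig(epochs=60, patience=60)
        m1, _ = train(labeled_500[:80], "main", seed=11, schedule=sched)
        m2, _ = train(labeled_500[:80], "main", seed=11, schedule=sched)
        for e in m1.networks:
            for w1, w2 in zip(m1.networks[e].weights, m2.networks[e].weights):
                np.testing.assert_array_equal(w1, w2)

    def test_auxiliary_ignores_forces(self, labeled_500):
        sched = TrainConfig(epochs=60, patience=60)
        sub = labeled_500[:60]
        a1, _ = train(sub, "auxiliary", seed=2, schedule=sched)
        perturbed = TrainingSet(
            [
                TrainingRecord(r.coords, r.elements, r.energies,
                               r.forces + 1.0)
                for r in sub
            ]
        )
        a2, _ = train(perturbed, "auxiliary", seed=2, schedule=sched)
        for e in a1.networks:
            for w1, w2 in zip(a1.networks[e].weights, a2.networks[e].weights):
                np.testing.assert_array_equal(w1, w2)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train(TrainingSet([]), "main")

    def test_main_requires_forces(self, labeled_500):
        no_forces = TrainingSet(
            [TrainingRecord(r.coords, r.elements, r.energies, None)
             for r in labeled_500[:10]]
        )
        with pytest.raises(ValueError, match="forces"):
            train(no_forces, "main")

    def test_heterogeneous_state_counts(self, lvc_1atom_2state, rng):
        """Mixed 2-state and 4-state records train together and the model
        predicts all four states."""
        from msalnamd import generate_labeled_set, make_lvc_model

        m4 = make_lvc_model(1, 4, seed=8)
        g2 = m4.ref_coords + 0.1 * rng.standard_normal((30, 1, 3))
        g4 = m4.ref_coords + 0.1 * rng.standard_normal((30, 1, 3))
        full = generate_labeled_set(m4, list(g2) + list(g4))
        mixed = TrainingSet(
            [
                TrainingRecord(r.coords, r.elements, r.energies[:2],
                               r.forces[:2])
                for r in full[:30]
            ]
            + list(full[30:].records)
        )
        model, _ = train(mixed, "main", seed=0,
                         schedule=TrainConfig(epochs=80, patience=80))
        e = model.predict_states(m4.ref_coords, m4.elements, [0, 1, 2, 3])
        assert np.all(np.isfinite(e))
        assert model.n_states_trained == 4


def test_self_atomic_energy_fit():
    rng = np.random.default_rng(0)
    true = {"C": -37.8, "H": -0.5}
    records = []
    for _ in range(20):
        n_c, n_h = rng.integers(1, 4), rng.integers(0, 5)
        elements = ["C"] * n_c + ["H"] * n_h
        e0 = n_c * true["C"] + n_h * true["H"]
        records.append(
            TrainingRecord(np.zeros((len(elements), 3)), elements,
                           np.array([e0]))
        )
    sae = fit_self_atomic_energies(TrainingSet(records))
    assert sae["C"] == pytest.approx(true["C"], abs=1e-8)
    assert sae["H"] == pytest.approx(true["H"], abs=1e-8)


def test_model_roundtrip(tmp_path, trained_main, lvc_1atom_2state):
    path = tmp_path / "model.npz"
    trained_main.save(path)
    loaded = MultiStateModel.load(path)
    x = lvc_1atom_2state.ref_coords + 0.07
    np.testing.assert_array_equal(
        trained_main.predict_states(x, lvc_1atom_2state.elements, [0, 1]),
        loaded.predict_states(x, lvc_1atom_2state.elements, [0, 1]),
    )
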