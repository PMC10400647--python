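"""Hybrid estimators: construction, training, baselines and the reservoir."""

import numpy as np
import pytest

from amn.autodiff import Tensor
from amn.estimators import (AMNRegressor, ANNFluxRegressor, UptakeNetwork,
                            build_reservoir)
from amn.evaluation import q2_score
from amn.fba import solve_fba
from amn.synthetic import ToyWorld, affine_uptake_map, make_toy_network


def _chain_data(n=50, seed=1, include_zeros=True):
    model, _ = make_toy_network("chain", length=2)
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.5, 5.0, size=(n, 1))
    if include_zeros:
        X[rng.random(n) < 0.4] = 0.0
    y = np.array([solve_fba(model, x).growth_rate for x in X])
    return model, X, y


@pytest.fixture(scope="module")
def chain_fit():
    """One trained AMN-QP on the chain, shared across read-only tests."""
    model, X, y = _chain_data()
    est = AMNRegressor(model=model, solver="qp", mode="UB",
                       hidden_sizes=(16,), dropout=0.0, epochs=200,
                       batch_size=5, learning_rate=5e-3, n_solver_iter=4,
                       seed=0).fit(X, y)
    return model, X, y, est


class TestConstruction:
    def test_wt_with_exact_bounds_rejected(self):
        model, _, _ = _chain_data(n=5)
        est = AMNRegressor(model=model, solver="wt", mode="EB")
        with pytest.raises(ValueError, match="exact bounds"):
            est.fit(np.ones((5, 1)), np.ones(5))

    def test_no_hidden_layer_is_single_linear_map(self):
        model, X, y = _chain_data(n=20)
        est = AMNRegressor(model=model, hidden_sizes=(), dropout=0.0,
                           epochs=2, seed=0).fit(X, y)
        assert len(est.net_.weights) == 1
        assert est.net_.weights[0].shape == (model.n_in, model.n)

    def test_hidden_500_shapes_for_core_model(self, ecoli_core_split):
        est = AMNRegressor(model=ecoli_core_split, hidden_sizes=(500,))
        P, net, _ = est._build()
        assert [w.shape for w in net.weights] == [(20, 500), (500, 154)]

    def test_unknown_solver_rejected(self):
        model, _, _ = _chain_data(n=3)
        with pytest.raises(ValueError, match="solver"):
            AMNRegressor(model=model, solver="simplex").fit(
                np.ones((3, 1)), np.ones(3))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model, _, _ = _chain_data(n=3)
        est = AMNRegressor(model=model, epochs=7, seed=3)
        cloned = clone(est)
        assert cloned.epochs == 7 and cloned.seed == 3


class TestTraining:
    @pytest.mark.parametrize("solver", ["qp", "lp", "wt"])
    def test_toy_training_reaches_high_q2(self, solver):
        model, X, y = _chain_data()
        est = AMNRegressor(model=model, solver=solver, mode="UB",
                           hidden_sizes=(16,), dropout=0.0, epochs=200,
                           batch_size=5, learning_rate=5e-3, seed=0)
        est.fit(X, y)
        assert q2_score(y, est.predict(X)) >= 0.95

    def test_eb_mode_clamps_uptake_bit_exact(self):
        model, X, y = _chain_data(include_zeros=False)
        est = AMNRegressor(model=model, solver="qp", mode="EB",
                           hidden_sizes=(16,), dropout=0.0, epochs=60,
                           learning_rate=5e-3, seed=0).fit(X, y)
        V, _ = est.predict_fluxes(X[:7])
        assert np.array_equal(V[:, 0], X[:7, 0])

    def test_zero_epochs_leaves_parameters_at_init(self):
        model, X, y = _chain_data(n=10)
        est = AMNRegressor(model=model, epochs=0, seed=0).fit(X, y)
        ref = AMNRegressor(model=model, epochs=0, seed=0)
        _, net, _ = ref._build()
        for a, b in zip(est.net_.weights, net.weights):
            np.testing.assert_array_equal(a.data, b.data)
        assert est.training_log_ == []

    def test_training_reduces_total_loss_tenfold(self):
        model, X, y = _chain_data()
        est0 = AMNRegressor(model=model, epochs=0, dropout=0.0,
                            hidden_sizes=(16,), seed=0).fit(X, y)
        before = est0._epoch_losses(X, y[:, None])["L_total"]
        est = AMNRegressor(model=model, epochs=200, dropout=0.0,
                           hidden_sizes=(16,), learning_rate=5e-3,
                           seed=0).fit(X, y)
        after = est.training_log_[-1]["L_total"]
        assert after < before / 10

    def test_non_finite_loss_aborts_with_epoch(self):
        model, X, y = _chain_data(n=10)
        est = AMNRegressor(model=model, epochs=5, dropout=0.0,
                           hidden_sizes=(4,), seed=0)
        bad = y.copy()
        bad[0] = np.inf
        with pytest.raises(FloatingPointError, match="epoch"):
            est.fit(X, bad)

    def test_backprop_matches_finite_differences(self):
        """Gradient w.r.t. neural parameters through the unrolled QP layer."""
        model, X, y = _chain_data(n=6)
        est = AMNRegressor(model=model, hidden_sizes=(4,), dropout=0.0,
                           epochs=0, seed=0).fit(X, y)
        Xb, yb = X[:4], y[:4, None]
        loss = est._loss_on(Xb, yb, training=False, rng=None)
        loss.backward()
        for p in est.net_.params:
            g = p.grad.copy()
            fd = np.zeros_like(g)
            it = np.nditer(p.data, flags=["multi_index"])
            eps = 1e-6
            for _ in it:
                i = it.multi_index
                p.data[i] += eps
                lp = est._loss_on(Xb, yb, training=False, rng=None).item()
                p.data[i] -= 2 * eps
                lm = est._loss_on(Xb, yb, training=False, rng=None).item()
                p.data[i] += eps
                fd[i] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(g, fd, atol=1e-4)

    def test_predict_is_deterministic(self, chain_fit):
        _, X, _, est = chain_fit
        a = est.predict(X[:10])
        b = est.predict(X[:10])
        np.testing.assert_array_equal(a, b)

    def test_ko_input_kind_trains_and_zeroes_ko_flux(self):
        """Knockout-aware input: media + binary KO vector, loss L5 active."""
        model, _ = make_toy_network("diamond", yields=(1.0, 0.4))
        rng = np.random.default_rng(0)
        n = 60
        C = np.ones((n, 1))
        R = (rng.random((n, 1)) < 0.5).astype(float)  # pAB knocked out or not
        j = model.reaction_index("pAB")
        y = np.array([
            solve_fba(model, [2.0], ko_indices=() if r else (j,)).growth_rate
            for r in R[:, 0]])
        est = AMNRegressor(model=model, solver="qp", input_kind="C_med+R_KO",
                           ko_ids=["pAB"], hidden_sizes=(16,), dropout=0.0,
                           epochs=200, learning_rate=5e-3, seed=0)
        est.fit(np.hstack([2.0 * C, R]), y)
        assert q2_score(y, est.predict(np.hstack([2.0 * C, R]))) >= 0.9


class TestANNBaseline:
    def test_growth_only_targets_rejected(self):
        model, X, y = _chain_data(n=10)
        ann = ANNFluxRegressor(model=model)
        with pytest.raises(ValueError, match="all-flux"):
            ann.fit(X, y[:, None])

    def test_memorizes_single_row(self):
        model, _, _ = _chain_data(n=1)
        X = np.array([[2.0]])
        V = solve_fba(model, [2.0]).fluxes[None, :]
        ann = ANNFluxRegressor(model=model, hidden_sizes=(8,), dropout=0.0,
                               epochs=800, learning_rate=1e-2, seed=0)
        ann.fit(X, V)
        pred, _ = ann.predict_fluxes(X)
        assert np.mean((pred - V) ** 2) < 1e-3

    def test_untrained_ann_has_larger_constraint_loss_than_trained_amn(self):
        model, X, y = _chain_data()
        ts_inputs = X
        targets = np.array([
            solve_fba(model, x).fluxes if solve_fba(model, x).feasible
            else np.zeros(model.n) for x in X])
        ann = ANNFluxRegressor(model=model, hidden_sizes=(16,), dropout=0.0,
                               epochs=0, seed=0).fit(ts_inputs, targets)
        _, ann_losses = ann.predict_fluxes(X)
        amn = AMNRegressor(model=model, hidden_sizes=(16,), dropout=0.0,
                           epochs=200, learning_rate=5e-3, seed=0).fit(X, y)
        _, amn_losses = amn.predict_fluxes(X)
        ann_total = np.mean([b.total for b in ann_losses])
        amn_total = np.mean([b.total for b in amn_losses])
        assert ann_total > 10 * amn_total

    def test_hybrid_beats_dense_on_equal_rows(self):
        """Same media rows: growth-only AMN keeps constraints tighter than
        the dense net trained on the same number of rows (data efficiency)."""
        model, X, y = _chain_data()
        targets = np.array([
            solve_fba(model, x).fluxes if solve_fba(model, x).feasible
            else np.zeros(model.n) for x in X])
        ann = ANNFluxRegressor(model=model, hidden_sizes=(16,), dropout=0.0,
                               epochs=30, learning_rate=5e-3,
                               seed=0).fit(X, targets)
        amn = AMNRegressor(model=model, hidden_sizes=(16,), dropout=0.0,
                           epochs=200, learning_rate=5e-3, seed=0).fit(X, y)
        _, ann_losses = ann.predict_fluxes(X)
        _, amn_losses = amn.predict_fluxes(X)
        ann_c = np.mean([b.L2 + b.L3 + b.L4 for b in ann_losses])
        amn_c = np.mean([b.L2 + b.L3 + b.L4 for b in amn_losses])
        assert amn_c < ann_c


class TestReservoir:
    def test_freezing_preserves_predictions(self, chain_fit):
        _, X, _, est = chain_fit
        frozen = build_reservoir(est)
        np.testing.assert_array_equal(est.predict(X[:8]), frozen.predict(X[:8]))

    def test_frozen_model_refuses_training(self, chain_fit):
        _, X, y, est = chain_fit
        frozen = build_reservoir(est)
        with pytest.raises(RuntimeError, match="frozen"):
            frozen.fit(X, y)

    def test_untrained_model_cannot_be_frozen(self):
        model, _, _ = _chain_data(n=3)
        with pytest.raises(ValueError, match="untrained"):
            build_reservoir(AMNRegressor(model=model))

    def test_gradient_flows_through_frozen_reservoir(self, chain_fit):
        _, _, _, est = chain_fit
        frozen = build_reservoir(est)
        Vin = Tensor(np.array([[1.5]]), requires_grad=True)
        V0 = frozen.net_.forward(Vin, training=False)
        Vout = frozen.layer_(V0, Vin)
        (Vout.square().sum()).backward()
        assert Vin.grad is not None
        assert np.abs(Vin.grad).max() > 0
        # finite-difference probe of the same scalar path
        def f(v):
            t = Tensor(np.array([[v]]))
            out = frozen.layer_(frozen.net_.forward(t, training=False), t)
            return float(out.square().sum().data)
        fd = (f(1.5 + 1e-5) - f(1.5 - 1e-5)) / 2e-5
        assert Vin.grad.ravel()[0] == pytest.approx(fd, rel=1e-4)

    def test_checksum_unchanged_after_prenet_training(self, chain_fit):
        model, _, _, est = chain_fit
        frozen = build_reservoir(est)
        before = frozen.net_.checksum()
        world = ToyWorld(model, affine_uptake_map(2.0))
        rng = np.random.default_rng(2)
        C = rng.integers(0, 2, size=(30, 1)).astype(float)
        UptakeNetwork(reservoir=frozen, hidden_sizes=(8,), dropout=0.0,
                      epochs=50, learning_rate=1e-3, seed=0).fit(
            C, world.growth(C))
        assert frozen.net_.checksum() == before

    def test_constant_dataset_warns(self, chain_fit):
        _, _, _, est = chain_fit
        frozen = build_reservoir(est)
        with pytest.warns(UserWarning, match="degenerate"):
            UptakeNetwork(reservoir=frozen, hidden_sizes=(4,), epochs=1,
                          seed=0).fit(np.ones((6, 1)), np.ones(6))

    def test_unfrozen_reservoir_rejected(self, chain_fit):
        _, _, _, est = chain_fit
        with pytest.raises(ValueError, match="frozen"):
            UptakeNetwork(reservoir=est).fit(np.ones((4, 1)), np.ones(4))

    def test_recovers_true_uptake_map(self, chain_fit):
        """Two-step scheme: V_in inferred from C_med reproduces the world's
        growth through the independent simplex oracle (R2 >= 0.95)."""
        model, _, _, est = chain_fit
        frozen = build_reservoir(est)
        world = ToyWorld(model, affine_uptake_map(2.0))
        rng = np.random.default_rng(5)
        C = rng.integers(0, 2, size=(60, 1)).astype(float)
        y = world.growth(C)
        un = UptakeNetwork(reservoir=frozen, hidden_sizes=(8,), dropout=0.0,
                           epochs=400, learning_rate=1e-3, seed=0).fit(C, y)
        vin = un.uptake_fluxes(C)
        rescored = np.array([solve_fba(model, v).growth_rate for v in vin])
        assert q2_score(y, rescored) >= 0.95
        # the affine coefficient itself is identified
        assert vin[C[:, 0] == 1].mean() == pytest.approx(2.0, abs=0.1)

    def test_export_bounds_files(self, chain_fit, tmp_path):
        from amn.fba import read_bounds_file

        model, _, _, est = chain_fit
        frozen = build_reservoir(est)
        world = ToyWorld(model, affine_uptake_map(2.0))
        C = np.array([[1.0], [0.0]])
        un = UptakeNetwork(reservoir=frozen, hidden_sizes=(4,), dropout=0.0,
                           epochs=100, learning_rate=1e-3, seed=0).fit(
            C, world.growth(C))
        paths = un.export_bounds(C, tmp_path / "vin")
        assert len(paths) == 2
        bounds = read_bounds_file(paths[0])
        assert set(bounds) == {"up_A_i"}
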