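"""Hybrid neural-mechanistic growth models (scikit-learn style).

:class:`AMNRegressor` couples a trainable dense layer, which maps medium
descriptors to an initial flux vector V0, with a differentiable mechanistic
layer that runs a few unrolled solver iterations (Wt, LP or QP form) to pull
V0 toward a steady-state flux distribution. Training minimizes the fit loss
on the reference fluxes plus the mechanistic constraint losses, with
gradients backpropagated through the unrolled solver.

:class:`ANNFluxRegressor` is the dense "black-box" baseline trained on full
flux distributions. :class:`UptakeNetwork` implements the reservoir scheme:
a trained AMN is frozen and a new pre-network learns medium-composition ->
uptake-flux bounds through it; the recovered bounds feed classical FBA.
"""

from __future__ import annotations

import copy
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .autodiff import Adam, Tensor
from .model_io import MetabolicModel, ProjectionSet, build_projections
from .nn import DenseNet
from .solvers import compute_losses

__all__ = ["AMNRegressor", "ANNFluxRegressor", "UptakeNetwork",
           "build_reservoir"]


# ---------------------------------------------------------------------------
# batched loss terms on the autodiff graph
# ---------------------------------------------------------------------------

def _batch_losses(V: Tensor, S_T, P_ref_T, P_in_T, Vin, y=None,
                  P_KO_T=None, R_KO=None, weights=(1.0, 1.0, 1.0, 1.0, 1.0)):
    """Total loss tensor: mean over the batch of L1..L5 (each dim-normalized)."""
    B = V.shape[0]
    m = S_T.shape[1]
    n = V.shape[1]
    n_in = P_in_T.shape[1]
    terms = []
    if y is not None:
        n_ref = P_ref_T.shape[1]
        r1 = V @ P_ref_T - y
        terms.append(r1.square().sum() * (weights[0] / (n_ref * B)))
    sv = V @ S_T
    terms.append(sv.square().sum() * (weights[1] / (m * B)))
    r3 = (V @ P_in_T - Vin).relu()
    terms.append(r3.square().sum() * (weights[2] / (n_in * B)))
    r4 = (-V).relu()
    terms.append(r4.square().sum() * (weights[3] / (n * B)))
    if P_KO_T is not None and R_KO is not None:
        n_ko = P_KO_T.shape[1]
        r5 = (V @ P_KO_T - R_KO).relu()
        terms.append(r5.square().sum() * (weights[4] / (n_ko * B)))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


# ---------------------------------------------------------------------------
# mechanistic layers (unrolled, autodiff-compatible)
# ---------------------------------------------------------------------------

class _QPLayer:
    """Unrolled gradient-descent refinement on the constraint loss."""

    def __init__(self, model, P: ProjectionSet, n_iter, dt, mode):
        self.n_iter = n_iter
        self.mode = mode
        smax = np.linalg.norm(model.S, 2)
        lip = (2.0 * smax ** 2 / model.m + 2.0 / P.P_in.shape[0]
               + 2.0 / model.n)
        self.dt = 0.9 / lip if dt == "auto" else float(dt)
        self.m, self.n, self.n_in = model.m, model.n, P.P_in.shape[0]
        self._S = Tensor(model.S)
        self._S_T = Tensor(model.S.T)
        self._P_in = Tensor(P.P_in)
        self._P_in_T = Tensor(P.P_in.T)
        mask = np.zeros(model.n)
        mask[P.uptake_indices] = 1.0
        self._up = Tensor(mask)
        self._keep = Tensor(1.0 - mask)

    def __call__(self, V0: Tensor, Vin: Tensor) -> Tensor:
        V = V0
        if self.mode == "EB":
            Vin_full = Vin @ self._P_in  # B x n scatter
            V = V * self._keep + Vin_full * self._up
        for _ in range(self.n_iter):
            g = (V @ self._S_T) @ self._S * (2.0 / self.m)
            g = g + ((V @ self._P_in_T - Vin).relu()
                     @ self._P_in) * (2.0 / self.n_in)
            g = g + (-1.0) * (-V).relu() * (2.0 / self.n)
            V = V - self.dt * g
            if self.mode == "EB":
                V = V * self._keep + Vin_full * self._up
        return V


class _LPLayer:
    """Unrolled primal-dual iterations with the growth objective."""

    def __init__(self, model, P: ProjectionSet, n_iter, dt, mode):
        self.n_iter = n_iter
        self.mode = mode
        K = P.S_int
        # numeric dt scales the diagonal (preconditioned) steps; the layer
        # should nudge V0 toward optimality, not replace it in few steps
        scale = 0.1 if dt == "auto" else float(dt)
        tau = scale / np.maximum(np.abs(K).sum(axis=0), 1e-12)
        sigma = scale / np.maximum(np.abs(K).sum(axis=1), 1e-12)
        self._tau, self._sigma = Tensor(tau), Tensor(sigma)
        self._S_int = Tensor(K)
        self._S_int_T = Tensor(K.T)
        c = np.zeros(model.n)
        c[model.reaction_index(model.objective_id)] = 1.0
        self._neg_c = Tensor(-c)
        up = P.uptake_indices
        S_up = model.S[:, up]  # m x n_in
        self._S_up_T = Tensor(S_up.T)
        # rows where slack may relax the balance: metabolites fed by uptakes
        med = (np.abs(S_up).sum(axis=1) > 0).astype(float)
        self._med = Tensor(med)
        self._hard = Tensor(1.0 - med)
        mask = np.zeros(model.n)
        mask[up] = 1.0
        self._up_mask = Tensor(mask)
        self._keep = Tensor(1.0 - mask)
        self._P_in = Tensor(P.P_in)

    def __call__(self, V0: Tensor, Vin: Tensor) -> Tensor:
        # b: uptake supply per metabolite row, B x m
        b = Vin @ self._S_up_T
        if self.mode == "EB":
            Vin_full = Vin @ self._P_in
            V = V0 * self._keep + Vin_full * self._up_mask
        else:
            V = V0
        clamped = V * self._up_mask
        U = 0.0 * b
        Vbar = V
        for _ in range(self.n_iter):
            r = Vbar @ self._S_int_T + b
            if self.mode == "UB":
                # slack absorbs surplus supply on medium rows only
                r = r * self._hard + (-1.0) * ((-1.0) * r).relu() * self._med
            U = U + self._sigma * r
            Vn = (V - self._tau * (self._neg_c + U @ self._S_int)).relu()
            Vn = Vn * self._keep + clamped
            Vbar = 2.0 * Vn - V
            V = Vn
        return V


class _WtLayer:
    """Unrolled branching-ratio propagation with trainable W_r.

    W_r is stored transposed (m x n) so the batched update is a single
    matrix product M @ (P_m2v^T * relu(W_r)).
    """

    def __init__(self, model, P: ProjectionSet, n_iter, seed):
        self.n_iter = n_iter
        self._P_v2m_T = Tensor(P.P_v2m.T)
        self._mask_T = Tensor(P.P_m2v.T)  # m x n uniform consumer split
        rng = np.random.default_rng(seed)
        self.W_r = Tensor(rng.uniform(0.5, 1.5, size=P.P_m2v.T.shape),
                          requires_grad=True)

    @property
    def params(self):
        return [self.W_r] if self.W_r.requires_grad else []

    def __call__(self, V0: Tensor, Vin: Tensor) -> Tensor:
        Weff_T = self._mask_T * self.W_r.relu()  # m x n
        V = V0
        for _ in range(self.n_iter):
            M = V @ self._P_v2m_T
            V = M @ Weff_T + V0
        return V


class AMNRegressor(BaseEstimator, RegressorMixin):
    """Neural layer + differentiable flux solver, trained end to end.

    Parameters
    ----------
    model : MetabolicModel
        Positive-flux (split) metabolic network.
    solver : {"qp", "lp", "wt"}
        Mechanistic layer kind. "wt" cannot be combined with exact bounds
        (EB): a single branching-ratio matrix cannot satisfy all exactly
        bounded flux distributions.
    mode : {"UB", "EB"}
        Whether inputs are upper bounds or exact uptake fluxes. In EB mode
        the uptake components of V are clamped to the input at every step.
    input_kind : {"V_in", "C_med", "C_med+R_KO"}
        V_in feeds measured/sampled uptake bounds directly. C_med feeds a
        binary composition; the uptake bounds for the bound loss are then
        the neural layer's own uptake predictions. C_med+R_KO appends a
        binary knockout vector (0 = knocked out) that also activates the
        knockout loss L5.
    hidden_sizes, dropout, epochs, batch_size, learning_rate
        Neural-layer hyperparameters (Adam optimizer).
    n_solver_iter : int
        Unrolled mechanistic iterations (a few suffice after the neural
        warm start).
    ref_ids : list of reaction ids or None
        Target fluxes; default the growth (objective) reaction.
    ko_ids : list of reaction ids
        Columns addressed by R_KO (required for input_kind C_med+R_KO).
    """

    def __init__(self, model=None, solver="qp", mode="UB", input_kind="V_in",
                 hidden_sizes=(500,), dropout=0.25, epochs=100, batch_size=5,
                 learning_rate=1e-3, n_solver_iter=4, solver_dt="auto",
                 loss_weights=(1.0, 1.0, 1.0, 1.0, 1.0),
                 output_activation="linear",
                 ref_ids=None, ko_ids=(), seed=0, verbose=0):
        self.model = model
        self.solver = solver
        self.mode = mode
        self.input_kind = input_kind
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_solver_iter = n_solver_iter
        self.solver_dt = solver_dt
        self.loss_weights = loss_weights
        self.output_activation = output_activation
        self.ref_ids = ref_ids
        self.ko_ids = ko_ids
        self.seed = seed
        self.verbose = verbose

    # -- construction ---------------------------------------------------------
    def _check_config(self):
        if self.model is None:
            raise ValueError("a MetabolicModel is required")
        if self.solver not in ("qp", "lp", "wt"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.mode not in ("UB", "EB"):
            raise ValueError("mode must be 'UB' or 'EB'")
        if self.solver == "wt" and self.mode == "EB":
            raise ValueError(
                "the Wt solver cannot be used with exact bounds (EB): a "
                "single branching-ratio matrix cannot reproduce all exactly "
                "bounded flux distributions")
        if self.input_kind not in ("V_in", "C_med", "C_med+R_KO"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.input_kind == "C_med+R_KO" and not len(self.ko_ids):
            raise ValueError("input_kind C_med+R_KO requires ko_ids")

    def _build(self):
        self._check_config()
        model: MetabolicModel = self.model
        ref_ids = self.ref_ids or [model.objective_id]
        P = build_projections(model, ref_ids, list(self.ko_ids))
        n_in = model.n_in
        width_in = n_in + (len(self.ko_ids)
                           if self.input_kind == "C_med+R_KO" else 0)
        sizes = [width_in, *self.hidden_sizes, model.n]
        # linear V0 output: a rectified output layer tends to die under
        # Adam here; flux positivity is enforced by L4 and the solver layer
        net = DenseNet(sizes, dropout=self.dropout,
                       output_activation=self.output_activation,
                       seed=self.seed)
        if self.solver == "qp":
            layer = _QPLayer(model, P, self.n_solver_iter, self.solver_dt,
                             self.mode)
        elif self.solver == "lp":
            layer = _LPLayer(model, P, self.n_solver_iter, self.solver_dt,
                             self.mode)
        else:
            layer = _WtLayer(model, P, self.n_solver_iter, self.seed)
        return P, net, layer

    # -- forward --------------------------------------------------------------
    def _split_input(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_in = self.model.n_in
        if self.input_kind == "C_med+R_KO":
            if X.shape[1] != n_in + len(self.ko_ids):
                raise ValueError("input width != n_in + n_KO")
            return X[:, :n_in], X[:, n_in:]
        if X.shape[1] != n_in:
            raise ValueError(f"input width {X.shape[1]} != n_in {n_in}")
        return X, None

    def _forward(self, X, training=False, rng=None):
        Xmed, Xko = self._split_input(X)
        Xt = Tensor(np.hstack([Xmed, Xko]) if Xko is not None else Xmed)
        V0 = self.net_.forward(Xt, training=training, rng=rng)
        if self.input_kind == "V_in":
            Vin = Tensor(Xmed)
        else:
            # bounds are the neural layer's own uptake prediction
            Vin = V0 @ Tensor(self.projections_.P_in.T)
        Vout = self.layer_(V0, Vin)
        return Vout, Vin, Xko

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y):
        """Train on media descriptors ``X`` and reference fluxes ``y``.

        ``y`` may be 1-D (growth rate) or 2-D (one column per reference
        reaction in ``ref_ids``).
        """
        P, net, layer = self._build()
        self.projections_ = P
        self.net_ = net
        self.layer_ = layer
        self.frozen_ = False
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y row counts differ")
        if y.shape[1] != P.P_ref.shape[0]:
            raise ValueError("y width != number of reference reactions")
        params = net.params + getattr(layer, "params", [])
        opt = Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)
        nsamp = X.shape[0]
        bs = max(1, min(self.batch_size, nsamp))
        self.training_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(nsamp)
            for start in range(0, nsamp, bs):
                idx = order[start:start + bs]
                loss = self._loss_on(X[idx], y[idx], training=True, rng=rng)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
            log = self._epoch_losses(X, y)
            self.training_log_.append(log)
            if self.verbose:
                print(f"epoch {epoch + 1}: " +
                      " ".join(f"{k}={v:.4g}" for k, v in log.items()))
        self.n_features_in_ = X.shape[1]
        return self

    def _loss_on(self, Xb, yb, training, rng):
        Vout, Vin, Xko = self._forward(Xb, training=training, rng=rng)
        P = self.projections_
        kw = {}
        if Xko is not None:
            kw = {"P_KO_T": P.P_KO.T, "R_KO": Tensor(Xko)}
        return _batch_losses(Vout, self.model.S.T, P.P_ref.T, P.P_in.T,
                             Vin, y=Tensor(yb), weights=self.loss_weights,
                             **kw)

    def _epoch_losses(self, X, y) -> dict:
        Vout, breakdowns = self.predict_fluxes(X)
        P = self.projections_
        pred = Vout @ P.P_ref.T
        l1 = float(np.mean(np.sum((pred - y) ** 2, axis=1))) / P.P_ref.shape[0]
        agg = {"L1": l1}
        for key in ("L2", "L3", "L4"):
            agg[key] = float(np.mean([getattr(b, key) for b in breakdowns]))
        agg["L_total"] = sum(agg.values())
        return agg

    def predict_fluxes(self, X):
        """Full flux matrix V_out and per-row loss breakdowns (no dropout)."""
        if not hasattr(self, "net_"):
            raise AttributeError("model is not fitted")
        Vout, Vin, Xko = self._forward(X, training=False)
        V = Vout.data
        Vin_d = Vin.data
        P = self.projections_
        breakdowns = []
        for i in range(V.shape[0]):
            rko = Xko[i] if Xko is not None else None
            breakdowns.append(compute_losses(
                V[i], self.model, P, Vin_d[i], V_ref=None, R_KO=rko))
        return V, breakdowns

    def predict(self, X):
        """Predicted reference fluxes (growth rate by default)."""
        V, _ = self.predict_fluxes(X)
        out = V @ self.projections_.P_ref.T
        return out.ravel() if out.shape[1] == 1 else out

    def score(self, X, y):
        from .evaluation import q2_score
        return q2_score(np.asarray(y, dtype=float).ravel(),
                        np.asarray(self.predict(X), dtype=float).ravel())


# ---------------------------------------------------------------------------
# dense baseline
# ---------------------------------------------------------------------------

class ANNFluxRegressor(BaseEstimator, RegressorMixin):
    """Dense network mapping uptake bounds to the full flux vector.

    The baseline is trained on *all* fluxes (mean squared error over every
    reaction), so each training row carries n labels instead of one;
    constraint losses are computed post hoc on the predictions for
    comparability with the hybrid models.
    """

    def __init__(self, model=None, hidden_sizes=(500,), dropout=0.25,
                 epochs=100, batch_size=5, learning_rate=1e-3, seed=0):
        self.model = model
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y):
        if self.model is None:
            raise ValueError("a MetabolicModel is required")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != self.model.n:
            raise ValueError(
                "the dense baseline requires all-flux targets "
                f"(n = {self.model.n} columns); growth-only targets are "
                "not accepted")
        self.projections_ = build_projections(self.model)
        net = DenseNet([X.shape[1], *self.hidden_sizes, self.model.n],
                       dropout=self.dropout, output_activation="linear",
                       seed=self.seed)
        opt = Adam(net.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)
        nsamp = X.shape[0]
        bs = max(1, min(self.batch_size, nsamp))
        for epoch in range(self.epochs):
            order = rng.permutation(nsamp)
            for start in range(0, nsamp, bs):
                idx = order[start:start + bs]
                out = net.forward(Tensor(X[idx]), training=True, rng=rng)
                resid = out - Tensor(y[idx])
                loss = resid.square().sum() * (1.0 / (len(idx) * self.model.n))
                opt.zero_grad()
                loss.backward()
                opt.step()
        self.net_ = net
        self.n_features_in_ = X.shape[1]
        return self

    def predict_fluxes(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        V = self.net_.forward(Tensor(X), training=False).data
        breakdowns = [compute_losses(v, self.model, self.projections_,
                                     X[i, :self.model.n_in])
                      for i, v in enumerate(V)]
        return V, breakdowns

    def predict(self, X):
        V, _ = self.predict_fluxes(X)
        obj = self.model.reaction_index(self.model.objective_id)
        return V[:, obj]


# ---------------------------------------------------------------------------
# reservoir scheme
# ---------------------------------------------------------------------------

def build_reservoir(amn: AMNRegressor) -> AMNRegressor:
    """Freeze a trained AMN so it can serve as a fixed FBA surrogate.

    The copy's parameters are immutable (``fit`` refuses to run) but
    gradients still flow *through* it to any upstream trainable layer.
    """
    if not hasattr(amn, "net_"):
        raise ValueError("cannot freeze an untrained model; fit it first")
    frozen = copy.deepcopy(amn)
    frozen.net_.freeze()
    if hasattr(frozen.layer_, "W_r"):
        frozen.layer_.W_r.requires_grad = False
    frozen.frozen_ = True
    frozen.fit = _refuse_fit
    return frozen


def _refuse_fit(*args, **kwargs):
    raise RuntimeError("this model is frozen (reservoir); training is "
                       "disabled")


class UptakeNetwork(BaseEstimator, RegressorMixin):
    """Pre-network inferring uptake-flux bounds from medium composition.

    A frozen, simulation-trained AMN acts as a differentiable stand-in for
    FBA; the pre-network maps a binary composition C_med to uptake bounds
    V_in, and is trained so that the composite prediction matches measured
    growth. After fitting, :meth:`uptake_fluxes` returns the inferred
    bounds, directly usable as exchange upper bounds in classical FBA.
    """

    def __init__(self, reservoir=None, hidden_sizes=(500,), dropout=0.25,
                 epochs=1000, batch_size=5, learning_rate=1e-4, seed=0,
                 verbose=0):
        self.reservoir = reservoir
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.verbose = verbose

    def fit(self, X, y):
        res = self.reservoir
        if res is None or not getattr(res, "frozen_", False):
            raise ValueError("reservoir must be a frozen, trained "
                             "AMNRegressor (see build_reservoir)")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if np.allclose(y, y.flat[0]):
            import warnings
            warnings.warn("constant target vector: the fit is degenerate",
                          UserWarning, stacklevel=2)
        n_in = res.model.n_in
        # linear output (a rectified one dies under Adam); nonnegativity of
        # the inferred bounds is driven by the positivity penalty below and
        # enforced exactly at export time
        prenet = DenseNet([X.shape[1], *self.hidden_sizes, n_in],
                          dropout=self.dropout, output_activation="linear",
                          seed=self.seed)
        # start every inferred bound at ~1 mmol/gDW/h: a small final layer
        # keeps the initial outputs away from the rectifier's dead side and
        # from spurious basins outside the reservoir's training range
        prenet.weights[-1].data *= 0.01
        prenet.biases[-1].data[:] = 1.0
        opt = Adam(prenet.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)
        nsamp = X.shape[0]
        bs = max(1, min(self.batch_size, nsamp))
        for epoch in range(self.epochs):
            order = rng.permutation(nsamp)
            for start in range(0, nsamp, bs):
                idx = order[start:start + bs]
                loss = self._composite_loss(prenet, X[idx], y[idx],
                                            training=True, rng=rng)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
        self.prenet_ = prenet
        self.n_features_in_ = X.shape[1]
        return self

    def _composite_loss(self, prenet, Xb, yb, training, rng):
        res: AMNRegressor = self.reservoir
        Vin = prenet.forward(Tensor(Xb), training=training, rng=rng)
        V0 = res.net_.forward(Vin, training=False)
        Vout = res.layer_(V0, Vin)
        P = res.projections_
        loss = _batch_losses(Vout, res.model.S.T, P.P_ref.T, P.P_in.T,
                             Vin, y=Tensor(yb))
        # uptake bounds are fluxes: keep the inferred V_in nonnegative
        n_in = Vin.shape[1]
        neg = (-Vin).relu()
        return loss + neg.square().sum() * (1.0 / (n_in * Xb.shape[0]))

    def uptake_fluxes(self, X) -> np.ndarray:
        """Inferred V_in (uptake upper bounds) per medium row.

        Rectified at 0: the training penalty keeps the raw outputs near or
        above zero, and a bound handed to FBA must be nonnegative.
        """
        if not hasattr(self, "prenet_"):
            raise AttributeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        raw = self.prenet_.forward(Tensor(X), training=False).data
        return np.maximum(raw, 0.0)

    def predict(self, X):
        """Composite growth prediction (prenet -> frozen reservoir)."""
        Vin = self.uptake_fluxes(X)
        res: AMNRegressor = self.reservoir
        V0 = res.net_.forward(Tensor(Vin), training=False)
        Vout = res.layer_(V0, Tensor(Vin)).data
        out = Vout @ res.projections_.P_ref.T
        return out.ravel() if out.shape[1] == 1 else out

    def export_bounds(self, X, prefix) -> list:
        """Write one FBA-ready bounds file per medium row; returns paths."""
        from .fba import write_bounds_file

        Vin = self.uptake_fluxes(X)
        paths = []
        for i, row in enumerate(Vin):
            path = f"{prefix}_medium{i:03d}.tsv"
            write_bounds_file(path, self.reservoir.model.uptake_ids, row)
            paths.append(path)
        return paths
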