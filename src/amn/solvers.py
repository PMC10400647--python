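"""Differentiable flux-balance surrogates: constraint losses, Wt, LP and QP.

Three iterative schemes approximate the steady-state flux distribution of a
positive-flux metabolic network while remaining differentiable end to end:

* ``wt_solve`` — alternating propagation between metabolite production
  fluxes M and reaction fluxes V through a branching-ratio weight matrix.
* ``lp_solve`` — projected primal-dual gradient iterations on (an augmented
  Lagrangian of) the growth-maximization LP, with the metabolite shadow
  prices U as dual variables.
* ``qp_solve`` — plain gradient descent on the quadratic constraint loss,
  fitting a flux distribution to partial reference data.

The shared loss has up to five terms, each normalized by its dimension:
fit to reference fluxes (L1, by n_ref), mass balance |S V|^2 (L2, by m),
uptake bound violation (L3, by n_in), flux negativity (L4, by n) and
knocked-out flux (L5, by n_KO).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import MetabolicModel, ProjectionSet

__all__ = [
    "LossBreakdown",
    "SolverState",
    "compute_losses",
    "loss_gradient",
    "wt_solve",
    "lp_solve",
    "qp_solve",
    "wr_from_reference",
]

_DIVERGENCE_CEILING = 1e9


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class LossBreakdown:
    L1: float
    L2: float
    L3: float
    L4: float
    L5: float | None = None

    @property
    def total(self) -> float:
        return self.L1 + self.L2 + self.L3 + self.L4 + (self.L5 or 0.0)

    def as_dict(self) -> dict:
        d = {"L1": self.L1, "L2": self.L2, "L3": self.L3, "L4": self.L4}
        if self.L5 is not None:
            d["L5"] = self.L5
        d["L_total"] = self.total
        return d


@dataclass
class SolverState:
    """Iterate of a mechanistic solver."""

    V: np.ndarray
    U: np.ndarray | None = None  # dual / shadow prices (LP)
    M: np.ndarray | None = None  # metabolite production fluxes (Wt)
    t: int = 0
    dt: float = 0.0
    converged: bool = False
    loss_trace: list | None = None


def compute_losses(V: np.ndarray,
                   model: MetabolicModel,
                   projections: ProjectionSet,
                   V_in: np.ndarray,
                   V_ref: np.ndarray | None = None,
                   R_KO: np.ndarray | None = None) -> LossBreakdown:
    """Evaluate the constraint-loss terms for a flux vector.

    ``V_in`` holds the uptake upper bounds, ``V_ref`` the reference fluxes
    for the rows of ``P_ref`` (L1 omitted as 0 when None), and binary
    ``R_KO`` marks knockouts (0 = knocked out) for the rows of ``P_KO``.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != (model.n,):
        raise ValueError(f"V has shape {V.shape}, expected ({model.n},)")
    P = projections
    V_in = np.asarray(V_in, dtype=float)
    if V_in.shape != (P.P_in.shape[0],):
        raise ValueError("V_in length != number of uptakes")
    L1 = 0.0
    if V_ref is not None:
        V_ref = np.asarray(V_ref, dtype=float)
        resid = P.P_ref @ V - V_ref
        L1 = float(resid @ resid) / P.P_ref.shape[0]
    sv = model.S @ V
    L2 = float(sv @ sv) / model.m
    v3 = _relu(P.P_in @ V - V_in)
    L3 = float(v3 @ v3) / P.P_in.shape[0]
    v4 = _relu(-V)
    L4 = float(v4 @ v4) / model.n
    L5 = None
    if R_KO is not None:
        if P.P_KO.shape[0] == 0:
            raise ValueError("R_KO given but projection set has no KO rows")
        v5 = _relu(P.P_KO @ V - np.asarray(R_KO, dtype=float))
        L5 = float(v5 @ v5) / P.P_KO.shape[0]
    return LossBreakdown(L1, L2, L3, L4, L5)


def loss_gradient(V: np.ndarray,
                  model: MetabolicModel,
                  projections: ProjectionSet,
                  V_in: np.ndarray,
                  V_ref: np.ndarray | None = None,
                  R_KO: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient of the total loss with respect to V.

    The rectifier contributes subgradient 0 at exactly 0, matching
    :func:`compute_losses` term by term.
    """
    P = projections
    g = np.zeros(model.n)
    if V_ref is not None:
        g += (2.0 / P.P_ref.shape[0]) * (P.P_ref.T @ (P.P_ref @ V - V_ref))
    g += (2.0 / model.m) * (model.S.T @ (model.S @ V))
    g += (2.0 / P.P_in.shape[0]) * (P.P_in.T @ _relu(P.P_in @ V - V_in))
    g += -(2.0 / model.n) * _relu(-V)
    if R_KO is not None:
        g += (2.0 / P.P_KO.shape[0]) * (P.P_KO.T @ _relu(P.P_KO @ V - R_KO))
    return g


# ---------------------------------------------------------------------------
# Wt-solver
# ---------------------------------------------------------------------------

def wt_solve(model: MetabolicModel,
             projections: ProjectionSet,
             W_r: np.ndarray,
             V0: np.ndarray,
             n_iter: int = 100) -> SolverState:
    """Alternate M = P_v2m V and V = (P_m2v * W_r) M + V0.

    ``W_r`` (n x m) rescales the uniform consumer split encoded in
    ``P_m2v`` into the network's actual branching ratios; with ratios taken
    from a reference distribution the iteration's fixed point reproduces
    that distribution's internal fluxes.
    """
    W_r = np.asarray(W_r, dtype=float)
    if np.any(W_r < 0):
        raise ValueError("W_r must be nonnegative")
    if W_r.shape != (model.n, model.m):
        raise ValueError(f"W_r must be (n, m) = ({model.n}, {model.m})")
    V = np.asarray(V0, dtype=float).copy()
    M = projections.P_v2m @ V
    Weff = projections.P_m2v * W_r
    for t in range(n_iter):
        M = projections.P_v2m @ V
        V = Weff @ M + V0
        if not np.all(np.isfinite(V)) or np.max(np.abs(V)) > _DIVERGENCE_CEILING:
            raise FloatingPointError(
                f"Wt iteration diverged at step {t + 1}")
    return SolverState(V=V, M=M, t=n_iter, converged=True)


def wr_from_reference(model: MetabolicModel,
                      projections: ProjectionSet,
                      V_ref_full: np.ndarray) -> np.ndarray:
    """Branching-ratio weights consistent with a full flux distribution.

    For each metabolite j with production M_j > 0 and each consumer k, the
    effective coefficient must equal V_k / M_j; W_r is that target divided
    by the uniform split stored in P_m2v.
    """
    V = np.asarray(V_ref_full, dtype=float)
    M = projections.P_v2m @ V
    n, m = model.n, model.m
    W = np.zeros((n, m))
    consumers = projections.P_m2v > 0
    for j in range(m):
        if M[j] <= 0:
            continue
        for k in np.nonzero(consumers[:, j])[0]:
            W[k, j] = (V[k] / M[j]) / projections.P_m2v[k, j]
    return W


# ---------------------------------------------------------------------------
# LP-solver (primal-dual gradient dynamics)
# ---------------------------------------------------------------------------

def _lp_medium_vector(model: MetabolicModel,
                      projections: ProjectionSet,
                      V_in: np.ndarray) -> np.ndarray:
    """b vector: uptake supply per metabolite row (S_uptake @ V_in-part)."""
    up = projections.uptake_indices
    S_up = model.S[:, up]
    return S_up @ np.asarray(V_in, dtype=float)


def lp_solve(model: MetabolicModel,
             projections: ProjectionSet,
             V_in: np.ndarray,
             mode: str = "EB",
             c_FBA: np.ndarray | None = None,
             dt: float | str = "auto",
             n_iter: int = 10000,
             tol: float = 1e-10,
             patience: int = 100) -> SolverState:
    """Solve max c^T V s.t. S_int V = -b, V >= 0 by primal-dual iterations.

    ``b`` carries the uptake supply on medium metabolite rows. EB treats the
    supply as exact; UB appends slack variables on medium rows so the
    network may consume less than the bound. V (primal) and the metabolite
    shadow prices U (dual) follow projected primal-dual gradient steps with
    primal extrapolation (Chambolle-Pock form); ``dt="auto"`` uses the
    standard diagonal step sizes 1/sum|K| per row/column, a scalar ``dt``
    uses that uniform step for both variables. Initialization is
    V0 = P_in^T V_in and U0 = 0. The uptake components of V (zero columns
    of S_int) are never updated.
    """
    if mode not in ("EB", "UB"):
        raise ValueError("mode must be 'EB' or 'UB'")
    P = projections
    n, m = model.n, model.m
    if c_FBA is None:
        c_FBA = np.zeros(n)
        c_FBA[model.reaction_index(model.objective_id)] = 1.0
    V_in = np.asarray(V_in, dtype=float)
    b = _lp_medium_vector(model, P, V_in)
    medium_rows = b != 0
    # constraint operator: K x + b = 0 with x = [V; slack] (slack UB only)
    if mode == "UB":
        K = np.hstack([P.S_int, -np.eye(m)[:, medium_rows]])
        c = np.concatenate([c_FBA, np.zeros(int(medium_rows.sum()))])
    else:
        K = P.S_int
        c = c_FBA
    if dt == "auto":
        tau = 1.0 / np.maximum(np.abs(K).sum(axis=0), 1e-12)
        sigma = 1.0 / np.maximum(np.abs(K).sum(axis=1), 1e-12)
    else:
        tau = np.full(K.shape[1], float(dt))
        sigma = np.full(m, float(dt))
    x = np.zeros(K.shape[1])
    x[:n] = P.P_in.T @ V_in  # V0
    U = np.zeros(m)
    clamp = np.zeros(K.shape[1], dtype=bool)
    clamp[P.uptake_indices] = True  # uptake columns are zero in S_int; keep V0
    x_bar = x.copy()
    trace = []
    still = 0
    converged = False
    for t in range(n_iter):
        U_new = U + sigma * (K @ x_bar + b)
        x_new = _relu(x - tau * (-c + K.T @ U_new))
        x_new[clamp] = x[clamp]
        x_bar = 2.0 * x_new - x
        # saddle-point convergence: both iterates stop moving
        step = max(np.max(np.abs(x_new - x)), np.max(np.abs(U_new - U)))
        x, U = x_new, U_new
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _DIVERGENCE_CEILING:
            raise FloatingPointError(f"LP iteration diverged at step {t + 1}")
        r = K @ x + b
        trace.append(float(r @ r))
        if step < tol:
            still += 1
            if still >= patience:
                converged = True
                break
        else:
            still = 0
    return SolverState(V=x[:n], U=U, t=t + 1,
                       dt=float(np.median(tau)), converged=converged,
                       loss_trace=trace)


# ---------------------------------------------------------------------------
# QP-solver
# ---------------------------------------------------------------------------

def qp_solve(model: MetabolicModel,
             projections: ProjectionSet,
             V_in: np.ndarray,
             V_ref: np.ndarray | None,
             mode: str = "UB",
             dt: float | str = "auto",
             n_iter: int = 10000,
             V0: np.ndarray | None = None,
             R_KO: np.ndarray | None = None,
             tol: float = 1e-9,
             patience: int = 100) -> SolverState:
    """Gradient descent on the constraint loss L(V).

    EB mode clamps the uptake components of V to ``V_in`` at every step
    (they are never updated); UB mode penalizes bound violations via L3.
    ``dt="auto"`` sets the step to 0.9 / Lipschitz(grad L) from the largest
    singular value of S, guaranteeing monotone descent on the smooth part.
    """
    if mode not in ("EB", "UB"):
        raise ValueError("mode must be 'EB' or 'UB'")
    P = projections
    if dt == "auto":
        smax = np.linalg.norm(model.S, 2)
        lip = (2.0 * smax ** 2 / model.m + 2.0 / P.P_ref.shape[0]
               + 2.0 / P.P_in.shape[0] + 2.0 / model.n)
        if P.P_KO.shape[0]:
            lip += 2.0 / P.P_KO.shape[0]
        dt = 0.9 / lip
    dt = float(dt)
    V_in = np.asarray(V_in, dtype=float)
    V = (P.P_in.T @ V_in if V0 is None
         else np.asarray(V0, dtype=float).copy())
    if mode == "EB":
        V[P.uptake_indices] = V_in
    trace = []
    best, still = np.inf, 0
    converged = False
    for t in range(n_iter):
        g = loss_gradient(V, model, P, V_in, V_ref, R_KO)
        if mode == "EB":
            g[P.uptake_indices] = 0.0
        V = V - dt * g
        if mode == "EB":
            V[P.uptake_indices] = V_in
        if not np.all(np.isfinite(V)) or np.max(np.abs(V)) > _DIVERGENCE_CEILING:
            raise FloatingPointError(f"QP iteration diverged at step {t + 1}")
        L = compute_losses(V, model, P, V_in, V_ref, R_KO).total
        trace.append(L)
        if L < best - tol:
            best, still = L, 0
        else:
            still += 1
            if still >= patience:
                converged = True
                break
    return SolverState(V=V, t=t + 1, dt=dt, converged=converged,
                       loss_trace=trace)


def write_trace(path, trace: Sequence[float]) -> None:
    """Dump a per-iteration loss trace as TSV for diagnostics."""
    import pandas as pd

    pd.DataFrame({"iteration": np.arange(1, len(trace) + 1),
                  "loss": np.asarray(trace, dtype=float)}).to_csv(
        path, sep="\t", index=False)
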