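"""Self-contained synthetic fixtures: toy networks, datasets and OD curves.

Everything the package consumes from the outside world — stoichiometric
models, media tables, growth-rate datasets, plate-reader files — can be
generated here with known ground truth, so the full pipeline is testable
without downloads. Toy networks have analytically known FBA optima; a
:class:`ToyWorld` couples a network with a hidden medium-composition ->
uptake-flux map so parameter-recovery experiments have a defined truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fba import solve_fba
from .growth import GrowthCurve
from .model_io import MetabolicModel

__all__ = ["ToyWorld", "make_toy_network", "make_synthetic_dataset",
           "simulate_od_curves", "make_random_network"]


def make_toy_network(kind: str, length: int = 2, n_branches: int = 2,
                     yields=(1.0, 0.5), seed: int = 0):
    """Small networks with known FBA optima.

    kinds
    -----
    chain
        up_A_i -> A1 -> ... -> biomass; optimum = uptake bound.
    branch
        A splits into ``n_branches`` sinks, only the first feeds biomass;
        optimum routes everything through the biomass branch.
    diamond
        Two paths A->B->D and A->C->D with the stated molar ``yields``;
        the optimum uses only the higher-yield path.
    reversible
        Signed-bound chain with a reversible middle reaction and a signed
        exchange, for exercising the splitting transform.

    Returns ``(model, optimum)`` where ``optimum(uptake_bound)`` gives the
    known maximal growth.
    """
    if kind == "chain":
        if length < 1:
            raise ValueError("chain length must be >= 1")
        mets = [f"A{i}" for i in range(1, length)]
        rids = ["up_A_i"] + [f"r{i}" for i in range(1, length - 1)] + ["bio"]
        if length == 1:
            rids = ["up_A_i", "bio"]
            mets = ["A1"]
        n = len(rids)
        m = len(mets)
        S = np.zeros((m, n))
        for i in range(m):
            S[i, i] = 1.0       # produced by previous reaction
            S[i, i + 1] = -1.0  # consumed by next
        model = MetabolicModel(rids, mets, S, np.zeros(n), np.full(n, 1000.0),
                               objective_id="bio", uptake_ids=["up_A_i"],
                               obligate_uptake_ids=["up_A_i"])
        return model, lambda ub: float(ub)
    if kind == "branch":
        if n_branches < 2:
            raise ValueError("need >= 2 branches")
        mets = ["A"] + [f"B{i}" for i in range(n_branches)]
        rids = (["up_A_i"] + [f"b{i}" for i in range(n_branches)]
                + ["bio"] + [f"out{i}_o" for i in range(1, n_branches)])
        n, m = len(rids), len(mets)
        S = np.zeros((m, n))
        S[0, 0] = 1.0
        for i in range(n_branches):
            S[0, 1 + i] = -1.0
            S[1 + i, 1 + i] = 1.0
        S[1, 1 + n_branches] = -1.0  # biomass consumes B0
        for i in range(1, n_branches):
            S[1 + i, n_branches + 1 + i] = -1.0  # outflow for other sinks
        model = MetabolicModel(rids, mets, S, np.zeros(n), np.full(n, 1000.0),
                               objective_id="bio", uptake_ids=["up_A_i"],
                               obligate_uptake_ids=["up_A_i"])
        return model, lambda ub: float(ub)
    if kind == "diamond":
        y1, y2 = yields
        if y1 == y2:
            raise ValueError("yields must differ for a unique optimum")
        mets = ["A", "B", "C", "D"]
        rids = ["up_A_i", "pAB", "pAC", "pBD", "pCD", "bio"]
        S = np.array([
            # up  pAB  pAC  pBD  pCD  bio
            [1.0, -1., -1., 0.0, 0.0, 0.0],   # A
            [0.0, 1.0, 0.0, -1., 0.0, 0.0],   # B
            [0.0, 0.0, 1.0, 0.0, -1., 0.0],   # C
            [0.0, 0.0, 0.0, y1, y2, -1.0],    # D (path-specific yields)
        ])
        n = len(rids)
        model = MetabolicModel(rids, mets, S, np.zeros(n), np.full(n, 1000.0),
                               objective_id="bio", uptake_ids=["up_A_i"],
                               obligate_uptake_ids=["up_A_i"])
        return model, lambda ub: float(max(yields) * ub)
    if kind == "reversible":
        # up: <-> A (signed exchange), A <-> B reversible, bio: B ->
        mets = ["A", "B"]
        rids = ["EX_A", "conv", "bio"]
        S = np.array([
            [1.0, -1.0, 0.0],
            [0.0, 1.0, -1.0],
        ])
        lb = np.array([-1000.0, -1000.0, 0.0])
        ub = np.array([1000.0, 1000.0, 1000.0])
        model = MetabolicModel(rids, mets, S, lb, ub, objective_id="bio")
        return model, lambda b: float(b)
    raise ValueError(f"unknown toy network kind {kind!r}")


def make_random_network(n_mets: int = 4, seed: int = 0):
    """Random layered branching network with a simplex-verifiable optimum.

    Metabolites form layers; each metabolite is converted onward by 1-2
    reactions with random integer-ish stoichiometry, the last layer feeds
    biomass, and every dead end gets an outflow. Fluxes are bounded only by
    the uptake, so the LP is bounded and feasible.
    """
    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(n_mets)]
    cols, rids = [], []

    def col(pairs):
        c = np.zeros(n_mets)
        for i, v in pairs:
            c[i] = v
        return c

    cols.append(col([(0, 1.0)]))
    rids.append("up_M0_i")
    for i in range(n_mets - 1):
        n_out = rng.integers(1, 3)
        for k in range(n_out):
            j = int(rng.integers(i + 1, n_mets))
            yield_ = float(rng.uniform(0.3, 1.5))
            cols.append(col([(i, -1.0), (j, yield_)]))
            rids.append(f"c{i}_{j}_{k}")
    cols.append(col([(n_mets - 1, -1.0)]))
    rids.append("bio")
    # outflow for every intermediate so no dead-end blocks the optimum
    for i in range(1, n_mets - 1):
        cols.append(col([(i, -1.0)]))
        rids.append(f"out_M{i}_o")
    n = len(rids)
    model = MetabolicModel(rids, mets, np.column_stack(cols),
                           np.zeros(n), np.full(n, 1000.0),
                           objective_id="bio", uptake_ids=["up_M0_i"],
                           obligate_uptake_ids=["up_M0_i"])
    return model


@dataclass
class ToyWorld:
    """A toy network plus a hidden medium -> uptake-flux map.

    ``true_uptake_map`` converts a binary composition row to uptake bounds;
    growth is FBA at those bounds plus replicate noise. The construction
    verifies that FBA is feasible with nonzero growth for the all-on
    medium.
    """

    model: MetabolicModel
    true_uptake_map: Callable[[np.ndarray], np.ndarray]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        probe = np.ones(self.model.n_in)
        res = solve_fba(self.model, self.true_uptake_map(probe))
        if not res.feasible or res.growth_rate <= 0:
            raise ValueError("world has no growth on the all-on medium")

    def growth(self, C_med: np.ndarray) -> np.ndarray:
        C_med = np.atleast_2d(np.asarray(C_med, dtype=float))
        return np.array([
            solve_fba(self.model, self.true_uptake_map(row)).growth_rate
            for row in C_med])


def affine_uptake_map(coef: float = 2.0, offset: float = 0.0):
    """V_in = coef * C_med + offset (identifiable default world)."""
    return lambda c: coef * np.asarray(c, dtype=float) + offset


def saturating_uptake_map(vmax: float = 4.0, k: float = 0.5):
    """Michaelis-Menten-like map to stress nonlinear recovery."""
    return lambda c: vmax * np.asarray(c, dtype=float) / (
        k + np.maximum(np.asarray(c, dtype=float), 1e-12))


def make_synthetic_dataset(world: ToyWorld, C_med: np.ndarray,
                           replicate_n: int = 3, seed: int = 0):
    """Replicate growth measurements for each composition row.

    Returns ``(y_mean, y_sd, replicates)``; replicate noise is additive
    Normal(0, noise_sd) around the FBA growth of the true uptake bounds.
    """
    rng = np.random.default_rng(seed)
    truth = world.growth(C_med)
    reps = truth[:, None] + rng.normal(
        0.0, world.noise_sd, size=(truth.size, replicate_n))
    return reps.mean(axis=1), reps.std(axis=1, ddof=0), reps


def simulate_od_curves(mu_max: float, lag_h: float = 0.0, od0: float = 0.05,
                       od_cap: float = 1.5, sampling_min: float = 10.0,
                       duration_h: float = 24.0, noise_sd: float = 0.0,
                       n_replicates: int = 1, seed: int = 0,
                       medium_id: str = "") -> list:
    """Logistic-with-lag OD600 trajectories with multiplicative noise.

    OD stays at ``od0`` until ``lag_h``, then follows logistic growth at
    rate ``mu_max`` toward ``od_cap`` (``od_cap=inf`` gives a pure
    exponential). Noise multiplies OD by lognormal(0, noise_sd).
    """
    if mu_max < 0:
        raise ValueError("mu_max must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, sampling_min / 60.0)
    te = np.maximum(t - lag_h, 0.0)
    if np.isinf(od_cap):
        od = od0 * np.exp(mu_max * te)
    else:
        od = od_cap * od0 * np.exp(mu_max * te) / (
            od_cap + od0 * (np.exp(mu_max * te) - 1.0))
    curves = []
    for r in range(n_replicates):
        noisy = od * np.exp(rng.normal(0.0, noise_sd, size=od.size))
        curves.append(GrowthCurve(t, noisy, well_id=f"W{r}",
                                  medium_id=medium_id))
    return curves
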