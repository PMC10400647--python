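"""Classical flux balance analysis oracle and training-set generation.

FBA maximizes the biomass flux subject to mass balance ``S V = 0`` and flux
bounds. The LP is delegated to scipy's HiGHS solver; cobra/GLPK is used only
as an independent cross-check in the test suite. On top of the oracle this
module generates UB/EB training sets from sampled media, the knockout
baseline, and the scaled-upper-bound search used to calibrate plain FBA
against measured growth rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "FBAResult",
    "TrainingSet",
    "solve_fba",
    "generate_training_set",
    "ko_fba_baseline",
    "scaled_bound_search",
    "write_bounds_file",
    "read_bounds_file",
]


@dataclass
class FBAResult:
    """Outcome of one FBA solve.

    ``feasible`` distinguishes an infeasible LP from a feasible one with
    zero growth.
    """

    fluxes: np.ndarray | None
    objective_value: float
    feasible: bool
    status: str

    @property
    def growth_rate(self) -> float:
        return self.objective_value if self.feasible else 0.0


@dataclass
class TrainingSet:
    """Rows of (inputs, targets) for model fitting.

    ``inputs`` holds uptake bounds (UB), realized uptake fluxes (EB) or a
    binary medium composition; ``targets`` the growth rate column or the
    full flux matrix. ``target_ids`` names the target columns.
    """

    inputs: np.ndarray
    targets: np.ndarray
    mode: str  # "UB" or "EB"
    input_ids: list
    target_ids: list
    metadata: dict = field(default_factory=dict)

    def save(self, prefix) -> None:
        """Write inputs/targets as TSV plus a JSON metadata sidecar."""
        import pandas as pd

        prefix = Path(prefix)
        pd.DataFrame(self.inputs, columns=self.input_ids).to_csv(
            f"{prefix}_inputs.tsv", sep="\t", index=False)
        pd.DataFrame(self.targets, columns=self.target_ids).to_csv(
            f"{prefix}_targets.tsv", sep="\t", index=False)
        meta = {"mode": self.mode, **self.metadata}
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "TrainingSet":
        import pandas as pd

        prefix = Path(prefix)
        inputs = pd.read_csv(f"{prefix}_inputs.tsv", sep="\t")
        targets = pd.read_csv(f"{prefix}_targets.tsv", sep="\t")
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
        mode = meta.pop("mode")
        return cls(inputs.to_numpy(float), targets.to_numpy(float), mode,
                   list(inputs.columns), list(targets.columns), meta)


def _as_bound_vector(model: MetabolicModel, upper_bounds) -> np.ndarray:
    if isinstance(upper_bounds, Mapping):
        vec = np.array([upper_bounds.get(r, 0.0) for r in model.uptake_ids])
    else:
        vec = np.asarray(upper_bounds, dtype=float)
        if vec.shape != (model.n_in,):
            raise ValueError("bound vector length != number of uptakes")
    return vec


def solve_fba(model: MetabolicModel,
              upper_bounds=None,
              objective_id: str | None = None,
              equality: bool = False,
              ko_indices: Sequence[int] = ()) -> FBAResult:
    """Maximize the objective flux subject to S V = 0 and bounds.

    Parameters
    ----------
    upper_bounds : mapping or (n_in,) array, optional
        Medium as upper bounds on the uptake reactions (UB mode); with
        ``equality=True`` the uptake fluxes are fixed to these values
        (EB mode). Uptakes not mentioned are closed.
    ko_indices : sequence of int
        Reaction columns clamped to zero flux (knockouts).
    """
    if objective_id is None:
        objective_id = model.objective_id
    obj = model.reaction_index(objective_id)
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    if upper_bounds is not None:
        vec = _as_bound_vector(model, upper_bounds)
        if np.any(vec < 0):
            raise ValueError("uptake bounds must be nonnegative")
        idx = model.indices(model.uptake_ids)
        ub[idx] = vec
        lb[idx] = vec if equality else 0.0
    for j in ko_indices:
        lb[j] = 0.0
        ub[j] = 0.0
    lb = np.minimum(lb, ub)
    c = np.zeros(model.n)
    c[obj] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.m),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if not res.success:
        return FBAResult(None, 0.0, False, res.message)
    return FBAResult(res.x, float(res.x[obj]), True, "optimal")


def generate_training_set(model: MetabolicModel,
                          media,
                          mode: str = "UB",
                          targets: str = "growth_only") -> TrainingSet:
    """Run FBA over a :class:`~amn.media.MediaSet` and collect a training set.

    In UB mode the inputs are the sampled bounds; in EB mode the realized
    steady-state uptake fluxes replace them. ``targets`` selects the growth
    rate only or the full flux distribution (dense-network baseline).
    Infeasible media are kept with growth 0 and flagged in the metadata.
    """
    if mode not in ("UB", "EB"):
        raise ValueError("mode must be 'UB' or 'EB'")
    if targets not in ("growth_only", "all_fluxes"):
        raise ValueError("targets must be 'growth_only' or 'all_fluxes'")
    if list(media.uptake_ids) != list(model.uptake_ids):
        raise ValueError("media uptake ids do not match model uptake ids")
    up_idx = model.indices(model.uptake_ids)
    rows_in, rows_t, infeasible = [], [], []
    for i, bounds in enumerate(np.asarray(media.rows, dtype=float)):
        res = solve_fba(model, bounds)
        if not res.feasible:
            infeasible.append(i)
            V = np.zeros(model.n)
        else:
            V = res.fluxes
        rows_in.append(V[up_idx] if mode == "EB" else bounds)
        rows_t.append(V if targets == "all_fluxes"
                      else [res.growth_rate])
    target_ids = (list(model.reaction_ids) if targets == "all_fluxes"
                  else [model.objective_id])
    return TrainingSet(
        inputs=np.asarray(rows_in), targets=np.asarray(rows_t),
        mode=mode, input_ids=list(model.uptake_ids), target_ids=target_ids,
        metadata={"seed": getattr(media, "seed", None),
                  "infeasible_rows": infeasible,
                  "targets": targets})


def ko_fba_baseline(model: MetabolicModel,
                    C_med: np.ndarray,
                    R_KO: np.ndarray | None = None,
                    ko_ids: Sequence[str] = (),
                    uptake_ub: float = 11.0) -> np.ndarray:
    """Plain-FBA growth rates for binary media plus reaction knockouts.

    Per row, substrates present in ``C_med`` get upper bound ``uptake_ub``
    (absent ones 0) and reactions with a 0 entry in ``R_KO`` are clamped to
    zero flux. The default bound of 11 mmol/gDW/h is the calibrated value
    for the knockout benchmark.
    """
    C_med = np.atleast_2d(np.asarray(C_med, dtype=float))
    if C_med.shape[1] != model.n_in:
        raise ValueError("C_med width != number of uptakes")
    if R_KO is not None:
        R_KO = np.atleast_2d(np.asarray(R_KO, dtype=float))
        ko_cols = model.indices(ko_ids)
        if R_KO.shape != (C_med.shape[0], len(ko_cols)):
            raise ValueError("R_KO shape inconsistent with C_med/ko_ids")
    growth = np.zeros(C_med.shape[0])
    for i in range(C_med.shape[0]):
        kos = ()
        if R_KO is not None:
            kos = tuple(ko_cols[R_KO[i] == 0])
        res = solve_fba(model, C_med[i] * uptake_ub, ko_indices=kos)
        growth[i] = res.growth_rate
    return growth


def scaled_bound_search(model: MetabolicModel,
                        C_med: np.ndarray,
                        measured: np.ndarray,
                        scaler_grid: Sequence[float] | None = None,
                        R_KO: np.ndarray | None = None,
                        ko_ids: Sequence[str] = ()) -> tuple:
    """Grid-search the uptake-bound scaler maximizing R2 vs measured growth.

    Present substrates all receive the same upper bound ``s``; the best
    ``s`` in [1, 10] (default grid step 0.1) and its R2 are returned.
    """
    from .evaluation import q2_score

    measured = np.asarray(measured, dtype=float)
    if measured.size == 0:
        raise ValueError("empty dataset")
    if np.allclose(measured, measured[0]):
        raise ValueError("measured growth rates are constant")
    if scaler_grid is None:
        scaler_grid = np.arange(1.0, 10.0 + 1e-9, 0.1)
    best = (None, -np.inf)
    any_feasible = False
    for s in scaler_grid:
        pred = ko_fba_baseline(model, C_med, R_KO, ko_ids, uptake_ub=float(s))
        if np.any(pred > 0):
            any_feasible = True
        r2 = q2_score(measured, pred)
        if r2 > best[1]:
            best = (float(s), float(r2))
    if not any_feasible:
        raise ValueError("FBA infeasible (zero growth) on every medium "
                         "for every scaler")
    return best


def write_bounds_file(path, uptake_ids: Sequence[str],
                      bounds: np.ndarray) -> None:
    """Write an uptake-bounds table (reaction id, upper bound) as TSV.

    This is the hand-off format: the file can be applied to any
    constraint-based model by setting each listed exchange bound.
    """
    import pandas as pd

    pd.DataFrame({"reaction_id": list(uptake_ids),
                  "upper_bound": np.asarray(bounds, dtype=float)}).to_csv(
        path, sep="\t", index=False)


def read_bounds_file(path) -> dict:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["reaction_id"], df["upper_bound"].astype(float)))
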