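"""Metabolic model I/O and network preparation.

Genome-scale metabolic models come with signed (reversible) fluxes, which a
rectified-flux learning architecture cannot represent. This module reads
SBML / BiGG-JSON models (through cobra), rewrites them with positive-only
fluxes by splitting every reversible reaction into a forward and a reverse
copy and every exchange reaction into an inflow/outflow pair, optionally
removes reactions that never carry flux over a collection of media, and
builds the projection matrices shared by the differentiable solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "MetabolicModel",
    "ProjectionSet",
    "read_model",
    "from_cobra",
    "to_cobra",
    "write_model",
    "split_bidirectional",
    "reduce_model",
    "build_projections",
    "find_obligate_uptakes",
    "ECOLI_CORE_OBLIGATE",
    "ECOLI_CORE_VARIABLE",
]

#: Exchange reactions open in the e_coli_core default (M9-like) medium.
#: These are the seven uptakes conventionally treated as obligate for that
#: model (CO2, glucose, H+, H2O, NH4, O2, phosphate).
ECOLI_CORE_OBLIGATE = (
    "EX_co2_e", "EX_glc__D_e", "EX_h_e", "EX_h2o_e",
    "EX_nh4_e", "EX_o2_e", "EX_pi_e",
)

#: The 13 variable carbon/nitrogen sources used for e_coli_core media.
ECOLI_CORE_VARIABLE = (
    "EX_ac_e", "EX_acald_e", "EX_akg_e", "EX_etoh_e", "EX_for_e",
    "EX_fru_e", "EX_fum_e", "EX_gln__L_e", "EX_glu__L_e", "EX_lac__D_e",
    "EX_mal__L_e", "EX_pyr_e", "EX_succ_e",
)


@dataclass
class MetabolicModel:
    """A stoichiometric model with dense matrices.

    Attributes
    ----------
    reaction_ids, metabolite_ids : list of str
        Unique identifiers; columns/rows of ``S``.
    S : (m, n) ndarray
        Stoichiometric coefficients.
    lower_bounds, upper_bounds : (n,) ndarray
        Flux bounds in mmol/gDW/h.
    objective_id : str
        Biomass (growth) reaction.
    uptake_ids : list of str
        Ordered inflow reactions (``*_i`` after splitting) whose bounds
        encode the growth medium.
    obligate_uptake_ids : list of str
        Subset of ``uptake_ids`` always present in the medium.
    gene_rules : dict
        reaction id -> list of gene ids (any knocked-out gene disables the
        reaction).
    provenance : list of str
        Source path and transform log.
    """

    reaction_ids: list
    metabolite_ids: list
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_id: str
    uptake_ids: list = field(default_factory=list)
    obligate_uptake_ids: list = field(default_factory=list)
    gene_rules: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        m, n = self.S.shape
        if len(self.reaction_ids) != n or len(self.metabolite_ids) != m:
            raise ValueError("S shape inconsistent with id lists")
        if len(set(self.reaction_ids)) != n:
            raise ValueError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if self.objective_id not in self.reaction_ids:
            raise ValueError(f"objective {self.objective_id!r} not in model")
        missing = set(self.uptake_ids) - set(self.reaction_ids)
        if missing:
            raise KeyError(f"uptake ids not in model: {sorted(missing)}")

    # -- conveniences ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n_in(self) -> int:
        return len(self.uptake_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def indices(self, rids: Sequence[str]) -> np.ndarray:
        return np.array([self.reaction_index(r) for r in rids], dtype=int)

    def is_exchange(self, j: int) -> bool:
        """A reaction is an exchange if its metabolites sit on one side only."""
        col = self.S[:, j]
        return not (np.any(col > 0) and np.any(col < 0))


@dataclass
class ProjectionSet:
    """Projection/selection matrices shared by losses and solvers.

    ``P_in`` (n_in x n), ``P_ref`` (n_ref x n) and ``P_KO`` (n_KO x n) are
    0/1 row selectors. ``S_int`` is S with uptake inflow columns zeroed.
    ``P_v2m = ReLU(S)`` maps fluxes to metabolite production;
    ``P_m2v[k, j] = ReLU(-1 / (z_j * S[j, k]))`` distributes a metabolite's
    production uniformly over its ``z_j`` consumers.
    """

    P_in: np.ndarray
    P_ref: np.ndarray
    P_KO: np.ndarray
    S_int: np.ndarray
    P_v2m: np.ndarray
    P_m2v: np.ndarray
    uptake_indices: np.ndarray
    ref_indices: np.ndarray
    ko_indices: np.ndarray


def _selector(indices: np.ndarray, n: int) -> np.ndarray:
    P = np.zeros((len(indices), n))
    P[np.arange(len(indices)), indices] = 1.0
    return P


# ---------------------------------------------------------------------------
# Readers / writers (cobra-backed)
# ---------------------------------------------------------------------------

def from_cobra(cm, source: str = "cobra") -> MetabolicModel:
    """Convert a cobra model to a dense :class:`MetabolicModel`."""
    objective = [r.id for r in cm.reactions if r.objective_coefficient]
    if not objective:
        raise ValueError("model has no objective reaction")
    rids = [r.id for r in cm.reactions]
    mids = [m.id for m in cm.metabolites]
    mindex = {mid: i for i, mid in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, rxn in enumerate(cm.reactions):
        for met, coef in rxn.metabolites.items():
            S[mindex[met.id], j] = coef
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    rules = {r.id: [g.id for g in r.genes] for r in cm.reactions if r.genes}
    return MetabolicModel(
        reaction_ids=rids, metabolite_ids=mids, S=S,
        lower_bounds=lb, upper_bounds=ub, objective_id=objective[0],
        gene_rules=rules, provenance=[f"read:{source}"])


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read an SBML or BiGG-style JSON model from ``path``.

    ``format`` is inferred from the suffix when omitted (``.xml``/``.sbml``
    vs ``.json``).
    """
    import cobra.io

    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        cm = cobra.io.load_json_model(str(path))
    elif format == "sbml":
        cm = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return from_cobra(cm, source=str(path))


def to_cobra(model: MetabolicModel):
    """Convert back to a cobra model (for writing or simplex cross-checks)."""
    import cobra

    cm = cobra.Model("amn_model")
    mets = {mid: cobra.Metabolite(mid) for mid in model.metabolite_ids}
    # cobra requires a compartment for SBML export
    for met in mets.values():
        met.compartment = "c"
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        nz = np.nonzero(col)[0]
        cm.reactions.get_by_id(rid).add_metabolites(
            {mets[model.metabolite_ids[i]]: col[i] for i in nz})
    cm.objective = model.objective_id
    return cm


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write the model as SBML or BiGG-style JSON, plus a transform log."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    cm = to_cobra(model)
    if format == "json":
        cobra.io.save_json_model(cm, str(path))
    else:
        cobra.io.write_sbml_model(cm, str(path))
    log = path.with_suffix(path.suffix + ".log")
    log.write_text("\n".join(model.provenance) + "\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def split_bidirectional(model: MetabolicModel) -> MetabolicModel:
    """Rewrite the network with positive-only fluxes.

    Every reversible internal reaction becomes ``<id>_for`` / ``<id>_rev``
    (negated column); every exchange reaction becomes an inflow ``<id>_i``
    (oriented to add matter to the system) and an outflow ``<id>_o``, even
    if it was one-sided. Raises if the model already carries split suffixes.
    """
    for rid in model.reaction_ids:
        if rid.endswith(("_for", "_rev", "_i", "_o")):
            raise ValueError(
                f"model already split (found {rid!r}); refusing to split twice")

    cols, rids, lbs, ubs = [], [], [], []
    uptakes = []
    rules = {}
    big = 1000.0
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        genes = model.gene_rules.get(rid)
        # the biomass pseudo-reaction is one-sided in toy models but is a
        # sink, not an exchange with the environment: never duplicate it
        if model.is_exchange(j) and rid != model.objective_id:
            # inflow = orientation that adds matter (positive coefficients)
            inflow = col.copy() if np.all(col >= 0) else -col
            outflow = -inflow
            # bound of the inflow direction in the original model
            in_ub = -lb if np.all(col <= 0) else ub
            out_ub = ub if np.all(col <= 0) else -lb
            cols += [inflow, outflow]
            rids += [f"{rid}_i", f"{rid}_o"]
            lbs += [0.0, 0.0]
            ubs += [max(in_ub, 0.0), max(out_ub, 0.0)]
            uptakes.append(f"{rid}_i")
            if genes:
                rules[f"{rid}_i"] = genes
                rules[f"{rid}_o"] = genes
        elif lb < 0:
            cols += [col, -col]
            rids += [f"{rid}_for", f"{rid}_rev"]
            lbs += [0.0, 0.0]
            ubs += [max(ub, 0.0), -lb]
            if genes:
                rules[f"{rid}_for"] = genes
                rules[f"{rid}_rev"] = genes
        else:
            cols.append(col)
            rids.append(rid)
            lbs.append(max(lb, 0.0))
            ubs.append(ub)
            if genes:
                rules[rid] = genes

    obligate = [f"{r}_i" for r in model.obligate_uptake_ids
                if f"{r}_i" in rids]
    return MetabolicModel(
        reaction_ids=rids,
        metabolite_ids=list(model.metabolite_ids),
        S=np.column_stack(cols),
        lower_bounds=np.array(lbs), upper_bounds=np.array(ubs),
        objective_id=model.objective_id,
        uptake_ids=uptakes,
        obligate_uptake_ids=obligate,
        gene_rules=rules,
        provenance=model.provenance + [
            f"split: {model.n} -> {len(rids)} reactions"])


def reduce_model(model: MetabolicModel,
                 flux_distributions: Iterable[np.ndarray],
                 tol: float = 1e-9) -> MetabolicModel:
    """Drop reactions that never carry flux over the given distributions.

    Reactions whose flux is <= ``tol`` in *every* distribution are removed
    (the objective and all uptake inflow reactions are always retained);
    metabolites left with all-zero stoichiometric rows are removed too.
    """
    flux_distributions = [np.asarray(v, dtype=float) for v in flux_distributions]
    if not flux_distributions:
        raise ValueError("need at least one flux distribution to reduce")
    V = np.vstack(flux_distributions)
    if V.shape[1] != model.n:
        raise ValueError("flux distributions do not match model size")
    active = (np.abs(V) > tol).any(axis=0)
    keep_always = {model.objective_id, *model.uptake_ids}
    keep = [j for j, rid in enumerate(model.reaction_ids)
            if active[j] or rid in keep_always]
    S = model.S[:, keep]
    met_keep = np.nonzero(np.any(S != 0, axis=1))[0]
    rids = [model.reaction_ids[j] for j in keep]
    return MetabolicModel(
        reaction_ids=rids,
        metabolite_ids=[model.metabolite_ids[i] for i in met_keep],
        S=S[met_keep, :],
        lower_bounds=model.lower_bounds[keep],
        upper_bounds=model.upper_bounds[keep],
        objective_id=model.objective_id,
        uptake_ids=[r for r in model.uptake_ids if r in set(rids)],
        obligate_uptake_ids=[r for r in model.obligate_uptake_ids
                             if r in set(rids)],
        gene_rules={r: g for r, g in model.gene_rules.items() if r in set(rids)},
        provenance=model.provenance + [
            f"reduce: {model.n} -> {len(rids)} reactions, "
            f"{model.m} -> {len(met_keep)} metabolites"])


def build_projections(model: MetabolicModel,
                      ref_ids: Sequence[str] | None = None,
                      ko_ids: Sequence[str] = ()) -> ProjectionSet:
    """Build the projection matrices used by losses and solvers."""
    if ref_ids is None:
        ref_ids = [model.objective_id]
    up_idx = model.indices(model.uptake_ids)
    ref_idx = model.indices(ref_ids)
    ko_idx = model.indices(ko_ids)
    n, m = model.n, model.m
    S = model.S
    S_int = S.copy()
    S_int[:, up_idx] = 0.0
    P_v2m = np.maximum(S, 0.0)
    # number of consumers of each metabolite (strictly negative row entries)
    z = (S < 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(S != 0, -1.0 / (z[:, None] * S), 0.0)
    raw[~np.isfinite(raw)] = 0.0
    P_m2v = np.maximum(raw, 0.0).T  # n x m
    return ProjectionSet(
        P_in=_selector(up_idx, n),
        P_ref=_selector(ref_idx, n),
        P_KO=_selector(ko_idx, n),
        S_int=S_int, P_v2m=P_v2m, P_m2v=P_m2v,
        uptake_indices=up_idx, ref_indices=ref_idx, ko_indices=ko_idx)


def find_obligate_uptakes(model: MetabolicModel,
                          candidates: Sequence[str] | None = None,
                          high_bound: float = 1000.0,
                          lp_oracle: Callable | None = None,
                          growth_tol: float = 1e-9) -> list:
    """Uptakes whose individual closure abolishes growth.

    Each candidate in turn has its upper bound set to 0 while all other
    candidates are opened at ``high_bound``; a candidate is obligate when
    the maximal growth is 0 (or the LP infeasible).
    """
    from .fba import solve_fba

    if candidates is None:
        candidates = list(model.uptake_ids)
    if lp_oracle is None:
        lp_oracle = solve_fba
    open_bounds = {c: high_bound for c in candidates}
    base = lp_oracle(model, open_bounds)
    if not base.feasible or base.objective_value <= growth_tol:
        raise ValueError("no growth even with all candidate uptakes open")
    obligate = []
    for c in candidates:
        bounds = dict(open_bounds)
        bounds[c] = 0.0
        res = lp_oracle(model, bounds)
        if (not res.feasible) or res.objective_value <= growth_tol:
            obligate.append(c)
    return obligate
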