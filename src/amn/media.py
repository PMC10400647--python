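"""Growth-media sampling and the carbon-source combination design.

Simulated media follow a two-stage draw: each variable uptake is switched
on independently with probability ``p`` (binomial selection) and, when on,
receives an upper bound drawn uniformly from an interval with 0 excluded.
Obligate uptakes are fixed in every medium. The experimental design
enumerates all single carbon sources and samples subsets of 2-4 sources
without replacement.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MediaSet",
    "MediaDesign",
    "sample_simulated_media",
    "build_experimental_design",
    "design_to_binary",
    "PRESETS",
]

#: Bound-draw presets: (low, high, obligate bound) in mmol/gDW/h.
PRESETS = {
    "e_coli_core": {"bound_low": 2.0, "bound_high": 10.0, "obligate_bound": 10.0},
    "iML1515": {"bound_low": 0.0, "bound_high": 2.2, "obligate_bound": 10.0},
    "iJN1463": {"bound_low": 0.0, "bound_high": 10.0, "obligate_bound": 10.0},
}


@dataclass
class MediaSet:
    """Sampled media as rows of uptake upper bounds."""

    uptake_ids: list
    rows: np.ndarray  # n_samples x n_in
    mode: str = "UB"
    seed: int | None = None
    variable_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[1] != len(self.uptake_ids):
            raise ValueError("row width != number of uptake ids")

    def save(self, path) -> None:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.rows, columns=self.uptake_ids).to_csv(
            path, sep="\t", index=False)
        sidecar = {"mode": self.mode, "seed": self.seed,
                   "variable_ids": list(self.variable_ids)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "MediaSet":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(list(df.columns), df.to_numpy(float), meta["mode"],
                   meta["seed"], meta.get("variable_ids", []))


@dataclass
class MediaDesign:
    """Chosen carbon-source subsets for an experimental campaign."""

    sources: list
    chosen: list  # list of tuples of source names
    seed: int | None = None

    def counts_per_size(self) -> dict:
        out: dict = {}
        for subset in self.chosen:
            out[len(subset)] = out.get(len(subset), 0) + 1
        return out


def sample_simulated_media(uptake_ids: Sequence[str],
                           variable_ids: Sequence[str],
                           p: float = 0.5,
                           bound_low: float = 2.0,
                           bound_high: float = 10.0,
                           n_samples: int = 1000,
                           obligate_bound: float = 10.0,
                           seed: int = 0) -> MediaSet:
    """Draw media: binomial uptake selection + uniform bounds (0 excluded).

    Each variable uptake is selected independently with probability ``p``;
    selected uptakes get a uniform bound in ``(bound_low, bound_high]``
    (rejection keeps 0 out when ``bound_low == 0``). Obligate uptakes (all
    non-variable ones) are fixed at ``obligate_bound``.
    """
    uptake_ids = list(uptake_ids)
    variable_ids = list(variable_ids)
    missing = set(variable_ids) - set(uptake_ids)
    if missing:
        raise KeyError(f"variable ids not among uptakes: {sorted(missing)}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if bound_low >= bound_high:
        raise ValueError("bound_low must be < bound_high")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    var_idx = np.array([uptake_ids.index(v) for v in variable_ids], dtype=int)
    obligate_idx = np.array(
        [i for i in range(len(uptake_ids)) if i not in set(var_idx)], dtype=int)
    rows = np.zeros((n_samples, len(uptake_ids)))
    rows[:, obligate_idx] = obligate_bound
    if len(var_idx):
        selected = rng.random((n_samples, len(var_idx))) < p
        draws = rng.uniform(bound_low, bound_high, size=selected.shape)
        # exclude exact lower edge (notably 0) by redrawing
        while np.any(at_edge := (draws <= bound_low) & selected):
            draws[at_edge] = rng.uniform(bound_low, bound_high,
                                         size=int(at_edge.sum()))
        rows[:, var_idx] = np.where(selected, draws, 0.0)
    return MediaSet(uptake_ids, rows, "UB", seed, variable_ids)


def build_experimental_design(sources: Sequence[str],
                              counts: Mapping[int, int | str] | None = None,
                              seed: int = 0) -> MediaDesign:
    """All 1-source media plus sampled 2-/3-/4-source combinations.

    The default counts reproduce the benchmark campaign over 10 carbon
    sources: all 10 singletons, 20 pairs, 40 triples and 40 quadruples
    (110 media in total), sampled without replacement per subset size.
    """
    sources = list(sources)
    if counts is None:
        counts = {1: "all", 2: 20, 3: 40, 4: 40}
    rng = np.random.default_rng(seed)
    chosen: list = []
    for size in sorted(counts):
        want = counts[size]
        available = comb(len(sources), size)
        if want == "all":
            want = available
        if want > available:
            raise ValueError(
                f"requested {want} subsets of size {size}, only "
                f"{available} exist")
        pool = list(itertools.combinations(sources, size))
        if want == available:
            picked = pool
        else:
            idx = rng.choice(available, size=want, replace=False)
            picked = [pool[i] for i in sorted(idx)]
        chosen.extend(picked)
    return MediaDesign(sources, chosen, seed)


def design_to_binary(design: MediaDesign,
                     uptake_ids: Sequence[str],
                     source_map: Mapping[str, str] | None = None,
                     obligate_ids: Sequence[str] = ()) -> np.ndarray:
    """Binary medium-composition matrix C_med (rows = media).

    ``source_map`` maps carbon-source names to uptake reaction ids (identity
    by default). Columns listed in ``obligate_ids`` are set to 1 everywhere.
    """
    uptake_ids = list(uptake_ids)
    source_map = dict(source_map or {})
    col = {}
    for s in design.sources:
        rid = source_map.get(s, s)
        if rid not in uptake_ids:
            raise KeyError(f"source {s!r} has no uptake column {rid!r}")
        col[s] = uptake_ids.index(rid)
    C = np.zeros((len(design.chosen), len(uptake_ids)))
    for i, subset in enumerate(design.chosen):
        if len(subset) == 0:
            raise ValueError("empty medium subset")
        for s in subset:
            C[i, col[s]] = 1.0
    for rid in obligate_ids:
        C[:, uptake_ids.index(rid)] = 1.0
    return C
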