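"""Shared fixtures: toy networks and the bundled E. coli core model."""

import os

import numpy as np
import pytest

from amn.model_io import MetabolicModel, build_projections
from amn.synthetic import make_toy_network


@pytest.fixture
def chain():
    """up_A_i -> A -> biomass; optimum equals the uptake bound."""
    model, _ = make_toy_network("chain", length=2)
    return model


@pytest.fixture
def chain_projections(chain):
    return build_projections(chain)


@pytest.fixture
def branch():
    """A feeds biomass branch and a secondary exported sink."""
    model, _ = make_toy_network("branch", n_branches=2)
    return model


@pytest.fixture
def dead_end_branch():
    """A -> B has no export: steady state forces all flux through A -> C."""
    S = np.array([
        # up   rAB   rAC   bio
        [1.0, -1.0, -1.0, 0.0],   # A
        [0.0, 1.0, 0.0, 0.0],     # B (no consumer: dead end)
        [0.0, 0.0, 1.0, -1.0],    # C
    ])
    return MetabolicModel(
        ["up_A_i", "rAB", "rAC", "bio"], ["A", "B", "C"], S,
        np.zeros(4), np.full(4, 1000.0), objective_id="bio",
        uptake_ids=["up_A_i"])


def _ecoli_core_path():
    import cobra

    return os.path.join(os.path.dirname(cobra.__file__), "data",
                        "textbook.xml.gz")


@pytest.fixture(scope="session")
def ecoli_core():
    """The E. coli core model shipped with cobra (95 reactions, 72 mets)."""
    import cobra.io

    from amn.model_io import from_cobra

    return from_cobra(cobra.io.read_sbml_model(_ecoli_core_path()),
                      source="cobra:textbook")


@pytest.fixture(scope="session")
def ecoli_core_split(ecoli_core):
    from amn.model_io import split_bidirectional

    return split_bidirectional(ecoli_core)
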