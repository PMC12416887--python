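"""Shared fixtures: small hand-built topologies and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from bkgating.core import Topology, Trajectory


def bead_topology(names, resids, resnames=None, chains=None, charges=None,
                  radii=None, elements=None) -> Topology:
    """Build a Topology from short parallel lists (single chain by default)."""
    n = len(names)
    return Topology(
        atom_ids=np.arange(1, n + 1),
        names=np.array(names, dtype=object),
        residue_numbers=np.array(resids, dtype=int),
        residue_names=np.array(resnames or ["GLY"] * n, dtype=object),
        chain_ids=np.array(chains or ["A"] * n, dtype=object),
        elements=np.array(
            elements or [str(nm)[0] for nm in names], dtype=object),
        charges=np.array(charges if charges is not None else np.zeros(n),
                         dtype=float),
        radii=np.array(radii if radii is not None else np.full(n, 1.7),
                       dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_chain_arg_topology():
    """Four chains each holding one ARG 213 (CZ) and S6 CA atoms 313-324."""
    names, resids, resnames, chains = [], [], [], []
    for c in "ABCD":
        names.append("CZ")
        resids.append(213)
        resnames.append("ARG")
        chains.append(c)
        for r in range(313, 325):
            names.append("CA")
            resids.append(r)
            resnames.append("ALA")
            chains.append(c)
    return bead_topology(names, resids, resnames, chains)


def single_frame(topology: Topology, coords: np.ndarray,
                 box=(100.0, 100.0, 100.0)) -> Trajectory:
    return Trajectory(np.asarray(coords, dtype=float)[None], np.asarray(box))
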