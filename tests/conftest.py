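"""Shared fixtures: tiny hand-built systems and reusable synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from gdminsert.model import Atom, HairpinSpec, Topology
from gdminsert.synthetic import PotentialSpec, make_membrane_frame, sample_umbrella


def chain_topology(n_residues: int, resname: str = "GLY") -> Topology:
    """A pseudo-peptide: one CA atom per residue, ids 1..n."""
    return Topology(
        [Atom(i, "CA", resname, i, element="C") for i in range(1, n_residues + 1)]
    )


@pytest.fixture(scope="session")
def planted_frame():
    """One planted membrane frame with every feature present."""
    return make_membrane_frame(
        n_defect_waters=12, n_core_phosphates=4,
        near_hairpin_by_class={"PE": 3, "PG": 2}, seed=42,
    )


@pytest.fixture(scope="session")
def toy_spec():
    return HairpinSpec("custom", ((1, 5), (7, 11)), 3)


@pytest.fixture(scope="session")
def double_well():
    """Asymmetric double well: minima near -1.0 and 2.0 nm, interior barrier."""
    return PotentialSpec(
        "double_well", {"A": 4.0, "c": 0.5, "w": 1.5, "b": -1.0},
        domain=(-2.5, 3.0),
    )


@pytest.fixture(scope="session")
def small_umbrella_windows(double_well):
    """A light umbrella-sampling run, adequate for structural checks."""
    return sample_umbrella(
        double_well, np.linspace(-2.0, 2.6, 24), k=1000.0,
        n_per_window=4000, seed=7,
    )


def selections(topology):
    """Standard name-based selections for synthetic membrane frames."""
    lipids = ("PE", "PG", "CDL")
    return {
        "lipid": topology.select(residue_names=lipids),
        "phosphate_o": topology.select(residue_names=lipids, atom_names=("OP1",)),
        "phosphorus": topology.select(residue_names=lipids, atom_names=("P8",)),
        "water_o": topology.select(residue_names=("SOL",), atom_names=("OW",)),
    }
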