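"""Shared fixtures: small synthetic scaffolds with planted triads.

Session-scoped because the design scan is the expensive step; everything
is deterministic, so sharing does not couple tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from triadscan.fixtures import make_scaffold, plant_triad
from triadscan.model import Atom, Residue, Structure
from triadscan.search import design_triads


@pytest.fixture(scope="session")
def helix8():
    return make_scaffold(8, "helix", seed=0)


@pytest.fixture(scope="session")
def helix12():
    return make_scaffold(12, "helix", seed=0)


@pytest.fixture(scope="session")
def planted8(helix8):
    """8-residue helix with a Ser1-His5-Asp8 triad at 3.0/3.0 A."""
    structure, spec = plant_triad(
        helix8, (1, 5, 8), {"d_ser_his": 3.0, "d_his_acid": 3.0}, seed=7
    )
    return structure, spec


@pytest.fixture(scope="session")
def design8(planted8):
    """Full design-stage result on the planted 8-residue helix."""
    structure, _ = planted8
    return design_triads(structure)


@pytest.fixture(scope="session")
def cage():
    """A residue fully enclosed by a shell of pseudo-residues: its central
    atoms have zero solvent accessibility."""
    rng = np.random.default_rng(0)
    center = Residue(
        "A", 1, "ALA",
        [
            Atom("N", "N", [0.0, 0.0, 1.2]),
            Atom("CA", "C", [0.0, 0.0, 0.0]),
            Atom("C", "C", [1.2, 0.0, 0.0]),
            Atom("O", "O", [1.2, 1.0, 0.0]),
            Atom("CB", "C", [0.0, 1.2, 0.0]),
        ],
    )
    shell = []
    # two concentric dense shells guarantee full burial of the centre
    npts, radii = 200, (4.2, 6.4)
    i = np.arange(npts)
    z = 1.0 - 2.0 * (i + 0.5) / npts
    r = np.sqrt(1.0 - z**2)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    unit = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    num = 2
    for rad in radii:
        for p in unit * rad:
            shell.append(
                Residue("A", num, "ALA", [Atom("CB", "C", p + [0.4, 0, 0])])
            )
            num += 1
    return Structure([center] + shell)
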