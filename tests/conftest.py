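"""Shared fixtures: toy structures, grids, and a hand-written PDB text."""

import numpy as np
import pytest

from xlambig import (
    build_grid,
    make_toy_dimer,
    recreate_reference,
)
from xlambig.structio import Atom, Chain, Residue, Structure

# Minimal two-chain PDB: 12 residues per chain, 3 lysines per chain.
# Includes an altloc pair on one atom and a water that must be dropped.
PDB_TOY = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  LYS A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA ALYS A   4      11.400   0.000   0.000  0.60  0.00           C
ATOM      5  CA BLYS A   4      11.500   0.100   0.000  0.40  0.00           C
ATOM      6  CA  ALA A   5      15.200   0.000   0.000  1.00  0.00           C
ATOM      7  CA  ALA A   6      19.000   0.000   0.000  1.00  0.00           C
ATOM      8  CA  ALA A   7      22.800   0.000   0.000  1.00  0.00           C
ATOM      9  CA  ALA A   8      26.600   0.000   0.000  1.00  0.00           C
ATOM     10  CA  ALA A   9      30.400   0.000   0.000  1.00  0.00           C
ATOM     11  CA  ALA A  10      34.200   0.000   0.000  1.00  0.00           C
ATOM     12  CA  LYS A  11      38.000   0.000   0.000  1.00  0.00           C
ATOM     13  CA  ALA A  12      41.800   0.000   0.000  1.00  0.00           C
TER
ATOM     14  CA  LYS B   1       0.000  10.000   0.000  1.00  0.00           C
ATOM     15  CA  ALA B   2       3.800  10.000   0.000  1.00  0.00           C
ATOM     16  CA  ALA B   3       7.600  10.000   0.000  1.00  0.00           C
ATOM     17  CA  LYS B   4      11.400  10.000   0.000  1.00  0.00           C
ATOM     18  CA  ALA B   5      15.200  10.000   0.000  1.00  0.00           C
ATOM     19  CA  ALA B   6      19.000  10.000   0.000  1.00  0.00           C
ATOM     20  CA  ALA B   7      22.800  10.000   0.000  1.00  0.00           C
ATOM     21  CA  ALA B   8      26.600  10.000   0.000  1.00  0.00           C
ATOM     22  CA  ALA B   9      30.400  10.000   0.000  1.00  0.00           C
ATOM     23  CA  ALA B  10      34.200  10.000   0.000  1.00  0.00           C
ATOM     24  CA  LYS B  11      38.000  10.000   0.000  1.00  0.00           C
ATOM     25  CA  ALA B  12      41.800  10.000   0.000  1.00  0.00           C
TER
HETATM   26  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_TOY)
    return path


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(seed=1)


@pytest.fixture(scope="session")
def reference(toy_dimer):
    return recreate_reference(toy_dimer)


@pytest.fixture(scope="session")
def reference_grid(reference):
    return build_grid(reference)


def atom_cloud_structure(points, name="cloud"):
    """One-chain structure whose residues are bare CA atoms at `points`."""
    chain = Chain("A")
    for i, p in enumerate(points, start=1):
        chain.residues.append(
            Residue(i, "", "ALA", [Atom("CA", "C", np.asarray(p, dtype=float))])
        )
    return Structure(name, [chain])


def wall_with_hole(nx=9, nz=9, hole=(4, 4), spacing=1.5, x_extent=20.0):
    """Two probe residues separated by an atom wall pierced by one hole.

    The wall spans the y-z plane at x=0; the endpoints sit on either side.
    Returns (structure, ref_left, ref_right).
    """
    from xlambig.structio import ResidueRef

    pts = []
    for iy in range(nx):
        for iz in range(nz):
            if (iy, iz) == hole:
                continue
            y = (iy - nx // 2) * spacing
            z = (iz - nz // 2) * spacing
            pts.append((0.0, y, z))
    left = (-x_extent / 2, 0.0, 0.0)
    right = (x_extent / 2, 0.0, 0.0)
    st = atom_cloud_structure([left, right] + pts, name="wall")
    return st, ResidueRef("A", 1), ResidueRef("A", 2)
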