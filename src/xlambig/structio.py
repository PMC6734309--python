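"""PDB structure I/O and rigid-body geometry for homo-oligomer models.

Structures are held as a light in-memory container built from gemmi's PDB
parser: ordered chains of ordered residues with per-atom coordinates in Å.
Residue identity follows PDB author numbering (resSeq + insertion code);
chain order is file order, so "first chain" is well defined.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueRef",
    "RigidTransform",
    "ValidationError",
    "read_pdb",
    "write_pdb",
    "lysine_calpha",
    "kabsch_superpose",
    "recreate_reference",
    "apply_transform",
]


class ValidationError(ValueError):
    """Raised when an input structure violates an operation's contract."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) float64, Å

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy())


@dataclass
class Residue:
    seqid: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.seqid, self.icode, self.name, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        return None

    def residue_keys(self) -> list[tuple[int, str]]:
        return [r.key for r in self.residues]

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """Ordered chains of residues with Å coordinates.

    Invariant: chain order is file order; every operation that says
    "first chain" means ``chains[0]``.
    """

    name: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ValidationError(f"chain {chain_id!r} not found in {self.name}")

    def copy(self) -> "Structure":
        return Structure(self.name, [c.copy() for c in self.chains])

    def heavy_atom_coords(self) -> np.ndarray:
        """All non-hydrogen atom positions, shape (n, 3)."""
        pts = [
            a.pos
            for c in self.chains
            for r in c.residues
            for a in r.atoms
            if a.element.upper() not in ("H", "D")
        ]
        if not pts:
            return np.empty((0, 3))
        return np.asarray(pts, dtype=float)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        chains = self.chains if chain_id is None else [self.chain(chain_id)]
        pts = []
        for c in chains:
            for r in c.residues:
                ca = r.atom("CA")
                if ca is not None:
                    pts.append(ca.pos)
        return np.asarray(pts, dtype=float) if pts else np.empty((0, 3))


@dataclass(frozen=True)
class ResidueRef:
    """Reference to one residue: chain id plus author numbering."""

    chain_id: str
    seqid: int
    icode: str = ""

    def resolve_ca(self, structure: Structure) -> np.ndarray:
        res = structure.chain(self.chain_id).residue(self.seqid, self.icode)
        if res is None:
            raise ValidationError(f"residue {self} not found in {structure.name}")
        ca = res.atom("CA")
        if ca is None:
            raise ValidationError(f"residue {self} has no CA atom")
        return ca.pos


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValidationError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a Structure.

    Only the first MODEL is used; HETATM records and waters are dropped;
    for alternate locations the first-listed altloc is kept.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise IOError(f"no models in PDB file {path}")
    model = st[0]
    out = Structure(name=path.stem)
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            if gres.het_flag != "A" or gres.is_water():
                continue
            res = Residue(gres.seqid.num, (gres.seqid.icode or " ").strip(), gres.name)
            seen: set[str] = set()
            for ga in gres:
                if ga.name in seen:  # keep first-listed altloc only
                    continue
                seen.add(ga.name)
                res.atoms.append(
                    Atom(ga.name, ga.element.name, np.array([ga.pos.x, ga.pos.y, ga.pos.z]))
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if not any(r.atom("CA") for c in out.chains for r in c.residues):
        raise ValidationError(f"no CA atoms found in {path}")
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as standard ATOM records via gemmi."""
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Lysine extraction


def lysine_calpha(structure: Structure) -> list[tuple[ResidueRef, np.ndarray]]:
    """Cα positions of all lysine residues, in (chain, residue) order.

    Lysines lacking a Cα atom (truncated records) are omitted with a warning.
    """
    out = []
    for chain in structure.chains:
        for res in chain.residues:
            if res.name != "LYS":
                continue
            ca = res.atom("CA")
            if ca is None:
                logger.warning(
                    "LYS %s%d%s has no CA atom; skipped", chain.chain_id, res.seqid, res.icode
                )
                continue
            out.append((ResidueRef(chain.chain_id, res.seqid, res.icode), ca.pos))
    return out


# ---------------------------------------------------------------------------
# Superposition and rigid-body transforms


def kabsch_superpose(
    mobile_coords: np.ndarray, target_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of mobile onto target (Kabsch).

    Returns the proper-rotation transform minimizing RMSD and the post-fit
    RMSD in Å.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(target_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("coordinate sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValidationError("need at least 3 points for superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def _common_ca(chain_a: Chain, chain_b: Chain) -> tuple[np.ndarray, np.ndarray]:
    keys_b = {r.key: r for r in chain_b.residues}
    pa, pb = [], []
    for res in chain_a.residues:
        other = keys_b.get(res.key)
        if other is None:
            continue
        ca_a, ca_b = res.atom("CA"), other.atom("CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a.pos)
            pb.append(ca_b.pos)
    return np.asarray(pa), np.asarray(pb)


def recreate_reference(structure: Structure) -> Structure:
    """Rebuild a homo-dimer with two identical chains.

    The second chain is replaced by a copy of the first chain rigidly
    superposed onto it via shared Cα atoms (matched by residue number and
    insertion code), so reference and docking models share an identical
    chain composition.
    """
    if len(structure.chains) != 2:
        raise ValidationError(
            f"recreate_reference needs a two-chain structure, got {len(structure.chains)}"
        )
    first, second = structure.chains
    pa, pb = _common_ca(first, second)
    if len(pa) < 3:
        raise ValidationError("chains share fewer than 3 common CA residues")
    transform, _ = kabsch_superpose(pa, pb)
    new_second = first.copy()
    new_second.chain_id = second.chain_id
    for res in new_second.residues:
        for atom in res.atoms:
            atom.pos = transform.apply(atom.pos[None, :])[0]
    return Structure(structure.name, [first.copy(), new_second])


def apply_transform(
    structure: Structure, chain_id: str, transform: RigidTransform
) -> Structure:
    """Move one chain by a rigid transform; all other chains untouched."""
    out = structure.copy()
    chain = out.chain(chain_id)  # raises ValidationError for unknown chain
    for res in chain.residues:
        for atom in res.atoms:
            atom.pos = transform.apply(atom.pos[None, :])[0]
    return out
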