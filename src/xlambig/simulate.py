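"""Synthetic benchmark inputs: simulated cross-links, toy dimers, decoys.

Experimental cross-linking data for homo-oligomers is scarce, so benchmarks
run on simulated data: cross-links are extracted from a reference dimer as
every lysine pair whose intra- or inter-subunit surface distance is within
the linker threshold, and docking models are emulated by rigid-body
placements of the second subunit around a fixed first subunit — a small
fraction drawn as near-native perturbations, the rest as random clash-free
placements.

The toy dimer generator builds an idealized α-helical Cα trace with
pseudo side-chain atoms, duplicated into an exact C2-symmetric dimer (the
two-fold axis is z, so the symmetry copy is a coordinate negation and the
two oriented inter readings agree to the bit). One lysine can be buried
under an icosahedral cage of pseudo-atoms so the non-accessible code paths
are exercised by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from . import sasd_engine
from .ambiguity import Assignment, classify, enumerate_candidates
from .structio import (
    Atom,
    Chain,
    Residue,
    RigidTransform,
    Structure,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedXLSet",
    "DecoyEnsemble",
    "GenerationError",
    "simulate_crosslinks",
    "make_toy_dimer",
    "generate_decoys",
    "bootstrap_coverage",
]


class GenerationError(RuntimeError):
    """Raised when decoy placement fails within the retry budget."""


@dataclass(frozen=True)
class SimulatedXLSet:
    """Residue-number pairs extracted from a reference as cross-links.

    Pairs are chain-ambiguous (residue numbers only), mirroring real XL-MS
    output for homo-oligomers; the true assignment in the reference is kept
    alongside for diagnostics.
    """

    pairs: tuple[tuple[int, int], ...]
    source: str
    threshold: float
    method: str = "SASD"
    true_labels: dict[tuple[int, int], Assignment] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def simulate_crosslinks(
    reference: Structure,
    threshold: float = 33.0,
    grid: "sasd_engine.SolventGrid | None" = None,
    access_radius: float = 4.0,
) -> SimulatedXLSet:
    """All lysine pairs whose intra or inter SASD is within the threshold.

    Runs on a recreated reference dimer; deterministic. An empty result is
    returned with a warning (such structures are excluded from benchmarks).
    """
    cands = enumerate_candidates(
        reference, method="SASD", grid=grid, access_radius=access_radius
    )
    pairs, labels = [], {}
    for c in cands:
        label = classify(c, threshold)
        if label is not Assignment.NON_ACCESSIBLE:
            pairs.append((c.res_i, c.res_j))
            labels[(c.res_i, c.res_j)] = label
    if not pairs:
        logger.warning("no simulated cross-links for %s at %.1f Å", reference.name, threshold)
    return SimulatedXLSet(
        pairs=tuple(sorted(pairs)),
        source=reference.name,
        threshold=threshold,
        true_labels=labels,
    )


# ---------------------------------------------------------------------------
# Toy dimer generator

# icosahedron vertices (unit radius): burial cage directions
_PHI = (1 + math.sqrt(5)) / 2
_ICOSA = np.array(
    [
        (0, 1, _PHI), (0, -1, _PHI), (0, 1, -_PHI), (0, -1, -_PHI),
        (1, _PHI, 0), (-1, _PHI, 0), (1, -_PHI, 0), (-1, -_PHI, 0),
        (_PHI, 0, 1), (-_PHI, 0, 1), (_PHI, 0, -1), (-_PHI, 0, -1),
    ]
) / math.sqrt(1 + _PHI**2)


def _helix_chain(
    chain_id: str,
    n_residues: int,
    lysine_positions: list[int],
    buried_lysine: int | None,
    x_offset: float,
) -> Chain:
    """Idealized α-helix (1.5 Å rise, 100° turn, 2.3 Å radius) along z."""
    rise, turn, radius = 1.5, math.radians(100.0), 2.3
    chain = Chain(chain_id)
    z0 = -(n_residues - 1) * rise / 2  # center the helix on z = 0
    for i in range(n_residues):
        seq = i + 1
        theta = i * turn
        ca = np.array(
            [x_offset + radius * math.cos(theta), radius * math.sin(theta), z0 + i * rise]
        )
        # pseudo side chain pointing radially outward from the helix axis
        out_dir = np.array([math.cos(theta), math.sin(theta), 0.0])
        cb = ca + 1.5 * out_dir
        name = "LYS" if seq in lysine_positions else "ALA"
        res = Residue(seq, "", name, [Atom("CA", "C", ca), Atom("CB", "C", cb)])
        if seq == buried_lysine:
            for k, v in enumerate(_ICOSA):
                res.atoms.append(Atom(f"D{k+1}", "C", ca + 3.5 * v))
        chain.residues.append(res)
    return chain


def make_toy_dimer(
    n_residues: int = 32,
    n_lysines: int = 6,
    interface_offset: float = 12.0,
    seed: int = 0,
    bury_one_lysine: bool | None = None,
) -> Structure:
    """Exact C2-symmetric toy homo-dimer with reproducible lysine placement.

    Two identical helical subunits sit with axes parallel to z at
    x = ±interface_offset/2; chain B is chain A rotated 180° about z, so the
    symmetry is exact to the bit. Lysines are roughly evenly spaced with
    seeded jitter; with ``n_residues >= 20`` (or ``bury_one_lysine=True``)
    the middle lysine is enclosed in a pseudo-atom cage, guaranteeing one
    buried and several exposed lysines.
    """
    if n_residues < 8 or n_lysines < 2:
        raise ValidationError("need n_residues >= 8 and n_lysines >= 2")
    if n_lysines > n_residues // 2:
        raise ValidationError("too many lysines for chain length")
    rng = np.random.default_rng(seed)
    base = np.linspace(2, n_residues - 1, n_lysines)
    jitter = rng.integers(-1, 2, size=n_lysines)
    positions = sorted(set(int(round(b)) + int(j) for b, j in zip(base, jitter)))
    positions = [min(max(p, 1), n_residues) for p in positions]
    while len(positions) < n_lysines:  # jitter collisions: fill deterministically
        for cand in range(2, n_residues):
            if cand not in positions:
                positions.append(cand)
                break
        positions.sort()
    if bury_one_lysine is None:
        bury_one_lysine = n_residues >= 20
    buried = positions[len(positions) // 2] if bury_one_lysine else None

    chain_a = _helix_chain("A", n_residues, positions, buried, interface_offset / 2)
    chain_b = _helix_chain("B", n_residues, positions, buried, interface_offset / 2)
    for res in chain_b.residues:  # C2 about z: exact coordinate negation
        for atom in res.atoms:
            atom.pos = np.array([-atom.pos[0], -atom.pos[1], atom.pos[2]])
    return Structure(f"toy_dimer_s{seed}", [chain_a, chain_b])


# ---------------------------------------------------------------------------
# Decoy ensembles


@dataclass
class DecoyEnsemble:
    """Rigid-body placements of chain 2 around the fixed chain 1."""

    reference: Structure
    transforms: list[tuple[str, RigidTransform]]
    seed: int

    @property
    def count(self) -> int:
        return len(self.transforms)

    def model(self, i: int) -> Structure:
        model_id, tf = self.transforms[i]
        from .structio import apply_transform

        st = apply_transform(self.reference, self.reference.chain_ids[1], tf)
        st.name = model_id
        return st

    def models(self) -> Iterator[Structure]:
        for i in range(self.count):
            yield self.model(i)


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0, max_angle_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _about_centroid(R: np.ndarray, t: np.ndarray, centroid: np.ndarray) -> RigidTransform:
    """Rotate about a pivot point, then translate by t."""
    return RigidTransform(R, centroid - R @ centroid + t)


def _twofold(reference: Structure) -> RigidTransform:
    """Rigid motion mapping chain 1's Cα set onto chain 2's (≈ the C2 operation)."""
    from .structio import kabsch_superpose

    tf, _ = kabsch_superpose(
        reference.ca_coords(reference.chain_ids[0]),
        reference.ca_coords(reference.chain_ids[1]),
    )
    return tf


def generate_decoys(
    reference: Structure,
    n_models: int = 200,
    near_native_fraction: float = 0.1,
    max_perturbation: float = 5.0,
    seed: int = 0,
    max_retries: int = 200,
) -> DecoyEnsemble:
    """Seeded rigid-body decoy ensemble emulating docking output.

    Docking programs for symmetric complexes return surface-contact poses
    — symmetric ones from symmetry-aware sampling, arbitrary ones from
    unconstrained sampling — so three pools are drawn, all as rigid
    transforms of chain 2 around the fixed chain 1:

    * near-native (``round(near_native_fraction * n_models)`` models,
      guaranteed, giving ranking tests a known precision ceiling): the
      reference two-fold conjugated by a small rigid motion (rotation ≤
      3·max_perturbation degrees, translation ≤ max_perturbation Å), which
      keeps the model exactly C2-symmetric; accepted only below 10 Å
      complex Cα-RMSD;
    * symmetric decoys (half the remainder): a 180° rotation about a
      random axis placed so the subunits touch — wrong interface, exact
      C2 symmetry;
    * random decoys (the other half): a uniform random rotation of chain
      2 slid into contact with chain 1 along a random direction.

    Contact means a minimum inter-chain Cα–Cα distance between 3 and 6 Å;
    clashes (< 2 Å) and wrong-pool models inside the 10 Å near-native
    cutoff are rejected.
    """
    if len(reference.chains) != 2:
        raise ValidationError("decoy generation needs a dimer reference")
    if not (0.0 <= near_native_fraction <= 1.0):
        raise ValidationError("near_native_fraction must be in [0, 1]")
    from .structio import kabsch_superpose

    rng = np.random.default_rng(seed)
    chain2_id = reference.chain_ids[1]
    ca1 = reference.ca_coords(reference.chain_ids[0])
    ca2 = reference.ca_coords(chain2_id)
    c1 = ca1.mean(axis=0)
    n_near = int(round(near_native_fraction * n_models))
    ref_direct = np.vstack([ca1, ca2])
    ref_swapped = np.vstack([ca2, ca1])  # chains are identical: labels arbitrary
    S = _twofold(reference)
    S_inv = S.inverse()
    scan_max = 2.0 * float(np.linalg.norm(ref_direct - ref_direct.mean(0), axis=1).max()) + 20.0

    def complex_rmsd(new_ca2: np.ndarray) -> float:
        model = np.vstack([ca1, new_ca2])
        return min(
            kabsch_superpose(model, ref_direct)[1],
            kabsch_superpose(model, ref_swapped)[1],
        )

    def min_dist(new_ca2: np.ndarray) -> float:
        return float(
            np.sqrt(((ca1[:, None, :] - new_ca2[None, :, :]) ** 2).sum(-1)).min()
        )

    def conjugated_twofold(g: RigidTransform) -> RigidTransform:
        """Chain-2 transform realizing the two-fold S' = g∘S∘g⁻¹."""
        return g.compose(S).compose(g.inverse()).compose(S_inv)

    def near_native_try() -> RigidTransform | None:
        R = _random_rotation(rng, 3.0 * max_perturbation)
        t = rng.uniform(-max_perturbation, max_perturbation, size=3)
        g = _about_centroid(R, t, c1)
        tf = conjugated_twofold(g)
        new_ca2 = tf.apply(ca2)
        if min_dist(new_ca2) < 2.0 or complex_rmsd(new_ca2) > 10.0:
            return None
        return tf

    def symmetric_try() -> RigidTransform | None:
        # 180° about a random axis, slid outward until the chains touch
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(math.pi * axis).as_matrix()
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        for r in np.arange(0.0, scan_max, 0.5):
            p = c1 + r * w
            Sp = RigidTransform(R, p - R @ p)
            tf = Sp.compose(S_inv)
            new_ca2 = tf.apply(ca2)
            d = min_dist(new_ca2)
            if d < 3.0:
                continue
            if d <= 6.0 and complex_rmsd(new_ca2) > 10.0:
                return tf
            return None  # jumped past the contact band or near-native
        return None

    def random_contact_try() -> RigidTransform | None:
        R = Rotation.random(rng=rng).as_matrix()
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rotated = (ca2 - ca2.mean(0)) @ R.T
        for t in np.arange(0.0, scan_max, 0.5):
            new_ca2 = rotated + c1 + t * u
            d = min_dist(new_ca2)
            if d < 3.0:
                continue
            if d <= 6.0 and complex_rmsd(new_ca2) > 10.0:
                target = c1 + t * u
                return RigidTransform(R, target - R @ ca2.mean(0))
            return None
        return None

    transforms: list[tuple[str, RigidTransform]] = []
    width = len(str(max(n_models - 1, 1)))
    for i in range(n_models):
        label = f"decoy_{i:0{width}d}"
        if i < n_near:
            attempt = near_native_try
        elif (i - n_near) % 2 == 0:
            attempt = symmetric_try
        else:
            attempt = random_contact_try
        for _ in range(max_retries):
            tf = attempt()
            if tf is not None:
                transforms.append((label, tf))
                break
        else:
            raise GenerationError(f"could not place {label} within {max_retries} tries")
    return DecoyEnsemble(reference=reference, transforms=transforms, seed=seed)


def bootstrap_coverage(
    xl_set: SimulatedXLSet,
    fraction: float,
    n_replicates: int = 1000,
    seed: int = 0,
) -> list[SimulatedXLSet]:
    """Random partial-coverage subsets of a cross-link set.

    Each replicate keeps ``round(fraction * |set|)`` distinct pairs, sampled
    without replacement (coverage means distinct cross-links observed, so
    with-replacement duplicates would be meaningless).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    size = int(round(fraction * len(xl_set)))
    if size == 0:
        raise ValidationError(f"fraction {fraction} of {len(xl_set)} pairs is an empty subset")
    rng = np.random.default_rng(seed)
    out = []
    pairs = list(xl_set.pairs)
    for rep in range(n_replicates):
        chosen_idx = rng.choice(len(pairs), size=size, replace=False)
        chosen = tuple(sorted(pairs[int(k)] for k in chosen_idx))
        out.append(
            SimulatedXLSet(
                pairs=chosen,
                source=f"{xl_set.source}|cov{fraction:g}|rep{rep}",
                threshold=xl_set.threshold,
                true_labels={p: xl_set.true_labels[p] for p in chosen if p in xl_set.true_labels},
            )
        )
    return out
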