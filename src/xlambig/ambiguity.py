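"""Intra/inter-subunit ambiguity of lysine cross-links in homo-oligomers.

In a homo-oligomer the subunits are sequence-identical, so a cross-link
identified between residue numbers (r_i, r_j) cannot be attributed to a
pair of chains from the peptide evidence alone: it may bridge residues
within one subunit (intra) or across two subunits (inter). This module
enumerates the non-redundant residue-number pairs, computes the intra
alternative and every inter chain combination, and classifies each pair at
a distance threshold as Intra, Inter, Ambiguous or Non-accessible.

Redundant chain combinations are avoided by requiring at least one endpoint
in the first chain, and multiple inter alternatives are reduced to the
shortest one (both oriented readings are additionally retained for dimers,
where the scoring functions need them).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from . import sasd_engine
from .sasd_engine import NON_ACCESSIBLE, euclidean_distance, is_matched
from .structio import ResidueRef, Structure, ValidationError

__all__ = [
    "Assignment",
    "CrossLinkCandidate",
    "enumerate_candidates",
    "classify",
    "assignment_statistics",
    "symmetry_differences",
]

DEFAULT_THRESHOLD = 33.0  # Å, Cα–Cα reach of lysine-reactive linkers (DSS/BS3)


class Assignment(str, Enum):
    INTRA = "Intra"
    INTER = "Inter"
    AMBIGUOUS = "Ambiguous"
    NON_ACCESSIBLE = "Non-accessible"


@dataclass(frozen=True)
class CrossLinkCandidate:
    """An unordered residue-number pair with all its distance alternatives.

    ``intra`` is the within-chain distance (``math.inf`` when undefined:
    a self pair, or a buried/over-threshold endpoint under SASD).
    ``inter_ab``/``inter_ba`` are the two oriented readings in a dimer
    (res_i on chain 1 & res_j on chain 2, and vice versa); for higher
    oligomers they are the two orientations through the first chain and
    ``shortest_inter`` minimizes over every chain combination.
    """

    res_i: int
    res_j: int
    intra: float
    inter_ab: float
    inter_ba: float
    shortest_inter: float
    method: str

    @property
    def is_self_pair(self) -> bool:
        return self.res_i == self.res_j

    def symmetry_difference(self) -> float | None:
        """|inter_AB − inter_BA| when both oriented readings are finite."""
        if math.isfinite(self.inter_ab) and math.isfinite(self.inter_ba):
            return abs(self.inter_ab - self.inter_ba)
        return None


def _lysines_by_chain(structure: Structure) -> dict[str, dict[int, ResidueRef]]:
    by_chain: dict[str, dict[int, ResidueRef]] = {}
    from .structio import lysine_calpha

    for ref, _pos in lysine_calpha(structure):
        by_chain.setdefault(ref.chain_id, {})[ref.seqid] = ref
    return by_chain


def enumerate_candidates(
    structure: Structure,
    method: str = "EUC",
    grid: "sasd_engine.SolventGrid | None" = None,
    access_radius: float = 4.0,
    include_self_pairs: bool = True,
    path_limit: float = math.inf,
) -> list[CrossLinkCandidate]:
    """Non-redundant lysine-pair candidates with all chain-combination distances.

    Every unordered residue-number pair {r_i, r_j} with at least one endpoint
    in the first chain yields one candidate; self pairs (r_i = r_j) are
    inter-only. The structure must be a homo-oligomer whose chains carry an
    identical lysine residue-number set (use ``recreate_reference`` first).

    For ``method="SASD"`` a prebuilt :class:`SolventGrid` of the same
    structure may be passed to share Dijkstra sweeps across calls.
    """
    method = method.upper()
    if method not in ("EUC", "SASD"):
        raise ValidationError(f"unknown distance method {method!r}")
    if len(structure.chains) < 2:
        raise ValidationError("need at least 2 chains to enumerate inter alternatives")
    by_chain = _lysines_by_chain(structure)
    chain_ids = structure.chain_ids
    first = chain_ids[0]
    lys_sets = [frozenset(by_chain.get(cid, {})) for cid in chain_ids]
    if len(set(lys_sets)) > 1:
        raise ValidationError(
            "chains differ in lysine content; recreate the reference first"
        )
    resnums = sorted(lys_sets[0])
    if not resnums:
        return []

    # one distance lookup per (chain, resnum) pair of Cα endpoints
    refs = [by_chain[cid][num] for cid in chain_ids for num in resnums]
    index = {(r.chain_id, r.seqid): k for k, r in enumerate(refs)}
    if method == "EUC":
        import numpy as np

        pos = np.array([r.resolve_ca(structure) for r in refs])
        diff = pos[:, None, :] - pos[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=-1))
    else:
        if grid is None:
            grid = sasd_engine.build_grid(structure)
        # every candidate has a first-chain endpoint, so sweeps from the
        # first chain's lysines cover all required matrix entries
        dmat = sasd_engine.sasd_matrix(
            grid, refs, access_radius=access_radius, path_limit=path_limit,
            sources=list(range(len(resnums))),
        )

    def dist(chain_a: str, num_a: int, chain_b: str, num_b: int) -> float:
        return float(dmat[index[(chain_a, num_a)], index[(chain_b, num_b)]])

    out: list[CrossLinkCandidate] = []
    pairs = list(itertools.combinations(resnums, 2))
    if include_self_pairs:
        pairs += [(n, n) for n in resnums]
    for r_i, r_j in sorted(pairs):
        if r_i == r_j:
            intra = NON_ACCESSIBLE  # a residue cannot cross-link to itself
        else:
            intra = dist(first, r_i, first, r_j)
        alternatives = []
        for other in chain_ids[1:]:
            alternatives.append(dist(first, r_i, other, r_j))
            if r_i != r_j:
                alternatives.append(dist(first, r_j, other, r_i))
        inter_ab = dist(first, r_i, chain_ids[1], r_j)
        inter_ba = dist(first, r_j, chain_ids[1], r_i)
        shortest = min(alternatives)
        out.append(
            CrossLinkCandidate(
                res_i=r_i,
                res_j=r_j,
                intra=intra,
                inter_ab=inter_ab,
                inter_ba=inter_ba,
                shortest_inter=shortest,
                method=method,
            )
        )
    return out


def classify(
    candidate: CrossLinkCandidate, threshold: float = DEFAULT_THRESHOLD
) -> Assignment:
    """Four-way assignment of one candidate at a distance threshold.

    Intra/Inter if exactly one alternative is at or below the threshold,
    Ambiguous if both are, Non-accessible if neither (an infinite distance —
    buried endpoint, disconnected solvent or undefined intra — never counts
    as below threshold).
    """
    intra_ok = is_matched(candidate.intra, threshold)
    inter_ok = is_matched(candidate.shortest_inter, threshold)
    if intra_ok and inter_ok:
        return Assignment.AMBIGUOUS
    if intra_ok:
        return Assignment.INTRA
    if inter_ok:
        return Assignment.INTER
    return Assignment.NON_ACCESSIBLE


_LABELS = [a.value for a in Assignment]


def assignment_statistics(
    candidates_euc: list[CrossLinkCandidate],
    candidates_sasd: list[CrossLinkCandidate],
    thresholds: tuple[float, ...] = (33.0, 30.0, 27.0, 25.0),
    matched_filter: bool = False,
) -> dict:
    """Cross-tabulate assignments under straight-line vs surface distances.

    Both lists must cover the same residue pairs. With ``matched_filter``
    only pairs whose straight-line intra or inter alternative is matched at
    the first threshold, and whose intra and inter alternatives were both
    calculable under both methods, enter the table — the filter used when
    comparing redistribution of assignations between the two methods.

    Returns joint 4×4 fractions, per-method marginals, and straight-line
    marginals for each threshold in the sweep.
    """
    key = lambda c: (c.res_i, c.res_j)
    if [key(c) for c in candidates_euc] != [key(c) for c in candidates_sasd]:
        raise ValidationError("EUC and SASD candidate sets cover different pairs")
    t0 = thresholds[0]
    pairs = list(zip(candidates_euc, candidates_sasd))
    if matched_filter:
        pairs = [
            (ce, cs)
            for ce, cs in pairs
            if (is_matched(ce.intra, t0) or is_matched(ce.shortest_inter, t0))
            and not ce.is_self_pair
            and math.isfinite(cs.intra)
            and math.isfinite(cs.shortest_inter)
        ]
    rows = [
        {"euc": classify(ce, t0).value, "sasd": classify(cs, t0).value}
        for ce, cs in pairs
    ]
    df = pd.DataFrame(rows, columns=["euc", "sasd"])
    joint = pd.crosstab(df["euc"], df["sasd"], normalize=True if len(df) else False)
    joint = joint.reindex(index=_LABELS, columns=_LABELS, fill_value=0.0)
    sweep = {}
    for t in thresholds:
        counts = pd.Series(
            [classify(ce, t).value for ce, _ in pairs], dtype="object"
        ).value_counts(normalize=True)
        sweep[t] = counts.reindex(_LABELS, fill_value=0.0)
    return {
        "joint": joint,
        "euc_marginal": joint.sum(axis=1),
        "sasd_marginal": joint.sum(axis=0),
        "threshold_sweep_euc": sweep,
        "n_pairs": len(pairs),
    }


def symmetry_differences(candidates: list[CrossLinkCandidate]) -> list[float]:
    """|inter_AB − inter_BA| for every candidate with both readings finite.

    On an exact C2 dimer these vanish; on asymmetric models they measure
    how far the two oriented readings of each cross-link disagree.
    """
    out = []
    for c in candidates:
        d = c.symmetry_difference()
        if d is not None:
            out.append(d)
    return out
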