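"""The MNXL scoring-function family for homo-dimer model ranking.

A cross-link restraint rewards a model when the linked residues are close
enough for the reagent and penalizes it otherwise. The base score for one
distance d is

    MNXL(d) = N(d; mu=18.62, sigma^2=35.94)   if d <= 33 Å (matched)
            = -0.1                            otherwise (non-accessible)

i.e. the Gaussian density fitted to experimentally observed cross-link
distances when the restraint is satisfiable, and a flat penalty when the
distance exceeds the linker reach or an endpoint is buried. A model's
total score is the sum of its inter-subunit cross-link contributions.

In a homo-dimer each cross-link has an intra-subunit alternative and two
oriented inter-subunit readings (chain A→B and B→A). The scoring variants
differ along four independent axes applied in a fixed order:

inclusion — when are the inter readings considered at all?
    ALL: always. ONLY_BEST: only if the better inter MNXL score is at
    least the intra score (ties kept, so the gated-in sets nest
    NON_INTRA ⊆ ONLY_BEST ⊆ ALL). NON_INTRA: only if the intra
    alternative is non-accessible.
symmetry — a gate on the oriented pair:
    NONE; SYMMETRY_MATCHED: both inter readings must be matched;
    SYMMETRY_DIFFERENCE: at least one matched and the two distances differ
    by less than 5 Å.
ambiguity — how penalties interact with the intra alternative:
    OBLIVIOUS: the raw MNXL score regardless of the intra alternative;
    NORMAL: a non-accessible inter reading whose intra alternative is
    matched scores the neutral 0.0 instead of the penalty.
orientation — how the two readings aggregate:
    ORIENTED: both scored separately and summed;
    STRINGENT: only the reading with the higher score counts.

Ambiguity substitution happens per reading before the orientation
aggregate, so STRINGENT maximizes over the already-substituted scores. A
cross-link gated out by inclusion or symmetry contributes exactly 0.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import sasd_engine
from .ambiguity import CrossLinkCandidate
from .sasd_engine import NON_ACCESSIBLE, is_matched
from .structio import Structure, ValidationError

__all__ = [
    "MNXLParams",
    "AmbiguityMode",
    "OrientationMode",
    "InclusionOption",
    "SymmetryMode",
    "ScoringConfig",
    "ModelScore",
    "PRESETS",
    "mnxl",
    "crosslink_contribution",
    "model_candidates",
    "score_model",
    "rank_models",
]


@dataclass(frozen=True)
class MNXLParams:
    """Numeric constants of the MNXL family.

    mean/variance of the matched-distance Gaussian come from an empirical
    cross-link distance database; the threshold is the Cα–Cα reach of
    lysine-reactive linkers such as DSS/BS3.
    """

    mean: float = 18.62  # Å
    variance: float = 35.94  # Å^2
    threshold: float = 33.0  # Å
    penalty: float = -0.1
    neutral: float = 0.0
    symmetry_difference_cutoff: float = 5.0  # Å

    def __post_init__(self):
        if self.variance <= 0 or self.threshold <= 0:
            raise ValidationError("variance and threshold must be positive")
        if not (self.penalty < 0 <= self.neutral):
            raise ValidationError("penalty must be negative, neutral nonnegative")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance)


class AmbiguityMode(str, Enum):
    OBLIVIOUS = "oblivious"
    NORMAL = "normal"


class OrientationMode(str, Enum):
    ORIENTED = "oriented"
    STRINGENT = "stringent"


class InclusionOption(str, Enum):
    ALL = "all"
    ONLY_BEST = "only-best"
    NON_INTRA = "non-intra"


class SymmetryMode(str, Enum):
    NONE = "none"
    SYMMETRY_MATCHED = "symmetry-matched"
    SYMMETRY_DIFFERENCE = "symmetry-difference"


@dataclass(frozen=True)
class ScoringConfig:
    method: str = "SASD"  # distance method: "EUC" or "SASD"
    ambiguity: AmbiguityMode = AmbiguityMode.NORMAL
    orientation: OrientationMode = OrientationMode.ORIENTED
    inclusion: InclusionOption = InclusionOption.ALL
    symmetry: SymmetryMode = SymmetryMode.NONE
    params: MNXLParams = field(default_factory=MNXLParams)

    @property
    def label(self) -> str:
        parts = [self.method.lower(), self.ambiguity.value, self.orientation.value,
                 self.inclusion.value]
        if self.symmetry is not SymmetryMode.NONE:
            parts.append(self.symmetry.value)
        return "-".join(parts)

    def with_method(self, method: str) -> "ScoringConfig":
        return replace(self, method=method.upper())

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScoringConfig":
        """Build a config from key-value pairs (e.g. a parsed config file).

        Recognized keys: method, ambiguity, orientation, inclusion,
        symmetry, and the numeric MNXL constants (mean, variance,
        threshold, penalty, neutral, symmetry_difference_cutoff).
        """
        m = {str(k).strip().lower(): str(v).strip() for k, v in mapping.items()}
        param_keys = (
            "mean", "variance", "threshold", "penalty", "neutral",
            "symmetry_difference_cutoff",
        )
        params = MNXLParams(
            **{k: float(m[k]) for k in param_keys if k in m}
        )
        kwargs = {"params": params}
        if "method" in m:
            kwargs["method"] = m["method"].upper()
        for key, enum in (
            ("ambiguity", AmbiguityMode),
            ("orientation", OrientationMode),
            ("inclusion", InclusionOption),
            ("symmetry", SymmetryMode),
        ):
            if key in m:
                kwargs[key] = enum(m[key].lower())
        unknown = set(m) - set(param_keys) - {"method", "ambiguity", "orientation",
                                              "inclusion", "symmetry"}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ScoringConfig":
        """Read a simple `key = value` config file (# comments allowed)."""
        mapping = {}
        for line in open(path):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            mapping[key] = value
        return cls.from_mapping(mapping)


#: Named scoring functions. The symmetry variants build on normal-oriented.
PRESETS: dict[str, ScoringConfig] = {
    "oblivious-oriented": ScoringConfig(
        ambiguity=AmbiguityMode.OBLIVIOUS, orientation=OrientationMode.ORIENTED
    ),
    "oblivious-stringent": ScoringConfig(
        ambiguity=AmbiguityMode.OBLIVIOUS, orientation=OrientationMode.STRINGENT
    ),
    "normal-oriented": ScoringConfig(
        ambiguity=AmbiguityMode.NORMAL, orientation=OrientationMode.ORIENTED
    ),
    "normal-stringent": ScoringConfig(
        ambiguity=AmbiguityMode.NORMAL, orientation=OrientationMode.STRINGENT
    ),
    "normal-oriented-only-best": ScoringConfig(
        orientation=OrientationMode.ORIENTED, inclusion=InclusionOption.ONLY_BEST
    ),
    "normal-oriented-non-intra": ScoringConfig(
        orientation=OrientationMode.ORIENTED, inclusion=InclusionOption.NON_INTRA
    ),
    "normal-stringent-only-best": ScoringConfig(
        orientation=OrientationMode.STRINGENT, inclusion=InclusionOption.ONLY_BEST
    ),
    "normal-stringent-non-intra": ScoringConfig(
        orientation=OrientationMode.STRINGENT, inclusion=InclusionOption.NON_INTRA
    ),
    "symmetry-matched": ScoringConfig(symmetry=SymmetryMode.SYMMETRY_MATCHED),
    "symmetry-difference": ScoringConfig(symmetry=SymmetryMode.SYMMETRY_DIFFERENCE),
}


def mnxl(distance: float, params: MNXLParams = MNXLParams()) -> float:
    """Base score of one distance: Gaussian density if matched, else penalty.

    ``math.inf`` (the non-accessible marker) takes the penalty branch.
    """
    if math.isfinite(distance) and distance < 0:
        raise ValidationError("distance must be nonnegative")
    if is_matched(distance, params.threshold):
        z = (distance - params.mean) / params.sigma
        return math.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2.0 * math.pi))
    return params.penalty


@dataclass(frozen=True)
class ContributionAudit:
    """How one cross-link's contribution was composed."""

    included: bool
    gate: str  # "included", or which gate excluded it
    score_ab: float
    score_ba: float
    contribution: float


def crosslink_contribution(
    candidate: CrossLinkCandidate, config: ScoringConfig
) -> ContributionAudit:
    """Contribution of one cross-link to a model's total inter-subunit score.

    Axes apply in order inclusion → symmetry → (ambiguity per reading) →
    orientation aggregate; a gated-out cross-link contributes exactly 0.0.
    """
    p = config.params
    raw_ab = mnxl(candidate.inter_ab, p)
    raw_ba = mnxl(candidate.inter_ba, p)
    intra_raw = mnxl(candidate.intra, p)
    intra_matched = is_matched(candidate.intra, p.threshold)

    # (1) inclusion gate: are the inter readings considered at all?
    # ONLY_BEST keeps ties (which arise only between identical penalty
    # constants) so that its gated-in set nests between NON_INTRA and ALL.
    if config.inclusion is InclusionOption.ONLY_BEST:
        if max(raw_ab, raw_ba) < intra_raw:
            return ContributionAudit(False, "inclusion:only-best", raw_ab, raw_ba, p.neutral)
    elif config.inclusion is InclusionOption.NON_INTRA:
        if intra_matched:
            return ContributionAudit(False, "inclusion:non-intra", raw_ab, raw_ba, p.neutral)

    # (2) symmetry gate on the oriented pair
    if config.symmetry is SymmetryMode.SYMMETRY_MATCHED:
        if not (
            is_matched(candidate.inter_ab, p.threshold)
            and is_matched(candidate.inter_ba, p.threshold)
        ):
            return ContributionAudit(False, "symmetry:matched", raw_ab, raw_ba, p.neutral)
    elif config.symmetry is SymmetryMode.SYMMETRY_DIFFERENCE:
        any_matched = is_matched(candidate.inter_ab, p.threshold) or is_matched(
            candidate.inter_ba, p.threshold
        )
        diff = candidate.symmetry_difference()
        if not any_matched or diff is None or diff >= p.symmetry_difference_cutoff:
            return ContributionAudit(False, "symmetry:difference", raw_ab, raw_ba, p.neutral)

    # (3) ambiguity substitution per oriented reading
    def substituted(raw: float) -> float:
        if (
            config.ambiguity is AmbiguityMode.NORMAL
            and raw == p.penalty
            and intra_matched
        ):
            return p.neutral
        return raw

    s_ab, s_ba = substituted(raw_ab), substituted(raw_ba)

    # (4) orientation aggregate
    if config.orientation is OrientationMode.ORIENTED:
        total = s_ab + s_ba
    else:
        total = max(s_ab, s_ba)
    return ContributionAudit(True, "included", s_ab, s_ba, total)


@dataclass
class ModelScore:
    model_id: str
    total: float
    breakdown: dict[tuple[int, int], ContributionAudit]


def model_candidates(
    xl_pairs: list[tuple[int, int]],
    model: Structure,
    method: str = "SASD",
    grid: "sasd_engine.SolventGrid | None" = None,
    access_radius: float = 4.0,
    path_limit: float = math.inf,
) -> list[CrossLinkCandidate]:
    """Evaluate a cross-link list's distance alternatives on one model.

    Residue numbers in ``xl_pairs`` are chain-ambiguous (as in real
    homo-oligomer XL-MS data); every intra and oriented inter alternative
    is computed on the model with the requested distance method.
    """
    from .ambiguity import enumerate_candidates

    wanted = {tuple(sorted(p)) for p in xl_pairs}
    cands = enumerate_candidates(
        model, method=method, grid=grid, access_radius=access_radius,
        path_limit=path_limit,
    )
    by_pair = {(c.res_i, c.res_j): c for c in cands}
    missing = wanted - set(by_pair)
    if missing:
        raise ValidationError(f"cross-links reference residues absent from model: {sorted(missing)}")
    return [by_pair[p] for p in sorted(wanted)]


def score_model(
    xl_pairs: list[tuple[int, int]],
    model: Structure,
    config: ScoringConfig,
    candidates: list[CrossLinkCandidate] | None = None,
) -> ModelScore:
    """Total inter-subunit MNXL score of one model under one configuration.

    Precomputed ``candidates`` (from :func:`model_candidates` with the same
    distance method) may be passed so several configurations can be scored
    from one set of distance calculations.
    """
    if not xl_pairs:
        raise ValidationError("cross-link set is empty")
    if candidates is None:
        candidates = model_candidates(xl_pairs, model, method=config.method)
    breakdown = {}
    total = 0.0
    for cand in candidates:
        audit = crosslink_contribution(cand, config)
        breakdown[(cand.res_i, cand.res_j)] = audit
        total += audit.contribution
    return ModelScore(model.name, total, breakdown)


def rank_models(model_scores: list[ModelScore]) -> list[ModelScore]:
    """Rank by descending total score; ties broken by ascending model id."""
    if not model_scores:
        raise ValidationError("no model scores to rank")
    return sorted(model_scores, key=lambda s: (-s.total, s.model_id))
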