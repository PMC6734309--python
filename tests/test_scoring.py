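"""MNXL base score and the scoring-function family.

The four-axis composition (inclusion, symmetry, ambiguity, orientation) is
checked exhaustively against an independent rule-application oracle written
directly from the variant definitions.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from xlambig import (
    NON_ACCESSIBLE,
    AmbiguityMode,
    InclusionOption,
    MNXLParams,
    OrientationMode,
    ScoringConfig,
    SymmetryMode,
    ValidationError,
    crosslink_contribution,
    mnxl,
    rank_models,
    score_model,
)
from xlambig.ambiguity import CrossLinkCandidate
from xlambig.scoring import PRESETS, ModelScore

P = MNXLParams()
SIGMA = math.sqrt(P.variance)


def cand(intra, ab, ba):
    return CrossLinkCandidate(
        res_i=1, res_j=2, intra=intra, inter_ab=ab, inter_ba=ba,
        shortest_inter=min(ab, ba), method="EUC",
    )


# ---------------------------------------------------------------------------
# independent oracle: literal transcription of the variant rules

def oracle_contribution(intra, ab, ba, config):
    p = config.params

    def base(d):
        if d <= p.threshold and math.isfinite(d):
            return norm.pdf(d, p.mean, math.sqrt(p.variance))
        return p.penalty

    matched = lambda d: math.isfinite(d) and d <= p.threshold
    s_intra, s_ab, s_ba = base(intra), base(ab), base(ba)

    if config.inclusion is InclusionOption.ONLY_BEST and max(s_ab, s_ba) < s_intra:
        return 0.0
    if config.inclusion is InclusionOption.NON_INTRA and matched(intra):
        return 0.0
    if config.symmetry is SymmetryMode.SYMMETRY_MATCHED:
        if not (matched(ab) and matched(ba)):
            return 0.0
    if config.symmetry is SymmetryMode.SYMMETRY_DIFFERENCE:
        if not (matched(ab) or matched(ba)):
            return 0.0
        if not (math.isfinite(ab) and math.isfinite(ba)):
            return 0.0
        if abs(ab - ba) >= p.symmetry_difference_cutoff:
            return 0.0
    if config.ambiguity is AmbiguityMode.NORMAL and matched(intra):
        s_ab = 0.0 if s_ab == p.penalty else s_ab
        s_ba = 0.0 if s_ba == p.penalty else s_ba
    if config.orientation is OrientationMode.ORIENTED:
        return s_ab + s_ba
    return max(s_ab, s_ba)


SCENARIOS = [
    # (intra, inter_ab, inter_ba) canonical distance scenarios
    (20.0, 19.0, 21.0),            # everything matched, near-symmetric
    (20.0, 40.0, 41.0),            # intra matched, both inter penalized
    (NON_ACCESSIBLE, 19.0, 30.0),  # intra buried, asymmetric matched inter
    (20.0, 25.0, 45.0),            # one inter matched, one penalized
    (45.0, 19.0, 21.0),            # intra over threshold
    (NON_ACCESSIBLE, NON_ACCESSIBLE, NON_ACCESSIBLE),  # nothing reachable
]

ALL_CONFIGS = [
    ScoringConfig(ambiguity=a, orientation=o, inclusion=i, symmetry=s)
    for a in AmbiguityMode
    for o in OrientationMode
    for i in InclusionOption
    for s in SymmetryMode
]


class TestMnxl:
    def test_penalty_beyond_threshold(self):
        assert mnxl(40.0) == -0.1

    def test_non_accessible_penalty(self):
        assert mnxl(NON_ACCESSIBLE) == -0.1

    def test_density_at_mode(self):
        assert mnxl(18.62) == pytest.approx(norm.pdf(18.62, 18.62, SIGMA), abs=1e-12)
        assert mnxl(18.62) == pytest.approx(0.0665459, abs=1e-6)

    def test_density_at_threshold_boundary(self):
        assert mnxl(33.0) == pytest.approx(norm.pdf(33.0, 18.62, SIGMA), abs=1e-12)
        assert mnxl(33.0) == pytest.approx(0.0037475, abs=1e-6)
        assert mnxl(33.0 + 1e-9) == -0.1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            mnxl(-1.0)

    def test_unimodal_on_matched_range(self):
        xs = np.linspace(0, 33, 500)
        ys = [mnxl(float(x)) for x in xs]
        peak = int(np.argmax(ys))
        assert xs[peak] == pytest.approx(18.62, abs=0.1)
        assert all(y > 0 for y in ys)
        # increasing up to the mode, decreasing after
        assert all(a <= b for a, b in zip(ys[: peak + 1], ys[1 : peak + 1]))
        assert all(a >= b for a, b in zip(ys[peak:], ys[peak + 1 :]))


class TestContribution:
    def test_normal_substitutes_neutral(self):
        c = cand(20.0, 40.0, 41.0)
        audit = crosslink_contribution(c, PRESETS["normal-oriented"])
        assert audit.contribution == 0.0

    def test_oblivious_double_penalty(self):
        c = cand(20.0, 40.0, 41.0)
        audit = crosslink_contribution(c, PRESETS["oblivious-oriented"])
        assert audit.contribution == pytest.approx(-0.2)

    def test_non_intra_excludes_matched_intra(self):
        c = cand(20.0, 25.0, 25.0)
        config = ScoringConfig(inclusion=InclusionOption.NON_INTRA)
        audit = crosslink_contribution(c, config)
        assert not audit.included and audit.contribution == 0.0

    def test_symmetry_difference_excludes_asymmetric(self):
        c = cand(NON_ACCESSIBLE, 19.0, 30.0)  # diff 11 >= 5
        config = ScoringConfig(symmetry=SymmetryMode.SYMMETRY_DIFFERENCE)
        audit = crosslink_contribution(c, config)
        assert not audit.included and audit.contribution == 0.0

    def test_symmetry_difference_includes_symmetric(self):
        c = cand(NON_ACCESSIBLE, 19.0, 21.0)
        config = ScoringConfig(symmetry=SymmetryMode.SYMMETRY_DIFFERENCE)
        audit = crosslink_contribution(c, config)
        assert audit.included
        assert audit.contribution == pytest.approx(mnxl(19.0) + mnxl(21.0))

    @pytest.mark.parametrize("config", ALL_CONFIGS, ids=lambda c: c.label)
    def test_full_truth_table_against_oracle(self, config):
        for intra, ab, ba in SCENARIOS:
            got = crosslink_contribution(cand(intra, ab, ba), config).contribution
            want = oracle_contribution(intra, ab, ba, config)
            assert got == pytest.approx(want, abs=1e-12), (intra, ab, ba)

    def test_random_scenarios_against_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            vals = []
            for _ in range(3):
                if rng.random() < 0.15:
                    vals.append(NON_ACCESSIBLE)
                else:
                    vals.append(float(rng.uniform(0, 60)))
            intra, ab, ba = vals
            for config in ALL_CONFIGS:
                got = crosslink_contribution(cand(intra, ab, ba), config).contribution
                want = oracle_contribution(intra, ab, ba, config)
                assert got == pytest.approx(want, abs=1e-12)

    def test_normal_never_below_oblivious(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            intra = NON_ACCESSIBLE if rng.random() < 0.2 else float(rng.uniform(0, 60))
            ab, ba = (float(rng.uniform(0, 60)) for _ in range(2))
            for o, i, s in itertools.product(OrientationMode, InclusionOption, SymmetryMode):
                normal = crosslink_contribution(
                    cand(intra, ab, ba),
                    ScoringConfig(ambiguity=AmbiguityMode.NORMAL, orientation=o,
                                  inclusion=i, symmetry=s),
                ).contribution
                oblivious = crosslink_contribution(
                    cand(intra, ab, ba),
                    ScoringConfig(ambiguity=AmbiguityMode.OBLIVIOUS, orientation=o,
                                  inclusion=i, symmetry=s),
                ).contribution
                assert normal >= oblivious - 1e-12

    def test_inclusion_nesting(self):
        """Gated-in sets: NON_INTRA ⊆ ONLY_BEST ⊆ ALL."""
        rng = np.random.default_rng(44)
        for _ in range(100):
            intra = NON_ACCESSIBLE if rng.random() < 0.3 else float(rng.uniform(0, 60))
            ab, ba = (float(rng.uniform(0, 60)) for _ in range(2))
            included = {}
            for inc in InclusionOption:
                audit = crosslink_contribution(
                    cand(intra, ab, ba), ScoringConfig(inclusion=inc)
                )
                included[inc] = audit.included
            if included[InclusionOption.NON_INTRA]:
                assert included[InclusionOption.ONLY_BEST]
            if included[InclusionOption.ONLY_BEST]:
                assert included[InclusionOption.ALL]

    def test_symmetry_matched_subset_of_any_matched(self):
        rng = np.random.default_rng(45)
        for _ in range(200):
            intra = float(rng.uniform(0, 60))
            ab, ba = (float(rng.uniform(0, 60)) for _ in range(2))
            both = crosslink_contribution(
                cand(intra, ab, ba),
                ScoringConfig(symmetry=SymmetryMode.SYMMETRY_MATCHED),
            ).included
            if both:
                assert ab <= P.threshold or ba <= P.threshold


class TestScoreModel:
    def test_reference_scored_on_own_crosslinks_no_penalties(self, reference):
        from xlambig import simulate_crosslinks

        xls = simulate_crosslinks(reference)
        score = score_model(list(xls.pairs), reference, PRESETS["normal-oriented"])
        for audit in score.breakdown.values():
            if audit.included:
                assert audit.score_ab >= 0.0 and audit.score_ba >= 0.0

    def test_total_is_sum_of_breakdown(self, reference):
        from xlambig import simulate_crosslinks

        xls = simulate_crosslinks(reference)
        score = score_model(list(xls.pairs), reference, PRESETS["oblivious-oriented"])
        assert score.total == pytest.approx(
            sum(a.contribution for a in score.breakdown.values()), abs=1e-12
        )

    def test_reorder_invariance(self, reference):
        from xlambig import simulate_crosslinks

        xls = list(simulate_crosslinks(reference).pairs)
        a = score_model(xls, reference, PRESETS["normal-oriented"]).total
        b = score_model(list(reversed(xls)), reference, PRESETS["normal-oriented"]).total
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_residue_rejected(self, reference):
        with pytest.raises(ValidationError):
            score_model([(999, 1000)], reference, PRESETS["normal-oriented"])


class TestRanking:
    def test_descending_order(self):
        scores = [ModelScore("a", 0.2, {}), ModelScore("b", 0.5, {}), ModelScore("c", -0.1, {})]
        assert [s.model_id for s in rank_models(scores)] == ["b", "a", "c"]

    def test_tie_broken_by_id(self):
        scores = [ModelScore(i, 1.0, {}) for i in ["m3", "m1", "m2"]]
        assert [s.model_id for s in rank_models(scores)] == ["m1", "m2", "m3"]

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(9)
        scores = [ModelScore(f"m{i:03d}", float(rng.normal()), {}) for i in range(50)]
        ranked = rank_models(scores)
        oracle = sorted(scores, key=lambda s: (-s.total, s.model_id))
        assert [s.model_id for s in ranked] == [s.model_id for s in oracle]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rank_models([])


class TestConfigFile:
    def test_from_mapping_round_trip(self):
        config = ScoringConfig.from_mapping(
            {"method": "euc", "ambiguity": "oblivious", "orientation": "stringent",
             "inclusion": "only-best", "symmetry": "symmetry-difference",
             "threshold": "30.0", "penalty": "-0.2"}
        )
        assert config.method == "EUC"
        assert config.ambiguity is AmbiguityMode.OBLIVIOUS
        assert config.orientation is OrientationMode.STRINGENT
        assert config.inclusion is InclusionOption.ONLY_BEST
        assert config.symmetry is SymmetryMode.SYMMETRY_DIFFERENCE
        assert config.params.threshold == 30.0 and config.params.penalty == -0.2

    def test_from_file_with_comments(self, tmp_path):
        path = tmp_path / "score.cfg"
        path.write_text("# variant\nambiguity = normal\nmethod = sasd\nmean = 20.0\n")
        config = ScoringConfig.from_file(path)
        assert config.method == "SASD" and config.params.mean == 20.0

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig.from_mapping({"bogus": "1"})
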