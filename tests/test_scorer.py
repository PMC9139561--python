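"""Rubric arithmetic, hospital-level aggregation, and cohort tallies."""

import itertools

import pytest

from cnvnomen import CMT1_REFERENCE, DGS_REFERENCE, canonical, parse
from cnvnomen.model import (
    MinorError,
    NOT_APPLICABLE,
    ParsedNomenclature,
    RubricConfig,
    Submission,
)
from cnvnomen.scorer import DEFAULT_CONFIG, score_cohort, score_hospital, score_single

# Hand-tabulated breakdown matrix for every survey row, built from the
# published per-item columns: (a, b, c, d, e, f, g, h, i, j, total);
# None marks deductions that were not assessed (prose-only row).
NA = NOT_APPLICABLE
TABLE3_ROWS = {
    "Hospital 1": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
    "Hospital 2": (5, 5, 0, 0, 1, 0, 0, 1, 0, 1, 7),
    "Hospital 3": (0, 0, NA, NA, NA, NA, NA, NA, NA, NA, 0),
    "Hospital 4": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
    "Hospital 5": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 6": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 7": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 8": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
    "Hospital 9": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
    "Hospital 10": (5, 5, 1, 1, 1, 0, 0, 0, 0, 1, 6),
    "Hospital 11": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 12": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 15": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 16": (5, 5, 0, 0, 0, 0, 0, 0, 0, 0, 10),
    "Hospital 17": (5, 5, 0, 0, 1, 0, 0, 0, 0, 1, 8),
    "Hospital 18": (5, 5, 1, 0, 0, 0, 0, 0, 0, 1, 8),
    "Hospital 20": (5, 5, 0, 0, 1, 0, 0, 1, 0, 1, 7),
    "Hospital 21": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
    "Hospital 22": (5, 5, 0, 0, 0, 0, 0, 0, 0, 1, 9),
}
ITEMS = ("a", "b", "c", "d", "e", "f", "g", "h", "i", "j", "total")


def _hospital_breakdown(sub, refs, config=DEFAULT_CONFIG):
    return score_hospital(parse(sub.text_dgs), parse(sub.text_cmt1), refs=refs, config=config)


class TestSurveyReproduction:
    def test_every_hospital_row_reproduced(self, table3):
        submissions, refs = table3
        for sub in submissions:
            br = _hospital_breakdown(sub, refs)
            got = tuple(getattr(br, item) for item in ITEMS)
            assert got == TABLE3_ROWS[sub.hospital_id], sub.hospital_id

    def test_perfect_and_zero_rows(self, table3):
        submissions, refs = table3
        by_id = {s.hospital_id: s for s in submissions}
        assert _hospital_breakdown(by_id["Hospital 16"], refs).total == 10
        assert _hospital_breakdown(by_id["Hospital 3"], refs).total == 0

    def test_cohort_tally_and_percentages(self, table3):
        submissions, refs = table3
        res = score_cohort(submissions, refs)
        assert res.tally == {"c": 2, "d": 1, "e": 10, "f": 0, "g": 0, "h": 2, "i": 0, "j": 17}
        assert res.not_following == {"a": 1, "b": 1}
        assert res.tally_percent["e"] == 52.63
        assert res.tally_percent["j"] == 89.47
        assert res.tally_percent["c"] == 10.52
        assert res.tally_percent["d"] == 5.26


class TestAggregationRules:
    def test_awards_require_both_strings(self, refs):
        good = parse(canonical(DGS_REFERENCE))
        prose = parse("There may be a duplication somewhere")
        br = score_hospital(good, prose, refs=refs)
        assert br.a == 0 and br.b == 0 and br.total == 0

    def test_deduction_fires_from_either_string(self, refs):
        # band too coarse on the deletion string only -> j still fires
        dgs = parse("seq[GRCh37]del(22)(q11.2)\nchr22:g.19009792_21452445del")
        cmt = parse(canonical(CMT1_REFERENCE))
        br = score_hospital(dgs, cmt, refs=refs)
        assert br.j == 1
        assert MinorError.BAND_LESS_SPECIFIC in br.fired_minor_errors
        assert br.total == 9

    def test_two_canonical_strings_score_ten(self, refs):
        br = score_hospital(
            parse(canonical(DGS_REFERENCE)), parse(canonical(CMT1_REFERENCE)), refs=refs
        )
        assert br.total == 10
        assert br.fired_minor_errors == frozenset()

    def test_empty_cohort_rejected(self, refs):
        with pytest.raises(ValueError):
            score_cohort([], refs)

    def test_cohort_of_one_perfect_pair(self, refs):
        sub = Submission(
            hospital_id="H",
            text_dgs=canonical(DGS_REFERENCE),
            text_cmt1=canonical(CMT1_REFERENCE),
        )
        res = score_cohort([sub], refs)
        assert res.totals == [10]
        assert all(count == 0 for count in res.tally.values())


def _vector_parsed(iscn, span, seq, build, gpfx, chrom, band, kw, n_minors):
    """Construct a feature set realizing one abstract rubric vector."""
    p = ParsedNomenclature()
    p.iscn_portion_present = iscn
    p.coordinate_span = (19009792, 21452445, "underscore") if span else None
    p.seq_symbol_present = seq
    p.build_tokens = [("GRCh37", "square")] if build else []
    p.g_prefix_present = gpfx
    p.iscn_chromosome = "22" if chrom else None
    p.iscn_arm_band = ("q", "11.21") if band else None
    p.iscn_variant_keyword = "del" if kw else None
    pool = (MinorError.HYPHEN_RANGE_SEPARATOR, MinorError.HASH_SEPARATOR)
    p.minor_error_flags = set(pool[:n_minors])
    return p


def _oracle(iscn, span, seq, build, gpfx, chrom, band, kw, n_minors):
    """Literal rubric arithmetic, independent of the scorer implementation."""
    a = 5 if iscn else 0
    b = 5 if span else 0
    if a == 0 and b == 0:
        return 0, None
    deductions = [
        not seq,
        not build,
        not gpfx,
        not chrom,
        not band,
        not kw,
        gpfx and not span,  # HGVS attempted but span missing
        n_minors > 0,
    ]
    total = max(0, a + b - sum(deductions))
    return total, sum(deductions)


ALL_VECTORS = list(itertools.product([False, True], repeat=8))


class TestRubricArithmetic:
    @pytest.mark.parametrize("n_minors", [0, 1, 2])
    def test_scorer_equals_bruteforce_oracle_on_all_vectors(self, n_minors):
        for vec in ALL_VECTORS:
            p = _vector_parsed(*vec, n_minors)
            br = score_single(p)
            total, _ = _oracle(*vec, n_minors)
            assert br.total == total, (vec, n_minors)
            if not vec[0] and not vec[1]:
                assert br.c is NOT_APPLICABLE and br.j is NOT_APPLICABLE

    def test_totals_bounded_and_awards_valid(self):
        for vec in ALL_VECTORS:
            br = score_single(_vector_parsed(*vec, 1))
            assert 0 <= br.total <= 10
            assert br.a in (0, 5) and br.b in (0, 5)

    def test_adding_a_deduction_never_raises_total(self):
        # flipping any single award-positive feature to its failing state
        # can only lower (or preserve) the total
        for vec in ALL_VECTORS:
            base = score_single(_vector_parsed(*vec, 0)).total
            for k in range(2, 8):  # c..h features
                worse = list(vec)
                if not worse[k]:
                    continue
                worse[k] = False
                assert score_single(_vector_parsed(*worse, 0)).total <= base

    def test_minor_error_cap_single_point(self):
        one = score_single(_vector_parsed(*([True] * 8), 1))
        two = score_single(_vector_parsed(*([True] * 8), 2))
        assert one.j == two.j == 1
        assert one.total == two.total == 9

    def test_clamp_floor_configurable(self):
        # a=0/b=5 with every deduction firing would go negative unclamped
        p = _vector_parsed(False, True, False, False, False, False, False, False, 2)
        assert score_single(p).total == 0
        unclamped = RubricConfig(clamp_floor=-10)
        assert score_single(p, config=unclamped).total < 0
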