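"""Ground-truth recovery for the error-injection generator."""

import itertools

import pytest

from cnvnomen import CMT1_REFERENCE, DGS_REFERENCE, ErrorProfile, canonical, parse
from cnvnomen.model import InconsistentFlagsError
from cnvnomen.scorer import score_hospital, score_single
from cnvnomen.synthetic import (
    FLAGS,
    MINOR_FLAGS,
    STRUCTURAL_FLAGS,
    check_flags,
    make_cohort,
    make_submission,
    make_survey_counts,
)

BOTH_REFS = (DGS_REFERENCE, CMT1_REFERENCE)


class TestSingleFlagRecovery:
    def test_empty_flag_set_is_canonical(self):
        for ref in BOTH_REFS:
            text, expected = make_submission(ref, ErrorProfile([]))
            assert text == canonical(ref)
            assert expected.total == 10

    @pytest.mark.parametrize("flag", FLAGS)
    @pytest.mark.parametrize("ref", BOTH_REFS, ids=lambda r: r.name)
    def test_every_single_injection_recovered_exactly(self, flag, ref):
        """scorer(parse(text)) must equal the generator's expected breakdown."""
        text, expected = make_submission(ref, ErrorProfile([flag]))
        got = score_single(parse(text), ref)
        assert got == expected, (flag, text)

    def test_dropping_g_prefix_costs_one_point(self):
        text, expected = make_submission(DGS_REFERENCE, ErrorProfile(["drop-g-prefix"]))
        assert expected.e == 1 and expected.total == 9
        assert score_single(parse(text), DGS_REFERENCE).total == 9

    def test_two_minor_errors_capped_at_one_point(self):
        profile = ErrorProfile(["hyphen-range-separator", "swap-build-hg19"])
        text, expected = make_submission(DGS_REFERENCE, profile)
        assert expected.j == 1 and expected.total == 9
        assert score_single(parse(text), DGS_REFERENCE) == expected

    def test_losing_both_portions_scores_zero_not_applicable(self):
        profile = ErrorProfile(["drop-iscn-portion", "drop-coordinates"])
        text, expected = make_submission(DGS_REFERENCE, profile)
        assert expected.total == 0 and expected.c is None
        assert score_single(parse(text), DGS_REFERENCE) == expected


class TestMultiFlagRecovery:
    def test_all_consistent_flag_pairs_recovered(self):
        for combo in itertools.combinations(FLAGS, 2):
            try:
                check_flags(combo)
            except InconsistentFlagsError:
                continue
            for ref in BOTH_REFS:
                text, expected = make_submission(ref, ErrorProfile(combo))
                assert score_single(parse(text), ref) == expected, (combo, text)

    def test_any_minor_multiset_keeps_j_at_one(self):
        compatible = [f for f in MINOR_FLAGS if f not in ("misspell-build",)]
        for r in (2, 3, 4):
            for combo in itertools.combinations(compatible, r):
                try:
                    check_flags(combo)
                except InconsistentFlagsError:
                    continue
                _, expected = make_submission(DGS_REFERENCE, ErrorProfile(combo))
                assert expected.j == 1 and expected.total == 9

    def test_structural_flags_only_lower_totals(self):
        baseline = make_submission(DGS_REFERENCE, ErrorProfile([]))[1].total
        for flag in STRUCTURAL_FLAGS:
            assert make_submission(DGS_REFERENCE, ErrorProfile([flag]))[1].total < baseline


class TestFlagConsistency:
    @pytest.mark.parametrize(
        "bad_combo",
        [
            ("drop-coordinates", "hyphen-range-separator"),
            ("drop-coordinates", "collapse-span-single-position"),
            ("drop-build", "swap-build-hg19"),
            ("drop-variant-keyword", "variant-type-mismatch"),
            ("drop-arm-band", "band-less-specific"),
        ],
    )
    def test_contradictory_sets_rejected(self, bad_combo):
        with pytest.raises(InconsistentFlagsError):
            make_submission(DGS_REFERENCE, ErrorProfile(bad_combo))

    def test_unknown_flag_rejected(self):
        with pytest.raises(InconsistentFlagsError):
            make_submission(DGS_REFERENCE, ErrorProfile(["no-such-error"]))


class TestCohortGeneration:
    FREQ = {
        "drop-g-prefix": 10 / 19,
        "drop-seq-symbol": 2 / 19,
        "swap-build-hg19": 0.6,
        "band-less-specific": 0.7,
    }

    def test_same_seed_reproduces_byte_identical_cohort(self):
        a = make_cohort(19, self.FREQ, seed=7)
        b = make_cohort(19, self.FREQ, seed=7)
        assert [(s.text_dgs, s.text_cmt1) for s, _ in a] == [
            (s.text_dgs, s.text_cmt1) for s, _ in b
        ]

    def test_scorer_recovers_every_expected_breakdown(self):
        for sub, expected in make_cohort(25, self.FREQ, seed=11):
            got = score_hospital(
                parse(sub.text_dgs), parse(sub.text_cmt1), refs=BOTH_REFS
            )
            assert got == expected, sub.hospital_id

    def test_perfect_cohort_when_frequencies_zero(self):
        cohort = make_cohort(1, {f: 0.0 for f in FLAGS}, seed=3)
        assert cohort[0][1].total == 10

    def test_injection_marginals_match_frequencies_in_expectation(self):
        # with p=10/19 for the g.-prefix drop, the expected e-tally on a
        # 19-hospital cohort is 10; allow binomial spread around it
        cohort = make_cohort(500, {"drop-g-prefix": 10 / 19}, seed=5)
        e_rate = sum(br.e for _, br in cohort) / len(cohort)
        assert abs(e_rate - 10 / 19) < 0.07

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(0, {}, seed=1)
        with pytest.raises(ValueError):
            make_cohort(3, {"drop-g-prefix": 1.5}, seed=1)


class TestSurveyCountsGeneration:
    def test_total_conserved(self):
        counts = make_survey_counts(seed=42)
        assert counts.total == 36432

    def test_proportions_close_to_targets(self):
        counts = make_survey_counts(seed=42)
        shares = [v / counts.total for v in counts.as_dict().values()]
        for got, want in zip(shares, (0.4187, 0.3382, 0.1966, 0.0465)):
            assert abs(got - want) < 0.01

    def test_seed_determinism(self):
        assert make_survey_counts(seed=9) == make_survey_counts(seed=9)
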