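"""The 10-point nomenclature-compliance rubric.

Two 5-point awards: *a* for using an ISCN-like format for the
chromosomal aberration, *b* for an HGVS-like description carrying the
nucleotide span.  Eight 1-point deductions (*c*–*j*) for missing
elements, with *j* a capped bucket for minor inconsistencies (wrong
range separator, unofficial build alias, normal chromosomes listed, …).
A submission that earns neither award scores 0 outright and the
deductions are not assessed — mirroring how the survey printed "-" for
its one prose-only respondent.

Hospitals submitted one string per reference CNV and were scored once:
awards must be earned on *both* strings, any deduction observed on
*either* string counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._rounding import truncate
from .model import (
    CnvReference,
    MinorError,
    NOT_APPLICABLE,
    ParsedNomenclature,
    RubricConfig,
    ScoreBreakdown,
    Submission,
)
from .parser import parse

__all__ = [
    "DEFAULT_CONFIG",
    "score_single",
    "score_hospital",
    "score_cohort",
    "CohortResult",
]

DEFAULT_CONFIG = RubricConfig()

_TALLY_ITEMS = ScoreBreakdown.DEDUCTION_ITEMS


def _reference_minors(parsed: ParsedNomenclature, reference: Optional[CnvReference]) -> set:
    """Minor errors that can only be judged against the reference CNV."""
    fired = set()
    if reference is not None and parsed.iscn_arm_band is not None:
        arm, band = parsed.iscn_arm_band
        if (
            arm == reference.arm
            and band != reference.band
            and reference.band.startswith(band)
        ):
            fired.add(MinorError.BAND_LESS_SPECIFIC)
    return fired


def _string_features(
    parsed: ParsedNomenclature,
    reference: Optional[CnvReference],
    config: RubricConfig,
) -> Tuple[bool, bool, Dict[str, bool], set]:
    """(award_a, award_b, deduction-fires c..i, fired minor labels) for one string."""
    award_a = parsed.iscn_portion_present
    award_b = parsed.coordinate_span is not None
    fires = {
        "c": not parsed.seq_symbol_present,
        "d": not parsed.build_tokens,
        "e": not parsed.g_prefix_present,
        "f": not parsed.has_chromosome,
        "g": parsed.iscn_arm_band is None,
        "h": not parsed.has_variant_keyword,
        "i": parsed.hgvs_attempt_present and parsed.coordinate_span is None,
    }
    minors = set(parsed.minor_error_flags) | _reference_minors(parsed, reference)
    minors = {label for label in minors if config.detector_enabled(label)}
    return award_a, award_b, fires, minors


def _assemble(
    award_a: bool,
    award_b: bool,
    fires: Dict[str, bool],
    minors: set,
    config: RubricConfig,
) -> ScoreBreakdown:
    a = config.award_points if award_a else 0
    b = config.award_points if award_b else 0
    if a == 0 and b == 0:
        return ScoreBreakdown(
            a=0, b=0,
            c=NOT_APPLICABLE, d=NOT_APPLICABLE, e=NOT_APPLICABLE, f=NOT_APPLICABLE,
            g=NOT_APPLICABLE, h=NOT_APPLICABLE, i=NOT_APPLICABLE, j=NOT_APPLICABLE,
            total=0, fired_minor_errors=frozenset(minors),
        )
    items = {item: int(fires[item]) for item in ("c", "d", "e", "f", "g", "h", "i")}
    items["j"] = int(bool(minors))  # capped: many minors, one point
    total = a + b - config.deduction_points * sum(items.values())
    total = max(config.clamp_floor, total)
    return ScoreBreakdown(
        a=a, b=b, **items, total=total, fired_minor_errors=frozenset(minors)
    )


def score_single(
    parsed: ParsedNomenclature,
    reference: Optional[CnvReference] = None,
    config: RubricConfig = DEFAULT_CONFIG,
) -> ScoreBreakdown:
    """Score one parsed submission string against one reference CNV."""
    award_a, award_b, fires, minors = _string_features(parsed, reference, config)
    return _assemble(award_a, award_b, fires, minors, config)


def score_hospital(
    parsed_dgs: ParsedNomenclature,
    parsed_cmt1: ParsedNomenclature,
    refs: Tuple[CnvReference, CnvReference],
    config: RubricConfig = DEFAULT_CONFIG,
) -> ScoreBreakdown:
    """Joint score for one hospital's deletion + duplication string pair.

    Awards require the feature on both strings (AND); deductions fire if
    observed on either (OR).
    """
    a1, b1, f1, m1 = _string_features(parsed_dgs, refs[0], config)
    a2, b2, f2, m2 = _string_features(parsed_cmt1, refs[1], config)
    fires = {item: f1[item] or f2[item] for item in f1}
    return _assemble(a1 and a2, b1 and b2, fires, m1 | m2, config)


@dataclass
class CohortResult:
    """Per-hospital breakdowns plus the cohort error tally."""

    hospital_ids: List[str]
    breakdowns: List[ScoreBreakdown]
    totals: List[int]
    #: hospitals (among those with assessable deductions) where each item fired
    tally: Dict[str, int] = field(default_factory=dict)
    #: the same counts as percentages of the whole cohort, truncated to 2 dp
    tally_percent: Dict[str, float] = field(default_factory=dict)
    #: hospitals that failed to earn each award at all
    not_following: Dict[str, int] = field(default_factory=dict)
    n: int = 0


def score_cohort(
    submissions: Sequence[Submission],
    refs: Tuple[CnvReference, CnvReference],
    config: RubricConfig = DEFAULT_CONFIG,
) -> CohortResult:
    """Parse and score every hospital, then tally error prevalence.

    Percentages use the full cohort size as denominator and truncate at
    two decimals, the convention of the survey's printed rates
    (10/19 -> 52.63, 2/19 -> 10.52).
    """
    if not submissions:
        raise ValueError("empty cohort")
    ids, breakdowns = [], []
    for sub in submissions:
        parsed_pair = (parse(sub.text_dgs), parse(sub.text_cmt1))
        breakdowns.append(score_hospital(*parsed_pair, refs=refs, config=config))
        ids.append(sub.hospital_id)
    n = len(breakdowns)
    tally = {
        item: sum(1 for br in breakdowns if br.deduction(item) == 1)
        for item in _TALLY_ITEMS
    }
    tally_percent = {item: truncate(100.0 * count / n) for item, count in tally.items()}
    not_following = {
        "a": sum(1 for br in breakdowns if br.a == 0),
        "b": sum(1 for br in breakdowns if br.b == 0),
    }
    return CohortResult(
        hospital_ids=ids,
        breakdowns=breakdowns,
        totals=[br.total for br in breakdowns],
        tally=tally,
        tally_percent=tally_percent,
        not_following=not_following,
        n=n,
    )
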