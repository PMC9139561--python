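"""Synthetic submissions with known, injected error classes.

Every mutation starts from the canonical two-line nomenclature and has
an unambiguous expected rubric outcome, so the parser+scorer pipeline
can be validated against exact ground truth without any external data.
Structural flags knock out award features (ISCN portion, coordinate
span) or deduction items c-i; minor flags plant exactly one entry of
the capped "other errors" bucket each.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .canonical import canonical
from .model import (
    CnvReference,
    ErrorProfile,
    InconsistentFlagsError,
    MinorError,
    RubricConfig,
    ScoreBreakdown,
    Submission,
    SurveyCounts,
)
from .scorer import DEFAULT_CONFIG, _assemble

__all__ = [
    "FLAGS",
    "STRUCTURAL_FLAGS",
    "MINOR_FLAGS",
    "make_submission",
    "make_cohort",
    "make_survey_counts",
]

# structural flags: change which rubric items fire
FLAG_DROP_ISCN = "drop-iscn-portion"
FLAG_DROP_COORDINATES = "drop-coordinates"
FLAG_DROP_SEQ = "drop-seq-symbol"
FLAG_DROP_BUILD = "drop-build"
FLAG_DROP_G_PREFIX = "drop-g-prefix"
FLAG_DROP_CHROMOSOME = "drop-chromosome"
FLAG_DROP_ARM_BAND = "drop-arm-band"
FLAG_DROP_KEYWORD = "drop-variant-keyword"
FLAG_SINGLE_POSITION = "collapse-span-single-position"

# minor flags: each plants one detector of the j bucket
FLAG_HYPHEN = "hyphen-range-separator"
FLAG_HG19 = "swap-build-hg19"
FLAG_MISSPELL_BUILD = "misspell-build"
FLAG_UNBRACKET_BUILD = "unbracket-build"
FLAG_KARYOTYPE = "prepend-karyotype"
FLAG_HASH = "insert-hash"
FLAG_WHITESPACE = "whitespace-in-hgvs"
FLAG_BAND_LESS = "band-less-specific"
FLAG_MISMATCH = "variant-type-mismatch"
FLAG_INVERT = "invert-range"

STRUCTURAL_FLAGS = (
    FLAG_DROP_ISCN,
    FLAG_DROP_COORDINATES,
    FLAG_DROP_SEQ,
    FLAG_DROP_BUILD,
    FLAG_DROP_G_PREFIX,
    FLAG_DROP_CHROMOSOME,
    FLAG_DROP_ARM_BAND,
    FLAG_DROP_KEYWORD,
    FLAG_SINGLE_POSITION,
)

_MINOR_LABELS = {
    FLAG_HYPHEN: MinorError.HYPHEN_RANGE_SEPARATOR,
    FLAG_HG19: MinorError.NON_OFFICIAL_BUILD_NAME,
    FLAG_MISSPELL_BUILD: MinorError.UNRECOGNIZED_BUILD_TOKEN,
    FLAG_UNBRACKET_BUILD: MinorError.BUILD_NOT_SQUARE_BRACKETED,
    FLAG_KARYOTYPE: MinorError.NORMAL_CHROMOSOMES_LISTED,
    FLAG_HASH: MinorError.HASH_SEPARATOR,
    FLAG_WHITESPACE: MinorError.WHITESPACE_INSIDE_HGVS,
    FLAG_BAND_LESS: MinorError.BAND_LESS_SPECIFIC,
    FLAG_MISMATCH: MinorError.VARIANT_TYPE_MISMATCH,
    FLAG_INVERT: MinorError.INVERTED_RANGE,
}

MINOR_FLAGS = tuple(_MINOR_LABELS)
FLAGS = STRUCTURAL_FLAGS + MINOR_FLAGS

# pairs whose combined mutation would produce a string the scorer cannot
# attribute the same way (the flag-consistency contract)
_CONFLICTS = {
    frozenset((FLAG_DROP_COORDINATES, FLAG_SINGLE_POSITION)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_HYPHEN)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_INVERT)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_WHITESPACE)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_MISMATCH)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_DROP_G_PREFIX)),
    frozenset((FLAG_DROP_COORDINATES, FLAG_HASH)),
    frozenset((FLAG_SINGLE_POSITION, FLAG_HYPHEN)),
    frozenset((FLAG_SINGLE_POSITION, FLAG_INVERT)),
    frozenset((FLAG_SINGLE_POSITION, FLAG_DROP_G_PREFIX)),
    frozenset((FLAG_DROP_BUILD, FLAG_HG19)),
    frozenset((FLAG_DROP_BUILD, FLAG_MISSPELL_BUILD)),
    frozenset((FLAG_DROP_BUILD, FLAG_UNBRACKET_BUILD)),
    frozenset((FLAG_MISSPELL_BUILD, FLAG_UNBRACKET_BUILD)),
    frozenset((FLAG_MISSPELL_BUILD, FLAG_HG19)),
    # a misspelled token is only attributable as a build via the seq[...] slot
    frozenset((FLAG_MISSPELL_BUILD, FLAG_DROP_SEQ)),
    frozenset((FLAG_DROP_KEYWORD, FLAG_MISMATCH)),
    frozenset((FLAG_DROP_KEYWORD, FLAG_WHITESPACE)),
    frozenset((FLAG_DROP_KEYWORD, FLAG_DROP_CHROMOSOME)),
    frozenset((FLAG_DROP_KEYWORD, FLAG_DROP_ARM_BAND)),
    frozenset((FLAG_DROP_CHROMOSOME, FLAG_DROP_ARM_BAND)),
    frozenset((FLAG_DROP_ARM_BAND, FLAG_BAND_LESS)),
    frozenset((FLAG_DROP_ISCN, FLAG_DROP_ARM_BAND)),
    frozenset((FLAG_DROP_ISCN, FLAG_BAND_LESS)),
    frozenset((FLAG_DROP_ISCN, FLAG_MISMATCH)),
    frozenset((FLAG_DROP_ISCN, FLAG_DROP_CHROMOSOME)),
}


def check_flags(flags: Sequence[str]) -> frozenset:
    """Validate a requested flag set; raise on unknown or conflicting flags."""
    flagset = frozenset(flags)
    unknown = flagset - set(FLAGS)
    if unknown:
        raise InconsistentFlagsError(f"unknown flags: {sorted(unknown)}")
    for pair in _CONFLICTS:
        if pair <= flagset:
            raise InconsistentFlagsError(f"conflicting flags: {sorted(pair)}")
    return flagset


def _misspell(build: str) -> str:
    # transpose the 2nd/3rd characters: GRCh37 -> GCRh37
    return build[0] + build[2] + build[1] + build[3:] if len(build) > 3 else build + "x"


def _render(reference: CnvReference, flags: frozenset, dialect: str) -> str:
    kw = reference.keyword
    build = reference.genome_build
    if FLAG_HG19 in flags:
        build = "hg19" if build == "GRCh37" else "hg38"
    elif FLAG_MISSPELL_BUILD in flags:
        build = _misspell(build)
    band = reference.band
    if FLAG_BAND_LESS in flags:
        band = band[:-1].rstrip(".")
        if not band:
            raise InconsistentFlagsError(
                f"reference band {reference.band!r} cannot be made less specific"
            )

    prefix = "" if FLAG_DROP_SEQ in flags else "seq"
    if FLAG_DROP_BUILD in flags:
        prefix += " "
    elif FLAG_UNBRACKET_BUILD in flags:
        prefix += (" " if prefix else "") + build + " "
    else:
        prefix += f"[{build}]"

    if FLAG_DROP_ISCN in flags:
        locus = ""
    else:
        kw_part = "" if FLAG_DROP_KEYWORD in flags else kw
        chrom_part = "" if FLAG_DROP_CHROMOSOME in flags else reference.chromosome
        band_part = "" if FLAG_DROP_ARM_BAND in flags else f"{reference.arm}{band}"
        locus = f"{kw_part}({chrom_part})"
        if band_part:
            locus += f"({band_part})"
    line1 = (prefix + locus).strip()
    if FLAG_KARYOTYPE in flags:
        line1 = "46,XN," + line1

    if FLAG_DROP_COORDINATES in flags:
        line2 = None
    else:
        start, end = reference.start_bp, reference.end_bp
        if FLAG_INVERT in flags:
            start, end = end, start
        sep = "-" if FLAG_HYPHEN in flags else "_"
        coords = str(start) if FLAG_SINGLE_POSITION in flags else f"{start}{sep}{end}"
        g_part = "" if FLAG_DROP_G_PREFIX in flags else "g."
        chrom_part = "" if FLAG_DROP_CHROMOSOME in flags else f"chr{reference.chromosome}:"
        kw2 = "" if FLAG_DROP_KEYWORD in flags else kw
        if FLAG_MISMATCH in flags:
            kw2 = "dup" if kw == "del" else "del"
        space = " " if FLAG_WHITESPACE in flags else ""
        line2 = f"{chrom_part}{g_part}{coords}{space}{kw2}"

    if line2 is None:
        return line1
    if not line1:
        return line2
    if FLAG_HASH in flags:
        return line1 + "#" + line2
    if dialect == "single-line":
        return line1 + line2
    return line1 + "\n" + line2


def expected_breakdown(
    flags: Sequence[str],
    config: RubricConfig = DEFAULT_CONFIG,
) -> ScoreBreakdown:
    """The breakdown the scorer must produce for a flag set (ground truth)."""
    flagset = check_flags(flags)
    award_a = FLAG_DROP_ISCN not in flagset
    award_b = not ({FLAG_DROP_COORDINATES, FLAG_SINGLE_POSITION} & flagset)
    fires = {
        "c": FLAG_DROP_SEQ in flagset,
        "d": FLAG_DROP_BUILD in flagset,
        "e": FLAG_DROP_G_PREFIX in flagset or FLAG_DROP_COORDINATES in flagset,
        "f": FLAG_DROP_CHROMOSOME in flagset,
        "g": FLAG_DROP_ARM_BAND in flagset or FLAG_DROP_ISCN in flagset,
        "h": FLAG_DROP_KEYWORD in flagset,
        "i": FLAG_SINGLE_POSITION in flagset,
    }
    minors = {_MINOR_LABELS[f] for f in flagset & set(MINOR_FLAGS)}
    if FLAG_SINGLE_POSITION in flagset:
        minors.add(MinorError.SINGLE_POSITION)
    minors = {label for label in minors if config.detector_enabled(label)}
    return _assemble(award_a, award_b, fires, minors, config)


def make_submission(
    reference: CnvReference,
    profile: ErrorProfile,
    config: RubricConfig = DEFAULT_CONFIG,
) -> Tuple[str, ScoreBreakdown]:
    """Mutate the canonical string per ``profile`` and return it with the
    breakdown the scorer must produce.  An empty flag set returns the
    canonical string itself (expected total 10)."""
    if profile.dialect not in ("canonical", "single-line"):
        raise ValueError(f"unknown dialect {profile.dialect!r}")
    flagset = check_flags(profile.target_flags)
    if not flagset and profile.dialect == "canonical":
        text = canonical(reference)
    else:
        text = _render(reference, flagset, profile.dialect)
    return text, expected_breakdown(flagset, config)


def make_cohort(
    n: int,
    flag_frequencies: Mapping[str, float],
    seed: int,
    refs: Tuple[CnvReference, CnvReference] = None,
    config: RubricConfig = DEFAULT_CONFIG,
) -> List[Tuple[Submission, ScoreBreakdown]]:
    """Draw ``n`` hospitals, each injecting flags independently at the given
    frequencies (same format for both CNVs, as real hospitals did).

    Sampled flags are repaired to a consistent subset deterministically:
    flags are considered in the fixed inventory order and dropped when they
    conflict with one already accepted.  Returns (submission, expected
    hospital-level breakdown) pairs; reproducible for a given seed.
    """
    from .model import CMT1_REFERENCE, DGS_REFERENCE

    if n < 1:
        raise ValueError("n must be >= 1")
    for flag, p in flag_frequencies.items():
        if flag not in FLAGS:
            raise InconsistentFlagsError(f"unknown flag {flag!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency for {flag!r} outside [0, 1]")
    refs = refs or (DGS_REFERENCE, CMT1_REFERENCE)
    rng = np.random.default_rng(seed)
    cohort = []
    for idx in range(n):
        drawn = [f for f in FLAGS if f in flag_frequencies and rng.random() < flag_frequencies[f]]
        accepted: List[str] = []
        for flag in drawn:
            if all(frozenset((flag, other)) not in _CONFLICTS for other in accepted):
                accepted.append(flag)
        profile = ErrorProfile(target_flags=accepted, seed=seed)
        text_dgs, expected = make_submission(refs[0], profile, config)
        text_cmt1, _ = make_submission(refs[1], profile, config)
        cohort.append(
            (
                Submission(
                    hospital_id=f"SynthHospital {idx + 1}",
                    text_dgs=text_dgs,
                    text_cmt1=text_cmt1,
                    manufacturer="synthetic",
                    platform="synthetic",
                ),
                expected,
            )
        )
    return cohort


#: printed referral shares used as emulation targets for synthetic cohorts
DEFAULT_PROPORTIONS = (0.4187, 0.3382, 0.1966, 0.0465)


def make_survey_counts(
    seed: int,
    total: int = 36_432,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
) -> SurveyCounts:
    """Multinomial draw of per-indication annual case counts."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total, p)
    return SurveyCounts(
        high_risk_pregnancy=int(draws[0]),
        spontaneous_abortion=int(draws[1]),
        adverse_pregnancy_history=int(draws[2]),
        congenital_birth_defect=int(draws[3]),
    )
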