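"""Domain types shared by every stage of the CNV-nomenclature audit.

The audit judges laboratory-submitted descriptions of two recurrent
pathogenic copy-number variants — the DiGeorge-syndrome 22q11.2 deletion
and the Charcot-Marie-Tooth 1A 17p12 duplication — against the reporting
formats recommended by ISCN 2016 (chromosomal aberrations) and HGVS
(sequence-level variants).  All coordinates are 1-based and inclusive,
the ISCN/HGVS convention; no half-open conversion happens anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "VALID_CHROMOSOMES",
    "MinorError",
    "DEFAULT_DETECTOR_TOGGLES",
    "CnvReference",
    "Submission",
    "ParsedNomenclature",
    "NOT_APPLICABLE",
    "ScoreBreakdown",
    "RubricConfig",
    "SurveyCounts",
    "SequencingSpec",
    "ScoreStats",
    "ErrorProfile",
    "DGS_REFERENCE",
    "CMT1_REFERENCE",
    "InvalidSubmissionError",
    "FixtureIntegrityError",
    "InconsistentFlagsError",
]

VALID_CHROMOSOMES = frozenset({str(i) for i in range(1, 23)} | {"X", "Y"})


class InvalidSubmissionError(ValueError):
    """Raised for empty / whitespace-only submission text."""


class FixtureIntegrityError(RuntimeError):
    """Raised when the bundled survey fixture fails its checksum."""


class InconsistentFlagsError(ValueError):
    """Raised when an error-injection profile requests contradictory mutations."""


class MinorError:
    """Labels for the 'other errors' bucket (rubric item j).

    Each is an independent detector; any enabled detector firing costs a
    single point, no matter how many fire.
    """

    HYPHEN_RANGE_SEPARATOR = "hyphen-range-separator"
    NON_OFFICIAL_BUILD_NAME = "non-official-build-name"
    UNRECOGNIZED_BUILD_TOKEN = "unrecognized-build-token"
    BUILD_NOT_SQUARE_BRACKETED = "build-not-square-bracketed"
    HASH_SEPARATOR = "hash-separator"
    NORMAL_CHROMOSOMES_LISTED = "normal-chromosomes-listed"
    WHITESPACE_INSIDE_HGVS = "whitespace-inside-hgvs-portion"
    BAND_LESS_SPECIFIC = "band-less-specific-than-reference"
    VARIANT_TYPE_MISMATCH = "variant-type-mismatch-between-portions"
    INVERTED_RANGE = "inverted-range"
    SINGLE_POSITION = "single-position"
    HGVS_NOT_ON_OWN_LINE = "hgvs-not-on-own-line"

    ALL = (
        HYPHEN_RANGE_SEPARATOR,
        NON_OFFICIAL_BUILD_NAME,
        UNRECOGNIZED_BUILD_TOKEN,
        BUILD_NOT_SQUARE_BRACKETED,
        HASH_SEPARATOR,
        NORMAL_CHROMOSOMES_LISTED,
        WHITESPACE_INSIDE_HGVS,
        BAND_LESS_SPECIFIC,
        VARIANT_TYPE_MISMATCH,
        INVERTED_RANGE,
        SINGLE_POSITION,
        HGVS_NOT_ON_OWN_LINE,
    )


# item i already deducts for a missing span, so the single-position flag is
# informational by default; the own-line rule is likewise off because the
# survey's printed scores never penalized single-line layouts.
DEFAULT_DETECTOR_TOGGLES: Mapping[str, bool] = {
    label: label not in (MinorError.SINGLE_POSITION, MinorError.HGVS_NOT_ON_OWN_LINE)
    for label in MinorError.ALL
}


@dataclass(frozen=True)
class CnvReference:
    """Gold-standard description of one reference CNV.

    ``expected_copy_number`` follows the autosomal convention: a
    heterozygous deletion leaves one copy, a duplication yields three.
    """

    name: str
    chromosome: str
    arm: str
    band: str
    start_bp: int
    end_bp: int
    variant_type: str  # "deletion" | "duplication"
    genome_build: str  # "GRCh37" | "GRCh38"

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValueError(f"invalid chromosome {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"invalid arm {self.arm!r}")
        import re

        if not re.fullmatch(r"[0-9]+(\.[0-9]+)*", self.band):
            raise ValueError(f"invalid band {self.band!r}")
        if not (1 <= self.start_bp <= self.end_bp):
            raise ValueError("require 1 <= start_bp <= end_bp")
        if self.variant_type not in ("deletion", "duplication"):
            raise ValueError(f"invalid variant_type {self.variant_type!r}")
        if self.genome_build not in ("GRCh37", "GRCh38"):
            raise ValueError(f"invalid genome_build {self.genome_build!r}")

    @property
    def expected_copy_number(self) -> int:
        return 1 if self.variant_type == "deletion" else 3

    @property
    def keyword(self) -> str:
        """ISCN/HGVS short variant keyword ('del' or 'dup')."""
        return "del" if self.variant_type == "deletion" else "dup"


#: The two reference CNVs the survey asked hospitals to describe.
DGS_REFERENCE = CnvReference(
    name="DGS",
    chromosome="22",
    arm="q",
    band="11.21",
    start_bp=19009792,
    end_bp=21452445,
    variant_type="deletion",
    genome_build="GRCh37",
)

CMT1_REFERENCE = CnvReference(
    name="CMT1",
    chromosome="17",
    arm="p",
    band="12",
    start_bp=14097915,
    end_bp=15470903,
    variant_type="duplication",
    genome_build="GRCh37",
)


@dataclass(frozen=True)
class Submission:
    """One hospital's pair of submitted nomenclature strings plus metadata."""

    hospital_id: str
    text_dgs: str
    text_cmt1: str
    manufacturer: str = ""
    platform: str = ""
    wet_lab_outsourced: bool = False
    bioinfo_outsourced: bool = False


@dataclass
class ParsedNomenclature:
    """Feature set extracted from one submitted string.

    Non-compliance is encoded as absent features and minor-error flags,
    never as parse failures.
    """

    seq_symbol_present: bool = False
    build_tokens: list = field(default_factory=list)  # [(token, bracket_style)]
    recognized_builds: set = field(default_factory=set)
    iscn_portion_present: bool = False
    iscn_chromosome: Optional[str] = None
    iscn_arm_band: Optional[tuple] = None  # (arm, band)
    iscn_variant_keyword: Optional[str] = None  # "del" | "dup"
    coordinate_span: Optional[tuple] = None  # (start, end, separator)
    g_prefix_present: bool = False
    hgvs_chromosome: Optional[str] = None
    hgvs_variant_keyword: Optional[str] = None
    copy_number_token: Optional[tuple] = None  # (value, marker)
    karyotype_prefix_present: bool = False
    inheritance_tokens: list = field(default_factory=list)
    hgvs_on_own_line: bool = False
    minor_error_flags: set = field(default_factory=set)
    free_text_segments: list = field(default_factory=list)

    @property
    def has_variant_keyword(self) -> bool:
        return self.iscn_variant_keyword is not None or self.hgvs_variant_keyword is not None

    @property
    def has_chromosome(self) -> bool:
        return self.iscn_chromosome is not None or self.hgvs_chromosome is not None

    @property
    def hgvs_attempt_present(self) -> bool:
        """An HGVS-like portion was attempted (g. prefix or chrN: anchor)."""
        return self.g_prefix_present or self.hgvs_chromosome is not None


#: Sentinel for rubric deductions that are not assessed (score-0 rows).
NOT_APPLICABLE = None


@dataclass(frozen=True)
class ScoreBreakdown:
    """Rubric items a-j and the clamped 0-10 total for one submission pair.

    ``a``/``b`` are the 5-point awards (ISCN-like / HGVS-like format used);
    ``c``..``j`` are the 1-point deductions, ``None`` when not applicable
    (both awards missed, total fixed at 0).
    """

    a: int
    b: int
    c: Optional[int]
    d: Optional[int]
    e: Optional[int]
    f: Optional[int]
    g: Optional[int]
    h: Optional[int]
    i: Optional[int]
    j: Optional[int]
    total: int
    fired_minor_errors: frozenset = frozenset()

    DEDUCTION_ITEMS = ("c", "d", "e", "f", "g", "h", "i", "j")

    def deduction(self, item: str) -> Optional[int]:
        return getattr(self, item)

    def as_record(self) -> dict:
        rec = {"a": self.a, "b": self.b}
        for item in self.DEDUCTION_ITEMS:
            v = getattr(self, item)
            rec[item] = "-" if v is NOT_APPLICABLE else v
        rec["total"] = self.total
        rec["minor_errors"] = sorted(self.fired_minor_errors)
        return rec


@dataclass(frozen=True)
class RubricConfig:
    """Tunable scoring parameters; the defaults reproduce the survey rubric."""

    award_points: int = 5
    deduction_points: int = 1
    minor_error_detector_toggles: Mapping[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_DETECTOR_TOGGLES)
    )
    build_whitelist: frozenset = frozenset({"GRCh37", "GRCh38", "hg19", "hg38"})
    inheritance_whitelist: frozenset = frozenset({"mat", "pat", "dn"})
    require_hgvs_own_line: bool = False
    clamp_floor: int = 0

    def detector_enabled(self, label: str) -> bool:
        if label == MinorError.HGVS_NOT_ON_OWN_LINE and self.require_hgvs_own_line:
            return True
        return bool(self.minor_error_detector_toggles.get(label, False))


@dataclass(frozen=True)
class SurveyCounts:
    """Annual case counts per referral indication."""

    high_risk_pregnancy: int
    spontaneous_abortion: int
    adverse_pregnancy_history: int
    congenital_birth_defect: int
    provider_counts: Optional[Mapping[str, int]] = None

    INDICATIONS = (
        "high_risk_pregnancy",
        "spontaneous_abortion",
        "adverse_pregnancy_history",
        "congenital_birth_defect",
    )

    def __post_init__(self) -> None:
        for key in self.INDICATIONS:
            if getattr(self, key) < 0:
                raise ValueError(f"negative count for {key}")

    def as_dict(self) -> dict:
        return {key: getattr(self, key) for key in self.INDICATIONS}

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class SequencingSpec:
    """One sequencing-run parameter tuple for depth-of-coverage arithmetic.

    ``read_count`` counts reads for single-end runs and read *pairs* for
    paired-end runs; paired mode therefore doubles the sequenced bases.
    """

    read_count: int
    read_length_bp: int
    mode: str = "single"  # "single" | "paired"
    genome_size_bp: int = 3_200_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("single", "paired"):
            raise ValueError(f"invalid mode {self.mode!r}")
        for name in ("read_count", "read_length_bp", "genome_size_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ScoreStats:
    """Summary statistics of a cohort score vector (2-decimal, half-up)."""

    n: int
    mean: float
    sd_population: float
    sd_sample: float
    ci_low: float
    ci_high: float
    ci_method: str = "t_sample_sd"


@dataclass(frozen=True)
class ErrorProfile:
    """Specification of which error classes the synthetic generator injects.

    An empty ``target_flags`` set yields the canonical, 10-point string.
    """

    target_flags: frozenset = frozenset()
    dialect: str = "canonical"
    seed: int = 0

    def __init__(self, target_flags: Sequence[str] = (), dialect: str = "canonical", seed: int = 0):
        object.__setattr__(self, "target_flags", frozenset(target_flags))
        object.__setattr__(self, "dialect", dialect)
        object.__setattr__(self, "seed", seed)
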