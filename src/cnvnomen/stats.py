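"""Descriptive statistics for the survey: referral composition, score
summaries, and low-pass WGS depth-of-coverage arithmetic.

Depth of coverage is the classic folds formula: total sequenced bases
(read count x read length, doubled for paired-end runs where counts are
read pairs) divided by the size of the reference human genome, taken
here as 3.2 Gb.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from ._rounding import round_half_up
from .model import ScoreStats, SequencingSpec, SurveyCounts

__all__ = ["composition", "score_stats", "depth_of_coverage", "ln_depth"]


def composition(
    counts: Union[SurveyCounts, Mapping[str, int]],
) -> Tuple[int, Dict[str, Tuple[int, float]]]:
    """Per-indication share of annual referrals.

    Returns ``(total, {indication: (count, percentage)})`` with
    percentages rounded half-up to two decimals.
    """
    mapping = counts.as_dict() if isinstance(counts, SurveyCounts) else dict(counts)
    if any(v < 0 for v in mapping.values()):
        raise ValueError("counts must be non-negative")
    total = sum(mapping.values())
    if total == 0:
        raise ValueError("at least one referral count must be positive")
    shares = {
        key: (count, round_half_up(100.0 * count / total))
        for key, count in mapping.items()
    }
    return total, shares


def score_stats(scores: Sequence[int], confidence: float = 0.95) -> ScoreStats:
    """Mean, both SD forms, and the t-interval of a cohort score vector.

    The confidence interval is mean +/- t(1-alpha/2, n-1) * s / sqrt(n)
    with the sample SD; the population SD is what small-sample survey
    tables usually print next to the mean.  Everything is reported to
    two decimals (half-up).
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two scores")
    mean = float(x.mean())
    sd_pop = float(x.std(ddof=0))
    sd_samp = float(x.std(ddof=1))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd_samp / math.sqrt(n)
    return ScoreStats(
        n=n,
        mean=round_half_up(mean),
        sd_population=round_half_up(sd_pop),
        sd_sample=round_half_up(sd_samp),
        ci_low=round_half_up(mean - half),
        ci_high=round_half_up(mean + half),
    )


def depth_of_coverage(spec: SequencingSpec) -> Tuple[float, float]:
    """Fold coverage of one sequencing configuration, raw and rounded.

    Returns ``(raw, rounded)``; rounding is half-up at two decimals, so
    5.625 reports as 5.63 and 0.035625 as 0.04.
    """
    bases_per_unit = spec.read_length_bp * (2 if spec.mode == "paired" else 1)
    raw = spec.read_count * bases_per_unit / spec.genome_size_bp
    return raw, round_half_up(raw)


def ln_depth(depth: float) -> float:
    """Natural log of a fold depth, to one decimal (for log-scale plots)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return round_half_up(math.log(depth), 1)
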