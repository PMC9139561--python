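#!/usr/bin/env python
"""Descriptive statistics of the survey cohort.

Computes (1) the referral composition of the ~36k annual cases,
(2) the compliance-score summary (mean, SD, 95% t-interval), and
(3) the depth-of-coverage arithmetic for the one hospital that ran two
sequencing configurations (low-pass prenatal, higher-depth postnatal).
"""

import json
from pathlib import Path

from cnvnomen import (
    SequencingSpec,
    composition,
    depth_of_coverage,
    ln_depth,
    load_table3_fixture,
    score_stats,
)
from cnvnomen.scorer import score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

REFERRAL_COUNTS = {
    "high_risk_pregnancy": 15254,
    "spontaneous_abortion": 12322,
    "adverse_pregnancy_history": 7162,
    "congenital_birth_defect": 1694,
}

SEQUENCING_CONFIGS = {
    "prenatal_low_pass": SequencingSpec(3_000_000, 38, "single"),
    "postnatal_higher_depth": SequencingSpec(60_000_000, 150, "paired"),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    total, shares = composition(REFERRAL_COUNTS)
    print(f"Annual referrals: {total} cases")
    for key, (count, pct) in shares.items():
        print(f"  {key:>26}: {count:>6}  ({pct:.2f}%)")

    submissions, refs = load_table3_fixture()
    stats = score_stats(score_cohort(submissions, refs).totals)
    print(
        f"Compliance score: mean {stats.mean} / 10 "
        f"(95% CI {stats.ci_low}-{stats.ci_high}), "
        f"SD {stats.sd_population} (population) / {stats.sd_sample} (sample)"
    )

    depths = {}
    for label, spec in SEQUENCING_CONFIGS.items():
        raw, rounded = depth_of_coverage(spec)
        depths[label] = {"fold": rounded, "ln_fold": ln_depth(raw)}
        print(f"  {label}: {rounded}-fold (ln {ln_depth(raw)})")

    payload = {
        "referrals": {"total": total, "shares": shares},
        "score_stats": stats.__dict__,
        "depth_of_coverage": depths,
        "ln_depth_anchors": {"0.03": ln_depth(0.03), "1.88": ln_depth(1.88)},
    }
    (RESULTS / "survey_statistics.json").write_text(json.dumps(payload, indent=2))
    print(f"Wrote {RESULTS / 'survey_statistics.json'}")


if __name__ == "__main__":
    main()
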