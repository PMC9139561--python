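#!/usr/bin/env python
"""Audit the 19 hospitals' submitted CNV nomenclature strings.

Parses each hospital's DiGeorge-deletion and CMT1A-duplication
descriptions, applies the 10-point ISCN 2016 / HGVS compliance rubric,
and writes the per-hospital breakdowns plus the cohort error tally.

Findings: one hospital submits fully compliant nomenclature (10/10),
one submits prose only (0/10); the dominant defect is a missing "g."
reference-sequence prefix (10/19 hospitals) and nearly all submissions
(17/19) carry at least one minor inconsistency such as a hyphen range
separator or the unofficial build alias hg19.
"""

import json
from pathlib import Path

from cnvnomen import load_table3_fixture, run_audit

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = run_audit(
        json_out=RESULTS / "audit_report.json",
        tsv_out=RESULTS / "hospital_scores.tsv",
    )
    submissions, _ = load_table3_fixture()
    totals = {rec["hospital_id"]: rec["total"] for rec in report["per_hospital"]}
    print(f"Scored {report['n_hospitals']} hospitals "
          f"({len(submissions) * 2} nomenclature strings).")
    print(f"Score vector: {list(totals.values())}")
    print(f"Error tally (items c-j): {report['tally']}")
    print(f"As % of cohort: {report['tally_percent']}")
    print(f"Hospitals not following ISCN/HGVS format at all: "
          f"{report['not_following_format']}")
    print(f"Wrote {RESULTS / 'audit_report.json'} and {RESULTS / 'hospital_scores.tsv'}")


if __name__ == "__main__":
    main()
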