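"""Fixture loading, TSV/JSON I/O, configuration, and the end-to-end audit.

The bundled fixture carries the 19 hospitals' submitted nomenclature
strings verbatim (en-dashes and curly quotes normalized to ASCII; the
``#`` glyphs some hospitals used as separators are part of their
submissions and kept).  Line breaks inside a submission are encoded as
the two-character escape ``\\n`` in the TSV and decoded on load;
Hospital 16's pair is stored as two lines each (ISCN portion, HGVS
portion), consistent with its error-free printed score.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .model import (
    CMT1_REFERENCE,
    DGS_REFERENCE,
    CnvReference,
    FixtureIntegrityError,
    MinorError,
    RubricConfig,
    Submission,
)
from .scorer import DEFAULT_CONFIG, CohortResult, score_cohort
from .stats import score_stats

__all__ = [
    "load_table3_fixture",
    "read_submissions_tsv",
    "write_submissions_tsv",
    "load_config",
    "run_audit",
    "REPORT_SCHEMA_VERSION",
]

log = logging.getLogger("cnvnomen")

REPORT_SCHEMA_VERSION = "1.0"

_FIXTURE_NAME = "table3_submissions.tsv"
_FIXTURE_SHA256 = "b33036f0b6d323fa38f6afd0f6e59b9d367d9f07cb8416d6cc8eb5179a2305ab"

_COLUMNS = [
    "hospital_id",
    "manufacturer",
    "platform",
    "wet_lab_outsourced",
    "bioinfo_outsourced",
    "text_dgs",
    "text_cmt1",
]
_REQUIRED_COLUMNS = ("hospital_id", "text_dgs", "text_cmt1")


def _decode(text: str) -> str:
    return text.replace("\\n", "\n")


def _encode(text: str) -> str:
    return text.replace("\n", "\\n")


def _frame_to_submissions(frame: pd.DataFrame) -> List[Submission]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"submissions table lacks required columns: {missing}")
    subs = []
    for row in frame.itertuples(index=False):
        subs.append(
            Submission(
                hospital_id=str(row.hospital_id),
                text_dgs=_decode(str(row.text_dgs)),
                text_cmt1=_decode(str(row.text_cmt1)),
                manufacturer=str(getattr(row, "manufacturer", "")),
                platform=str(getattr(row, "platform", "")),
                wet_lab_outsourced=str(getattr(row, "wet_lab_outsourced", "false")).lower()
                == "true",
                bioinfo_outsourced=str(getattr(row, "bioinfo_outsourced", "false")).lower()
                == "true",
            )
        )
    return subs


def read_submissions_tsv(path: Union[str, Path]) -> List[Submission]:
    """Read a tab-delimited submissions table (UTF-8, header row)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"no submissions in {path}")
    return _frame_to_submissions(frame)


def write_submissions_tsv(submissions: List[Submission], path: Union[str, Path]) -> None:
    rows = [
        {
            "hospital_id": s.hospital_id,
            "manufacturer": s.manufacturer,
            "platform": s.platform,
            "wet_lab_outsourced": str(s.wet_lab_outsourced).lower(),
            "bioinfo_outsourced": str(s.bioinfo_outsourced).lower(),
            "text_dgs": _encode(s.text_dgs),
            "text_cmt1": _encode(s.text_cmt1),
        }
        for s in submissions
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_table3_fixture() -> Tuple[List[Submission], Tuple[CnvReference, CnvReference]]:
    """The 19-hospital survey fixture plus the two reference CNVs.

    Verifies the bundled file against a frozen checksum before parsing.
    """
    data = resources.files("cnvnomen.data").joinpath(_FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import StringIO

    frame = pd.read_csv(StringIO(data.decode("utf-8")), sep="\t", dtype=str, keep_default_na=False)
    return _frame_to_submissions(frame), (DGS_REFERENCE, CMT1_REFERENCE)


def load_config(path: Union[str, Path]) -> RubricConfig:
    """Parse a flat ``key = value`` rubric-configuration file.

    Recognized keys: ``award_points``, ``deduction_points``,
    ``clamp_floor``, ``require_hgvs_own_line`` and per-detector toggles
    ``detector.<label> = on|off``.
    """
    toggles = dict(RubricConfig().minor_error_detector_toggles)
    kwargs: Dict[str, object] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("detector."):
            label = key[len("detector."):]
            if label not in MinorError.ALL:
                raise ValueError(f"{path}:{lineno}: unknown detector {label!r}")
            toggles[label] = value.lower() in ("on", "true", "1", "yes")
        elif key in ("award_points", "deduction_points", "clamp_floor"):
            kwargs[key] = int(value)
        elif key == "require_hgvs_own_line":
            kwargs[key] = value.lower() in ("on", "true", "1", "yes")
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return RubricConfig(minor_error_detector_toggles=toggles, **kwargs)


def _report(result: CohortResult) -> dict:
    stats = score_stats(result.totals)
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_hospitals": result.n,
        "per_hospital": [
            {"hospital_id": hid, **br.as_record()}
            for hid, br in zip(result.hospital_ids, result.breakdowns)
        ],
        "tally": dict(result.tally),
        "tally_percent": dict(result.tally_percent),
        "not_following_format": dict(result.not_following),
        "score_stats": {
            "n": stats.n,
            "mean": stats.mean,
            "sd_population": stats.sd_population,
            "sd_sample": stats.sd_sample,
            "ci_low": stats.ci_low,
            "ci_high": stats.ci_high,
            "ci_method": stats.ci_method,
        },
    }


def run_audit(
    submissions_path: Optional[Union[str, Path]] = None,
    config_path: Optional[Union[str, Path]] = None,
    json_out: Optional[Union[str, Path]] = None,
    tsv_out: Optional[Union[str, Path]] = None,
) -> dict:
    """Parse, score and summarize a submissions table end to end.

    With no ``submissions_path`` the bundled survey fixture is audited.
    Returns the report dict; optionally writes it as JSON and the
    per-hospital breakdowns as TSV (both carry identical numbers).
    """
    if submissions_path is None:
        submissions, refs = load_table3_fixture()
    else:
        submissions = read_submissions_tsv(submissions_path)
        refs = (DGS_REFERENCE, CMT1_REFERENCE)
    config = load_config(config_path) if config_path else DEFAULT_CONFIG
    result = score_cohort(submissions, refs, config)
    for hid, br in zip(result.hospital_ids, result.breakdowns):
        if br.fired_minor_errors:
            log.info("%s: minor errors fired: %s", hid, sorted(br.fired_minor_errors))
    report = _report(result)
    if json_out:
        Path(json_out).write_text(json.dumps(report, indent=2), encoding="utf-8")
    if tsv_out:
        frame = pd.DataFrame(
            [
                {
                    "hospital_id": rec["hospital_id"],
                    **{k: rec[k] for k in ("a", "b", "c", "d", "e", "f", "g", "h", "i", "j", "total")},
                    "minor_errors": ";".join(rec["minor_errors"]),
                }
                for rec in report["per_hospital"]
            ]
        )
        frame.to_csv(tsv_out, sep="\t", index=False)
    return report
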