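"""Emission of fully compliant CNV nomenclature.

Two profiles are supported.  ``iscn2016`` is the audit's gold format:

    seq[GRCh37]del(22)(q11.21)
    chr22:g.19009792_21452445del

``iscn2020`` applies the later edition's structural changes: the HGVS
portion opens with the genomic reference-sequence accession and no
longer repeats the chromosome.  Accessions are assembly-specific user
data (e.g. NC_000022.11 for chr22 on GRCh38) and must be supplied by
the caller; they are deliberately not bundled.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .model import CnvReference

__all__ = ["canonical", "PROFILES"]

PROFILES = ("iscn2016", "iscn2020")


def canonical(
    reference: CnvReference,
    profile: str = "iscn2016",
    *,
    single_line: bool = False,
    inheritance: Optional[str] = None,
    accessions: Optional[Mapping[str, str]] = None,
) -> str:
    """Build the compliant nomenclature string for ``reference``.

    By default the HGVS portion is emitted on its own line (the minor-error
    list treats a shared line as an inconsistency); ``single_line=True``
    concatenates the two portions as the survey's answer key printed them.
    ``inheritance`` appends a whitelisted inheritance annotation such as
    ``"mat/pat/dn"`` to the ISCN line.
    """
    if profile not in PROFILES:
        raise ValueError(f"unsupported profile {profile!r}; expected one of {PROFILES}")
    kw = reference.keyword
    iscn = (
        f"seq[{reference.genome_build}]"
        f"{kw}({reference.chromosome})({reference.arm}{reference.band})"
    )
    if inheritance:
        iscn += f" {inheritance}"
    if profile == "iscn2016":
        hgvs = f"chr{reference.chromosome}:g.{reference.start_bp}_{reference.end_bp}{kw}"
    else:
        if not accessions or reference.chromosome not in accessions:
            raise ValueError(
                "iscn2020 profile needs a chromosome->accession mapping "
                f"covering chromosome {reference.chromosome}"
            )
        accession = accessions[reference.chromosome]
        hgvs = f"{accession}:g.{reference.start_bp}_{reference.end_bp}{kw}"
    return iscn + ("" if single_line else "\n") + hgvs
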