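# Methods

## The scoring model

The audit treats nomenclature compliance as a feature-presence problem.
Each submitted string is reduced to a fixed feature set (which tokens
are present, in which style) and the rubric is pure arithmetic over
that feature set:

```
total = clamp( a + b − Σ deductions, 0, 10 )
a = 5 · [ISCN-like portion present]        b = 5 · [coordinate span present]
deductions: c..i ∈ {0,1} for missing elements, j = min(1, #minor errors)
```

Two special rules come from how the survey scored its cohort:

* **Joint pair scoring.** Each hospital submitted one deletion and one
  duplication string in the same house style.  Awards are ANDed across
  the pair (both strings must carry the feature) while deductions are
  ORed (a defect on either string counts once).
* **Not-applicable deductions.** When neither award is earned (a prose
  description), the total is fixed at 0 and items c–j are reported as
  not applicable rather than 0 — deducting from nothing is meaningless.

Item *i* ("span not provided") is interpreted narrowly: it fires only
when an HGVS-like attempt exists (a `g.` prefix or `chrN:` anchor)
without a two-coordinate range.  When no coordinates are given at all,
award *b* is simply not earned and *i* stays 0.

## Parsing

`parser.parse` is a linter, not a grammar.  Observed submissions span
at least twelve dialects, including hybrid forms
(`22q11.2(19009792_21452445)X1`, `del(22q11.2).seq[GRCh37](…)×1`) and
prose wrappers; a strict ISCN/HGVS grammar would reject exactly the
strings the rubric must score.  Extraction therefore uses ordered
regular-expression passes over a lightly normalized string (en-dashes →
hyphen, curly quotes → straight, NBSP → space) and encodes
noncompliance as absent features plus minor-error flags.  Only empty
input raises.

Recognition rules worth noting:

* An ISCN-like portion is accepted in any of: classic
  `del(22)(q11.21)`, fused `del(22q11.2)`, keyword-with-chromosome
  `del(22)`, keyword-with-band `del()(q11.21)`, bare parenthesized
  locus `(22)(q11.21)`, or a band locus (`22q11.2`) that is either
  followed by a parenthesized coordinate list or accompanied by a
  coordinate span anywhere in the string.  A band mentioned in prose
  with no coordinates anywhere (e.g. "There may be 22q11 microdeletion
  syndrome") does **not** count — that distinction separates the
  coordinate-list dialects, which earned the award, from prose, which
  did not.
* A coordinate span is any two ≥6-digit integers joined by `_` or `-`;
  the HGVS award keys on span presence, not on the full `chrN:g.` form,
  because most surveyed laboratories omitted `g.` yet were credited
  with an HGVS-like attempt.
* A token in the `seq[...]` slot containing letters counts as an
  *attempted* genome build even when unrecognized (`GCRh37`), so item d
  does not fire but the minor error `unrecognized-build-token` does.
  `hg19`/`hg38` are recognized (d = 0) but raise
  `non-official-build-name`; dual tokens (`GRCh37/hg19`) record both.
* `X`, `x` and `×` are all accepted copy-number markers and never raise
  an error.
* Variant keywords are collected from either portion, including the
  prose words "deletion"/"duplication" — a laboratory that wrote
  "type: heterozygous deletion" did name the variant type.  The
  HGVS-side keyword must follow a ≥6-digit coordinate, so the ISCN
  keyword is not double-counted.

### Minor-error detector inventory

Each detector is independently toggleable; defaults in parentheses.

| detector | fires when | default |
|---|---|---|
| hyphen-range-separator | span joined by `-` instead of `_` | on |
| non-official-build-name | `hg19`/`hg38` used | on |
| unrecognized-build-token | misspelled token in the `seq[…]` slot | on |
| build-not-square-bracketed | build in round brackets or bare | on |
| hash-separator | `#` used as a field separator | on |
| normal-chromosomes-listed | leading `46,XN,` karyotype prefix | on |
| whitespace-inside-hgvs-portion | space inside the HGVS tokens | on |
| band-less-specific-than-reference | submitted band a proper prefix of the reference band (needs a reference) | on |
| variant-type-mismatch-between-portions | ISCN `del` with HGVS `dup` or vice versa | on |
| inverted-range | span start > end | on |
| single-position | `g.` with one coordinate only | **off** |
| hgvs-not-on-own-line | span shares a line with the ISCN portion | **off** |

`single-position` is off for the *j* bucket because item *i* already
deducts for the missing span; double-charging the same defect would be
arbitrary.  The flag is still recorded by the parser.
`hgvs-not-on-own-line` is off because the surveyed cohort was scored
from single-line submissions without that penalty; with it on, nearly
every submission would lose a point the published scores do not show.
This inventory was frozen after validating it row-by-row against all
19 published per-item score rows.

## Canonical generation

`canonical()` emits the gold two-line form (ISCN line, HGVS line); a
single-line variant reproduces the survey answer key's layout.  The
round-trip guarantee — `score(parse(canonical(ref))) = 10` for every
valid reference — is enforced by property tests over randomized
references.  The ISCN 2020 profile implements the three structural
deltas of the newer edition: the HGVS line opens with the genomic
reference-sequence accession, the chromosome is not repeated there,
and GRCh38 is the recommended build.  Accession strings are
assembly-specific user data and are not bundled; the profile raises
without them.  Only these three deltas are implemented; the 2020
edition's further changes are out of scope.

## Survey statistics

* **Score summary.** The mean is reported with the *population* SD
  (divisor n), which is what the survey printed (2.04 for the published
  score vector); the sample SD (2.10) is also exposed.  The 95% CI is
  the t-interval with the sample SD, mean ± t₀.₉₇₅,ₙ₋₁·s/√n — the only
  standard construction that reproduces the published interval
  (6.78, 8.80) from the published scores.
* **Depth of coverage.** fold = reads × read-length × (2 if paired) /
  genome size, with the genome size defaulting to 3.2 Gb (overridable);
  read counts denote pairs in paired mode.  `ln_depth` is the natural
  log at one decimal, matching log-scale depth plots.
* **Rounding.** Summary statistics, composition percentages and depths
  round half-up at two decimals (5.625 → 5.63, not banker's 5.62).
  Cohort error-rate percentages *truncate* at two decimals
  (2/19 → 10.52), the convention evident in the survey's printed rates.
  Both helpers go through `decimal` to avoid binary-float artifacts.

## Synthetic data

`synthetic.make_submission` starts from the canonical string and
applies requested mutations — one per rubric item (drop `seq`, drop the
build, drop `g.`, drop the chromosome, drop arm/band, drop the
keyword, collapse the span to a single position, drop either whole
portion) and one per minor-error class — returning both the mutated
text and the exact breakdown the scorer must produce.  Mutations are
template re-renders of the canonical layout, not edits of arbitrary
dialects, so the ground truth is unambiguous.  A consistency checker
rejects contradictory flag sets (e.g. a hyphen separator in a dropped
span, or a misspelled build with the `seq` anchor removed, since the
misspelling is only attributable as a build via the `seq[…]` slot).
Ground-truth recovery is tested exhaustively for all single flags and
all consistent flag pairs on both reference CNVs.

`make_cohort` draws per-hospital flag sets independently at caller-set
frequencies (identical flags for both CNVs of a hospital, as real
hospitals reused one house format), repairing conflicts
deterministically in inventory order.  `make_survey_counts` draws
referral counts from a multinomial at the observed survey proportions
(0.4187 / 0.3382 / 0.1966 / 0.0465) around a configurable total,
default 36,432.  All generators are `numpy` `default_rng`-seeded and
byte-reproducible.

What the generator does *not* emulate: real free-text phrasing beyond
the observed template families, per-hospital sequencing read-count
distributions, multi-CNV reports, sex-chromosome copy-number
ambiguity, or mosaicism.  Passing the synthetic suites shows the
pipeline is exact on the defined error algebra, not that it covers
every dialect a new laboratory might invent.

## Fixture and I/O conventions

The bundled fixture stores each of the 38 submitted strings verbatim
(ASCII-normalized; the `#` glyphs are part of the submissions) in a
TSV with literal `\n` escapes for line breaks.  One hospital's pair is
stored as two lines each (ISCN line, HGVS line), consistent with its
error-free score under the separate-line rule.  The file is guarded by
a SHA-256 checksum at load.  The italics key of the source table marks
bioinformatics outsourcing and is preserved; the shading key (wet-lab
outsourcing) is not recoverable from text, so that flag is stored as
false throughout — it is metadata only and affects no computation.
Audit reports are emitted as schema-versioned JSON and TSV carrying
identical numbers.

## Known limitations

* The rubric floor/cap, point values and detector toggles are
  configurable, but the defaults are the validated configuration; other
  settings reproduce no published row.
* Band-vs-coordinate cross-validation against a cytoband table is out
  of scope: a submission with a correct band but deviant coordinates
  (observed once in the cohort) is penalized only if a detector such as
  the build alias fires, mirroring the published scoring.
* Balanced rearrangements, SNV/indel HGVS, mosaicism notation and
  liftover between builds are out of scope.
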