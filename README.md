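# cnvnomen

Compliance auditing of clinical copy-number-variant (CNV) nomenclature.

Clinical laboratories reporting CNVs from low-pass whole-genome
sequencing are expected to describe each variant twice: once in ISCN
2016 style for the chromosomal aberration and once in HGVS style for
the nucleotide-level span, e.g. for the recurrent DiGeorge-syndrome
deletion:

```
seq[GRCh37]del(22)(q11.21)
chr22:g.19009792_21452445del
```

In practice, laboratory reports drift into a dozen dialects — missing
`g.` prefixes, `hg19` instead of the official assembly name `GRCh37`,
hyphens instead of underscores in coordinate ranges, karyotype
prefixes, or plain prose.  `cnvnomen` is a rule-based linter and
scoring engine for such strings, built around a national survey of 19
tertiary-hospital laboratories that were each asked to report two
reference CNVs (the 22q11.21 DiGeorge deletion and the 17p12 CMT1A
duplication).

## The rubric

A submission pair earns up to 10 points:

* **a** (+5): an ISCN-like description of the chromosomal aberration is used;
* **b** (+5): an HGVS-like description with the nucleotide span is used;
* **c–i** (−1 each): the sequencing-technology symbol `seq`, the genome
  build, the `g.` prefix, the chromosome, the arm+band, the `del`/`dup`
  keyword, or the coordinate span is missing;
* **j** (−1, capped): any number of minor inconsistencies (hyphen range
  separator, unofficial build alias, unbracketed build, normal
  chromosomes listed, band coarser than the reference, conflicting
  variant types between portions, …) costs a single point in total.

Awards must be earned on **both** strings of a pair; a deduction fires
if observed on **either**.  A pair earning neither award scores 0 and
the deductions are not assessed.  Totals are clamped at 0.

## Worked example

```python
>>> from cnvnomen import parse, score_hospital, DGS_REFERENCE, CMT1_REFERENCE
>>> br = score_hospital(
...     parse("seq[hg19] 22q11.21(18620001_21820000)X1"),
...     parse("seq[hg19] 17p12(14097915_15470903)X3"),
...     refs=(DGS_REFERENCE, CMT1_REFERENCE),
... )
>>> br.total
7
>>> sorted(br.fired_minor_errors)
['non-official-build-name']
```

The coordinate-list dialect earns both awards (a band locus plus a
span), but loses one point for the missing `g.` prefix (item e), one
for never naming the variant type `del`/`dup` (item h), and one minor
point for `hg19`: total 7.

Auditing the bundled 19-hospital survey fixture end to end:

```
$ cnvnomen audit
```

prints per-hospital breakdowns, the error tally
`{"c": 2, "d": 1, "e": 10, "f": 0, "g": 0, "h": 2, "i": 0, "j": 17}`
and the cohort summary (mean 7.79 of 10, 95% CI 6.78–8.80).  The same
pipeline is scripted as a narrative under `analysis/`:

* `01_audit_nomenclature.py` — parse and score the fixture, write
  `results/hospital_scores.tsv` and `results/audit_report.json`;
* `02_survey_statistics.py` — referral composition of the 36,432 annual
  cases, score summary statistics, and depth-of-coverage arithmetic
  (3M single-end 38 bp reads → 0.04-fold; 60M pairs of 150 bp → 5.63-fold);
* `03_synthetic_validation.py` — exhaustive error-injection ground-truth
  recovery and a synthetic survey-like cohort.

Other CLI surfaces: `cnvnomen score`, `cnvnomen generate` (canonical
nomenclature under ISCN 2016 or ISCN 2020 profiles), `cnvnomen synth
submissions` (error-injected cohorts with a ground-truth column), and
`cnvnomen stats` (composition / depth / score summaries).

## Layout

```
src/cnvnomen/     library: model, parser, scorer, canonical, stats,
                  synthetic, io, cli (fixture TSV under data/)
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property, end-to-end)
docs/methods.md   model, conventions, design choices, limitations
```
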