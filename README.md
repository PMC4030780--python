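# triotriage

Trio-exome variant triage for cohorts of fetuses and neonates with structural
abnormalities first seen on prenatal ultrasound.

In such cohorts each affected child (the proband) is sequenced together with
both healthy parents, and the question is which rare coding variant — if any —
explains the malformation. Because the parents are unaffected, the plausible
inheritance models are **dominant de novo** (the child carries an allele absent
from both parental germlines), **autosomal recessive** (homozygous, or
compound-heterozygous with one damaged copy from each parent), and **X-linked
hemizygous** (a carrier mother transmitting to a son). `triotriage` implements
the full triage layer between per-caller VCFs and a per-proband causality
report:

- **merging** of each individual's call sets from several variant callers into
  one normalized (left-aligned, parsimonious, biallelic) call set, with
  majority-vote resolution of genotype discordance;
- a **de novo screen** — proband carries ≥1 alt allele, both parents are
  confidently homozygous reference (alt-supporting reads ≤ a cap), site rare
  (MAF < 1% or absent from reference databases) — plus validation bookkeeping
  (every candidate is assumed to go to orthogonal confirmation), **twin-aware
  independence collapse** (an identical variant in monozygotic twins is one
  mutational event), and **mosaicism flagging** via an exact two-sided binomial
  test of the alt-read fraction against the heterozygous expectation of 0.5;
- **inherited screens** under the recessive and X-linked models, restricted to
  rare (MAF < 1%) variants with a functional consequence (essential splice
  site, stop gained, frameshift, non-synonymous, stop lost); compound
  heterozygotes are phased by parental transmission — a variant's origin is the
  unique parent carrying it, and a gene qualifies only with one confidently
  maternal and one confidently paternal hit (or one inherited hit paired with a
  validated de novo "second hit");
- a **CNV filter** for externally called copy-number variants: confidence cut,
  reciprocal-overlap match against a common-CNV catalog, protein-coding gene
  overlap, and mode-of-inheritance consistency;
- an **evidence classifier**: a decision tree mapping curated per-gene evidence
  (known disease gene, previously reported pathogenic variant, damaging variant
  class in a known domain, dosage sensitivity, model-organism support,
  functional plausibility) and the proband's HPO phenotype onto three
  categories — *highly likely causal*, *possibly causal*, *unknown* — with
  phenotype match scored as an ancestor-closure overlap
  `|closure(A) ∩ closure(B)| / min(|closure(A)|, |closure(B)|)` on the HPO DAG;
- **cohort statistics**: exact one-sided binomial test for depletion of
  synonymous de novo variants below the expected 29% fraction
  (P = Σ_{i≤k} C(n,i) p^i (1−p)^{n−i}), a uniform-rate recurrent-gene
  probability P(≥2 hits) = 1 − (1+λ)e^{−λ} with λ = n·L/E, and per-proband
  candidate-count summaries;
- a **synthetic cohort generator** that emits the same file dialects with a
  ground-truth table (Hardy-Weinberg parents, Mendelian transmission, Poisson
  de novo events at 1.1/proband with a 29% synonymous fraction, MZ-twin
  genotype identity, mosaic allele fractions, per-caller dropout), so every
  stage is testable without controlled-access data.

A packaged fixture encodes a published 30-proband cohort's candidate-gene
table, curated evidence, and phenotypes against a synthetic miniature HPO.

## Worked example

```python
from triotriage.fixtures import (
    classify_fixture_cohort, load_fixture_cohort, validated_denovo_candidates,
)
from triotriage.denovo import collapse_independent
from triotriage.stats import recurrent_gene_probability, synonymous_enrichment_test

records, summary = classify_fixture_cohort()
print(summary.counts)    # {'unknown': 22, 'possibly': 5, 'highly_likely': 3}
print(summary.percent)   # {'unknown': 73, 'possibly': 17, 'highly_likely': 10}

cohort = load_fixture_cohort()
collapsed = collapse_independent(validated_denovo_candidates(cohort), cohort)
independent = [c for c in collapsed if c.independent]
print(len(independent))  # 33  (34 validated events, one shared by MZ twins)

n_syn = sum(1 for c in independent if c.trio.site.consequence.value == "synonymous")
print(n_syn, synonymous_enrichment_test(len(independent), n_syn))
# 3 0.0058563443525524485

print(recurrent_gene_probability(3600, len(independent) - n_syn))
# (6.464468975060037e-06, 2.5e-06)
```

Reading the output: of the 30 probands, 3 (10%) carry a candidate classified
highly likely causal (a de novo missense in a known skeletal-dysplasia gene
whose identical variant is already reported pathogenic; a de novo glycine
substitution in a collagen triple-helical domain; a de novo whole-gene
deletion of a dosage-sensitive disease gene), and 5 more (17%) carry possibly
causal candidates. The 34 validated de novo events collapse to 33 independent
ones, of which only 3 are synonymous — significantly fewer than the 29%
expected by chance (one-sided exact P ≈ 0.006), i.e. functional de novo
mutations are enriched. A gene of 3.6 kb coding sequence hit twice by the 30
functional de novos has chance probability ≈ 6.5 × 10⁻⁶, just above the
Bonferroni threshold for all genes (0.05 / 20,000 = 2.5 × 10⁻⁶).

## Command line

```bash
triotriage simulate --seed 1 --out sim/          # synthetic cohort + truth table
triotriage merge sample.c1.vcf sample.c2.vcf --out merged.vcf
triotriage run-all --config analysis.yaml        # merge → screens → CNVs → classify → stats
```

Subcommands `denovo`, `inherited`, `cnv`, `classify`, and `stats` run the same
pipeline and report the corresponding stage; composing stages over
intermediate files yields byte-identical reports to `run-all`.

## Layout

| Module | Role |
| --- | --- |
| `triotriage.cohort_io` | pedigree (PED + MZ-twin column), phenotype TSV, VCF I/O, caller merging, normalization |
| `triotriage.simulate` | synthetic cohort generator + truth table |
| `triotriage.denovo` | de novo screen, validation, independence collapse, mosaic flag |
| `triotriage.inherited` | homozygous / compound-het / hemizygous screens |
| `triotriage.cnv` | CNV filtering, mode assignment, span arithmetic |
| `triotriage.classify` | HPO overlap, decision tree, cohort summary |
| `triotriage.stats` | exact binomial depletion test, recurrence probability, count summaries |
| `triotriage.pipeline` / `triotriage.cli` | end-to-end orchestration and subcommands |

See `docs/methods.md` for the modelling choices, defaults, and limitations.
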