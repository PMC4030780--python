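# Methods

This note documents the models, defaults, and design choices behind
`triotriage`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Call-set merging and normalization

Per-caller call sets for one individual are merged by site identity
(chrom, pos, ref, alt) after every record has been left-aligned and trimmed to
its minimal representation and multiallelic records split per alternate
allele. Site identity across callers and individuals is only well defined on
normalized records, which is why normalization is a precondition of every
screen. The normalization algorithm is the standard one: trim shared allele
suffixes (extending leftward with reference bases whenever an allele would
become empty), then trim shared prefixes; it is idempotent and converges to
the left-most parsimonious spelling, verified in tests against brute-force
enumeration of equivalent representations on a toy sequence.

Genotype discordance between callers has no published resolution rule in the
workflow this package re-implements, so an explicit one is defined: majority
vote across callers, two-way ties resolved toward the **less severe** call
(het over hom-alt, reference over het), with a `discordant` flag retained so
downstream consumers can filter on it. The merged record keeps the allele
depths of the deepest supporting record; the `callers` field is the union of
contributing labels. The merge is invariant under permutation of its inputs
(property-tested), which a first-wins rule would not be.

A site absent from an individual's merged call set is treated as **missing**,
not homozygous reference: an absent record cannot be distinguished from a
coverage hole. Trio rows with a missing parental genotype are skipped with a
logged reason; the synthetic generator therefore emits explicit
homozygous-reference records for every family member at any site where some
member carries an alternate allele, mirroring joint-calling output.

Coordinates are 1-based inclusive everywhere, including the BED-like gene and
CNV tables (documented in their readers), so that printed genomic intervals
like `g.13770686_13791294del` can be used verbatim: that deletion spans
13 791 294 − 13 770 686 + 1 = 20 609 bp ≈ 21 kb.

## De novo screen

The screen is a transparent threshold rule rather than a probabilistic joint
caller: a candidate requires the proband to carry an alternate allele while
both parents are reference calls. Defaults: child depth ≥ 10 and GQ ≥ 20,
parent depth ≥ 10, at most **1** alt-supporting read in either parent,
population frequency ≤ 1% (a frequency missing from reference databases
passes as rare but is flagged upstream), consequence within coding/splicing
(synonymous included — the de novo screen is consequence-agnostic inside
coding sequence; the functional restriction belongs to the inherited
screens). The depth floor of 10 reads echoes the conventional coverage
benchmark for exome studies; the remaining values are conventional and fully
configurable. The candidate score is min(child GQ, parental GQs).

The screen is deliberately high-sensitivity / low-specificity; the workflow
it implements validates every candidate orthogonally, and
`apply_validation` excludes refuted candidates from all downstream sets. On
simulation, a shallow noisy preset (mean depth 6, base error 2%, 5% caller
dropout) produces false candidates — parental heterozygotes whose sampled
allele depths contain no alternate reads — and truth-driven validation
removes exactly those, reproducing the candidate-funnel structure.

**Independence collapse.** An identical (chrom, pos, ref, alt) candidate in
both members of a monozygotic twin pair is one germline mutational event: the
twin with the lexically smaller identifier keeps `independent=True`. The same
variant in unrelated probands remains two events.

**Mosaicism.** `mosaic_p` is the exact two-sided binomial probability of the
observed alt-read count at expected fraction 0.5; the flag requires both
p < α (default 0.01) and an alt fraction **below** 0.5, since a depleted alt
fraction is the somatic-mosaicism signature while the enriched side is not.
The direction restriction and α are package choices (the emulated workflow
reported mosaicism only as "suggestive", without criteria).

## Inherited screens

"Functional" is exactly the five-class list {essential splice site, stop
gained, frameshift coding, non-synonymous, stop lost}; synonymous and other
never qualify. Rarity is MAF < 1%, with missing MAF treated as rare.

Compound heterozygotes are phased by transmission, not reads: a variant's
parental origin is the unique parent carrying the allele; a variant carried
by both parents is ambiguous and cannot anchor either side of a pair, though
it is listed alongside a qualifying pair. A gene qualifies with ≥1
confidently maternal and ≥1 confidently paternal rare functional het — or
with one confident inherited het plus a validated de novo in the same gene
(the "second hit" configuration, emitted with a mixed-origin note). The
screen is verified against an exhaustive pair-enumeration oracle on 1,000
random gene instances.

X-linked hemizygous candidates require a male proband hemizygous for the
alternate allele outside the pseudoautosomal regions (GRCh37-like defaults,
configurable), a het carrier mother, and a hemizygous-reference father.
Female probands are never screened hemizygously; their X candidates surface
through the homozygous / compound-het screens run on chrX (on X the
"homozygous" configuration accepts a hemizygous-alt father in place of a het
father, since that is the only way a female can inherit a paternal X allele).

## CNV filter

CNV detection is out of scope; calls arrive as a table with a confidence
score and per-member carrier status. Four independent predicates — and
therefore order-commuting, which is property-tested — keep a call:
confidence ≥ cut, no common-catalog interval at ≥ 50% reciprocal overlap
(field convention; configurable), ≥ 1 protein-coding gene overlapped, and an
assigned mode in {de novo, recessive, X-linked}. Mode assignment checks
de novo first, so a proband-only X call in a female is de novo rather than
X-linked. The default confidence cut (10.0) is the 99th percentile of the
synthetic generator's noise-score distribution (Normal(5, 2)); with real
caller scores it must be recalibrated.

## Evidence classifier

The decision tree reconstructs a manual curation workflow from its worked
outcomes rather than from a published flowchart, so every branch and cutoff
is exposed in `ClassifierConfig` and the contract is behavioral: the packaged
fixture must reproduce all narrated category assignments exactly, which the
test suite checks per gene.

Phenotype match between a proband's HPO set and a known disorder's HPO set is
the ancestor-closure overlap `|A∩B| / min(|A|,|B|)` with ontology roots
excluded; ≥ 0.5 is a match, [0.2, 0.5) a partial match. The min-normalization
makes a disorder whose full term set is contained in a richly annotated
proband score 1.0. The cutoffs are explicit stand-ins for expert judgment and
deliberately tunable.

Branches: *highly likely* requires a known human disease gene, a phenotype
match, and variant-level support — an identical variant previously reported
pathogenic, a damaging variant class in a known domain (the
glycine-in-triple-helix archetype), or a mode-consistent whole-gene loss
(CNV) in a dosage-sensitive known gene. The dosage branch is why
`GeneEvidence` carries a `dosage_sensitive` flag and why CNV-supported
records pass their mode as `cnv_*`. *Possibly* catches known genes with
partial (or match-without-variant-support) phenotype overlap, model-organism
phenotype overlap, or functional plausibility with phenotype relevance
(relevant expression or at least partial match). Everything else is
*unknown* — including a known disease gene whose disorder does not match the
proband's phenotype, and genes whose model-organism data the curator judged
insufficient (encoded as an all-false evidence row). Adding a true evidence
flag can never demote a category (property-tested).

A proband's cohort-level category is the most severe among its records;
fractions are over all analyzed probands and reported as nearest-integer
percentages (3/30 → 10%, 5/30 → 17%).

## Cohort statistics

The synonymous-depletion test is an exact one-sided lower-tail binomial sum
at the expected synonymous fraction p = 0.29, applied to the independent
(post-collapse) de novo events: depletion of synonymous variants is the
direction of the claim (enrichment of functional ones). For the packaged
cohort (3 of 33) it gives P = 0.005856; a two-sided test over all 34
validated events gives 0.0074, so printed figures near 0.007 are consistent
with either convention — this package fixes the one-sided form and documents
the alternative here.

The recurrent-gene probability uses a uniform mutation-rate-per-bp model:
each of n functional de novo events lands in a gene of coding length L with
probability L/E (E = 30 Mb coding exome), so the gene's hit count is
≈ Poisson(λ = nL/E) and P(≥2) = 1 − (1+λ)e^{−λ}. The closed form is verified
against 10⁶-replicate Monte Carlo placement within 3 standard errors. A
published figure computed under an unknown, possibly sequence-context-aware
rate model will differ from this uniform-model value; the uniform model is
kept because it is transparent and oracle-checkable. The Bonferroni threshold
is α/n_genes = 0.05/20 000 = 2.5 × 10⁻⁶ exactly.

## Synthetic cohort generator

The generator's defaults are the study conditions of the emulated cohort: 26
trios plus one sibling quad and one MZ-twin quad (30 probands, 86
individuals), mean target depth 103×, three callers, de novo events at
Poisson(1.1) per proband with a 29% synonymous fraction (functional de novos
split 86.7% missense / 10% nonsense / 3.3% splice, matching the observed
composition of validated sets), two compound-het genes, one homozygous gene,
and one hemizygous gene (males) injected per proband, and mosaic de novos at
rate 0.06 with alt fraction 0.15. MZ twins receive identical genotypes
including their de novo events; allele depths are sampled independently per
twin (different tissue samples). Background sites get population frequencies
from Beta(0.3, 3) — a pragmatic mix of rare and common variation; no
frequency spectrum was published for the emulated data — with Hardy-Weinberg
parents and Mendelian transmission.

Two deliberate departures from naive simulation:

1. **Benign background stays benign.** Chance configurations in background
   variation that would satisfy a screen (a rare functional homozygote, a
   chance compound-het pair, a chance male X carrier) are demoted at
   generation time by adjusting the child genotype. This makes the truth
   table the *exact* expectation of the screens at noiseless settings, so
   recovery tests can assert set equality (sensitivity 1.0, zero false
   genes) instead of statistical closeness. The cost is a slight local
   violation of Mendelian sampling at a handful of rare sites.
2. **Genotype calls are depth-driven.** Each member's called genotype equals
   the truth unless the sampled allele depths are uninformative (a het with
   zero alt reads is called hom-ref) or misleading (a ref-homozygote with ≥3
   alt reads at ≥20% fraction is called het). At the default 103× depth these
   miscalls essentially never occur; at the shallow noisy preset they
   generate the false de novo candidates the validation funnel test relies
   on.

What the generator does **not** model: reads and alignment, caller-specific
error profiles (the three callers differ only by independent dropout),
sequence-context mutation-rate variation, linkage between background sites,
population structure (every family is drawn from one panmictic population —
the ancestry-outlier effect seen in real cohorts, where one family of a
different ancestry accumulates spuriously "rare" variants, is not emulated),
and segmental duplication artifacts in CNV calls. Passing recovery tests
therefore demonstrates the correctness of the screening logic, not the
field performance of the thresholds on real exomes.

Problem sizes used by the test suite: the recovery and calibration tests run
the full default cohort (30 probands, 1,500 background sites, three callers);
rate-convergence tests use 900 trios with injections only; the oracle suites
use 1,000 random gene instances and 10⁶ Monte Carlo replicates. The whole
suite completes in well under a minute.

## Packaged fixture

`triotriage/fixtures/` encodes a published 30-proband cohort as plain text:
the pedigree (including the MZ twin pair sharing one identical de novo
variant, and a sibling pair), the per-proband candidate-gene table with 34
validated de novo events (3 synonymous among the 33 independent), inherited
candidate genes (mean 5.3 distinct genes per proband, range 0–15 — one
proband carries the same gene under two modes, counted once), three
gene-overlapping CNVs, curated evidence rows for the twelve narrated genes
(all other genes default to no-evidence), and per-proband HPO sets. SNV/indel
coordinates in the fixture are synthetic placeholders; only their identity
structure (the twin-shared variant) and consequence classes carry
information. The ontology is a synthetic ~60-term miniature shaped like the
HPO (file `hpo_mini_synthetic.obo`), built so closure-overlap scores are
small auditable sets; disease and proband term sets were chosen so that each
narrated phenotype relationship (full match, partial match, mismatch) holds
under the default cutoffs.

## Known limitations

- Compound-het phasing by transmission cannot resolve two variants both
  carried by both parents; read-backed or population phasing would.
- The classifier consumes a curated evidence table; it performs no literature
  or database queries, so its output is only as good as the curation.
- The recurrence model ignores gene-specific mutability.
- The CNV confidence scale is caller-specific; the default cut is calibrated
  to the synthetic noise model only.
- X-linked logic assumes a standard karyotype; sex-chromosome aneuploidies
  are out of scope.
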