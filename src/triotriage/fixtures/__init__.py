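"""Packaged cohort fixture: a 30-proband fetal structural-abnormality cohort.

The fixture encodes, as plain-text tables, the published candidate-gene
landscape of a trio-exome cohort of 30 fetuses and neonates (26 trios and two
quads, including one monozygotic twin pair): per-proband candidate genes by
inheritance mode (34 validated de novo events, inherited compound-het /
homozygous / hemizygous genes, and three gene-overlapping CNVs), curated
per-gene evidence flags, and per-proband phenotype term sets.

The accompanying ontology (``hpo_mini_synthetic.obo``) is a synthetic
miniature shaped like the Human Phenotype Ontology — HP-style identifiers
over a small organ-system DAG — built so that phenotype-overlap scores are
small, auditable closures rather than a 17,000-term graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import networkx as nx

from triotriage import classify as _classify
from triotriage.cohort_io import (
    Cohort,
    Consequence,
    Genotype,
    GenotypeObservation,
    TrioGenotypes,
    VariantSite,
    read_pedigree,
    read_phenotypes,
)
from triotriage.denovo import DeNovoCandidate

__all__ = [
    "fixture_path",
    "load_fixture_cohort",
    "load_fixture_phenotypes",
    "load_fixture_ontology",
    "load_fixture_evidence",
    "load_fixture_candidates",
    "validated_denovo_candidates",
    "classify_fixture_cohort",
    "CandidateRow",
]


def fixture_path(name: str) -> Path:
    return Path(str(files("triotriage.fixtures") / name))


@dataclass(frozen=True)
class CandidateRow:
    proband_id: str
    gene: str
    mode: str  # de_novo | compound_het | homozygous | hemizygous | cnv_*
    variant: str | None  # "chrom:pos:ref:alt" for SNV/indel, "chrom:start:end:type" for CNV
    consequence: str | None
    note: str | None


def load_fixture_cohort() -> Cohort:
    return read_pedigree(fixture_path("cohort.ped"))


def load_fixture_phenotypes() -> dict[str, set[str]]:
    return {r.proband_id: r.hpo_terms for r in read_phenotypes(fixture_path("cohort_phenotypes.tsv"))}


def load_fixture_ontology() -> nx.MultiDiGraph:
    return _classify.load_ontology(fixture_path("hpo_mini_synthetic.obo"))


def load_fixture_evidence() -> dict[str, _classify.GeneEvidence]:
    return _classify.read_evidence_table(fixture_path("gene_evidence.tsv"))


def load_fixture_candidates() -> list[CandidateRow]:
    rows: list[CandidateRow] = []
    for line in fixture_path("table1_candidates.tsv").read_text().splitlines()[1:]:
        if not line.strip():
            continue
        pid, gene, mode, variant, csq, note = line.split("\t")
        rows.append(
            CandidateRow(
                proband_id=pid,
                gene=gene,
                mode=mode,
                variant=None if variant == "." else variant,
                consequence=None if csq == "." else csq,
                note=None if note == "." else note,
            )
        )
    return rows


def validated_denovo_candidates(cohort: Cohort | None = None) -> list[DeNovoCandidate]:
    """The 34 validated de novo events as fully formed candidate records.

    Variant coordinates are synthetic placeholders; what matters downstream
    is their identity structure — in particular the identical variant shared
    by the monozygotic twin pair — and their consequence classes.
    """
    cohort = cohort or load_fixture_cohort()
    out: list[DeNovoCandidate] = []
    for row in load_fixture_candidates():
        if row.mode != "de_novo":
            continue
        chrom, pos, ref, alt = row.variant.split(":")
        site = VariantSite(
            chrom=chrom,
            pos=int(pos),
            ref=ref,
            alt=alt,
            gene=row.gene,
            consequence=Consequence(row.consequence),
            population_af=None,
        )
        mother, father = cohort.parents_of(row.proband_id)

        def obs(ind: str, gt: Genotype) -> GenotypeObservation:
            ad_alt = 50 if gt.carries_alt else 0
            return GenotypeObservation(
                individual_id=ind, gt=gt, ad_ref=100 - ad_alt, ad_alt=ad_alt,
                depth=100, gq=99, callers=frozenset({"merged"}),
            )

        trio = TrioGenotypes(
            site=site,
            proband=obs(row.proband_id, Genotype.het),
            mother=obs(mother.individual_id, Genotype.hom_ref),
            father=obs(father.individual_id, Genotype.hom_ref),
        )
        out.append(
            DeNovoCandidate(
                trio=trio, proband_id=row.proband_id, score=99,
                validation_status="validated",
            )
        )
    return out


def classify_fixture_cohort() -> tuple[list[tuple[str, str, str, _classify.Classification]], _classify.CohortSummary]:
    """Classify every proband-gene candidate record and summarize the cohort.

    Returns the per-record classifications and the cohort summary whose
    ``percent`` field is the diagnostic-yield report (nearest-integer
    percentages of probands per best category).
    """
    cohort = load_fixture_cohort()
    phenotypes = load_fixture_phenotypes()
    ontology = load_fixture_ontology()
    evidence = load_fixture_evidence()
    records = []
    per_proband: dict[str, list[_classify.Classification]] = {}
    for row in load_fixture_candidates():
        ev = evidence.get(row.gene, _classify.GeneEvidence(gene=row.gene))
        cls = _classify.classify_variant_gene(
            ev, row.mode, phenotypes.get(row.proband_id, set()), ontology
        )
        records.append((row.proband_id, row.gene, row.mode, cls))
        per_proband.setdefault(row.proband_id, []).append(cls)
    summary = _classify.summarize_cohort(per_proband, cohort)
    return records, summary
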