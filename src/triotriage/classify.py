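"""Evidence-based three-way classification of candidate genes.

Each candidate gene in a proband is mapped, against a curated evidence record
and the proband's HPO phenotype, to one of three causality categories:
``highly_likely``, ``possibly``, or ``unknown``.  The decision tree mirrors
the manual curation workflow of clinical trio studies (evidence sources of
the OMIM / DDG2P / model-organism-database kind are consumed as a prepared
table, never queried live):

highly_likely
    the gene is a known human disease gene, the proband's phenotype matches
    the known disorder, and at least one of: the identical variant was
    previously reported pathogenic; the variant belongs to a damaging class
    in a known domain (e.g. a glycine substitution in a triple-helical
    collagen domain); or the variant is a mode-consistent whole-gene loss
    (a de novo / recessive / X-linked CNV) in a dosage-sensitive known gene.

possibly
    not highly_likely, and at least one of: known disease gene with partial
    phenotype match; model-organism phenotype overlap; or functional
    plausibility with phenotype relevance (relevant expression or at least a
    partial phenotype match).

unknown
    everything else.

Phenotype match is computed on the HPO DAG: the ancestor closures (root
excluded) of the proband and disease term sets are intersected and scored as
``|A∩B| / min(|A|, |B|)``; a score >= ``match_cutoff`` (default 0.5) is a
match, a score in the partial band (default [0.2, 0.5)) a partial match.
Every cutoff is exposed so an alternative tree can be encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from triotriage.cohort_io import Cohort

__all__ = [
    "GeneEvidence",
    "Classification",
    "CohortSummary",
    "ClassifierConfig",
    "load_ontology",
    "ancestor_closure",
    "phenotype_overlap",
    "classify_variant_gene",
    "summarize_cohort",
    "read_evidence_table",
    "write_classification_report",
    "CATEGORY_ORDER",
]

#: Severity order; higher index = more severe.
CATEGORY_ORDER = ("unknown", "possibly", "highly_likely")

#: Inheritance modes under which a CNV loss can support the dosage branch.
CNV_LOSS_MODES = frozenset({"cnv_de_novo", "cnv_recessive", "cnv_x_linked"})


@dataclass(frozen=True)
class GeneEvidence:
    gene: str
    known_human_disease_gene: bool = False
    disease_hpo: frozenset[str] = frozenset()
    identical_variant_reported_pathogenic: bool = False
    damaging_variant_class_in_known_domain: bool = False
    dosage_sensitive: bool = False
    model_organism_phenotype_overlap: bool = False
    functional_plausibility: bool = False
    expression_relevant: bool = False

    def __post_init__(self) -> None:
        if self.disease_hpo and not self.known_human_disease_gene:
            raise ValueError(
                f"{self.gene}: disease_hpo must be empty when known_human_disease_gene is False"
            )


@dataclass
class Classification:
    category: str
    rationale: list[str] = field(default_factory=list)
    phenotype_score: float = 0.0


@dataclass
class ClassifierConfig:
    match_cutoff: float = 0.5
    partial_low: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.partial_low <= self.match_cutoff <= 1:
            raise ValueError("need 0 <= partial_low <= match_cutoff <= 1")


@dataclass
class CohortSummary:
    per_proband: dict[str, str]  # proband_id -> best category
    counts: dict[str, int]
    fractions: dict[str, float]
    percent: dict[str, int]  # nearest-integer percentages
    n_probands: int


def load_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Load an OBO ontology (edges point child -> parent, obonet convention)."""
    return obonet.read_obo(str(path))


def _roots(graph: nx.MultiDiGraph) -> set[str]:
    return {n for n in graph.nodes if graph.out_degree(n) == 0}


def ancestor_closure(graph: nx.MultiDiGraph, terms: Iterable[str]) -> set[str]:
    """Union of each term and all its ancestors, with ontology roots excluded."""
    closure: set[str] = set()
    for t in terms:
        if t not in graph:
            raise KeyError(f"unknown ontology term {t!r}")
        closure.add(t)
        closure.update(nx.descendants(graph, t))  # child->parent edges: ancestors
    return closure - _roots(graph)


def phenotype_overlap(
    proband_terms: Iterable[str],
    disease_terms: Iterable[str],
    ontology: nx.MultiDiGraph,
    match_cutoff: float = 0.5,
) -> tuple[float, bool]:
    """Closure-overlap score in [0, 1] and a match flag at ``match_cutoff``.

    score = |closure(A) ∩ closure(B)| / min(|closure(A)|, |closure(B)|),
    where closures include the terms themselves and all ancestors below the
    ontology root.  Two disjoint branches sharing only the root score 0.
    """
    a = ancestor_closure(ontology, proband_terms)
    b = ancestor_closure(ontology, disease_terms)
    if not a or not b:
        return 0.0, False
    score = len(a & b) / min(len(a), len(b))
    return score, score >= match_cutoff


def classify_variant_gene(
    evidence: GeneEvidence,
    mode: str,
    proband_terms: Iterable[str],
    ontology: nx.MultiDiGraph,
    config: ClassifierConfig | None = None,
) -> Classification:
    """Run the decision tree for one proband-gene record.

    ``mode`` is the inheritance mode of the supporting variant(s):
    de_novo | compound_het | homozygous | hemizygous | cnv_de_novo |
    cnv_recessive | cnv_x_linked.  The rationale names every satisfied branch
    so identical inputs always yield an identical trace.
    """
    cfg = config or ClassifierConfig()
    rationale: list[str] = []
    score = 0.0
    if evidence.known_human_disease_gene and evidence.disease_hpo:
        score, match = phenotype_overlap(
            proband_terms, evidence.disease_hpo, ontology, cfg.match_cutoff
        )
    else:
        match = False
    partial = cfg.partial_low <= score < cfg.match_cutoff
    phenotype_relevant = score >= cfg.partial_low or evidence.expression_relevant

    if evidence.known_human_disease_gene and match:
        rationale.append("known disease gene with phenotype match")
        if evidence.identical_variant_reported_pathogenic:
            rationale.append("identical variant previously reported pathogenic")
            return Classification("highly_likely", rationale, score)
        if evidence.damaging_variant_class_in_known_domain:
            rationale.append("damaging variant class in known domain")
            return Classification("highly_likely", rationale, score)
        if mode in CNV_LOSS_MODES and evidence.dosage_sensitive:
            rationale.append("mode-consistent loss in dosage-sensitive known gene")
            return Classification("highly_likely", rationale, score)

    if evidence.known_human_disease_gene and (partial or match):
        rationale.append(
            "known disease gene with partial phenotype match"
            if partial
            else "known disease gene with phenotype match but no variant-level support"
        )
        return Classification("possibly", rationale, score)
    if evidence.model_organism_phenotype_overlap:
        rationale.append("model-organism phenotype overlap")
        return Classification("possibly", rationale, score)
    if evidence.functional_plausibility and phenotype_relevant:
        rationale.append("functional plausibility with phenotype relevance")
        return Classification("possibly", rationale, score)

    rationale.append("insufficient evidence")
    return Classification("unknown", rationale, score)


def summarize_cohort(
    classifications: Mapping[str, Sequence[Classification]],
    cohort: Cohort,
) -> CohortSummary:
    """Cohort diagnostic yield: per-proband best category and fractions.

    A proband's category is the most severe among its proband-gene records
    (highly_likely > possibly > unknown); probands with no candidates count
    as unknown.  Fractions use all cohort probands as the denominator; the
    reported percentages are rounded to the nearest integer.
    """
    probands = [p.individual_id for p in cohort.probands]
    if not probands:
        raise ValueError("cohort has no probands: diagnostic yield undefined")
    unknown_keys = set(classifications) - set(probands)
    if unknown_keys:
        raise ValueError(f"classifications for unknown probands: {sorted(unknown_keys)}")
    per_proband: dict[str, str] = {}
    for pid in probands:
        records = classifications.get(pid, ())
        best = max(
            (CATEGORY_ORDER.index(c.category) for c in records),
            default=0,
        )
        per_proband[pid] = CATEGORY_ORDER[best]
    counts = {cat: sum(1 for v in per_proband.values() if v == cat) for cat in CATEGORY_ORDER}
    n = len(probands)
    fractions = {cat: counts[cat] / n for cat in CATEGORY_ORDER}
    percent = {cat: int(fractions[cat] * 100 + 0.5) for cat in CATEGORY_ORDER}
    return CohortSummary(
        per_proband=per_proband, counts=counts, fractions=fractions, percent=percent, n_probands=n
    )


# ---------------------------------------------------------------------------
# Evidence table I/O
# ---------------------------------------------------------------------------

_BOOL_COLS = (
    "known_human_disease_gene",
    "identical_variant_reported_pathogenic",
    "damaging_variant_class_in_known_domain",
    "dosage_sensitive",
    "model_organism_phenotype_overlap",
    "functional_plausibility",
    "expression_relevant",
)


def read_evidence_table(path: str | Path) -> dict[str, GeneEvidence]:
    """Read a curated gene-evidence TSV into a dict keyed by gene symbol.

    Columns: gene, the seven boolean flags, and ``disease_hpo`` as a
    ';'-separated HPO term list.  Genes absent from the table default to an
    all-false record (no curated evidence).
    """
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    col = {name: header.index(name) for name in ("gene", "disease_hpo", *_BOOL_COLS)}
    out: dict[str, GeneEvidence] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        kwargs = {name: parts[col[name]] == "1" for name in _BOOL_COLS}
        hpo_field = parts[col["disease_hpo"]]
        out[parts[col["gene"]]] = GeneEvidence(
            gene=parts[col["gene"]],
            disease_hpo=frozenset(t for t in hpo_field.split(";") if t and t != "."),
            **kwargs,
        )
    return out


def write_evidence_table(evidence: Iterable[GeneEvidence], path: str | Path) -> None:
    header = "\t".join(["gene", "disease_hpo", *_BOOL_COLS])
    rows = [header]
    for ev in evidence:
        rows.append(
            "\t".join(
                [
                    ev.gene,
                    ";".join(sorted(ev.disease_hpo)) or ".",
                    *(str(int(getattr(ev, c))) for c in _BOOL_COLS),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_classification_report(
    records: Sequence[tuple[str, str, str, Classification]],
    summary: CohortSummary,
    path: str | Path,
) -> None:
    """Write a per-proband-gene classification TSV plus a summary footer."""
    rows = ["proband_id\tgene\tmode\tcategory\tphenotype_score\trationale"]
    for pid, gene, mode, cls in records:
        rows.append(
            f"{pid}\t{gene}\t{mode}\t{cls.category}\t{cls.phenotype_score:.3f}\t"
            + "; ".join(cls.rationale)
        )
    rows.append("")
    rows.append(f"# probands analyzed: {summary.n_probands}")
    for cat in reversed(CATEGORY_ORDER):
        rows.append(f"# {cat}: {summary.counts[cat]} ({summary.percent[cat]}%)")
    Path(path).write_text("\n".join(rows) + "\n")
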