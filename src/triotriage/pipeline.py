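"""End-to-end orchestration: merge -> trio screens -> CNV filter ->
classification -> cohort statistics, from a single serializable config.

Every stage is also callable on its own (the CLI exposes each as a
subcommand); running the stages individually over intermediate files yields
the same reports as a single-shot run, because each stage communicates only
through the documented file formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from triotriage import classify as _classify
from triotriage import stats as _stats
from triotriage.cnv import filter_cnvs, read_cnv_table, read_gene_model, write_cnv_table
from triotriage.cohort_io import (
    CALLER_LABELS,
    Cohort,
    IndividualCallset,
    build_trios,
    merge_caller_calls,
    read_caller_vcf,
    read_pedigree,
    read_phenotypes,
    write_callset_tsv,
)
from triotriage.denovo import (
    ScreenThresholds,
    apply_validation,
    collapse_independent,
    flag_mosaic,
    screen_denovo,
)
from triotriage.inherited import (
    group_trios_by_gene,
    screen_compound_het,
    screen_hemizygous,
    screen_homozygous,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline", "read_validation_table"]


@dataclass
class AnalysisConfig:
    """Paths and tunables for a full run.  Round-trips through YAML."""

    pedigree: str
    phenotypes: str
    calls_dir: str  # contains <individual>.<caller>.vcf
    output_dir: str
    callers: tuple[str, ...] = CALLER_LABELS
    cnvs: str | None = None
    common_cnvs: str | None = None
    gene_model: str | None = None
    evidence: str | None = None
    ontology: str | None = None
    validation: str | None = None  # de novo validation statuses
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    stats: _stats.StatsConfig = field(default_factory=_stats.StatsConfig)
    classifier: _classify.ClassifierConfig = field(default_factory=_classify.ClassifierConfig)
    cnv_min_confidence: float = 10.0
    cnv_reciprocal_overlap: float = 0.5
    mosaic_alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, typ in (
            ("thresholds", ScreenThresholds),
            ("stats", _stats.StatsConfig),
            ("classifier", _classify.ClassifierConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        if "callers" in raw:
            raw["callers"] = tuple(raw["callers"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["callers"] = list(d["callers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class PipelineResult:
    cohort: Cohort
    merged: dict[str, IndividualCallset]
    denovo_candidates: list
    denovo_validated: list
    inherited_candidates: list
    cnv_kept: list
    classifications: dict[str, list]
    summary: _classify.CohortSummary | None
    stats_report: dict


def read_validation_table(path: str | Path) -> dict[tuple[str, str, int, str, str], str]:
    """TSV: proband_id, chrom, pos, ref, alt, status(validated|refuted|candidate)."""
    out: dict[tuple[str, str, int, str, str], str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "proband_id\t")):
            continue
        p = line.split("\t")
        out[(p[0], p[1], int(p[2]), p[3], p[4])] = p[5]
    return out


def merge_stage(config: AnalysisConfig, cohort: Cohort) -> dict[str, IndividualCallset]:
    calls_dir = Path(config.calls_dir)
    merged: dict[str, IndividualCallset] = {}
    for member in cohort.members:
        callsets = []
        for caller in config.callers:
            p = calls_dir / f"{member.individual_id}.{caller}.vcf"
            if p.exists():
                callsets.append(read_caller_vcf(p, caller))
        if callsets:
            merged[member.individual_id] = merge_caller_calls(callsets)
        else:
            logger.warning("no call files found for %s", member.individual_id)
    return merged


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``output_dir``.

    Reports: a per-proband candidate-gene table (one column per inheritance
    mode), the classification report with the cohort yield summary, a
    statistics JSON, and a run log echoing the resolved config.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(outdir / "resolved_config.yaml")

    cohort = read_pedigree(config.pedigree)
    phenotypes = {r.proband_id: r.hpo_terms for r in read_phenotypes(config.phenotypes)}

    # merge per-caller call sets per individual
    merged = merge_stage(config, cohort)
    for ind, cs in sorted(merged.items()):
        write_callset_tsv(cs, outdir / f"merged.{ind}.tsv")

    trios_by_proband = build_trios(cohort, merged)

    # de novo screen + validation + collapse + mosaic
    statuses = read_validation_table(config.validation) if config.validation else {}
    denovo_all = []
    for pid in sorted(trios_by_proband):
        denovo_all.extend(screen_denovo(trios_by_proband[pid], config.thresholds, proband_id=pid))
    denovo_kept = apply_validation(denovo_all, statuses)
    denovo_kept = collapse_independent(denovo_kept, cohort)
    denovo_kept = [flag_mosaic(c, config.mosaic_alpha) for c in denovo_kept]
    validated_set = [c for c in denovo_kept if c.validation_status == "validated"]
    downstream_denovo = validated_set if statuses else denovo_kept

    # inherited screens
    inherited = []
    for pid in sorted(trios_by_proband):
        by_gene = group_trios_by_gene(trios_by_proband[pid])
        dn_hits = [c for c in downstream_denovo if c.proband_id == pid]
        inherited.extend(screen_homozygous(by_gene, config.thresholds, proband_id=pid))
        inherited.extend(
            screen_compound_het(by_gene, config.thresholds, proband_id=pid, denovo_hits=dn_hits)
        )
        inherited.extend(
            screen_hemizygous(by_gene, config.thresholds, cohort=cohort, proband_id=pid)
        )

    # CNVs
    cnv_kept = []
    if config.cnvs and config.gene_model:
        calls = read_cnv_table(config.cnvs)
        catalog = []
        if config.common_cnvs:
            for line in Path(config.common_cnvs).read_text().splitlines():
                if not line.strip() or line.startswith(("#", "chrom\t")):
                    continue
                c, s, e = line.split("\t")[:3]
                catalog.append((c, int(s), int(e)))
        gene_model = read_gene_model(config.gene_model)
        cnv_kept = filter_cnvs(
            calls, catalog, gene_model, cohort,
            min_confidence=config.cnv_min_confidence,
            reciprocal_overlap_threshold=config.cnv_reciprocal_overlap,
        )
        write_cnv_table(cnv_kept, outdir / "cnvs_filtered.tsv")

    # candidate table in per-proband, per-mode layout
    _write_candidate_table(outdir / "candidates.tsv", cohort, downstream_denovo, inherited, cnv_kept)

    # classification
    classifications: dict[str, list] = {}
    class_records = []
    summary = None
    if config.evidence and config.ontology:
        evidence = _classify.read_evidence_table(config.evidence)
        ontology = _classify.load_ontology(config.ontology)
        records = _candidate_gene_records(downstream_denovo, inherited, cnv_kept)
        for pid, gene, mode in records:
            ev = evidence.get(gene, _classify.GeneEvidence(gene=gene))
            cls = _classify.classify_variant_gene(
                ev, mode, phenotypes.get(pid, set()), ontology, config.classifier
            )
            classifications.setdefault(pid, []).append(cls)
            class_records.append((pid, gene, mode, cls))
        summary = _classify.summarize_cohort(classifications, cohort)
        _classify.write_classification_report(
            class_records, summary, outdir / "classification.tsv"
        )

    # statistics
    independents = [c for c in downstream_denovo if c.independent]
    n_syn = sum(
        1 for c in independents if c.trio.site.consequence.value == "synonymous"
    )
    stats_report: dict = {}
    if independents:
        stats_report["n_denovo"] = len(downstream_denovo)
        stats_report["n_independent_denovo"] = len(independents)
        stats_report["n_synonymous"] = n_syn
        stats_report["synonymous_depletion_p"] = _stats.synonymous_enrichment_test(
            len(independents), n_syn, config.stats
        )
    per_proband_inherited = {
        p.individual_id: len({c.gene for c in inherited if c.proband_id == p.individual_id})
        for p in cohort.probands
    }
    mean, lo, hi = _stats.candidate_count_summary(list(per_proband_inherited.values()))
    stats_report["inherited_candidates_per_proband"] = {"mean": mean, "min": lo, "max": hi}
    if summary is not None:
        stats_report["diagnostic_yield_percent"] = summary.percent
    (outdir / "stats.json").write_text(json.dumps(stats_report, indent=2, sort_keys=True))

    return PipelineResult(
        cohort=cohort, merged=merged,
        denovo_candidates=denovo_kept, denovo_validated=validated_set,
        inherited_candidates=inherited, cnv_kept=cnv_kept,
        classifications=classifications, summary=summary, stats_report=stats_report,
    )


def _candidate_gene_records(denovo, inherited, cnv_kept) -> list[tuple[str, str, str]]:
    records: list[tuple[str, str, str]] = []
    for c in denovo:
        if c.trio.site.gene:
            records.append((c.proband_id, c.trio.site.gene, "de_novo"))
    for c in inherited:
        records.append((c.proband_id, c.gene, c.mode))
    for call in cnv_kept:
        carriers = [i for i, v in call.carrier.items() if v]
        for gene in call.genes:
            for pid in carriers:
                records.append((pid, gene, f"cnv_{call.mode}"))
    return sorted(set(records))


def _write_candidate_table(path: Path, cohort, denovo, inherited, cnv_kept) -> None:
    modes = ("de_novo", "compound_het", "homozygous", "hemizygous", "cnv")
    rows = ["proband_id\t" + "\t".join(modes)]
    proband_ids = {p.individual_id for p in cohort.probands}
    for p in sorted(proband_ids):
        cells = {m: set() for m in modes}
        for c in denovo:
            if c.proband_id == p and c.trio.site.gene:
                cells["de_novo"].add(c.trio.site.gene)
        for c in inherited:
            if c.proband_id == p:
                cells[c.mode].add(c.gene)
        for call in cnv_kept:
            if call.carrier.get(p):
                cells["cnv"].update(call.genes)
        rows.append(
            p + "\t" + "\t".join(";".join(sorted(cells[m])) or "." for m in modes)
        )
    path.write_text("\n".join(rows) + "\n")
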