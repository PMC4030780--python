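"""Filtering of externally produced CNV calls.

CNV detection itself is out of scope: calls arrive as a BED-like table
(chrom, start, end, type, confidence, per-family-member carrier status) from
an exome CNV caller.  The filter keeps calls that are high-confidence, not
matched by a common-CNV catalog at a reciprocal-overlap threshold, overlap at
least one protein-coding gene, and fit an expected mode of inheritance
(de novo, recessive, or X-linked).  Coordinates are 1-based inclusive; spans
therefore count end - start + 1 bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from triotriage.cohort_io import Cohort, Sex, in_par

logger = logging.getLogger(__name__)

__all__ = [
    "CnvCall",
    "GeneInterval",
    "read_cnv_table",
    "write_cnv_table",
    "read_gene_model",
    "annotate_genes",
    "reciprocal_overlap",
    "assign_cnv_mode",
    "filter_cnvs",
    "cnv_span",
]


@dataclass
class CnvCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    cnv_type: str  # deletion | duplication
    confidence: float
    family_id: str = ""
    carrier: dict[str, bool] = field(default_factory=dict)  # individual_id -> carries call
    genes: list[str] = field(default_factory=list)
    mode: str = ""  # filled by assign_cnv_mode

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int
    end: int
    gene: str
    biotype: str = "protein_coding"
    coding_length: int = 0


def read_gene_model(path: str | Path) -> list[GeneInterval]:
    """Read a BED-like gene model: chrom, start, end, gene, biotype[, coding_length].

    Coordinates in the file are 1-based inclusive (matching the rest of the
    package), not BED half-open.
    """
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "chrom\t")):
            continue
        parts = line.split("\t")
        genes.append(
            GeneInterval(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                gene=parts[3],
                biotype=parts[4] if len(parts) > 4 else "protein_coding",
                coding_length=int(parts[5]) if len(parts) > 5 else 0,
            )
        )
    return genes


def read_cnv_table(path: str | Path) -> list[CnvCall]:
    """Read a CNV TSV: chrom, start, end, type, confidence, family, carriers.

    ``carriers`` is a comma-separated list of ``individual_id=0|1`` entries.
    """
    calls = []
    lines = Path(path).read_text().splitlines()
    for idx, line in enumerate(lines):
        if not line.strip() or line.startswith(("#", "chrom\t")):
            continue
        parts = line.split("\t")
        try:
            carrier = {}
            if len(parts) > 6 and parts[6] not in (".", ""):
                for item in parts[6].split(","):
                    ind, val = item.split("=")
                    carrier[ind] = val == "1"
            calls.append(
                CnvCall(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    cnv_type=parts[3],
                    confidence=float(parts[4]),
                    family_id=parts[5] if len(parts) > 5 else "",
                    carrier=carrier,
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed CNV record at line index {idx}: {exc}") from exc
    return calls


def write_cnv_table(calls: Iterable[CnvCall], path: str | Path) -> None:
    rows = ["chrom\tstart\tend\tcnv_type\tconfidence\tfamily_id\tcarriers\tgenes\tmode"]
    for c in calls:
        carriers = ",".join(f"{k}={int(v)}" for k, v in sorted(c.carrier.items()))
        rows.append(
            "\t".join(
                [
                    c.chrom,
                    str(c.start),
                    str(c.end),
                    c.cnv_type,
                    f"{c.confidence:g}",
                    c.family_id,
                    carriers or ".",
                    ";".join(c.genes) or ".",
                    c.mode or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def cnv_span(call: CnvCall) -> tuple[int, int]:
    """(bp, kb) span of a call; bp = end - start + 1, kb rounded half-up."""
    bp = call.end - call.start + 1
    kb = int(bp / 1000 + 0.5)
    return bp, kb


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap fraction of two 1-based inclusive intervals.

    Returns the smaller of the two mutual overlap fractions, i.e. the largest
    f such that the overlap covers >= f of *both* intervals.
    """
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    len_a = a[1] - a[0] + 1
    len_b = b[1] - b[0] + 1
    return min(ov / len_a, ov / len_b)


def _build_trees(intervals: Iterable[tuple[str, int, int, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, payload in intervals:
        # IntervalTree is half-open; store [start, end+1)
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, payload)
    return trees


def annotate_genes(calls: Sequence[CnvCall], gene_model: Sequence[GeneInterval]) -> list[CnvCall]:
    """Fill each call's ``genes`` list with overlapping gene symbols (any biotype)."""
    trees = _build_trees((g.chrom, g.start, g.end, g) for g in gene_model)
    out = []
    for call in calls:
        hits = trees.get(call.chrom, IntervalTree()).overlap(call.start, call.end + 1)
        genes = sorted({iv.data.gene for iv in hits})
        out.append(replace(call, carrier=dict(call.carrier), genes=genes))
    return out


def assign_cnv_mode(call: CnvCall, cohort: Cohort) -> str:
    """Assign a mode of inheritance from per-family carrier status.

    ``de_novo``: the proband carries the call and neither parent does (checked
    first, so a proband-only X call in a female is de novo, not X-linked).
    ``x_linked``: chrX outside the PAR, male proband carrier, carrier mother,
    non-carrier father.  ``recessive``: biallelic loss — a deletion carried by
    the proband and both parents.  Anything else (e.g. a call shared with one
    parent on an autosome, dominant-inconsistent here) is ``other``.  Missing
    parental carrier status yields ``other`` with a logged reason.
    """
    proband_ids = [p.individual_id for p in cohort.probands if call.carrier.get(p.individual_id)]
    if not proband_ids:
        return "other"
    pid = proband_ids[0]
    mother, father = cohort.parents_of(pid)
    m = call.carrier.get(mother.individual_id)
    f = call.carrier.get(father.individual_id)
    if m is None or f is None:
        logger.info(
            "CNV %s:%d-%d: missing parental carrier status; mode set to other",
            call.chrom, call.start, call.end,
        )
        return "other"
    if not m and not f:
        return "de_novo"
    on_x = call.chrom.removeprefix("chr") == "X" and not in_par(call.chrom, call.start)
    if on_x and m and not f and cohort.member(pid).sex is Sex.male:
        return "x_linked"
    if call.cnv_type == "deletion" and m and f:
        return "recessive"
    return "other"


def filter_cnvs(
    calls: Sequence[CnvCall],
    common_catalog: Sequence[tuple[str, int, int]],
    gene_model: Sequence[GeneInterval],
    cohort: Cohort,
    min_confidence: float,
    reciprocal_overlap_threshold: float = 0.5,
) -> list[CnvCall]:
    """Keep rare, confident, genic CNVs under an expected inheritance mode.

    A call survives iff confidence >= ``min_confidence``, no common-catalog
    interval reaches ``reciprocal_overlap_threshold`` reciprocal overlap, it
    overlaps >= 1 protein-coding gene, and its assigned mode is one of
    de_novo / recessive / x_linked.  The four conditions are independent
    predicates, so their order of application cannot change the result.
    """
    common_trees = _build_trees((c, s, e, (s, e)) for c, s, e in common_catalog)
    coding_model = [g for g in gene_model if g.biotype == "protein_coding"]
    coding_trees = _build_trees((g.chrom, g.start, g.end, g) for g in coding_model)

    kept = []
    annotated = annotate_genes(calls, gene_model)
    for call in annotated:
        if call.confidence < min_confidence:
            continue
        span = (call.start, call.end)
        common_hits = common_trees.get(call.chrom, IntervalTree()).overlap(call.start, call.end + 1)
        if any(
            reciprocal_overlap(span, iv.data) >= reciprocal_overlap_threshold
            for iv in common_hits
        ):
            continue
        coding_hits = coding_trees.get(call.chrom, IntervalTree()).overlap(call.start, call.end + 1)
        if not coding_hits:
            continue
        mode = assign_cnv_mode(call, cohort)
        if mode not in ("de_novo", "recessive", "x_linked"):
            continue
        call.mode = mode
        kept.append(call)
    return kept
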