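"""Inherited candidate-gene screens: homozygous-recessive, compound-
heterozygous, and X-linked hemizygous.

All three screens apply the same rarity and consequence filter: population
minor allele frequency strictly below ``max_af`` (default 1%; a frequency
missing from reference databases passes as rare) and a predicted protein
consequence in the functional set {essential splice site, stop gained,
frameshift coding, non-synonymous, stop lost}.  Synonymous and other
consequences never qualify.

Compound heterozygotes are phased by parental transmission, not reads: a
variant's origin is the unique parent carrying the allele; a variant carried
by both parents is of ambiguous origin and cannot anchor either side of a
pair.  A gene is a compound-het candidate only with at least one confidently
maternal and one confidently paternal variant — or, as a special case, one
inherited variant paired with a validated de novo hit in the same gene (the
"second hit" configuration).

Females are not screened hemizygously: female X candidates surface through
the homozygous / compound-het screens applied to chrX, consistent with dosage
logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from triotriage.cohort_io import (
    FUNCTIONAL_CONSEQUENCES,
    Cohort,
    Genotype,
    Sex,
    TrioGenotypes,
    VariantSite,
    in_par,
)
from triotriage.denovo import DeNovoCandidate, ScreenThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "InheritedCandidate",
    "screen_homozygous",
    "screen_compound_het",
    "screen_hemizygous",
    "group_trios_by_gene",
]


@dataclass
class InheritedCandidate:
    proband_id: str
    gene: str
    mode: str  # homozygous | compound_het | hemizygous
    variants: list[tuple[VariantSite, str]]  # (site, origin: maternal|paternal|ambiguous|de_novo)
    note: str = ""


def _passes_site_filter(site: VariantSite, th: ScreenThresholds) -> bool:
    if site.population_af is not None and site.population_af >= th.max_af:
        return False
    return site.consequence in FUNCTIONAL_CONSEQUENCES


def _quality_ok(trio: TrioGenotypes, th: ScreenThresholds) -> bool:
    return (
        (trio.proband.depth or 0) >= th.min_child_depth
        and (trio.proband.gq or 0) >= th.min_child_gq
        and (trio.mother.depth or 0) >= th.min_parent_depth
        and (trio.father.depth or 0) >= th.min_parent_depth
    )


def group_trios_by_gene(trios: Iterable[TrioGenotypes]) -> dict[str, list[TrioGenotypes]]:
    by_gene: dict[str, list[TrioGenotypes]] = {}
    for t in trios:
        if t.site.gene:
            by_gene.setdefault(t.site.gene, []).append(t)
    return by_gene


def screen_homozygous(
    trios_by_gene: Mapping[str, Sequence[TrioGenotypes]],
    thresholds: ScreenThresholds | None = None,
    proband_id: str | None = None,
) -> list[InheritedCandidate]:
    """Homozygous-recessive candidates: proband hom_alt with both parents het.

    A parent homozygous for the alt allele at a candidate site is
    inconsistent with the unaffected-parent assumption; such sites are
    excluded and logged.
    """
    th = thresholds or ScreenThresholds()
    out: list[InheritedCandidate] = []
    for gene in sorted(trios_by_gene):
        hits: list[tuple[VariantSite, str]] = []
        pid = proband_id
        for trio in trios_by_gene[gene]:
            if trio.proband.gt is not Genotype.hom_alt:
                continue
            if not _passes_site_filter(trio.site, th) or not _quality_ok(trio, th):
                continue
            if Genotype.hom_alt in (trio.mother.gt, trio.father.gt):
                logger.info(
                    "homozygous screen: %s:%d in %s excluded (alt-homozygous parent)",
                    trio.site.chrom, trio.site.pos, gene,
                )
                continue
            # on chrX a female proband's "homozygous" configuration has a
            # hemizygous-alt father in place of a het father
            on_x = trio.site.chrom.removeprefix("chr") == "X"
            father_ok = trio.father.gt is Genotype.het or (
                on_x and trio.father.gt is Genotype.hemi_alt
            )
            if trio.mother.gt is Genotype.het and father_ok:
                hits.append((trio.site, "ambiguous"))
                pid = pid or trio.proband.individual_id
        if hits:
            out.append(
                InheritedCandidate(proband_id=pid or "", gene=gene, mode="homozygous", variants=hits)
            )
    return out


def screen_compound_het(
    trios_by_gene: Mapping[str, Sequence[TrioGenotypes]],
    thresholds: ScreenThresholds | None = None,
    proband_id: str | None = None,
    denovo_hits: Sequence[DeNovoCandidate] = (),
) -> list[InheritedCandidate]:
    """Compound-heterozygous candidate genes phased by parental transmission.

    A gene qualifies iff the proband carries >= 2 distinct rare functional het
    variants with at least one confidently maternal and one confidently
    paternal (origin = the unique parent carrying the allele).  Variants
    carried by both parents have ambiguous origin and cannot anchor either
    side, but are listed alongside a qualifying pair.  ``denovo_hits``
    (validated de novo candidates) may stand in for one side; the resulting
    candidate carries a mixed-origin note.
    """
    th = thresholds or ScreenThresholds()
    dn_by_gene: dict[str, list[DeNovoCandidate]] = {}
    for d in denovo_hits:
        if d.trio.site.gene:
            dn_by_gene.setdefault(d.trio.site.gene, []).append(d)

    out: list[InheritedCandidate] = []
    for gene in sorted(set(trios_by_gene) | set(dn_by_gene)):
        variants: list[tuple[VariantSite, str]] = []
        pid = proband_id
        for trio in trios_by_gene.get(gene, ()):
            if trio.proband.gt is not Genotype.het:
                continue
            if not _passes_site_filter(trio.site, th) or not _quality_ok(trio, th):
                continue
            m_carries = trio.mother.gt.carries_alt
            f_carries = trio.father.gt.carries_alt
            if m_carries and not f_carries:
                origin = "maternal"
            elif f_carries and not m_carries:
                origin = "paternal"
            elif m_carries and f_carries:
                origin = "ambiguous"
            else:
                continue  # neither parent carries it: de novo territory, not inherited
            variants.append((trio.site, origin))
            pid = pid or trio.proband.individual_id
        dn_sites = [
            (d.trio.site, "de_novo")
            for d in dn_by_gene.get(gene, ())
            if d.trio.site.key not in {s.key for s, _ in variants}
        ]
        origins = {o for _, o in variants}
        has_maternal = "maternal" in origins
        has_paternal = "paternal" in origins
        note = ""
        if has_maternal and has_paternal:
            pass
        elif (has_maternal or has_paternal) and dn_sites:
            variants = variants + dn_sites
            note = "second hit: inherited variant paired with a validated de novo"
            if pid is None:
                pid = dn_by_gene[gene][0].proband_id
        else:
            continue
        out.append(
            InheritedCandidate(
                proband_id=pid or "", gene=gene, mode="compound_het", variants=variants, note=note
            )
        )
    return out


def screen_hemizygous(
    trios_by_gene: Mapping[str, Sequence[TrioGenotypes]],
    thresholds: ScreenThresholds | None = None,
    cohort: Cohort | None = None,
    proband_id: str | None = None,
    par_regions=None,
) -> list[InheritedCandidate]:
    """X-linked hemizygous candidates in male probands.

    A site qualifies iff it lies on chrX outside the pseudoautosomal regions,
    the male proband is hemizygous alt, the mother is a het carrier and the
    father is hemizygous reference.  Female probands are not screened here
    (their X candidates come from the recessive screens run on chrX); routing
    a female proband in returns an empty result with a logged note.
    """
    th = thresholds or ScreenThresholds()
    out: list[InheritedCandidate] = []
    for gene in sorted(trios_by_gene):
        hits: list[tuple[VariantSite, str]] = []
        pid = proband_id
        for trio in trios_by_gene[gene]:
            site = trio.site
            if site.chrom.removeprefix("chr") != "X" or in_par(site.chrom, site.pos, par_regions):
                continue
            if cohort is not None:
                member = cohort.member(trio.proband.individual_id)
                if member.sex is Sex.female:
                    logger.info(
                        "hemizygous screen: %s is female; X handled by recessive screens",
                        trio.proband.individual_id,
                    )
                    continue
            if trio.proband.gt is not Genotype.hemi_alt:
                continue
            if not _passes_site_filter(site, th) or not _quality_ok(trio, th):
                continue
            if trio.mother.gt is not Genotype.het or trio.father.gt is not Genotype.hemi_ref:
                continue
            hits.append((site, "maternal"))
            pid = pid or trio.proband.individual_id
        if hits:
            out.append(
                InheritedCandidate(proband_id=pid or "", gene=gene, mode="hemizygous", variants=hits)
            )
    return out
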