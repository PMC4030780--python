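"""High-sensitivity trio de novo screening.

A candidate de novo variant is one the proband carries while both parents are
confidently homozygous (or hemizygous) reference.  The screen is a transparent
threshold rule (child depth/GQ, parental depth, a cap on parental alt-supporting
reads, a rarity cap) rather than a probabilistic joint-genotype caller: in the
study design it mimics, every candidate was pushed to orthogonal capillary
validation, so sensitivity is favored over specificity and validation status is
first-class bookkeeping.

Also here: the twin-aware independence collapse (an identical variant shared by
monozygotic twins is a single mutational event) and mosaicism flagging from
skewed allele depths (exact two-sided binomial test against an expected alt
fraction of 0.5, flagged only when the alt fraction is depleted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from triotriage.cohort_io import (
    CODING_CONSEQUENCES,
    Cohort,
    Genotype,
    TrioGenotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenThresholds",
    "DeNovoCandidate",
    "screen_denovo",
    "collapse_independent",
    "flag_mosaic",
    "apply_validation",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Quality and rarity knobs shared by the trio screens.

    Defaults are conventional: a 10-read depth floor for child and parents
    (the coverage benchmark exome studies report against), GQ >= 20 for the
    child call, at most one alt-supporting read in either parent, and a
    population-frequency cap of 1%.
    """

    min_child_depth: int = 10
    min_parent_depth: int = 10
    min_child_gq: int = 20
    max_parent_alt_reads: int = 1
    max_af: float = 0.01
    restrict_to_coding: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_af <= 1.0:
            raise ValueError("max_af must be in [0, 1]")
        for name in ("min_child_depth", "min_parent_depth", "min_child_gq", "max_parent_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DeNovoCandidate:
    trio: TrioGenotypes
    proband_id: str
    score: int = 0
    validation_status: str = "candidate"  # candidate | validated | refuted
    independent: bool = True
    mosaic_flag: bool = False
    mosaic_p: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.trio.site.key


def _parent_is_ref(obs, thresholds: ScreenThresholds) -> bool:
    if not obs.gt.is_reference:
        return False
    if (obs.depth or 0) < thresholds.min_parent_depth:
        return False
    if obs.ad_alt is not None and obs.ad_alt > thresholds.max_parent_alt_reads:
        return False
    return True


def screen_denovo(
    trios: Iterable[TrioGenotypes],
    thresholds: ScreenThresholds | None = None,
    proband_id: str | None = None,
) -> list[DeNovoCandidate]:
    """Emit candidate de novo variants from merged, normalized trio rows.

    A site qualifies iff the proband carries >= 1 alt allele, both parents are
    reference calls with alt-read support within ``max_parent_alt_reads``,
    depth/GQ thresholds are met, the site's population frequency does not
    exceed ``max_af`` (a missing frequency passes, as absence from reference
    databases implies rarity), and the consequence is coding/splicing when
    ``restrict_to_coding``.  Sites with a missing parental genotype are
    skipped with a logged reason, never silently.
    """
    th = thresholds or ScreenThresholds()
    out: list[DeNovoCandidate] = []
    for trio in trios:
        site = trio.site
        if trio.proband.gt is Genotype.missing:
            continue
        if trio.mother.gt is Genotype.missing or trio.father.gt is Genotype.missing:
            logger.info(
                "de novo screen: skipping %s:%d %s>%s (missing parental genotype)",
                site.chrom, site.pos, site.ref, site.alt,
            )
            continue
        if not trio.proband.gt.carries_alt:
            continue
        if site.population_af is not None and site.population_af > th.max_af:
            continue
        if th.restrict_to_coding and site.consequence not in CODING_CONSEQUENCES:
            continue
        if (trio.proband.depth or 0) < th.min_child_depth:
            continue
        if (trio.proband.gq or 0) < th.min_child_gq:
            continue
        if not (_parent_is_ref(trio.mother, th) and _parent_is_ref(trio.father, th)):
            continue
        score = min(
            trio.proband.gq or 0,
            trio.mother.gq or 0,
            trio.father.gq or 0,
        )
        out.append(
            DeNovoCandidate(
                trio=trio,
                proband_id=proband_id or trio.proband.individual_id,
                score=score,
            )
        )
    return out


def collapse_independent(
    candidates: Sequence[DeNovoCandidate], cohort: Cohort
) -> list[DeNovoCandidate]:
    """Mark one representative per MZ-identical event as independent.

    Identical (chrom, pos, ref, alt) candidates carried by a monozygotic twin
    pair are a single mutational event: the twin with the lexically smaller
    individual id keeps ``independent=True``, the partner is marked False.
    The same variant in unrelated probands remains separate events.
    """
    out = [replace(c) for c in candidates]
    by_variant: dict[tuple[str, int, str, str], list[DeNovoCandidate]] = {}
    for c in out:
        by_variant.setdefault(c.key, []).append(c)
    for group in by_variant.values():
        seen_pairs: set[frozenset[str]] = set()
        carriers = {c.proband_id for c in group}
        for c in group:
            partner = cohort.mz_partner(c.proband_id)
            if partner is None or partner not in carriers:
                c.independent = True
                continue
            pair = frozenset({c.proband_id, partner})
            seen_pairs.add(pair)
            c.independent = c.proband_id == min(pair)
    return out


def flag_mosaic(candidate: DeNovoCandidate, alpha: float = 0.01) -> DeNovoCandidate:
    """Flag suggestive mosaicism from skewed allele depths.

    ``mosaic_p`` is the exact two-sided binomial probability of the observed
    alt-read count under an expected alt fraction of 0.5 (a germline
    heterozygote); the flag is set only when the test rejects at ``alpha``
    AND the alt fraction is below 0.5 (a depleted alt fraction is the mosaic
    signature; the enriched side is not flagged).  With zero informative
    reads the flag is not evaluable and ``mosaic_p`` stays None.
    """
    obs = candidate.trio.proband
    c = replace(candidate)
    if obs.ad_ref is None or obs.ad_alt is None or obs.ad_ref + obs.ad_alt == 0:
        logger.info(
            "mosaic flag not evaluable for %s %s (no informative allele depths)",
            candidate.proband_id, candidate.key,
        )
        c.mosaic_p = None
        c.mosaic_flag = False
        return c
    n = obs.ad_ref + obs.ad_alt
    k = obs.ad_alt
    p = binomtest(k, n, 0.5, alternative="two-sided").pvalue
    c.mosaic_p = float(p)
    c.mosaic_flag = bool(p < alpha and k / n < 0.5)
    return c


def apply_validation(
    candidates: Sequence[DeNovoCandidate],
    statuses: Mapping[tuple[str, str, int, str, str], str],
) -> list[DeNovoCandidate]:
    """Fold in an external validation table keyed by (proband, chrom, pos, ref, alt).

    Refuted candidates are excluded from the returned (downstream) list;
    candidates without a status entry are retained as ``candidate``.  Statuses
    for unknown candidates produce a warning and are ignored.
    """
    known = {(c.proband_id, *c.key) for c in candidates}
    for key in statuses:
        if key not in known:
            logger.warning("validation status for unknown candidate %s ignored", (key,))
    out: list[DeNovoCandidate] = []
    for c in candidates:
        status = statuses.get((c.proband_id, *c.key), "candidate")
        if status not in ("candidate", "validated", "refuted"):
            raise ValueError(f"unknown validation status {status!r}")
        if status == "refuted":
            continue
        out.append(replace(c, validation_status=status))
    return out


def validated(candidates: Iterable[DeNovoCandidate]) -> list[DeNovoCandidate]:
    return [c for c in candidates if c.validation_status == "validated"]
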