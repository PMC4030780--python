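"""Cohort-level statistics for trio de novo and inherited candidate sets.

Three quantities, all with transparent oracle-checkable forms:

* **Synonymous depletion among independent de novo events.**  Under a null in
  which 29% of coding/splicing de novo point mutations are synonymous, an
  exact one-sided lower-tail binomial sum gives the probability of observing
  at most the seen number of synonymous events — depletion of synonymous
  variants is enrichment of functional ones.
* **Recurrent-gene probability.**  Under a uniform mutation-rate-per-bp model
  with ``n`` functional de novo events over a coding exome of ``E`` bp, the
  count landing in a gene of coding length ``L`` is ~Poisson with
  ``lambda = n * L / E`` and ``P(>=2) = 1 - (1 + lambda) * exp(-lambda)``;
  reported alongside the Bonferroni threshold ``alpha / n_genes``.
* **Per-proband candidate-count summaries** (mean to 2 decimals, min, max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binom

__all__ = [
    "StatsConfig",
    "synonymous_enrichment_test",
    "recurrent_gene_probability",
    "candidate_count_summary",
]


@dataclass(frozen=True)
class StatsConfig:
    expected_synonymous_fraction: float = 0.29
    exome_coding_size: int = 30_000_000
    n_genes_for_bonferroni: int = 20_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.expected_synonymous_fraction <= 1.0:
            raise ValueError("expected_synonymous_fraction must be in [0, 1]")
        if self.exome_coding_size <= 0 or self.n_genes_for_bonferroni <= 0:
            raise ValueError("sizes must be positive")


def synonymous_enrichment_test(
    n_independent: int, n_synonymous: int, config: StatsConfig | None = None
) -> float:
    """Exact one-sided lower-tail binomial probability of <= k synonymous.

    Returns sum_{i=0..k} C(n, i) p^i (1-p)^(n-i) with p the expected
    synonymous fraction.  A small value means the observed synonymous count
    is depleted, i.e. functional de novo events are enriched.
    """
    cfg = config or StatsConfig()
    if n_independent < 0 or n_synonymous < 0 or n_synonymous > n_independent:
        raise ValueError(
            f"invalid counts: n_independent={n_independent}, n_synonymous={n_synonymous}"
        )
    return float(binom.cdf(n_synonymous, n_independent, cfg.expected_synonymous_fraction))


def recurrent_gene_probability(
    gene_coding_length: int,
    n_functional_denovos: int,
    config: StatsConfig | None = None,
) -> tuple[float, float]:
    """(P(>= 2 de novo hits in the gene by chance), Bonferroni threshold).

    Uniform-rate model: each of the ``n`` functional de novo events falls in
    the gene with probability L/E, so the gene's hit count is approximately
    Poisson(lambda = n L / E).
    """
    cfg = config or StatsConfig()
    if gene_coding_length < 0 or n_functional_denovos < 0:
        raise ValueError("counts and lengths must be non-negative")
    if gene_coding_length > cfg.exome_coding_size:
        raise ValueError("gene length exceeds exome size")
    lam = n_functional_denovos * gene_coding_length / cfg.exome_coding_size
    p_recurrent = -math.expm1(-lam) - lam * math.exp(-lam)  # 1 - (1+lam) e^-lam, stable
    return max(p_recurrent, 0.0), cfg.alpha / cfg.n_genes_for_bonferroni


def candidate_count_summary(per_proband_counts: Sequence[int]) -> tuple[float, int, int]:
    """(mean rounded to 2 decimals, min, max) of per-proband candidate counts."""
    if not per_proband_counts:
        raise ValueError("no proband counts supplied")
    mean = round(sum(per_proband_counts) / len(per_proband_counts), 2)
    return mean, min(per_proband_counts), max(per_proband_counts)
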