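"""Shared fixtures: session-scoped simulated bundles and trio builders."""

from __future__ import annotations

import pytest

from triotriage.cohort_io import (
    CALLER_LABELS,
    Cohort,
    Consequence,
    Genotype,
    GenotypeObservation,
    TrioGenotypes,
    VariantSite,
    build_trios,
    merge_caller_calls,
)
from triotriage.fixtures import load_fixture_cohort, load_fixture_ontology
from triotriage.simulate import SimConfig, simulate_cohort


def make_obs(
    ind: str,
    gt: Genotype,
    ad_ref: int = 50,
    ad_alt: int | None = None,
    depth: int | None = None,
    gq: int = 99,
) -> GenotypeObservation:
    if ad_alt is None:
        ad_alt = {True: 50, False: 0}[gt.carries_alt]
        if gt in (Genotype.hom_alt, Genotype.hemi_alt):
            ad_ref = 0
    if depth is None:
        depth = ad_ref + ad_alt
    return GenotypeObservation(
        individual_id=ind, gt=gt, ad_ref=ad_ref, ad_alt=ad_alt,
        depth=depth, gq=gq, callers=frozenset({"merged"}),
    )


def make_trio(
    proband_gt: Genotype,
    mother_gt: Genotype,
    father_gt: Genotype,
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    gene: str = "GENE1",
    consequence: Consequence = Consequence.non_synonymous,
    population_af: float | None = 0.001,
    **obs_kwargs,
) -> TrioGenotypes:
    site = VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, population_af=population_af,
    )
    return TrioGenotypes(
        site=site,
        proband=make_obs("F1", proband_gt, **obs_kwargs),
        mother=make_obs("M1", mother_gt),
        father=make_obs("P1", father_gt),
    )


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def ontology():
    return load_fixture_ontology()


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default study conditions (30 probands, rate 1.1) without depth noise."""
    return simulate_cohort(SimConfig(seed=1).noiseless())


@pytest.fixture(scope="session")
def noiseless_trios(noiseless_bundle):
    b = noiseless_bundle
    merged = {
        m.individual_id: merge_caller_calls(
            [b.callsets[(m.individual_id, c)] for c in CALLER_LABELS]
        )
        for m in b.cohort.members
    }
    return build_trios(b.cohort, merged)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, tiny cohort for I/O and pipeline plumbing tests."""
    cfg = SimConfig(
        seed=11, n_trios=4, n_quads=1, n_mz_twin_pairs=1,
        n_sites=150, n_genes=120,
    ).noiseless()
    return simulate_cohort(cfg)
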