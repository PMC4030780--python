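"""Inherited screens: homozygous, compound-het (vs brute-force oracle),
X-linked hemizygous, and their filter properties."""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pytest

from tests.conftest import make_obs, make_trio
from triotriage.cohort_io import (
    Consequence,
    Genotype,
    TrioGenotypes,
    VariantSite,
)
from triotriage.denovo import DeNovoCandidate, ScreenThresholds, screen_denovo
from triotriage.fixtures import load_fixture_cohort
from triotriage.inherited import (
    group_trios_by_gene,
    screen_compound_het,
    screen_hemizygous,
    screen_homozygous,
)

TH = ScreenThresholds()


class TestHomozygous:
    def test_classic_recessive_configuration(self):
        trio = make_trio(Genotype.hom_alt, Genotype.het, Genotype.het)
        (cand,) = screen_homozygous({"GENE1": [trio]}, TH)
        assert cand.mode == "homozygous"
        assert cand.gene == "GENE1"

    def test_common_variant_rejected(self):
        trio = make_trio(Genotype.hom_alt, Genotype.het, Genotype.het, population_af=0.02)
        assert screen_homozygous({"GENE1": [trio]}, TH) == []

    def test_synonymous_rejected(self):
        trio = make_trio(
            Genotype.hom_alt, Genotype.het, Genotype.het,
            consequence=Consequence.synonymous,
        )
        assert screen_homozygous({"GENE1": [trio]}, TH) == []

    def test_alt_homozygous_parent_excluded_and_logged(self, caplog):
        trio = make_trio(Genotype.hom_alt, Genotype.hom_alt, Genotype.het)
        with caplog.at_level("INFO", logger="triotriage.inherited"):
            assert screen_homozygous({"GENE1": [trio]}, TH) == []
        assert any("alt-homozygous parent" in r.message for r in caplog.records)


def _chet_site(pos: int, af=0.001, csq=Consequence.non_synonymous) -> VariantSite:
    return VariantSite(chrom="2", pos=pos, ref="A", alt="G", gene="GENE1",
                       consequence=csq, population_af=af)


def _chet_trio(pos, proband, mother, father, af=0.001, csq=Consequence.non_synonymous):
    return TrioGenotypes(
        site=_chet_site(pos, af, csq),
        proband=make_obs("F1", proband),
        mother=make_obs("M1", mother),
        father=make_obs("P1", father),
    )


class TestCompoundHet:
    def test_opposite_parent_pair_is_candidate(self):
        trios = [
            _chet_trio(100, Genotype.het, Genotype.het, Genotype.hom_ref),
            _chet_trio(200, Genotype.het, Genotype.hom_ref, Genotype.het),
        ]
        (cand,) = screen_compound_het({"GENE1": trios}, TH)
        origins = {o for _, o in cand.variants}
        assert origins == {"maternal", "paternal"}

    def test_same_parent_pair_is_not_a_candidate(self):
        trios = [
            _chet_trio(100, Genotype.het, Genotype.het, Genotype.hom_ref),
            _chet_trio(200, Genotype.het, Genotype.het, Genotype.hom_ref),
        ]
        assert screen_compound_het({"GENE1": trios}, TH) == []

    def test_ambiguous_variants_cannot_anchor(self):
        # both variants carried by both parents: no confident phase
        trios = [
            _chet_trio(100, Genotype.het, Genotype.het, Genotype.het),
            _chet_trio(200, Genotype.het, Genotype.het, Genotype.het),
        ]
        assert screen_compound_het({"GENE1": trios}, TH) == []

    def test_ambiguous_variant_listed_alongside_confident_pair(self):
        trios = [
            _chet_trio(100, Genotype.het, Genotype.het, Genotype.hom_ref),
            _chet_trio(200, Genotype.het, Genotype.hom_ref, Genotype.het),
            _chet_trio(300, Genotype.het, Genotype.het, Genotype.het),
        ]
        (cand,) = screen_compound_het({"GENE1": trios}, TH)
        assert {o for _, o in cand.variants} == {"maternal", "paternal", "ambiguous"}

    def test_de_novo_second_hit_pairs_with_inherited_variant(self):
        inherited = _chet_trio(100, Genotype.het, Genotype.het, Genotype.hom_ref)
        dn_trio = _chet_trio(500, Genotype.het, Genotype.hom_ref, Genotype.hom_ref, af=None)
        dn = DeNovoCandidate(trio=dn_trio, proband_id="F1", validation_status="validated")
        (cand,) = screen_compound_het({"GENE1": [inherited]}, TH, denovo_hits=[dn])
        assert "second hit" in cand.note
        assert {o for _, o in cand.variants} == {"maternal", "de_novo"}

    def test_matches_brute_force_pair_enumeration_oracle(self):
        """1,000 random small gene instances against exhaustive enumeration."""
        rng = np.random.default_rng(42)
        gts = [Genotype.hom_ref, Genotype.het, Genotype.hom_alt]
        for trial in range(1000):
            n_var = int(rng.integers(1, 7))
            trios = []
            for i in range(n_var):
                trios.append(
                    _chet_trio(
                        100 + i,
                        proband=gts[int(rng.integers(3))],
                        mother=gts[int(rng.integers(3))],
                        father=gts[int(rng.integers(3))],
                        af=float(rng.choice([0.0001, 0.005, 0.05])),
                        csq=Consequence(
                            str(rng.choice(["non_synonymous", "synonymous", "stop_gained"]))
                        ),
                    )
                )
            got = bool(screen_compound_het({"GENE1": trios}, TH))
            assert got == _oracle_comphet(trios), f"trial {trial}"


def _oracle_comphet(trios) -> bool:
    """Exhaustive: some pair of usable variants has one confidently maternal
    and one confidently paternal origin."""

    def usable(t):
        return (
            t.proband.gt is Genotype.het
            and (t.site.population_af is None or t.site.population_af < 0.01)
            and t.site.consequence.value in (
                "essential_splice_site", "stop_gained", "frameshift_coding",
                "non_synonymous", "stop_lost",
            )
        )

    def origin(t):
        m, f = t.mother.gt.carries_alt, t.father.gt.carries_alt
        if m and not f:
            return "maternal"
        if f and not m:
            return "paternal"
        return None  # ambiguous or untransmitted

    usable_trios = [t for t in trios if usable(t)]
    for a, b in itertools.combinations(usable_trios, 2):
        if {origin(a), origin(b)} == {"maternal", "paternal"}:
            return True
    return False


def _x_trio(proband_gt, mother_gt, father_gt, pos=5_000_000, af=0.002,
            csq=Consequence.stop_gained):
    return TrioGenotypes(
        site=VariantSite(chrom="X", pos=pos, ref="A", alt="G", gene="XG1",
                         consequence=csq, population_af=af),
        proband=make_obs("F1", proband_gt),
        mother=make_obs("M1", mother_gt),
        father=make_obs("P1", father_gt),
    )


class TestHemizygous:
    def test_carrier_mother_transmits_to_male(self):
        trio = _x_trio(Genotype.hemi_alt, Genotype.het, Genotype.hemi_ref)
        (cand,) = screen_hemizygous({"XG1": [trio]}, TH)
        assert cand.mode == "hemizygous"
        assert cand.variants[0][1] == "maternal"

    def test_carrier_father_excluded(self):
        trio = _x_trio(Genotype.hemi_alt, Genotype.het, Genotype.hemi_alt)
        assert screen_hemizygous({"XG1": [trio]}, TH) == []

    def test_par_site_not_hemizygous(self):
        trio = _x_trio(Genotype.hemi_alt, Genotype.het, Genotype.hemi_ref, pos=100_000)
        assert screen_hemizygous({"XG1": [trio]}, TH) == []

    def test_female_proband_routed_out(self, fixture_cohort, caplog):
        # F2 is female: her X sites never reach the hemizygous screen
        trio = TrioGenotypes(
            site=VariantSite(chrom="X", pos=5_000_000, ref="A", alt="G", gene="XG1",
                             consequence=Consequence.stop_gained, population_af=0.002),
            proband=make_obs("F2", Genotype.het),
            mother=make_obs("M2", Genotype.het),
            father=make_obs("P2", Genotype.hemi_ref),
        )
        with caplog.at_level("INFO", logger="triotriage.inherited"):
            assert screen_hemizygous({"XG1": [trio]}, TH, cohort=fixture_cohort) == []
        assert any("female" in r.message for r in caplog.records)


class TestProperties:
    def test_modes_disjoint_per_gene(self, noiseless_bundle, noiseless_trios):
        for p in noiseless_bundle.cohort.probands:
            pid = p.individual_id
            by_gene = group_trios_by_gene(noiseless_trios[pid])
            hom = {c.gene for c in screen_homozygous(by_gene, TH, proband_id=pid)}
            ch = {c.gene for c in screen_compound_het(by_gene, TH, proband_id=pid)}
            hemi = {c.gene for c in screen_hemizygous(
                by_gene, TH, cohort=noiseless_bundle.cohort, proband_id=pid)}
            assert not (hom & ch) and not (hom & hemi) and not (ch & hemi)

    def test_maf_threshold_monotonicity(self, noiseless_trios):
        pid = sorted(noiseless_trios)[0]
        by_gene = group_trios_by_gene(noiseless_trios[pid])
        previous: set[str] = set()
        for max_af in (0.0001, 0.001, 0.01, 0.1, 1.0):
            th = replace(TH, max_af=max_af)
            genes = {c.gene for c in screen_homozygous(by_gene, th, proband_id=pid)}
            genes |= {c.gene for c in screen_compound_het(by_gene, th, proband_id=pid)}
            assert previous <= genes
            previous = genes

    def test_truth_table_equivalence_on_noiseless_cohort(
        self, noiseless_bundle, noiseless_trios
    ):
        b = noiseless_bundle
        for p in b.cohort.probands:
            pid = p.individual_id
            by_gene = group_trios_by_gene(noiseless_trios[pid])
            assert {c.gene for c in screen_homozygous(by_gene, TH, proband_id=pid)} == \
                b.truth.genes_for(pid, ["homozygous"])
            assert {c.gene for c in screen_compound_het(by_gene, TH, proband_id=pid)} == \
                b.truth.genes_for(pid, ["comphet_partner_a", "comphet_partner_b"])
            assert {c.gene for c in screen_hemizygous(
                by_gene, TH, cohort=b.cohort, proband_id=pid)} == \
                b.truth.genes_for(pid, ["hemizygous"])

    def test_candidate_gene_counts_within_reported_range_across_seeds(self):
        """>= 95% of probands carry 0-15 inherited candidate genes under the
        default study conditions (the published per-fetus range)."""
        from triotriage.cohort_io import CALLER_LABELS, build_trios, merge_caller_calls
        from triotriage.simulate import SimConfig, simulate_cohort

        counts = []
        for seed in (1, 2):
            b = simulate_cohort(SimConfig(seed=seed).noiseless())
            merged = {
                m.individual_id: merge_caller_calls(
                    [b.callsets[(m.individual_id, c)] for c in CALLER_LABELS]
                )
                for m in b.cohort.members
            }
            trios = build_trios(b.cohort, merged)
            for p in b.cohort.probands:
                pid = p.individual_id
                by_gene = group_trios_by_gene(trios[pid])
                genes = {c.gene for c in screen_homozygous(by_gene, TH, proband_id=pid)}
                genes |= {c.gene for c in screen_compound_het(by_gene, TH, proband_id=pid)}
                genes |= {c.gene for c in screen_hemizygous(
                    by_gene, TH, cohort=b.cohort, proband_id=pid)}
                counts.append(len(genes))
        in_range = sum(1 for c in counts if 0 <= c <= 15)
        assert in_range / len(counts) >= 0.95
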