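"""Pedigree / phenotype / VCF I/O, caller merging, and variant normalization."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triotriage.cohort_io import (
    CALLER_LABELS,
    Cohort,
    Consequence,
    Genotype,
    GenotypeObservation,
    IndividualCallset,
    PedigreeError,
    PhenotypeError,
    ReferenceContext,
    VariantSite,
    in_par,
    merge_caller_calls,
    normalize_variant,
    read_caller_vcf,
    read_pedigree,
    read_phenotypes,
    write_callset_vcf,
    write_pedigree,
    write_phenotypes,
)
from triotriage.classify import ancestor_closure
from triotriage.fixtures import fixture_path, load_fixture_phenotypes


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


class TestPedigree:
    def test_single_trio(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text(
            "FAM1\tP1\t0\t0\t1\t1\t.\n"
            "FAM1\tM1\t0\t0\t2\t1\t.\n"
            "FAM1\tF1\tP1\tM1\t1\t2\t.\n"
        )
        cohort = read_pedigree(p)
        assert len(cohort.members) == 3
        assert [m.individual_id for m in cohort.probands] == ["F1"]
        mother, father = cohort.parents_of("F1")
        assert (mother.individual_id, father.individual_id) == ("M1", "P1")

    def test_quad_two_affected_siblings(self, tmp_path):
        p = tmp_path / "q.ped"
        p.write_text(
            "FAM1\tP1\t0\t0\t1\t1\t.\n"
            "FAM1\tM1\t0\t0\t2\t1\t.\n"
            "FAM1\tF1\tP1\tM1\t2\t2\t.\n"
            "FAM1\tF2\tP1\tM1\t2\t2\t.\n"
        )
        cohort = read_pedigree(p)
        assert len(cohort.members) == 4
        assert len(cohort.probands) == 2

    def test_unknown_father_names_family(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text(
            "FAM9\tM1\t0\t0\t2\t1\t.\n"
            "FAM9\tF1\tP9\tM1\t1\t2\t.\n"
        )
        with pytest.raises(PedigreeError, match="FAM9"):
            read_pedigree(p)

    def test_duplicate_individual_rejected(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("FAM1\tP1\t0\t0\t1\t1\t.\nFAM1\tP1\t0\t0\t1\t1\t.\n")
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(p)

    def test_mz_twin_links_parsed_and_symmetric(self, fixture_cohort):
        assert fixture_cohort.mz_partner("F3") == "F16"
        assert fixture_cohort.mz_partner("F16") == "F3"
        assert fixture_cohort.mz_partner("F1") is None

    def test_asymmetric_twin_link_rejected(self, tmp_path):
        p = tmp_path / "tw.ped"
        p.write_text(
            "FAM1\tP1\t0\t0\t1\t1\t.\n"
            "FAM1\tM1\t0\t0\t2\t1\t.\n"
            "FAM1\tF1\tP1\tM1\t1\t2\tMZ:F2\n"
            "FAM1\tF2\tP1\tM1\t1\t2\t.\n"
        )
        with pytest.raises(PedigreeError, match="symmetric"):
            read_pedigree(p)

    def test_round_trip(self, tmp_path, fixture_cohort):
        out = tmp_path / "rt.ped"
        write_pedigree(fixture_cohort, out)
        again = read_pedigree(out)
        assert again.members == fixture_cohort.members

    def test_fixture_cohort_shape(self, fixture_cohort):
        # 26 trios and two quads: 86 individuals, 30 probands
        assert len(fixture_cohort.members) == 86
        assert len(fixture_cohort.probands) == 30


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


class TestPhenotypes:
    def test_parse_and_dedup(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text(
            "proband_id\thpo_terms\tsource\n"
            "F23\tHP:0002652;HP:0001166;HP:0002652\tultrasound\n"
        )
        (rec,) = read_phenotypes(p)
        assert rec.hpo_terms == {"HP:0002652", "HP:0001166"}
        assert rec.source == "ultrasound"

    def test_malformed_term_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("proband_id\thpo_terms\tsource\nF1\tHP:12\tultrasound\n")
        with pytest.raises(PhenotypeError, match=":2"):
            read_phenotypes(p)

    def test_round_trip(self, tmp_path):
        records = read_phenotypes(fixture_path("cohort_phenotypes.tsv"))
        out = tmp_path / "rt.tsv"
        write_phenotypes(records, out)
        again = read_phenotypes(out)
        assert [(r.proband_id, r.hpo_terms, r.source) for r in again] == [
            (r.proband_id, r.hpo_terms, r.source) for r in records
        ]

    def test_skeletal_category_tally_at_least_eight(self, ontology):
        # the most skeletally affected proband carries >= 8 distinct terms
        # whose ancestor closure reaches the skeletal-system category
        phenos = load_fixture_phenotypes()
        skeletal = sum(
            1 for t in phenos["F1"]
            if "HP:0000924" in ancestor_closure(ontology, [t])
        )
        assert skeletal >= 8


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _callset(ind: str, caller: str, entries) -> IndividualCallset:
    cs = IndividualCallset(individual_id=ind, caller=caller)
    for pos, gt in entries:
        site = VariantSite(chrom="1", pos=pos, ref="A", alt="G", gene="G1",
                           consequence=Consequence.non_synonymous, population_af=0.001)
        cs.add(site, GenotypeObservation(
            individual_id=ind, gt=gt, ad_ref=30, ad_alt=30, depth=60, gq=99,
            callers=frozenset({caller}),
        ))
    return cs


class TestMerge:
    def test_identical_call_unions_callers(self):
        sets = [_callset("F1", c, [(100, Genotype.het)]) for c in CALLER_LABELS]
        merged = merge_caller_calls(sets)
        assert len(merged) == 1
        (_, obs), = merged.calls.values()
        assert obs.callers == frozenset(CALLER_LABELS)
        assert obs.gt is Genotype.het
        assert not obs.discordant

    def test_disjoint_sets_union(self):
        sets = [
            _callset("F1", c, [(100 + i, Genotype.het)])
            for i, c in enumerate(CALLER_LABELS)
        ]
        merged = merge_caller_calls(sets)
        assert len(merged) == 3
        assert all(len(obs.callers) == 1 for _, obs in merged.calls.values())

    def test_majority_vote_keeps_het_and_flags_discordance(self):
        sets = [
            _callset("F1", "samtools_like", [(100, Genotype.het)]),
            _callset("F1", "gatk_like", [(100, Genotype.het)]),
            _callset("F1", "dindel_like", [(100, Genotype.hom_alt)]),
        ]
        (_, obs), = merge_caller_calls(sets).calls.values()
        assert obs.gt is Genotype.het
        assert obs.discordant

    def test_two_way_tie_resolves_to_less_severe(self):
        sets = [
            _callset("F1", "samtools_like", [(100, Genotype.het)]),
            _callset("F1", "gatk_like", [(100, Genotype.hom_alt)]),
        ]
        (_, obs), = merge_caller_calls(sets).calls.values()
        assert obs.gt is Genotype.het
        assert obs.discordant

    def test_different_individuals_rejected(self):
        with pytest.raises(ValueError, match="different individuals"):
            merge_caller_calls([
                _callset("F1", "a", [(100, Genotype.het)]),
                _callset("F2", "b", [(100, Genotype.het)]),
            ])

    def test_size_bounds_and_order_invariance(self):
        sets = [
            _callset("F1", "samtools_like", [(100, Genotype.het), (200, Genotype.hom_alt)]),
            _callset("F1", "gatk_like", [(100, Genotype.hom_alt), (300, Genotype.het)]),
            _callset("F1", "dindel_like", [(200, Genotype.hom_alt)]),
        ]
        reference = merge_caller_calls(sets)
        assert max(len(s) for s in sets) <= len(reference) <= sum(len(s) for s in sets)
        for perm in itertools.permutations(sets):
            other = merge_caller_calls(list(perm))
            assert other.calls == reference.calls


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

# toy reference: positions 100..119
_TOY = ReferenceContext(chrom="1", start=100, seq="GCTAAAACGTTGATCGATCG")


def _site(pos, ref, alt):
    return VariantSite(chrom="1", pos=pos, ref=ref, alt=alt)


def _brute_force_minimal(site: VariantSite) -> tuple[int, str, str]:
    """Enumerate every representation of the same edit on the toy sequence
    and return the left-most parsimonious one."""
    seq, start = _TOY.seq, _TOY.start
    i = site.pos - start
    edited = seq[:i] + site.alt + seq[i + len(site.ref):]
    best = None
    for p in range(len(seq)):
        for rl in range(0, len(seq) - p + 1):
            for alt_len in range(0, 6):
                for alt in _enumerate_strings(seq, p, alt_len):
                    cand = seq[:p] + alt + seq[p + rl:]
                    ref = seq[p:p + rl]
                    if cand != edited or ref == alt or not ref or not alt:
                        continue
                    key = (p + start, ref, alt)
                    if best is None or (len(ref) + len(alt), key[0]) < (
                        len(best[1]) + len(best[2]), best[0]
                    ):
                        best = key
    return best


def _enumerate_strings(seq, p, alt_len):
    # candidate alt strings must reproduce the edited sequence, so only
    # substrings drawn from the local context are worth trying
    seen = set()
    for q in range(max(0, p - 6), min(len(seq), p + 6)):
        s = seq[q:q + alt_len]
        if len(s) == alt_len and s not in seen:
            seen.add(s)
            yield s


class TestNormalize:
    def test_snv_unchanged(self):
        s = _site(103, "A", "G")
        assert normalize_variant(s, _TOY) == s

    def test_right_shifted_deletion_left_aligns_to_run_start(self):
        # AAAA run occupies 103..106; a deletion written at the run's right
        # edge must shift to the anchor base before the run
        shifted = _site(105, "AA", "A")
        norm = normalize_variant(shifted, _TOY)
        assert (norm.pos, norm.ref, norm.alt) == (102, "TA", "T")

    def test_padded_representation_trims(self):
        # GTT at 108..110 followed by G: "TTG"->"TG" is a padded T deletion
        padded = _site(109, "TTG", "TG")
        norm = normalize_variant(padded, _TOY)
        assert (norm.pos, norm.ref, norm.alt) == (108, "GT", "G")

    def test_idempotent(self):
        norm = normalize_variant(_site(105, "AA", "A"), _TOY)
        assert normalize_variant(norm, _TOY) == norm

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            normalize_variant(_site(103, "C", "G"), _TOY)

    @pytest.mark.parametrize(
        "pos,ref,alt",
        [
            (105, "AA", "A"), (104, "AA", "A"), (104, "AAA", "AA"),
            (109, "TTG", "TG"), (110, "TG", "G"), (103, "AAAAC", "AAAC"),
            (112, "ATC", "A"), (113, "TCGAT", "T"),
        ],
    )
    def test_equivalent_representations_normalize_identically(self, pos, ref, alt):
        site = _site(pos, ref, alt)
        norm = normalize_variant(site, _TOY)
        expect = _brute_force_minimal(site)
        assert (norm.pos, norm.ref, norm.alt) == expect

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        pos=st.integers(min_value=102, max_value=114),
        del_len=st.integers(min_value=1, max_value=3),
    )
    def test_all_shifts_of_a_deletion_converge(self, pos, del_len):
        # any padded/shifted spelling of the same deletion normalizes to one record
        ref = _TOY.slice(pos, del_len + 1)
        site = _site(pos, ref, ref[0])
        norm = normalize_variant(site, _TOY)
        padded = _site(pos, ref + _TOY.base_at(pos + del_len + 1), ref[0] + _TOY.base_at(pos + del_len + 1))
        assert normalize_variant(padded, _TOY) == norm


# ---------------------------------------------------------------------------
# VCF round trip + PAR helper
# ---------------------------------------------------------------------------


class TestVcfRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path, small_bundle):
        b = small_bundle
        ind, caller = next(iter(b.callsets))
        cs = b.callsets[(ind, caller)]
        out = tmp_path / "rt.vcf"
        write_callset_vcf(cs, out)
        again = read_caller_vcf(out, caller)
        assert again.individual_id == ind
        assert set(again.calls) == set(cs.calls)
        for key, (site, obs) in cs.calls.items():
            site2, obs2 = again.calls[key]
            assert site2 == site
            assert (obs2.gt, obs2.ad_ref, obs2.ad_alt, obs2.depth, obs2.gq) == (
                obs.gt, obs.ad_ref, obs.ad_alt, obs.depth, obs.gq
            )


def test_par_boundaries():
    assert in_par("X", 60_001)
    assert in_par("X", 2_699_520)
    assert not in_par("X", 2_699_521)
    assert not in_par("X", 50_000_000)
    assert not in_par("7", 60_001)
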