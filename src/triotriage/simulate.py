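"""Synthetic trio-exome cohort generator with a ground-truth table.

The generator emulates the data a family-based exome study hands to the
triage pipeline: per-individual, per-caller call sets over a shared set of
population (background) sites plus injected events with known truth —
de novo point mutations at a Poisson rate of 1.1 per proband (29% of them
synonymous), compound-heterozygous pairs placed on opposite parental
haplotypes, homozygous-recessive and male X-linked hemizygous
configurations, mosaic de novos with a depleted alt-read fraction, and
monozygotic twins with identical genotypes including their de novos.

Background genotypes follow Hardy-Weinberg at each site's population allele
frequency with Mendelian transmission to children.  The generator guarantees
that background variation never forms a candidate-grade configuration
(rare + functional homozygous / compound-het / hemizygous) by demoting the
child genotype in the few chance cases — so, at noiseless settings, the
screens' output must equal the truth-table projection exactly.  Observed
noise consists of allele-depth sampling, a per-base error rate that can
produce depth-driven genotype miscalls, and per-caller call dropout; read
simulation and caller internals are out of scope.

With a fixed seed the emitted bundle is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from triotriage.cnv import CnvCall, GeneInterval, write_cnv_table
from triotriage.cohort_io import (
    CALLER_LABELS,
    Cohort,
    Consequence,
    Genotype,
    GenotypeObservation,
    IndividualCallset,
    PedigreeMember,
    PhenotypeRecord,
    Role,
    Sex,
    VariantSite,
    in_par,
    write_callset_vcf,
    write_pedigree,
    write_phenotypes,
)
from triotriage.classify import GeneEvidence, write_evidence_table

__all__ = [
    "DepthModel",
    "SimConfig",
    "TruthRecord",
    "TruthTable",
    "CohortBundle",
    "simulate_cohort",
    "make_gene_model",
    "write_truth",
    "read_truth",
    "MIN_CNV_CONFIDENCE",
]

#: Default confidence cut for CNV filtering: the 99th percentile of the
#: generator's noise-score distribution (Normal(5, 2) truncated at 0).
MIN_CNV_CONFIDENCE = 10.0

_BASES = ("A", "C", "G", "T")

#: Split of functional consequences among non-synonymous-fraction de novos,
#: matching the observed composition of validated de novo sets
#: (missense-dominated, a few nonsense, occasional splice).
_FUNCTIONAL_DENOVO_CLASSES = (
    (Consequence.non_synonymous, 0.867),
    (Consequence.stop_gained, 0.100),
    (Consequence.essential_splice_site, 0.033),
)

_BACKGROUND_CSQ = (
    (Consequence.non_synonymous, 0.50),
    (Consequence.synonymous, 0.30),
    (Consequence.other, 0.15),
    (Consequence.stop_gained, 0.03),
    (Consequence.frameshift_coding, 0.01),
    (Consequence.essential_splice_site, 0.01),
)

#: Phenotype leaf terms the generator samples proband HPO sets from (a subset
#: of the packaged mini ontology).
_PHENOTYPE_POOL = (
    "HP:0002652", "HP:0003026", "HP:0000774", "HP:0001762", "HP:0005180",
    "HP:0001631", "HP:0001660", "HP:0011611", "HP:0001392", "HP:0010442",
    "HP:0002119", "HP:0001274", "HP:0001250", "HP:0000202", "HP:0002721",
    "HP:0000252", "HP:0001999", "HP:0000062", "HP:0002575", "HP:0000104",
    "HP:0000772", "HP:0000925", "HP:0002650", "HP:0001363", "HP:0000347",
    "HP:0000003", "HP:0001989", "HP:0002804", "HP:0000957", "HP:0002021",
)


@dataclass(frozen=True)
class DepthModel:
    """Sequencing-depth and allele-depth noise model.

    ``mean_depth`` defaults to 103 (the coverage scale of the emulated
    study); ``dispersion`` switches depth from Poisson to negative binomial;
    ``base_error_rate`` is the probability that a read supports the wrong
    allele, which at low depth can drive genotype miscalls.
    """

    mean_depth: float = 103.0
    dispersion: float | None = None
    base_error_rate: float = 0.002


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated cohort: 26 trios plus one sibling quad and
    one monozygotic-twin quad (30 probands, 86 individuals), a de novo rate
    of 1.1 per proband with a 29% synonymous fraction, and three callers
    with independent dropout.
    """

    n_trios: int = 26
    n_quads: int = 1
    n_mz_twin_pairs: int = 1
    n_genes: int = 1000
    n_sites: int = 1500
    de_novo_rate_per_proband: float = 1.1
    synonymous_fraction_de_novo: float = 0.29
    n_comphet_genes_per_proband: int = 2
    n_homozygous_per_proband: int = 1
    n_hemizygous_per_male_proband: int = 1
    af_beta: tuple[float, float] = (0.3, 3.0)
    depth: DepthModel = field(default_factory=DepthModel)
    mosaic_fraction: float | None = 0.15
    mosaic_rate: float = 0.06
    caller_dropout: float = 0.0
    n_cnv_noise_per_family: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "synonymous_fraction_de_novo", "mosaic_rate", "caller_dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_trios", "n_quads", "n_mz_twin_pairs", "n_genes", "n_sites",
            "n_comphet_genes_per_proband", "n_homozygous_per_proband",
            "n_hemizygous_per_male_proband",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "SimConfig":
        """The same conditions with depth noise and caller dropout removed."""
        return replace(
            self,
            depth=replace(self.depth, base_error_rate=0.0),
            caller_dropout=0.0,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "depth" in raw:
            raw["depth"] = DepthModel(**raw["depth"])
        if "af_beta" in raw:
            raw["af_beta"] = tuple(raw["af_beta"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["af_beta"] = list(d["af_beta"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class TruthRecord:
    proband_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    true_class: str  # de_novo | mosaic_de_novo | comphet_partner_a/b | homozygous | hemizygous
    dropped: bool = False  # true if no caller emitted the proband record

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class TruthTable(list):
    """List of TruthRecord with per-class and per-proband projections."""

    def by_class(self, true_class: str) -> list[TruthRecord]:
        return [r for r in self if r.true_class == true_class]

    def denovo_records(self) -> list[TruthRecord]:
        return [r for r in self if r.true_class in ("de_novo", "mosaic_de_novo")]

    def genes_for(self, proband_id: str, classes: Iterable[str]) -> set[str]:
        cls = set(classes)
        return {r.gene for r in self if r.proband_id == proband_id and r.true_class in cls}


def write_truth(truth: TruthTable, path: str | Path) -> None:
    rows = ["proband_id\tchrom\tpos\tref\talt\tgene\tconsequence\ttrue_class\tdropped"]
    for r in truth:
        rows.append(
            f"{r.proband_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.gene}\t"
            f"{r.consequence}\t{r.true_class}\t{int(r.dropped)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_truth(path: str | Path) -> TruthTable:
    truth = TruthTable()
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        p = line.split("\t")
        truth.append(
            TruthRecord(p[0], p[1], int(p[2]), p[3], p[4], p[5], p[6], p[7], p[8] == "1")
        )
    return truth


@dataclass
class CohortBundle:
    """Everything one simulated cohort produced, in memory and (optionally) on disk."""

    config: SimConfig
    cohort: Cohort
    phenotypes: list[PhenotypeRecord]
    gene_model: list[GeneInterval]
    callsets: dict[tuple[str, str], IndividualCallset]  # (individual, caller) -> calls
    truth: TruthTable
    cnv_calls: list[CnvCall]
    cnv_truth_keys: set[tuple[str, int, int, str]]  # (chrom, start, end, family)
    common_catalog: list[tuple[str, int, int]]
    evidence: dict[str, GeneEvidence]
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)


def make_gene_model(n_genes: int, rng: np.random.Generator) -> list[GeneInterval]:
    """Synthetic gene set: coding lengths log-normal around 1.5 kb, genes laid
    end to end with 10 kb gaps, spread over chr1-22 and X (X genes start at
    position 60,001 so the first ones fall inside the pseudoautosomal region
    and exercise the PAR boundary)."""
    lengths = np.maximum(150, rng.lognormal(np.log(1500), 0.6, size=n_genes)).astype(int)
    per_chrom = int(np.ceil(n_genes / len(_CHROMS)))
    genes: list[GeneInterval] = []
    i = 0
    for chrom in _CHROMS:
        cursor = 60_001 if chrom == "X" else 1_000_000
        n_on_chrom = 0
        for _ in range(per_chrom):
            if i >= n_genes:
                break
            # on X, keep the first three genes inside PAR1 to exercise the
            # boundary, then jump past it so the rest are truly hemizygous
            if chrom == "X" and n_on_chrom == 3:
                cursor = max(cursor, 3_000_000)
            n_on_chrom += 1
            span = int(lengths[i]) * 3
            genes.append(
                GeneInterval(
                    chrom=chrom,
                    start=cursor,
                    end=cursor + span - 1,
                    gene=f"G{i + 1:04d}",
                    biotype="protein_coding" if rng.random() > 0.05 else "lincRNA",
                    coding_length=int(lengths[i]),
                )
            )
            cursor += span + 10_000
            i += 1
    return genes


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------


def _build_pedigree(config: SimConfig, rng: np.random.Generator) -> Cohort:
    members: list[PedigreeMember] = []
    fam_no = 0

    def add_family(proband_specs: list[tuple[str, Sex, str | None]]) -> None:
        nonlocal fam_no
        fam_no += 1
        fam = f"FAM{fam_no:03d}"
        mother = f"M{fam_no:03d}"
        father = f"P{fam_no:03d}"
        members.append(PedigreeMember(mother, fam, Role.mother, Sex.female))
        members.append(PedigreeMember(father, fam, Role.father, Sex.male))
        for pid, sex, twin in proband_specs:
            members.append(
                PedigreeMember(
                    pid, fam, Role.proband, sex,
                    mz_twin_of=twin, affected=True,
                    mother_id=mother, father_id=father,
                )
            )

    for _ in range(config.n_trios):
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        add_family([(f"F{fam_no + 1:03d}", sex, None)])
    for _ in range(config.n_quads):
        n = fam_no + 1
        sexes = [Sex.male if rng.random() < 0.5 else Sex.female for _ in range(2)]
        add_family([(f"F{n:03d}a", sexes[0], None), (f"F{n:03d}b", sexes[1], None)])
    for _ in range(config.n_mz_twin_pairs):
        n = fam_no + 1
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        a, b = f"F{n:03d}a", f"F{n:03d}b"
        add_family([(a, sex, b), (b, sex, a)])
    return Cohort(members)


# ---------------------------------------------------------------------------
# Genotype machinery (truth genotypes as allele tuples)
# ---------------------------------------------------------------------------


def _gt_from_alleles(alleles: tuple[int, ...]) -> Genotype:
    if len(alleles) == 1:
        return Genotype.hemi_alt if alleles[0] else Genotype.hemi_ref
    s = sum(alleles)
    return (Genotype.hom_ref, Genotype.het, Genotype.hom_alt)[s]


def _hw_alleles(af: float, ploidy: int, rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(int(rng.random() < af) for _ in range(ploidy))


def _transmit(parent: tuple[int, ...], rng: np.random.Generator) -> int:
    return parent[int(rng.integers(len(parent)))] if len(parent) > 1 else parent[0]


# ---------------------------------------------------------------------------
# The generator
# ---------------------------------------------------------------------------


class _SiteFactory:
    """Allocates unique variant sites inside genes."""

    def __init__(self, gene_model: Sequence[GeneInterval], rng: np.random.Generator):
        self.rng = rng
        self.genes = list(gene_model)
        self.autosomal = [g for g in self.genes if g.chrom != "X"]
        self.x_nonpar = [
            g for g in self.genes if g.chrom == "X" and not in_par("X", g.start)
        ]
        self.used: set[tuple[str, int]] = set()

    def new_site(
        self,
        gene: GeneInterval,
        consequence: Consequence,
        population_af: float | None,
        indel: bool = False,
    ) -> VariantSite:
        for _ in range(1000):
            pos = int(self.rng.integers(gene.start, gene.end + 1))
            if (gene.chrom, pos) not in self.used:
                break
        else:  # pragma: no cover - gene saturated
            raise RuntimeError(f"cannot place new site in gene {gene.gene}")
        self.used.add((gene.chrom, pos))
        ref = _BASES[int(self.rng.integers(4))]
        if indel:
            ins = _BASES[int(self.rng.integers(4))]
            return VariantSite(
                chrom=gene.chrom, pos=pos, ref=ref, alt=ref + ins,
                gene=gene.gene, consequence=consequence, population_af=population_af,
            )
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(self.rng.integers(3))) % 4]
        return VariantSite(
            chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
            gene=gene.gene, consequence=consequence, population_af=population_af,
        )


def _pick_unused_gene(
    pool: Sequence[GeneInterval], used: set[str], rng: np.random.Generator
) -> GeneInterval:
    for _ in range(200):
        g = pool[int(rng.integers(len(pool)))]
        if g.gene not in used:
            used.add(g.gene)
            return g
    raise RuntimeError("gene pool exhausted: too many injections for the gene model")


def _rare_af(rng: np.random.Generator) -> float:
    return float(f"{float(rng.uniform(1e-4, 0.009)):.6g}")


def _draw_categorical(rng: np.random.Generator, table: Sequence[tuple]) -> object:
    u = rng.random()
    acc = 0.0
    for value, p in table:
        acc += p
        if u < acc:
            return value
    return table[-1][0]


def simulate_cohort(config: SimConfig, outdir: str | Path | None = None) -> CohortBundle:
    """Generate a full cohort bundle; write it under ``outdir`` if given.

    The bundle contains the pedigree, phenotype table, per-individual
    per-caller call sets, CNV call table with a common-CNV catalog, an
    (all-false) gene-evidence table, and the truth table for every injected
    event.  Same config (including seed) -> byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    gene_model = make_gene_model(config.n_genes, rng)
    factory = _SiteFactory(gene_model, rng)
    cohort = _build_pedigree(config, rng)

    # -- background population sites -------------------------------------
    coding_genes = [g for g in gene_model if g.biotype == "protein_coding"]
    background: list[VariantSite] = []
    for _ in range(config.n_sites):
        gene = coding_genes[int(rng.integers(len(coding_genes)))]
        csq = _draw_categorical(rng, _BACKGROUND_CSQ)
        # quantize to the precision the VCF writer emits
        af = float(f"{float(np.clip(rng.beta(*config.af_beta), 1e-5, 0.99)):.6g}")
        background.append(factory.new_site(gene, csq, af))

    truth = TruthTable()
    phenotypes: list[PhenotypeRecord] = []
    # (individual, caller) -> callset
    callsets: dict[tuple[str, str], IndividualCallset] = {
        (m.individual_id, c): IndividualCallset(m.individual_id, c)
        for m in cohort.members
        for c in CALLER_LABELS
    }

    families: dict[str, list[PedigreeMember]] = {}
    for m in cohort.members:
        families.setdefault(m.family_id, []).append(m)

    for fam_id in sorted(families):
        fam_members = families[fam_id]
        probands = [m for m in fam_members if m.role is Role.proband]
        mother = next(m for m in fam_members if m.role is Role.mother)
        father = next(m for m in fam_members if m.role is Role.father)
        mz_pair = {p.individual_id for p in probands if p.mz_twin_of}

        # truth alleles per site per member
        sites: dict[tuple[str, int, str, str], VariantSite] = {}
        alleles: dict[tuple[str, int, str, str], dict[str, tuple[int, ...]]] = {}
        mosaic_sites: set[tuple[tuple[str, int, str, str], str]] = set()

        def member_ploidy(member: PedigreeMember, site: VariantSite) -> int:
            on_x = site.chrom == "X" and not in_par(site.chrom, site.pos)
            return 1 if on_x and member.sex is Sex.male else 2

        def set_site(site: VariantSite, fam_alleles: dict[str, tuple[int, ...]]) -> None:
            sites[site.key] = site
            alleles[site.key] = fam_alleles

        # background genotypes under HW + Mendelian transmission
        for site in background:
            m_al = _hw_alleles(site.population_af, member_ploidy(mother, site), rng)
            f_al = _hw_alleles(site.population_af, member_ploidy(father, site), rng)
            fam_al = {mother.individual_id: m_al, father.individual_id: f_al}
            twin_cache: tuple[int, ...] | None = None
            for child in probands:
                if child.individual_id in mz_pair and twin_cache is not None:
                    fam_al[child.individual_id] = twin_cache
                    continue
                maternal = _transmit(m_al, rng)
                if member_ploidy(child, site) == 1:
                    child_al: tuple[int, ...] = (maternal,)
                else:
                    child_al = (maternal, _transmit(f_al, rng))
                fam_al[child.individual_id] = child_al
                if child.individual_id in mz_pair:
                    twin_cache = child_al
            if any(sum(a) for a in fam_al.values()):
                set_site(site, fam_al)

        # scrub chance candidate-grade background configurations so the
        # truth table stays the exact expectation for the screens
        for key in list(sites):
            site = sites[key]
            if not (site.is_rare and site.consequence.value in (
                "essential_splice_site", "stop_gained", "frameshift_coding",
                "non_synonymous", "stop_lost",
            )):
                continue
            fam_al = alleles[key]
            for child in probands:
                c_al = fam_al[child.individual_id]
                if len(c_al) == 1 and c_al[0] == 1:
                    fam_al[child.individual_id] = (0,)  # chance hemizygous
                elif len(c_al) == 2 and sum(c_al) == 2:
                    fam_al[child.individual_id] = (0, 1)  # chance homozygous -> het
        # chance compound-het: demote one side if a gene gathers confident
        # maternal and paternal rare functional hets in a child
        per_gene: dict[tuple[str, str], list[tuple[str, tuple[str, int, str, str]]]] = {}
        for key, site in sites.items():
            if not (site.is_rare and site.consequence.value != "synonymous"
                    and site.consequence.value != "other"):
                continue
            fam_al = alleles[key]
            m_car = sum(fam_al[mother.individual_id]) > 0
            f_car = sum(fam_al[father.individual_id]) > 0
            for child in probands:
                if sum(fam_al[child.individual_id]) == 1 and len(fam_al[child.individual_id]) == 2:
                    if m_car != f_car:
                        origin = "maternal" if m_car else "paternal"
                        per_gene.setdefault((child.individual_id, site.gene), []).append(
                            (origin, key)
                        )
        for (child_id, _gene), hits in per_gene.items():
            origins = {o for o, _ in hits}
            if {"maternal", "paternal"} <= origins:
                _, key = hits[0]
                demoted = dict(alleles[key])
                demoted[child_id] = (0, 0) if len(demoted[child_id]) == 2 else (0,)
                alleles[key] = demoted

        # -- injected events ---------------------------------------------
        def inject(site: VariantSite, fam_alleles: dict[str, tuple[int, ...]],
                   proband_id: str, true_class: str) -> None:
            set_site(site, fam_alleles)
            truth.append(
                TruthRecord(
                    proband_id=proband_id, chrom=site.chrom, pos=site.pos,
                    ref=site.ref, alt=site.alt, gene=site.gene,
                    consequence=site.consequence.value, true_class=true_class,
                )
            )

        handled_twins: set[str] = set()
        for child in probands:
            cid = child.individual_id
            if cid in handled_twins:
                continue
            twin_id = child.mz_twin_of
            recipients = [cid] + ([twin_id] if twin_id else [])
            if twin_id:
                handled_twins.update(recipients)

            # de novo events
            n_dn = int(rng.poisson(config.de_novo_rate_per_proband))
            for _ in range(n_dn):
                if rng.random() < config.synonymous_fraction_de_novo:
                    csq = Consequence.synonymous
                else:
                    csq = _draw_categorical(rng, _FUNCTIONAL_DENOVO_CLASSES)
                gene = factory.genes[int(rng.integers(len(factory.genes)))]
                site = factory.new_site(gene, csq, None)
                is_mosaic = (
                    config.mosaic_fraction is not None
                    and rng.random() < config.mosaic_rate
                )
                fam_al = {
                    mother.individual_id: (0,) * member_ploidy(mother, site),
                    father.individual_id: (0,) * member_ploidy(father, site),
                }
                for p in probands:
                    ploidy = member_ploidy(p, site)
                    if p.individual_id in recipients:
                        fam_al[p.individual_id] = (1,) if ploidy == 1 else (0, 1)
                    else:
                        fam_al[p.individual_id] = (0,) * ploidy
                cls = "mosaic_de_novo" if is_mosaic else "de_novo"
                for rec in recipients:
                    inject(site, fam_al, rec, cls)
                    if is_mosaic:
                        mosaic_sites.add((site.key, rec))

            # compound-het pairs on opposite parental haplotypes
            used_genes: set[str] = set()
            for _ in range(config.n_comphet_genes_per_proband):
                gene = _pick_unused_gene(factory.autosomal, used_genes, rng)
                for partner, carrier in (("comphet_partner_a", mother), ("comphet_partner_b", father)):
                    af = _rare_af(rng)
                    site = factory.new_site(gene, Consequence.non_synonymous, af)
                    fam_al = {
                        mother.individual_id: (0, 1) if carrier is mother else (0, 0),
                        father.individual_id: (0, 1) if carrier is father else (0, 0),
                    }
                    for p in probands:
                        fam_al[p.individual_id] = (
                            (0, 1) if p.individual_id in recipients else (0, 0)
                        )
                    for rec in recipients:
                        inject(site, fam_al, rec, partner)

            # homozygous recessive
            for _ in range(config.n_homozygous_per_proband):
                gene = _pick_unused_gene(factory.autosomal, used_genes, rng)
                af = _rare_af(rng)
                site = factory.new_site(gene, Consequence.non_synonymous, af)
                fam_al = {mother.individual_id: (0, 1), father.individual_id: (0, 1)}
                for p in probands:
                    fam_al[p.individual_id] = (
                        (1, 1) if p.individual_id in recipients else (0, 0)
                    )
                for rec in recipients:
                    inject(site, fam_al, rec, "homozygous")

            # X-linked hemizygous (male probands only)
            if child.sex is Sex.male and factory.x_nonpar:
                for _ in range(config.n_hemizygous_per_male_proband):
                    gene = _pick_unused_gene(factory.x_nonpar, used_genes, rng)
                    af = _rare_af(rng)
                    site = factory.new_site(gene, Consequence.non_synonymous, af)
                    fam_al = {mother.individual_id: (0, 1), father.individual_id: (0,)}
                    for p in probands:
                        ploidy = member_ploidy(p, site)
                        if p.individual_id in recipients:
                            fam_al[p.individual_id] = (1,) if ploidy == 1 else (0, 1)
                        else:
                            fam_al[p.individual_id] = (0,) * ploidy
                    for rec in recipients:
                        inject(site, fam_al, rec, "hemizygous")

        # -- observations: depths, called genotypes, caller dropout -------
        dm = config.depth
        ordered_keys = sorted(sites)
        for key in ordered_keys:
            site = sites[key]
            fam_al = alleles[key]
            for member in fam_members:
                true_gt = _gt_from_alleles(fam_al[member.individual_id])
                if dm.dispersion is not None:
                    p_nb = dm.dispersion / (dm.dispersion + dm.mean_depth)
                    depth = int(rng.negative_binomial(dm.dispersion, p_nb))
                else:
                    depth = int(rng.poisson(dm.mean_depth))
                depth = max(depth, 1)
                is_mosaic = (key, member.individual_id) in mosaic_sites
                if true_gt is Genotype.het:
                    frac = config.mosaic_fraction if is_mosaic else 0.5
                    ad_alt = int(rng.binomial(depth, frac))
                elif true_gt in (Genotype.hom_alt, Genotype.hemi_alt):
                    ad_alt = depth - int(rng.binomial(depth, dm.base_error_rate))
                else:
                    ad_alt = int(rng.binomial(depth, dm.base_error_rate))
                ad_ref = depth - ad_alt
                called = _call_genotype(true_gt, ad_ref, ad_alt)
                gq = min(99, 3 * depth) if called is not Genotype.missing else 0
                obs_template = dict(
                    individual_id=member.individual_id,
                    gt=called, ad_ref=ad_ref, ad_alt=ad_alt, depth=depth, gq=gq,
                )
                for caller in CALLER_LABELS:
                    if rng.random() < config.caller_dropout:
                        continue
                    callsets[(member.individual_id, caller)].add(
                        site,
                        GenotypeObservation(callers=frozenset({caller}), **obs_template),
                    )

        # phenotype records (1-3 terms per proband; twins share)
        twin_terms: dict[str, set[str]] = {}
        for child in probands:
            if child.mz_twin_of and child.mz_twin_of in twin_terms:
                terms = twin_terms[child.mz_twin_of]
            else:
                n_terms = int(rng.integers(1, 4))
                idx = rng.choice(len(_PHENOTYPE_POOL), size=n_terms, replace=False)
                terms = {_PHENOTYPE_POOL[i] for i in idx}
                twin_terms[child.individual_id] = terms
            phenotypes.append(
                PhenotypeRecord(proband_id=child.individual_id, hpo_terms=set(terms))
            )

    # mark truth records whose proband record every caller dropped
    for rec in truth:
        present = any(
            rec.site_key in callsets[(rec.proband_id, c)].calls for c in CALLER_LABELS
        )
        rec.dropped = not present

    # -- CNVs --------------------------------------------------------------
    cnv_calls, cnv_truth_keys, common_catalog = _simulate_cnvs(
        config, cohort, gene_model, rng
    )

    # -- evidence table (no curated evidence: all flags false) -------------
    evidence = {
        gene: GeneEvidence(gene=gene)
        for gene in sorted({r.gene for r in truth})
    }

    bundle = CohortBundle(
        config=config, cohort=cohort, phenotypes=phenotypes, gene_model=gene_model,
        callsets=callsets, truth=truth, cnv_calls=cnv_calls,
        cnv_truth_keys=cnv_truth_keys, common_catalog=common_catalog,
        evidence=evidence,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _call_genotype(true_gt: Genotype, ad_ref: int, ad_alt: int) -> Genotype:
    """Depth-driven genotype call: the truth unless the sampled allele depths
    are uninformative (het with no alt reads) or misleading (ref call with
    substantial alt support)."""
    depth = ad_ref + ad_alt
    if true_gt is Genotype.het:
        if ad_alt == 0:
            return Genotype.hom_ref
        if ad_ref == 0:
            return Genotype.hom_alt
        return Genotype.het
    if true_gt is Genotype.hom_ref and ad_alt >= 3 and ad_alt >= 0.2 * depth:
        return Genotype.het
    if true_gt is Genotype.hom_alt and ad_ref >= 3 and ad_ref >= 0.2 * depth:
        return Genotype.het
    if true_gt is Genotype.hemi_ref and ad_alt >= 3 and ad_alt >= 0.2 * depth:
        return Genotype.hemi_alt
    if true_gt is Genotype.hemi_alt and ad_alt == 0:
        return Genotype.hemi_ref
    return true_gt


def _simulate_cnvs(
    config: SimConfig,
    cohort: Cohort,
    gene_model: Sequence[GeneInterval],
    rng: np.random.Generator,
) -> tuple[list[CnvCall], set[tuple[str, int, int, str]], list[tuple[str, int, int]]]:
    """Inject pathogenic-configuration CNVs plus assorted noise calls.

    Pathogenic set (echoing the emulated study's three survivors): a de novo
    deletion, a de novo duplication, and an X-linked maternally inherited
    deletion in a male proband if one exists.  Noise per family: a
    low-confidence call, a common-CNV match, an intergenic call, and a
    dominant-inconsistent call (all removable by exactly one filter each).
    """
    autosomal = [g for g in gene_model if g.chrom != "X" and g.biotype == "protein_coding"]
    x_genes = [g for g in gene_model if g.chrom == "X" and not in_par("X", g.start)
               and g.biotype == "protein_coding"]
    # common catalog: intervals over a sample of genes
    catalog: list[tuple[str, int, int]] = []
    idx = rng.choice(len(autosomal), size=min(30, len(autosomal)), replace=False)
    for i in sorted(idx):
        g = autosomal[i]
        catalog.append((g.chrom, g.start - 500, g.end + 500))

    calls: list[CnvCall] = []
    truth_keys: set[tuple[str, int, int, str]] = set()
    probands = cohort.probands
    catalog_genes = {autosomal[i].gene for i in idx}
    clean = [g for g in autosomal if g.gene not in catalog_genes]

    def family_carriers(pid: str, carry: Mapping[str, bool]) -> dict[str, bool]:
        mother, father = cohort.parents_of(pid)
        base = {pid: False, mother.individual_id: False, father.individual_id: False}
        base.update(carry)
        return base

    def pathogenic(pid: str, gene: GeneInterval, cnv_type: str,
                   carry: Mapping[str, bool]) -> None:
        start = gene.start - int(rng.integers(200, 2000))
        end = gene.end + int(rng.integers(200, 2000))
        member = cohort.member(pid)
        call = CnvCall(
            chrom=gene.chrom, start=start, end=end, cnv_type=cnv_type,
            confidence=float(rng.uniform(15, 30)), family_id=member.family_id,
            carrier=family_carriers(pid, carry),
        )
        calls.append(call)
        truth_keys.add((call.chrom, call.start, call.end, call.family_id))

    # de novo deletion + de novo duplication in the first two probands
    if probands and clean:
        pathogenic(probands[0].individual_id,
                   clean[int(rng.integers(len(clean)))], "deletion",
                   {probands[0].individual_id: True})
    if len(probands) > 1 and clean:
        pathogenic(probands[1].individual_id,
                   clean[int(rng.integers(len(clean)))], "duplication",
                   {probands[1].individual_id: True})
    males = [p for p in probands[2:] if p.sex is Sex.male]
    if males and x_genes:
        pid = males[0].individual_id
        mother, _ = cohort.parents_of(pid)
        pathogenic(pid, x_genes[int(rng.integers(len(x_genes)))], "deletion",
                   {pid: True, mother.individual_id: True})

    # noise calls per family
    fams = sorted({p.family_id for p in probands})
    for fam in fams:
        fam_probands = [p for p in probands if p.family_id == fam]
        pid = fam_probands[0].individual_id
        mother, father = cohort.parents_of(pid)
        for _ in range(config.n_cnv_noise_per_family):
            kind = int(rng.integers(4))
            if kind == 0 and clean:  # low confidence, genic, de novo
                g = clean[int(rng.integers(len(clean)))]
                calls.append(CnvCall(
                    chrom=g.chrom, start=g.start, end=g.end, cnv_type="deletion",
                    confidence=float(max(0.1, rng.normal(5, 2))), family_id=fam,
                    carrier=family_carriers(pid, {pid: True}),
                ))
            elif kind == 1 and catalog:  # matches a common CNV exactly
                c, s, e = catalog[int(rng.integers(len(catalog)))]
                calls.append(CnvCall(
                    chrom=c, start=s, end=e, cnv_type="duplication",
                    confidence=float(rng.uniform(15, 30)), family_id=fam,
                    carrier=family_carriers(pid, {pid: True}),
                ))
            elif kind == 2:  # intergenic
                g = autosomal[int(rng.integers(len(autosomal) - 1))]
                calls.append(CnvCall(
                    chrom=g.chrom, start=g.end + 1000, end=g.end + 5000,
                    cnv_type="deletion",
                    confidence=float(rng.uniform(15, 30)), family_id=fam,
                    carrier=family_carriers(pid, {pid: True}),
                ))
            else:  # dominant-inconsistent: father + proband carriers
                g = clean[int(rng.integers(len(clean)))] if clean else autosomal[0]
                calls.append(CnvCall(
                    chrom=g.chrom, start=g.start, end=g.end, cnv_type="duplication",
                    confidence=float(rng.uniform(15, 30)), family_id=fam,
                    carrier=family_carriers(
                        pid, {pid: True, father.individual_id: True}),
                ))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.family_id, c.cnv_type))
    return calls, truth_keys, catalog


# ---------------------------------------------------------------------------
# Bundle output
# ---------------------------------------------------------------------------


def _write_bundle(bundle: CohortBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.ped",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "cnvs": outdir / "cnvs.tsv",
        "common_cnvs": outdir / "common_cnvs.tsv",
        "genes": outdir / "genes.tsv",
        "evidence": outdir / "evidence.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_pedigree(bundle.cohort, paths["pedigree"])
    write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    write_truth(bundle.truth, paths["truth"])
    write_cnv_table(bundle.cnv_calls, paths["cnvs"])
    rows = ["chrom\tstart\tend"]
    rows += [f"{c}\t{s}\t{e}" for c, s, e in bundle.common_catalog]
    paths["common_cnvs"].write_text("\n".join(rows) + "\n")
    rows = ["chrom\tstart\tend\tgene\tbiotype\tcoding_length"]
    rows += [
        f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t{g.biotype}\t{g.coding_length}"
        for g in bundle.gene_model
    ]
    paths["genes"].write_text("\n".join(rows) + "\n")
    write_evidence_table(bundle.evidence.values(), paths["evidence"])
    bundle.config.to_yaml(paths["config"])
    for (ind, caller), cs in sorted(bundle.callsets.items()):
        p = calls_dir / f"{ind}.{caller}.vcf"
        write_callset_vcf(cs, p)
        paths[f"calls/{ind}.{caller}"] = p
    bundle.paths = paths
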