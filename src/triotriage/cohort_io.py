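"""Pedigrees, phenotypes, and per-caller variant call sets.

This module owns the domain types shared by every screen (pedigree members,
variant sites, genotype observations, trio units) and the I/O around them:

* a PED dialect with an optional 7th column ``MZ:<individual_id>`` marking
  monozygotic twin links (standard PED has no twin notation);
* a phenotype TSV of HPO term sets per proband;
* per-individual, per-caller VCFs (FORMAT GT/AD/DP/GQ honored, multiallelic
  records split) read through :mod:`cyvcf2`;
* merging of the per-caller call sets of one individual into a unified call
  set, with majority-vote resolution of genotype discordance;
* left-align-and-trim normalization of variant representations so that
  cross-caller and cross-individual site matching is well defined.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

__all__ = [
    "Sex",
    "Role",
    "Genotype",
    "Consequence",
    "FUNCTIONAL_CONSEQUENCES",
    "CALLER_LABELS",
    "PAR_REGIONS",
    "in_par",
    "PedigreeMember",
    "Cohort",
    "PhenotypeRecord",
    "VariantSite",
    "GenotypeObservation",
    "TrioGenotypes",
    "IndividualCallset",
    "PedigreeError",
    "PhenotypeError",
    "ReferenceContext",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_caller_vcf",
    "write_callset_vcf",
    "write_callset_tsv",
    "merge_caller_calls",
    "normalize_variant",
    "build_trios",
]

HPO_TERM_RE = re.compile(r"^HP:\d{7}$")

#: Caller labels used by the synthetic cohort; real inputs may use any labels.
CALLER_LABELS = ("samtools_like", "gatk_like", "dindel_like")

#: Pseudoautosomal regions on X, 1-based inclusive (GRCh37-like defaults).
#: Male genotypes inside these intervals are diploid-coded.
PAR_REGIONS: dict[str, tuple[tuple[int, int], ...]] = {
    "X": ((60001, 2_699_520), (154_931_044, 155_260_560)),
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree file."""


class PhenotypeError(ValueError):
    """Malformed phenotype table."""


class Sex(str, Enum):
    male = "male"
    female = "female"


class Role(str, Enum):
    proband = "proband"
    mother = "mother"
    father = "father"


class Genotype(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    hemi_ref = "hemi_ref"
    hemi_alt = "hemi_alt"
    missing = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.het, Genotype.hom_alt, Genotype.hemi_alt)

    @property
    def is_reference(self) -> bool:
        return self in (Genotype.hom_ref, Genotype.hemi_ref)


#: Severity used to break two-way ties at merge time (less severe wins).
_GT_SEVERITY = {
    Genotype.missing: 0,
    Genotype.hom_ref: 1,
    Genotype.hemi_ref: 1,
    Genotype.het: 2,
    Genotype.hom_alt: 3,
    Genotype.hemi_alt: 3,
}


class Consequence(str, Enum):
    essential_splice_site = "essential_splice_site"
    stop_gained = "stop_gained"
    frameshift_coding = "frameshift_coding"
    non_synonymous = "non_synonymous"
    stop_lost = "stop_lost"
    synonymous = "synonymous"
    other = "other"


#: The five protein-consequence classes treated as "functional" by the
#: inherited screens.  Synonymous and other never qualify.
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        Consequence.essential_splice_site,
        Consequence.stop_gained,
        Consequence.frameshift_coding,
        Consequence.non_synonymous,
        Consequence.stop_lost,
    }
)

#: Consequence classes considered coding/splicing for the de novo screen
#: (synonymous included: the screen is consequence-agnostic within coding).
CODING_CONSEQUENCES = frozenset(FUNCTIONAL_CONSEQUENCES | {Consequence.synonymous})


def in_par(
    chrom: str,
    pos: int,
    par_regions: Mapping[str, tuple[tuple[int, int], ...]] | None = None,
) -> bool:
    """True if (chrom, pos) lies inside a pseudoautosomal region."""
    regions = PAR_REGIONS if par_regions is None else par_regions
    for start, end in regions.get(chrom.removeprefix("chr"), ()):
        if start <= pos <= end:
            return True
    return False


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    family_id: str
    role: Role
    sex: Sex
    mz_twin_of: str | None = None
    affected: bool = False
    mother_id: str | None = None
    father_id: str | None = None


@dataclass
class Cohort:
    """A set of families with resolvable proband/parent structure."""

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            dup = [i for i, c in Counter(m.individual_id for m in self.members).items() if c > 1]
            raise PedigreeError(f"duplicate individual id(s): {', '.join(sorted(dup))}")
        for p in self.probands:
            for label, pid in (("mother", p.mother_id), ("father", p.father_id)):
                if pid is None or pid not in self._by_id:
                    raise PedigreeError(
                        f"family {p.family_id}: proband {p.individual_id} has "
                        f"unresolvable {label} id {pid!r}"
                    )
        for m in self.members:
            if m.mz_twin_of is not None:
                twin = self._by_id.get(m.mz_twin_of)
                if twin is None or twin.mz_twin_of != m.individual_id:
                    raise PedigreeError(
                        f"MZ twin link {m.individual_id} -> {m.mz_twin_of} is not symmetric"
                    )
                if twin.sex != m.sex:
                    raise PedigreeError(
                        f"MZ twins {m.individual_id}/{twin.individual_id} differ in sex"
                    )

    @property
    def probands(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.role is Role.proband]

    def member(self, individual_id: str) -> PedigreeMember:
        return self._by_id[individual_id]

    def parents_of(self, proband_id: str) -> tuple[PedigreeMember, PedigreeMember]:
        """(mother, father) of a proband."""
        p = self._by_id[proband_id]
        return self._by_id[p.mother_id], self._by_id[p.father_id]

    def mz_partner(self, individual_id: str) -> str | None:
        return self._by_id[individual_id].mz_twin_of


@dataclass
class PhenotypeRecord:
    proband_id: str
    hpo_terms: set[str]
    source: str = "ultrasound"

    def __post_init__(self) -> None:
        bad = sorted(t for t in self.hpo_terms if not HPO_TERM_RE.match(t))
        if bad:
            raise PhenotypeError(f"invalid HPO term id(s): {', '.join(bad)}")


@dataclass(frozen=True, order=True)
class VariantSite:
    """One biallelic variant site (after multiallelic split), left-aligned."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.other
    population_af: float | None = None  # None = absent from reference databases

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_rare(self) -> bool:
        """Missing population frequency is treated as rare (flagged upstream)."""
        return self.population_af is None or self.population_af < 0.01


@dataclass(frozen=True)
class GenotypeObservation:
    individual_id: str
    gt: Genotype
    ad_ref: int | None = None
    ad_alt: int | None = None
    depth: int | None = None
    gq: int | None = None
    callers: frozenset[str] = frozenset()
    discordant: bool = False

    def __post_init__(self) -> None:
        if (
            self.ad_ref is not None
            and self.ad_alt is not None
            and self.depth is not None
            and self.ad_ref + self.ad_alt > self.depth
        ):
            raise ValueError(
                f"{self.individual_id}: ad_ref+ad_alt ({self.ad_ref}+{self.ad_alt}) "
                f"exceeds depth {self.depth}"
            )
        if self.gt is not Genotype.missing and not self.callers:
            raise ValueError(f"{self.individual_id}: non-missing genotype with no caller label")


#: Placeholder observation for a site absent from an individual's call set.
def missing_observation(individual_id: str) -> GenotypeObservation:
    return GenotypeObservation(individual_id=individual_id, gt=Genotype.missing)


@dataclass(frozen=True)
class TrioGenotypes:
    site: VariantSite
    proband: GenotypeObservation
    mother: GenotypeObservation
    father: GenotypeObservation


@dataclass
class IndividualCallset:
    """All calls for one individual from one caller (or merged)."""

    individual_id: str
    caller: str
    calls: dict[tuple[str, int, str, str], tuple[VariantSite, GenotypeObservation]] = field(
        default_factory=dict
    )

    def add(self, site: VariantSite, obs: GenotypeObservation) -> None:
        self.calls[site.key] = (site, obs)

    def __len__(self) -> int:
        return len(self.calls)


# ---------------------------------------------------------------------------
# Pedigree I/O
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": Sex.male, "2": Sex.female}


def read_pedigree(path: str | Path) -> Cohort:
    """Read a 6(+1)-column PED file into a :class:`Cohort`.

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (2=affected), and an optional 7th column ``MZ:<id>`` linking
    monozygotic twins.  Rows whose father and mother are both ``0`` are
    founders; affected non-founders are probands.
    """
    rows: list[tuple[str, ...]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = tuple(line.split("\t"))
        if len(parts) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
        rows.append(parts)

    ids = [r[1] for r in rows]
    dups = sorted(i for i, c in Counter(ids).items() if c > 1)
    if dups:
        raise PedigreeError(f"duplicate individual id(s): {', '.join(dups)}")
    known = set(ids)

    members: list[PedigreeMember] = []
    for parts in rows:
        fam, ind, father, mother, sex_code, pheno = parts[:6]
        mz: str | None = None
        if len(parts) >= 7 and parts[6] not in (".", "", "0"):
            if not parts[6].startswith("MZ:"):
                raise PedigreeError(f"individual {ind}: bad twin column {parts[6]!r}")
            mz = parts[6][3:]
        if sex_code not in _SEX_CODE:
            raise PedigreeError(f"individual {ind}: bad sex code {sex_code!r}")
        is_founder = father == "0" and mother == "0"
        if not is_founder:
            for label, pid in (("father", father), ("mother", mother)):
                if pid not in known:
                    raise PedigreeError(
                        f"family {fam}: {label} {pid!r} of {ind} is not in the pedigree"
                    )
            role = Role.proband
        else:
            role = Role.mother if _SEX_CODE[sex_code] is Sex.female else Role.father
        members.append(
            PedigreeMember(
                individual_id=ind,
                family_id=fam,
                role=role,
                sex=_SEX_CODE[sex_code],
                mz_twin_of=mz,
                affected=pheno == "2",
                mother_id=None if is_founder else mother,
                father_id=None if is_founder else father,
            )
        )
    return Cohort(members)


def write_pedigree(cohort: Cohort, path: str | Path) -> None:
    lines = []
    for m in cohort.members:
        sex = "1" if m.sex is Sex.male else "2"
        pheno = "2" if m.affected else "1"
        twin = f"MZ:{m.mz_twin_of}" if m.mz_twin_of else "."
        lines.append(
            "\t".join(
                [m.family_id, m.individual_id, m.father_id or "0", m.mother_id or "0", sex, pheno, twin]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV (proband_id, ';'-separated HPO terms, source)."""
    records: list[PhenotypeRecord] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("proband_id") or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise PhenotypeError(f"{path}:{lineno}: expected >= 2 columns")
        pid, terms_field = parts[0], parts[1]
        source = parts[2] if len(parts) > 2 else "ultrasound"
        terms = {t for t in terms_field.split(";") if t}
        bad = sorted(t for t in terms if not HPO_TERM_RE.match(t))
        if bad:
            raise PhenotypeError(f"{path}:{lineno}: invalid HPO term id(s): {', '.join(bad)}")
        records.append(PhenotypeRecord(proband_id=pid, hpo_terms=terms, source=source))
    return records


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    lines = ["proband_id\thpo_terms\tsource"]
    for r in records:
        lines.append(f"{r.proband_id}\t{';'.join(sorted(r.hpo_terms))}\t{r.source}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_CONTIG_LINES = "\n".join(
    f"##contig=<ID={c}>" for c in [str(i) for i in range(1, 23)] + ["X", "Y"]
)

VCF_HEADER_TEMPLATE = """##fileformat=VCFv4.2
##source=triotriage
""" + _CONTIG_LINES + """
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted protein consequence">
##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency; absent if not in reference databases">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _decode_genotype(alleles: Sequence[int], alt_index: int) -> Genotype:
    """Map cyvcf2 allele indices (without the phased flag) to a Genotype.

    ``alt_index`` is the 1-based ALT allele being extracted (multiallelic
    split); any other non-ref allele is treated as ref for this record.
    """
    if any(a < 0 for a in alleles):
        return Genotype.missing
    hits = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        return Genotype.hemi_alt if hits else Genotype.hemi_ref
    if hits == 0:
        return Genotype.hom_ref
    if hits == len(alleles):
        return Genotype.hom_alt
    return Genotype.het


def read_caller_vcf(path: str | Path, caller: str) -> IndividualCallset:
    """Read a single-sample VCF from one caller into an IndividualCallset.

    Multiallelic records are split into biallelic records.  Missing AD/GQ are
    tolerated (fields left as None; downstream screens degrade gracefully).
    """
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, got {vcf.samples}")
    individual_id = vcf.samples[0]
    callset = IndividualCallset(individual_id=individual_id, caller=caller)
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        gq = rec.format("GQ")
        alleles = [a for a in rec.genotypes[0][:-1]]
        csq_raw = rec.INFO.get("CSQ")
        popaf = rec.INFO.get("POPAF")
        if popaf is not None:
            # htslib stores floats at single precision; re-quantize to the
            # 6 significant digits the writer emits so round trips are exact
            popaf = float(f"{float(popaf):.6g}")
        gene = rec.INFO.get("GENE") or ""
        for alt_i, alt in enumerate(rec.ALT, start=1):
            try:
                consequence = Consequence(csq_raw) if csq_raw else Consequence.other
            except ValueError:
                consequence = Consequence.other
            site = VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene=gene,
                consequence=consequence,
                population_af=popaf,
            )
            gt = _decode_genotype(alleles, alt_i)
            ad_ref = int(ad[0][0]) if ad is not None and ad[0][0] >= 0 else None
            ad_alt = int(ad[0][alt_i]) if ad is not None and len(ad[0]) > alt_i and ad[0][alt_i] >= 0 else None
            obs = GenotypeObservation(
                individual_id=individual_id,
                gt=gt,
                ad_ref=ad_ref,
                ad_alt=ad_alt,
                depth=int(dp[0][0]) if dp is not None and dp[0][0] >= 0 else None,
                gq=int(gq[0][0]) if gq is not None and gq[0][0] >= 0 else None,
                callers=frozenset() if gt is Genotype.missing else frozenset({caller}),
            )
            callset.add(site, obs)
    vcf.close()
    return callset


_GT_FIELD = {
    Genotype.hom_ref: "0/0",
    Genotype.het: "0/1",
    Genotype.hom_alt: "1/1",
    Genotype.hemi_ref: "0",
    Genotype.hemi_alt: "1",
    Genotype.missing: "./.",
}


def _format_record(site: VariantSite, obs: GenotypeObservation) -> str:
    info = [f"GENE={site.gene}" if site.gene else None, f"CSQ={site.consequence.value}"]
    if site.population_af is not None:
        info.append(f"POPAF={site.population_af:.6g}")
    ad = f"{obs.ad_ref if obs.ad_ref is not None else '.'},{obs.ad_alt if obs.ad_alt is not None else '.'}"
    fields = [
        site.chrom,
        str(site.pos),
        ".",
        site.ref,
        site.alt,
        ".",
        "PASS",
        ";".join(i for i in info if i),
        "GT:AD:DP:GQ",
        ":".join(
            [
                _GT_FIELD[obs.gt],
                ad,
                str(obs.depth) if obs.depth is not None else ".",
                str(obs.gq) if obs.gq is not None else ".",
            ]
        ),
    ]
    return "\t".join(fields)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (100, c)


def write_callset_vcf(callset: IndividualCallset, path: str | Path) -> None:
    """Write an IndividualCallset as an uncompressed single-sample VCF."""
    body = []
    for key in sorted(callset.calls, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
        site, obs = callset.calls[key]
        body.append(_format_record(site, obs))
    Path(path).write_text(
        VCF_HEADER_TEMPLATE.format(sample=callset.individual_id) + "\n".join(body) + ("\n" if body else "")
    )


def write_callset_tsv(callset: IndividualCallset, path: str | Path) -> None:
    header = "chrom\tpos\tref\talt\tgene\tconsequence\tpopulation_af\tgt\tad_ref\tad_alt\tdepth\tgq\tcallers\tdiscordant"
    rows = [header]
    for key in sorted(callset.calls, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
        site, obs = callset.calls[key]
        rows.append(
            "\t".join(
                str(x) if x is not None else "."
                for x in [
                    site.chrom,
                    site.pos,
                    site.ref,
                    site.alt,
                    site.gene,
                    site.consequence.value,
                    site.population_af,
                    obs.gt.value,
                    obs.ad_ref,
                    obs.ad_alt,
                    obs.depth,
                    obs.gq,
                    ",".join(sorted(obs.callers)),
                    int(obs.discordant),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_caller_calls(callsets: Sequence[IndividualCallset]) -> IndividualCallset:
    """Union the per-caller call sets of one individual.

    Identical (chrom, pos, ref, alt) records collapse into one observation
    whose ``callers`` field is the union of contributing caller labels.
    Genotype discordance is resolved by majority vote; two-way ties go to the
    less severe call (het over hom_alt), and a ``discordant`` flag is kept for
    downstream quality filtering.  The result is independent of the order of
    the input call sets.
    """
    if not callsets:
        raise ValueError("no call sets to merge")
    ids = {cs.individual_id for cs in callsets}
    if len(ids) != 1:
        raise ValueError(f"call sets belong to different individuals: {sorted(ids)}")
    individual_id = callsets[0].individual_id

    merged = IndividualCallset(individual_id=individual_id, caller="merged")
    all_keys = sorted(
        {k for cs in callsets for k in cs.calls},
        key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3]),
    )
    for key in all_keys:
        entries = [(cs.caller, *cs.calls[key]) for cs in callsets if key in cs.calls]
        entries.sort(key=lambda e: e[0])  # caller-label order: permutation invariance
        site = entries[0][1]
        votes = Counter(obs.gt for _, _, obs in entries if obs.gt is not Genotype.missing)
        if votes:
            top = max(votes.values())
            # among tied majority genotypes, the least severe wins
            winner = min(
                (gt for gt, n in votes.items() if n == top),
                key=lambda gt: (_GT_SEVERITY[gt], gt.value),
            )
            discordant = len(votes) > 1
        else:
            winner, discordant = Genotype.missing, False
        callers = frozenset().union(*(obs.callers for _, _, obs in entries))
        support = [
            (caller, obs)
            for caller, _, obs in entries
            if obs.gt is winner
        ]
        # representative depths/quality: deepest supporting record (det. tie-break)
        support.sort(key=lambda e: (-(e[1].depth or 0), e[0]))
        rep = support[0][1] if support else entries[0][2]
        merged.add(
            site,
            replace(rep, gt=winner, callers=callers, discordant=discordant),
        )
    return merged


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceContext:
    """A slice of reference sequence anchored at a 1-based start position."""

    chrom: str
    start: int  # 1-based coordinate of seq[0]
    seq: str

    def base_at(self, pos: int) -> str:
        i = pos - self.start
        if i < 0 or i >= len(self.seq):
            raise ValueError(f"position {pos} outside context [{self.start}, {self.start + len(self.seq) - 1}]")
        return self.seq[i]

    def slice(self, pos: int, length: int) -> str:
        return "".join(self.base_at(pos + i) for i in range(length))


def normalize_variant(site: VariantSite, context: ReferenceContext) -> VariantSite:
    """Left-align and trim a variant to its minimal representation.

    Implements the standard left-align-and-parsimony algorithm: shared
    suffixes are trimmed (extending left with reference bases when an allele
    would empty), then shared prefixes are trimmed.  Idempotent; raises if the
    stated ref allele disagrees with the reference context.
    """
    if context.slice(site.pos, len(site.ref)) != site.ref:
        raise ValueError(
            f"ref allele {site.ref!r} at {site.chrom}:{site.pos} does not match reference context"
        )
    pos, ref, alt = site.pos, site.ref, site.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
            # an allele would become empty: extend left
            b = context.base_at(pos - 1)
            pos -= 1
            ref, alt = b + ref, b + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    if (pos, ref, alt) == (site.pos, site.ref, site.alt):
        return site
    return replace(site, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Trio assembly
# ---------------------------------------------------------------------------


def build_trios(
    cohort: Cohort,
    merged_callsets: Mapping[str, IndividualCallset],
) -> dict[str, list[TrioGenotypes]]:
    """Assemble per-proband trio genotype rows over the union of family sites.

    A site absent from an individual's merged call set yields a ``missing``
    observation (the screens skip and log such sites rather than assuming
    hom_ref, since an absent record cannot be distinguished from no coverage).
    """
    out: dict[str, list[TrioGenotypes]] = {}
    for proband in cohort.probands:
        mother, father = cohort.parents_of(proband.individual_id)
        sets = {
            "proband": merged_callsets.get(proband.individual_id),
            "mother": merged_callsets.get(mother.individual_id),
            "father": merged_callsets.get(father.individual_id),
        }
        keys: set[tuple[str, int, str, str]] = set()
        for cs in sets.values():
            if cs is not None:
                keys.update(cs.calls)
        trios: list[TrioGenotypes] = []
        for key in sorted(keys, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
            site = None
            obs = {}
            for role, cs in sets.items():
                if cs is not None and key in cs.calls:
                    s, o = cs.calls[key]
                    site = site or s
                    obs[role] = o
            assert site is not None
            trios.append(
                TrioGenotypes(
                    site=site,
                    proband=obs.get("proband", missing_observation(proband.individual_id)),
                    mother=obs.get("mother", missing_observation(mother.individual_id)),
                    father=obs.get("father", missing_observation(father.individual_id)),
                )
            )
        out[proband.individual_id] = trios
    return out
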