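"""Genome, gene and pedigree domain types, plus codon-aware consequence annotation.

Coordinates are 1-based inclusive throughout (HGVS ``c.`` style); conversion to
0-based half-open happens only at BED boundaries (see :mod:`enuscreen.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "CoordinateError",
    "ReferenceMismatchError",
    "PedigreeError",
    "GeneModel",
    "SequenceStore",
    "GenomeModel",
    "Variant",
    "Individual",
    "Pedigree",
    "ScreenConstants",
    "Consequence",
    "consequence_annotate",
]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# consequence classes, in overlap precedence order (highest first)
CODING_CLASSES = ("nonsense", "missense", "synonymous")
CLASS_PRECEDENCE = (
    "nonsense",
    "missense",
    "synonymous",
    "utr5",
    "utr3",
    "intronic",
    "intergenic",
)


class CoordinateError(ValueError):
    """A position falls outside the declared chromosomes."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the attached genome sequence."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``cds_intervals`` are 1-based inclusive (start, end) pairs sorted by start;
    concatenated in transcription order they begin at reading frame 0.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    utr5_intervals: tuple[tuple[int, int], ...] = ()
    utr3_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        if not ivs:
            raise ValueError(f"gene {self.gene_id} has no CDS intervals")
        for (s, e) in ivs:
            if s > e:
                raise ValueError(f"bad interval ({s}, {e}) in {self.gene_id}")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 <= e0:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        object.__setattr__(self, "cds_intervals", tuple(ivs))

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent of the gene (all CDS + UTR intervals)."""
        ivs = list(self.cds_intervals) + list(self.utr5_intervals) + list(self.utr3_intervals)
        return min(s for s, _ in ivs), max(e for _, e in ivs)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in transcription order."""
        pos = [p for s, e in self.cds_intervals for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def contains(self, position: int) -> bool:
        s, e = self.span
        return s <= position <= e


class SequenceStore:
    """Sparse per-chromosome sequence: explicit segments on a large coordinate axis.

    Desk-scale genomes only need sequence around genes; everything else can stay
    undefined.  A plain string covering the whole chromosome also works.
    """

    def __init__(self, length: int):
        self.length = length
        self._segments: list[tuple[int, str]] = []  # (1-based start, bases)

    @classmethod
    def from_string(cls, seq: str) -> "SequenceStore":
        store = cls(len(seq))
        store.add_segment(1, seq)
        return store

    def add_segment(self, start: int, bases: str) -> None:
        bases = bases.upper()
        if start < 1 or start + len(bases) - 1 > self.length:
            raise CoordinateError("segment outside chromosome")
        self._segments.append((start, bases))
        self._segments.sort()

    def base(self, position: int) -> str | None:
        """Base at 1-based ``position``, or None where sequence is undefined."""
        for start, bases in self._segments:
            if start <= position < start + len(bases):
                return bases[position - start]
        return None


@dataclass(frozen=True)
class Variant:
    """A biallelic single-nucleotide variant."""

    chromosome: str
    position: int
    ref: str
    alt: str
    origin_tag: str = "enu"  # enu | polymorphism | error
    carrier_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"alleles must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        """Matching key for known-polymorphism lookups (ref-agnostic)."""
        return (self.chromosome, self.position, self.alt)


class GenomeModel:
    """Chromosomes, gene models, a uniform recombination map and optional sequence.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    genes
        :class:`GeneModel` list; each must fit inside its chromosome.
    recomb_rate
        Uniform map density in cM/Mb (default 1.0).
    sequence
        Optional mapping ``chromosome -> SequenceStore | str``; required only for
        consequence annotation of coding variants.
    """

    def __init__(
        self,
        chromosomes: list[tuple[str, int]],
        genes: list[GeneModel] | None = None,
        recomb_rate: float = 1.0,
        sequence: dict[str, "SequenceStore | str"] | None = None,
    ):
        if not chromosomes:
            raise ValueError("at least one chromosome required")
        self.chromosomes: list[tuple[str, int]] = []
        for name, length in chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            self.chromosomes.append((str(name), int(length)))
        self.lengths = {n: l for n, l in self.chromosomes}
        self.recomb_rate = float(recomb_rate)
        self.genes: list[GeneModel] = sorted(genes or [], key=lambda g: g.gene_id)
        for g in self.genes:
            if g.chromosome not in self.lengths:
                raise CoordinateError(f"gene {g.gene_id} on unknown chromosome {g.chromosome}")
            s, e = g.span
            if s < 1 or e > self.lengths[g.chromosome]:
                raise CoordinateError(f"gene {g.gene_id} outside chromosome {g.chromosome}")
        self.sequence: dict[str, SequenceStore] = {}
        for chrom, seq in (sequence or {}).items():
            if isinstance(seq, str):
                seq = SequenceStore.from_string(seq)
            self.sequence[chrom] = seq
        self._check_cds_frames()

    def _check_cds_frames(self):
        for g in self.genes:
            if g.chromosome in self.sequence and g.cds_length % 3 != 0:
                raise ValueError(f"CDS length of {g.gene_id} not a multiple of 3")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def base(self, chromosome: str, position: int) -> str | None:
        self._check_coord(chromosome, position)
        store = self.sequence.get(chromosome)
        return store.base(position) if store is not None else None

    def _check_coord(self, chromosome: str, position: int) -> None:
        if chromosome not in self.lengths:
            raise CoordinateError(f"unknown chromosome {chromosome}")
        if not 1 <= position <= self.lengths[chromosome]:
            raise CoordinateError(f"{chromosome}:{position} outside chromosome")

    def genes_at(self, chromosome: str, position: int) -> list[GeneModel]:
        return [g for g in self.genes if g.chromosome == chromosome and g.contains(position)]


# ---------------------------------------------------------------------------
# pedigrees


@dataclass
class Individual:
    id: str
    sex: str  # "M" | "F"
    sire_id: str | None = None
    dam_id: str | None = None
    generation: str = "founder"  # G0 | G1 | G2 | G3 | founder
    affected: bool | None = None  # None = unknown

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """Three-generation screen pedigree.

    The only permitted loop is the sire-daughter backcross: a male who sires a
    female and also sires that female's offspring.
    """

    def __init__(self, individuals: list[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate id {ind.id}")
            self.individuals[ind.id] = ind
        self._validate()

    def _validate(self):
        order = {gen: i for i, gen in enumerate(["founder", "G0", "G1", "G2", "G3"])}
        for ind in self.individuals.values():
            for pid, expected_sex in ((ind.sire_id, "M"), (ind.dam_id, "F")):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise PedigreeError(f"{ind.id}: unknown parent {pid}")
                parent = self.individuals[pid]
                if parent.sex != expected_sex:
                    raise PedigreeError(f"{ind.id}: parent {pid} has wrong sex")
                if order[parent.generation] >= order[ind.generation] and not (
                    parent.generation == "founder"
                ):
                    # backcross G3 child of a G1 sire is fine; otherwise parents
                    # must precede children generationally
                    if not (parent.generation == "G1" and ind.generation == "G3"):
                        if order[parent.generation] >= order[ind.generation]:
                            raise PedigreeError(
                                f"{ind.id} ({ind.generation}) has parent {pid} "
                                f"({parent.generation}) not preceding it"
                            )

    def __iter__(self):
        return iter(self.individuals.values())

    def __len__(self):
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    @property
    def ids(self) -> list[str]:
        return list(self.individuals)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def children_of(self, sire_id: str, dam_id: str) -> list[Individual]:
        return [i for i in self if i.sire_id == sire_id and i.dam_id == dam_id]

    def families(self) -> list[tuple[str, str, list[str]]]:
        """Nuclear families as (sire, dam, children) triples."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self:
            if ind.sire_id is not None and ind.dam_id is not None:
                fams.setdefault((ind.sire_id, ind.dam_id), []).append(ind.id)
        return [(s, d, kids) for (s, d), kids in fams.items()]

    def by_generation(self, generation: str) -> list[Individual]:
        return [i for i in self if i.generation == generation]

    def subset(self, ids: list[str]) -> "Pedigree":
        """Restrict to ``ids``; individuals whose parents fall outside the
        subset are re-rooted as founders (e.g. dropping the G0 generation for
        a G1-anchored linkage analysis)."""
        keep = set(ids)
        out = []
        for ind in self:
            if ind.id not in keep:
                continue
            both = ind.sire_id in keep and ind.dam_id in keep
            sire = ind.sire_id if both else None
            dam = ind.dam_id if both else None
            gen = ind.generation if both else "founder"
            out.append(replace(ind, sire_id=sire, dam_id=dam, generation=gen))
        return Pedigree(out)

    def with_affection(self, affection: dict[str, bool | None]) -> "Pedigree":
        return Pedigree(
            [replace(ind, affected=affection.get(ind.id, ind.affected)) for ind in self]
        )


# ---------------------------------------------------------------------------
# fixed constants of the burden-extrapolation arithmetic


@dataclass(frozen=True)
class ScreenConstants:
    """Biological constants of the pig screen's extrapolation model."""

    genome_size: float = 2.81e9  # bp
    n_genes: float = 2.2e4
    mean_cds: float = 1.6e3  # bp per gene
    aa_change_fraction: float = 0.55  # coding mutations that change an amino acid
    spontaneous_rate: float = 1.2e-8  # per site per generation
    dose_rates: tuple[tuple[int, float], ...] = ((65, 1.63e-6), (85, 5.86e-6))

    def __post_init__(self):
        for name in ("genome_size", "n_genes", "mean_cds", "aa_change_fraction", "spontaneous_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.aa_change_fraction <= 1:
            raise ValueError("aa_change_fraction must be in (0, 1]")

    def rate_for_dose(self, dose_mg_per_kg: int) -> float:
        for dose, rate in self.dose_rates:
            if dose == dose_mg_per_kg:
                return rate
        raise KeyError(f"no calibrated rate for dose {dose_mg_per_kg} mg/kg")


# ---------------------------------------------------------------------------
# consequence annotation


@dataclass(frozen=True)
class Consequence:
    """Predicted effect of an SNV on the (alphabetically first) overlapping gene."""

    klass: str
    gene_id: str | None = None
    cds_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    protein_position: int | None = None
    near_splice: bool = False  # intronic within 2 bp of a CDS edge
    other_gene_ids: tuple[str, ...] = ()


def _classify_in_gene(variant: Variant, gene: GeneModel, genome: GenomeModel) -> Consequence:
    pos = variant.position
    for s, e in gene.utr5_intervals:
        if s <= pos <= e:
            return Consequence("utr5", gene.gene_id)
    for s, e in gene.utr3_intervals:
        if s <= pos <= e:
            return Consequence("utr3", gene.gene_id)
    in_cds = any(s <= pos <= e for s, e in gene.cds_intervals)
    if not in_cds:
        near = any(
            abs(pos - edge) <= 2 for s, e in gene.cds_intervals for edge in (s - 1, e + 1)
            if (pos < s or pos > e)
        )
        return Consequence("intronic", gene.gene_id, near_splice=near)

    cds_pos_list = gene.cds_positions()  # transcription order
    cds_index = cds_pos_list.index(pos)  # 0-based offset in spliced CDS
    cds_position = cds_index + 1
    protein_position = math.ceil(cds_position / 3)
    codon_index = (cds_position - 1) // 3
    codon_genomic = cds_pos_list[codon_index * 3 : codon_index * 3 + 3]

    bases = []
    for gpos in codon_genomic:
        b = genome.base(gene.chromosome, gpos)
        if b is None:
            raise ReferenceMismatchError(
                f"no sequence for {gene.chromosome}:{gpos} (needed for codon of {gene.gene_id})"
            )
        bases.append(b if gene.strand == "+" else COMPLEMENT[b])
    ref_codon = "".join(bases)

    ref_base_tx = variant.ref if gene.strand == "+" else COMPLEMENT[variant.ref]
    alt_base_tx = variant.alt if gene.strand == "+" else COMPLEMENT[variant.alt]
    offset_in_codon = (cds_position - 1) % 3
    if ref_codon[offset_in_codon] != ref_base_tx:
        raise ReferenceMismatchError(
            f"variant ref {variant.ref} does not match genome at "
            f"{variant.chromosome}:{variant.position}"
        )
    alt_codon = ref_codon[:offset_in_codon] + alt_base_tx + ref_codon[offset_in_codon + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        klass = "nonsense"
    elif ref_aa == alt_aa:
        klass = "synonymous"
    else:
        # stop-loss folds into missense by design: minimal class set
        klass = "missense"
    return Consequence(
        klass,
        gene.gene_id,
        cds_position=cds_position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        protein_position=protein_position,
    )


def consequence_annotate(variant: Variant, genome: GenomeModel) -> Consequence:
    """Annotate an SNV against the gene models of ``genome``.

    Overlap precedence is CDS > UTR > intron > intergenic; among equally ranked
    overlapping genes the alphabetically first gene is reported and the rest are
    retained in ``other_gene_ids``.
    """
    genome._check_coord(variant.chromosome, variant.position)
    known = genome.base(variant.chromosome, variant.position)
    if known is not None and known != variant.ref:
        raise ReferenceMismatchError(
            f"variant ref {variant.ref} != genome base {known} at "
            f"{variant.chromosome}:{variant.position}"
        )
    hits = genome.genes_at(variant.chromosome, variant.position)
    if not hits:
        return Consequence("intergenic")
    records = [_classify_in_gene(variant, g, genome) for g in hits]
    rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    records.sort(key=lambda r: (rank[r.klass], r.gene_id))
    best = records[0]
    others = tuple(r.gene_id for r in records[1:] if r.gene_id is not None)
    if others:
        best = replace(best, other_gene_ids=others)
    return best
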