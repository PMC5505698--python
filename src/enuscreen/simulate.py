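"""Synthetic-data generator for a three-generation ENU mutagenesis screen.

Simulates ENU point mutagenesis of founder sperm, meiosis with recombination
(Haldane map function, uniform cM/Mb), the G0 -> G1 -> G2 -> backcross-G3
breeding scheme, single-locus phenotypes, and three sequencing read-outs:
reduced-representation (2b-RAD-like) read counts, SNP-array genotypes with
missingness, and WGS-style variant call sets.

All randomness flows from explicit seeds; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import as_rng, stage_rng
from .genome import (
    BASES,
    CoordinateError,
    GeneModel,
    GenomeModel,
    Individual,
    Pedigree,
    SequenceStore,
    Variant,
)
from .spectrum import CLASS_STRANDS, SUBSTITUTION_CLASSES, MutationSpectrum

__all__ = [
    "BreedingStructureError",
    "PhenotypeModel",
    "SimConfig",
    "LociIndex",
    "ScreenResult",
    "ReadCountSet",
    "mutate_gamete",
    "simulate_meiosis",
    "breed_screen",
    "assign_phenotypes",
    "emulate_rad",
    "emulate_snp_array",
    "emulate_wgs_calls",
    "genotypes_at",
    "toy_genome",
    "make_test_gene",
]


class BreedingStructureError(RuntimeError):
    """The configured breeding scheme cannot be realized (e.g. too few G2 sows)."""


@dataclass(frozen=True)
class PhenotypeModel:
    """Single-locus phenotype: carriers (dominant) or alt-homozygotes (recessive)
    are affected with probability ``penetrance``."""

    locus: Variant
    mode: str  # dominant | recessive
    penetrance: float = 1.0

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"mode must be dominant or recessive, got {self.mode!r}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")


@dataclass
class SimConfig:
    """Screen-simulation parameters.

    ``dose`` is a calibrated dose label (65 or 85 mg/kg) or an explicit per-site
    mutation rate.  Counts follow the screen design: one tracked G1 boar is mated
    to ``dams_per_g1`` wild-type sows and ``g2_dams_backcrossed`` of his daughters
    are mated back to him.
    """

    genome: GenomeModel
    dose: float | int = 85
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum)
    n_g1: int = 1
    dams_per_g1: int = 4
    g2_dams_backcrossed: int = 4
    litter_size: int = 8
    phenotype_model: PhenotypeModel | None = None
    rad_fraction: float = 0.02
    mean_depth: float = 20.0
    seq_error: float = 0.01
    array_marker_count: int = 500
    array_missing_rate: float = 0.02
    background_poly_rate: float = 1e-3
    max_extra_litters: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("rad_fraction", "seq_error", "array_missing_rate", "background_poly_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_g1", "dams_per_g1", "g2_dams_backcrossed", "litter_size",
                     "array_marker_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rate(self) -> float:
        if isinstance(self.dose, int) and self.dose in (65, 85):
            return {65: 1.63e-6, 85: 5.86e-6}[self.dose]
        return float(self.dose)


# ---------------------------------------------------------------------------
# tracked loci


class LociIndex:
    """Registry of the genome positions tracked through meiosis.

    Loci are sorted by (chromosome order, position) and deduplicated on
    position.  ``kind`` distinguishes planted ENU mutations, background
    polymorphisms, array markers and the phenotype locus.
    """

    def __init__(self, genome: GenomeModel):
        self.genome = genome
        self.chrom_names = [n for n, _ in genome.chromosomes]
        self._chrom_code = {n: i for i, n in enumerate(self.chrom_names)}
        self.chrom = np.empty(0, dtype=np.int32)
        self.pos = np.empty(0, dtype=np.int64)
        self.ref = np.empty(0, dtype="U1")
        self.alt = np.empty(0, dtype="U1")
        self.kind = np.empty(0, dtype="U10")
        self.freq = np.empty(0, dtype=float)  # founder alt-allele frequency

    def __len__(self) -> int:
        return len(self.pos)

    def add(self, chrom, pos, ref, alt, kind, freq) -> None:
        self.chrom = np.concatenate([self.chrom, np.asarray(chrom, dtype=np.int32)])
        self.pos = np.concatenate([self.pos, np.asarray(pos, dtype=np.int64)])
        self.ref = np.concatenate([self.ref, np.asarray(ref, dtype="U1")])
        self.alt = np.concatenate([self.alt, np.asarray(alt, dtype="U1")])
        self.kind = np.concatenate([self.kind, np.asarray(kind, dtype="U10")])
        self.freq = np.concatenate([self.freq, np.asarray(freq, dtype=float)])

    def finalize(self) -> None:
        """Sort by genome order and drop duplicate positions; planted kinds take
        precedence over markers and background polymorphisms."""
        prio_map = {"phenotype": 0, "enu": 1, "marker": 2, "poly": 3}
        prio = np.array([prio_map.get(str(k), 4) for k in self.kind], dtype=np.int8)
        order = np.lexsort((prio, self.pos, self.chrom))
        for name in ("chrom", "pos", "ref", "alt", "kind", "freq"):
            setattr(self, name, getattr(self, name)[order])
        key = self.chrom.astype(np.int64) * (2**40) + self.pos
        keep = np.concatenate([[True], key[1:] != key[:-1]])
        for name in ("chrom", "pos", "ref", "alt", "kind", "freq"):
            setattr(self, name, getattr(self, name)[keep])

    def code(self, chrom_name: str) -> int:
        return self._chrom_code[chrom_name]

    def locate(self, chrom_name: str, position: int) -> int:
        mask = (self.chrom == self.code(chrom_name)) & (self.pos == position)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise CoordinateError(f"locus {chrom_name}:{position} not tracked")
        return int(idx[0])

    def variant(self, i: int) -> Variant:
        tag = {"enu": "enu", "phenotype": "enu"}.get(str(self.kind[i]), "polymorphism")
        return Variant(
            self.chrom_names[self.chrom[i]], int(self.pos[i]),
            str(self.ref[i]), str(self.alt[i]), origin_tag=tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.chrom],
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "kind": self.kind,
                "founder_freq": self.freq,
            }
        )


# ---------------------------------------------------------------------------
# mutagenesis


def _draw_unique_offsets(total: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct uniform offsets in [0, total)].

    Sparse draws (the usual case: mutation rates <= 1e-3) use rejection on
    duplicates; dense draws fall back to a full permutation.
    """
    if n * 3 >= total:
        return rng.permutation(total)[:n]
    offsets = np.unique(rng.integers(0, total, size=n))
    while len(offsets) < n:
        extra = rng.integers(0, total, size=n - len(offsets))
        offsets = np.unique(np.concatenate([offsets, extra]))
    return rng.permutation(offsets)[:n]


def mutate_gamete(
    genome: GenomeModel,
    rate: float,
    spectrum: MutationSpectrum | None = None,
    seed: int | np.random.Generator = 0,
) -> list[Variant]:
    """Draw the ENU-induced point mutations carried by one gamete.

    The number of mutations is Binomial(genome bases, rate) with positions
    uniform without replacement.  Where the genome carries sequence, the
    substitution class is drawn from the spectrum conditioned on the reference
    base; elsewhere the class is drawn from the marginal spectrum and the
    reference base uniformly between the class's two strand representations, so
    the configured aggregate spectrum is reproduced exactly.
    """
    if not 0 <= rate <= 1e-3:
        raise ValueError(f"per-site rate {rate} outside [0, 1e-3]")
    spectrum = spectrum or MutationSpectrum()
    rng = as_rng(seed)
    total = genome.total_length
    n = rng.binomial(total, rate)
    if n == 0:
        return []
    offsets = np.sort(_draw_unique_offsets(total, n, rng))
    bounds = np.cumsum([l for _, l in genome.chromosomes])
    chrom_idx = np.searchsorted(bounds, offsets, side="right")
    starts = np.concatenate([[0], bounds[:-1]])
    positions = offsets - starts[chrom_idx] + 1

    chrom_names = [c for c, _ in genome.chromosomes]
    refs = [
        genome.base(chrom_names[ci], int(pos)) if chrom_names[ci] in genome.sequence
        else None
        for ci, pos in zip(chrom_idx, positions)
    ]
    ref_arr = np.array(["N" if r is None else r for r in refs], dtype="U1")
    alt_arr = np.empty(n, dtype="U1")

    # unknown reference: class from the marginal spectrum, ref base uniform
    # between the class's two strand representations (preserves the aggregate)
    unknown = np.flatnonzero(ref_arr == "N")
    if len(unknown):
        probs = np.array(spectrum.probs_vector())
        cls_idx = rng.choice(len(SUBSTITUTION_CLASSES), size=len(unknown), p=probs)
        strand = rng.integers(2, size=len(unknown))
        for j, (k, s) in zip(unknown, zip(cls_idx, strand)):
            r, a = CLASS_STRANDS[SUBSTITUTION_CLASSES[k]][s]
            ref_arr[j], alt_arr[j] = r, a
    # known reference: class conditioned on the base
    for j in np.flatnonzero(ref_arr != "N"):
        if refs[j] is None:
            continue
        cond = spectrum.conditional_probs(str(ref_arr[j]))
        names = list(cond)
        cls = names[rng.choice(len(names), p=np.array(list(cond.values())))]
        alt_arr[j] = spectrum.alt_for(cls, str(ref_arr[j]))

    return [
        Variant(chrom_names[ci], int(pos), str(r), str(a), origin_tag="enu")
        for ci, pos, r, a in zip(chrom_idx, positions, ref_arr, alt_arr)
    ]


# ---------------------------------------------------------------------------
# meiosis


def recombination_fraction(distance_bp: np.ndarray, recomb_rate: float) -> np.ndarray:
    """Haldane map function: theta = (1 - exp(-2 d)) / 2 with d in Morgans."""
    d_morgans = np.asarray(distance_bp, dtype=float) / 1e6 * recomb_rate / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def simulate_meiosis(
    diplotype: np.ndarray,
    loci: LociIndex,
    genome: GenomeModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One gamete from a (2, n_loci) parental diplotype.

    Crossovers follow Haldane's no-interference model at the genome's uniform
    cM/Mb rate; chromosomes assort independently.
    """
    rng = as_rng(seed)
    genome = genome or loci.genome
    n = len(loci)
    if diplotype.shape != (2, n):
        raise CoordinateError("diplotype does not cover the tracked loci")
    if n == 0:
        return np.empty(0, dtype=diplotype.dtype)
    theta = recombination_fraction(np.diff(loci.pos), genome.recomb_rate)
    theta[np.diff(loci.chrom) != 0] = 0.5  # independent chromosomes
    start = rng.integers(2)
    switches = rng.random(n - 1) < theta
    hap_choice = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
    return diplotype[hap_choice, np.arange(n)]


# ---------------------------------------------------------------------------
# the breeding scheme


@dataclass
class ScreenResult:
    """Everything the simulator knows: pedigree, tracked loci, per-individual
    diplotypes (2, n_loci) with 0=ref/1=alt, and the truth record of planted
    ENU mutations."""

    pedigree: Pedigree
    loci: LociIndex
    diplotypes: dict[str, np.ndarray]
    truth: pd.DataFrame  # chrom, pos, ref, alt, g1_id, is_phenotype_locus
    config: SimConfig

    def genotype(self, ind_id: str, locus_index: int) -> int:
        return int(self.diplotypes[ind_id][:, locus_index].sum())

    @property
    def phenotype_locus_index(self) -> int | None:
        idx = np.flatnonzero(self.loci.kind == "phenotype")
        return int(idx[0]) if len(idx) else None


def _hwe_diplotype(freq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((2, len(freq))) < freq).astype(np.uint8)


def breed_screen(config: SimConfig) -> ScreenResult:
    """Run the three-generation breeding scheme and return the full truth record.

    Each tracked G1 offspring receives an independent, freshly drawn ENU mutation
    set (mutations in distinct sperm are disjoint by construction).  G1 boars are
    mated to unrelated wild-type sows; the configured number of G2 daughters is
    backcrossed to the G1 sire.  If a phenotype model is configured, its locus is
    planted in the first G1 boar's mutation set.
    """
    genome = config.genome
    rng_poly = stage_rng(config.seed, "founder-poly")
    rng_enu = stage_rng(config.seed, "enu")
    rng_meiosis = stage_rng(config.seed, "meiosis")
    rng_sex = stage_rng(config.seed, "sex")

    loci = LociIndex(genome)

    # background polymorphisms segregating in the founder population
    n_poly = rng_poly.binomial(genome.total_length, config.background_poly_rate)
    if n_poly:
        offsets = np.sort(_draw_unique_offsets(genome.total_length, n_poly, rng_poly))
        bounds = np.cumsum([l for _, l in genome.chromosomes])
        starts = np.concatenate([[0], bounds[:-1]])
        ci = np.searchsorted(bounds, offsets, side="right")
        pos = offsets - starts[ci] + 1
        refs, alts = [], []
        for c, p in zip(ci, pos):
            b = genome.base(genome.chromosomes[c][0], int(p))
            r = b if b is not None else BASES[rng_poly.integers(4)]
            a = BASES[rng_poly.integers(4)]
            while a == r:
                a = BASES[rng_poly.integers(4)]
            refs.append(r)
            alts.append(a)
        # common-SNP allele-frequency band
        freqs = rng_poly.uniform(0.05, 0.5, size=n_poly)
        loci.add(ci, pos, refs, alts, ["poly"] * n_poly, freqs)

    # evenly spaced array markers per chromosome, proportional to length
    if config.array_marker_count:
        weights = np.array([l for _, l in genome.chromosomes], dtype=float)
        per_chrom = np.maximum(
            1, np.round(weights / weights.sum() * config.array_marker_count).astype(int)
        )
        for (name, length), k in zip(genome.chromosomes, per_chrom):
            spacing = length / (k + 1)
            mpos = (spacing * np.arange(1, k + 1)).astype(np.int64)
            mpos = np.clip(mpos, 1, length)
            refs, alts = [], []
            for p in mpos:
                b = genome.base(name, int(p))
                r = b if b is not None else BASES[rng_poly.integers(4)]
                a = BASES[rng_poly.integers(4)]
                while a == r:
                    a = BASES[rng_poly.integers(4)]
                refs.append(r)
                alts.append(a)
            mfreq = rng_poly.uniform(0.05, 0.5, size=k)
            loci.add([loci.code(name)] * k, mpos, refs, alts, ["marker"] * k, mfreq)

    # fresh ENU mutation set per G1 gamete; uniqueness across siblings holds by
    # construction (duplicate positions are dropped at finalize)
    g1_ids = [f"G1-{i + 1}" for i in range(config.n_g1)]
    enu_sets: dict[str, list[Variant]] = {}
    seen: set[tuple[int, int]] = set()
    for gid in g1_ids:
        muts = mutate_gamete(genome, config.rate, config.spectrum, rng_enu)
        muts = [m for m in muts if (loci.code(m.chromosome), m.position) not in seen]
        for m in muts:
            seen.add((loci.code(m.chromosome), m.position))
        enu_sets[gid] = muts

    if config.phenotype_model is not None and g1_ids:
        pl = config.phenotype_model.locus
        genome._check_coord(pl.chromosome, pl.position)
        enu_sets[g1_ids[0]] = [
            m for m in enu_sets[g1_ids[0]]
            if (m.chromosome, m.position) != (pl.chromosome, pl.position)
        ]
        loci.add(
            [loci.code(pl.chromosome)], [pl.position], [pl.ref], [pl.alt],
            ["phenotype"], [0.0],
        )
    for gid, muts in enu_sets.items():
        if muts:
            loci.add(
                [loci.code(m.chromosome) for m in muts],
                [m.position for m in muts],
                [m.ref for m in muts],
                [m.alt for m in muts],
                ["enu"] * len(muts),
                [0.0] * len(muts),
            )
    loci.finalize()

    enu_carrier = {}  # locus index -> g1 id
    for gid, muts in enu_sets.items():
        for m in muts:
            enu_carrier[loci.locate(m.chromosome, m.position)] = gid
    if config.phenotype_model is not None and g1_ids:
        pl = config.phenotype_model.locus
        enu_carrier[loci.locate(pl.chromosome, pl.position)] = g1_ids[0]

    founder_mask = np.isin(loci.kind, ["poly", "marker"])
    founder_freq = np.where(founder_mask, loci.freq, 0.0)

    individuals: list[Individual] = []
    diplotypes: dict[str, np.ndarray] = {}

    def new_founder(ind_id: str, sex: str, generation: str = "G0") -> None:
        individuals.append(Individual(ind_id, sex, generation=generation))
        diplotypes[ind_id] = _hwe_diplotype(founder_freq, rng_poly)

    def offspring(ind_id, sire, dam, sex, generation) -> None:
        pat = simulate_meiosis(diplotypes[sire], loci, genome, rng_meiosis)
        mat = simulate_meiosis(diplotypes[dam], loci, genome, rng_meiosis)
        individuals.append(Individual(ind_id, sex, sire, dam, generation))
        diplotypes[ind_id] = np.stack([pat, mat])

    new_founder("G0-BOAR", "M")
    new_founder("G0-SOW", "F")
    for gid in g1_ids:
        offspring(gid, "G0-BOAR", "G0-SOW", "M", "G1")
        for idx, carrier in enu_carrier.items():
            if carrier == gid:
                diplotypes[gid][0, idx] = 1  # mutation rode in on the paternal gamete

    for gid in g1_ids:
        g2_females: list[str] = []
        litter_no = 0
        sow_no = 0
        while True:
            need_more = len(g2_females) < config.g2_dams_backcrossed
            if litter_no >= config.dams_per_g1:
                if not need_more:
                    break
                if litter_no >= config.dams_per_g1 + config.max_extra_litters:
                    raise BreedingStructureError(
                        f"{gid}: only {len(g2_females)} G2 females after "
                        f"{litter_no} litters; need {config.g2_dams_backcrossed}"
                    )
            sow_no += 1
            sow_id = f"SOW-{gid}-{sow_no}"
            new_founder(sow_id, "F", generation="founder")
            litter_no += 1
            for j in range(config.litter_size):
                sex = "F" if rng_sex.random() < 0.5 else "M"
                cid = f"G2-{gid}-{litter_no}-{j + 1}"
                offspring(cid, gid, sow_id, sex, "G2")
                if sex == "F":
                    g2_females.append(cid)
            if litter_no >= config.dams_per_g1 and len(g2_females) >= config.g2_dams_backcrossed:
                break
        for dam_id in g2_females[: config.g2_dams_backcrossed]:
            for j in range(config.litter_size):
                sex = "F" if rng_sex.random() < 0.5 else "M"
                offspring(f"G3-{dam_id[3:]}-{j + 1}", gid, dam_id, sex, "G3")

    pedigree = Pedigree(individuals)

    rows = []
    for idx, gid in sorted(enu_carrier.items()):
        rows.append(
            {
                "chrom": loci.chrom_names[loci.chrom[idx]],
                "pos": int(loci.pos[idx]),
                "ref": str(loci.ref[idx]),
                "alt": str(loci.alt[idx]),
                "g1_id": gid,
                "is_phenotype_locus": str(loci.kind[idx]) == "phenotype",
            }
        )
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "g1_id", "is_phenotype_locus"]
    )

    result = ScreenResult(pedigree, loci, diplotypes, truth, config)
    if config.phenotype_model is not None:
        result = assign_phenotypes(
            result, config.phenotype_model, stage_rng(config.seed, "phenotype")
        )
    return result


def assign_phenotypes(
    screen: ScreenResult,
    model: PhenotypeModel,
    seed: int | np.random.Generator = 0,
) -> ScreenResult:
    """Set affection flags from the phenotype locus genotypes and penetrance."""
    rng = as_rng(seed)
    idx = screen.loci.locate(model.locus.chromosome, model.locus.position)
    affection: dict[str, bool | None] = {}
    for ind in screen.pedigree:
        g = screen.genotype(ind.id, idx)
        at_risk = g >= 1 if model.mode == "dominant" else g == 2
        affection[ind.id] = bool(at_risk and rng.random() < model.penetrance)
    return ScreenResult(
        screen.pedigree.with_affection(affection),
        screen.loci,
        screen.diplotypes,
        screen.truth,
        screen.config,
    )


# ---------------------------------------------------------------------------
# sequencing read-outs


class ReadCountSet:
    """Per-individual (ref, alt) read counts at a shared site set."""

    def __init__(self, chrom_names, chrom, pos, ref, alt):
        self.chrom_names = list(chrom_names)
        self.chrom = np.asarray(chrom, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="U1")
        self.alt = np.asarray(alt, dtype="U1")
        self.counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def individuals(self) -> list[str]:
        return list(self.counts)

    def add_individual(self, ind_id: str, ref_counts, alt_counts) -> None:
        self.counts[ind_id] = (
            np.asarray(ref_counts, dtype=np.int16),
            np.asarray(alt_counts, dtype=np.int16),
        )

    def depth(self, ind_id: str) -> np.ndarray:
        r, a = self.counts[ind_id]
        return (r.astype(np.int32) + a).astype(np.int32)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for ind, (r, a) in self.counts.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": [self.chrom_names[c] for c in self.chrom],
                        "pos": self.pos,
                        "individual": ind,
                        "ref_count": r,
                        "alt_count": a,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _site_genotypes(
    screen: ScreenResult, ind_id: str, site_chrom: np.ndarray, site_pos: np.ndarray
) -> np.ndarray:
    """Genotype (0/1/2) of an individual at arbitrary sites: tracked loci carry
    their simulated genotype, all other sites are homozygous reference."""
    loci = screen.loci
    g = np.zeros(len(site_pos), dtype=np.int8)
    key_sites = site_chrom.astype(np.int64) * (2**40) + site_pos
    key_loci = loci.chrom.astype(np.int64) * (2**40) + loci.pos
    idx = np.searchsorted(key_loci, key_sites)
    idx_c = np.clip(idx, 0, len(key_loci) - 1)
    hit = (len(key_loci) > 0) & (key_loci[idx_c] == key_sites)
    dip = screen.diplotypes[ind_id]
    g[hit] = dip[:, idx_c[hit]].sum(axis=0)
    return g


def emulate_rad(
    screen: ScreenResult,
    individuals: list[str] | None = None,
    rad_fraction: float | None = None,
    mean_depth: float | None = None,
    seq_error: float | None = None,
    seed: int | np.random.Generator = 0,
) -> ReadCountSet:
    """Reduced-representation read counts at a seeded Bernoulli sample of genome
    positions, identical across individuals (tag-locus behaviour).

    Per-site depth is Poisson(mean_depth); alt reads are Binomial(depth, p) with
    p = epsilon, 1/2, 1-epsilon for genotypes 0, 1, 2.
    """
    cfg = screen.config
    rad_fraction = cfg.rad_fraction if rad_fraction is None else rad_fraction
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    seq_error = cfg.seq_error if seq_error is None else seq_error
    if not 0 <= rad_fraction <= 1:
        raise ValueError("rad_fraction outside [0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = as_rng(seed)
    genome = screen.config.genome
    individuals = individuals or screen.pedigree.ids

    total = genome.total_length
    n_sites = rng.binomial(total, rad_fraction)
    if n_sites == 0:
        rcs = ReadCountSet(screen.loci.chrom_names, [], [], [], [])
        for ind in individuals:
            rcs.add_individual(ind, [], [])
        return rcs
    offsets = np.sort(_draw_unique_offsets(total, n_sites, rng))
    bounds = np.cumsum([l for _, l in genome.chromosomes])
    starts = np.concatenate([[0], bounds[:-1]])
    ci = np.searchsorted(bounds, offsets, side="right").astype(np.int32)
    pos = offsets - starts[ci] + 1

    # site ref/alt: tracked loci keep their alleles, untracked sites get a
    # nominal A>G pair (allele identity is irrelevant off-locus)
    ref = np.full(n_sites, "A", dtype="U1")
    alt = np.full(n_sites, "G", dtype="U1")
    loci = screen.loci
    key_sites = ci.astype(np.int64) * (2**40) + pos
    key_loci = loci.chrom.astype(np.int64) * (2**40) + loci.pos
    idx = np.searchsorted(key_loci, key_sites)
    idx_c = np.clip(idx, 0, max(len(key_loci) - 1, 0))
    if len(key_loci):
        hit = key_loci[idx_c] == key_sites
        ref[hit] = loci.ref[idx_c[hit]]
        alt[hit] = loci.alt[idx_c[hit]]

    rcs = ReadCountSet(loci.chrom_names, ci, pos, ref, alt)
    p_alt = np.array([seq_error, 0.5, 1.0 - seq_error])
    for ind in individuals:
        g = _site_genotypes(screen, ind, ci, pos)
        depth = rng.poisson(mean_depth, size=n_sites)
        alt_reads = rng.binomial(depth, p_alt[g])
        rcs.add_individual(ind, depth - alt_reads, alt_reads)
    return rcs


def emulate_snp_array(
    screen: ScreenResult,
    individuals: list[str] | None = None,
    missing_rate: float | None = None,
    seed: int | np.random.Generator = 0,
):
    """SNP-array genotypes at the simulated marker loci, with independent
    missingness.  Returns a :class:`enuscreen.linkage.GenotypeMatrix`."""
    from .linkage import GenotypeMatrix

    cfg = screen.config
    missing_rate = cfg.array_missing_rate if missing_rate is None else missing_rate
    rng = as_rng(seed)
    individuals = individuals or screen.pedigree.ids
    loci = screen.loci
    midx = np.flatnonzero(loci.kind == "marker")
    markers = pd.DataFrame(
        {
            "chrom": [loci.chrom_names[c] for c in loci.chrom[midx]],
            "pos": loci.pos[midx],
            "ref": loci.ref[midx],
            "alt": loci.alt[midx],
            "founder_freq": loci.freq[midx],
        }
    )
    geno = np.zeros((len(midx), len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        geno[:, j] = screen.diplotypes[ind][:, midx].sum(axis=0)
    miss = rng.random(geno.shape) < missing_rate
    geno[miss] = -1
    return GenotypeMatrix(markers, geno, individuals)


def emulate_wgs_calls(
    screen: ScreenResult,
    individuals: list[str],
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, pd.DataFrame], list[Variant]]:
    """WGS-style variant call sets (all non-reference tracked loci per
    individual) plus the known-polymorphism list (background polymorphisms and
    array markers — never planted ENU variants)."""
    loci = screen.loci
    calls: dict[str, pd.DataFrame] = {}
    for ind in individuals:
        if ind not in screen.pedigree:
            raise KeyError(f"unknown individual {ind}")
        g = screen.diplotypes[ind].sum(axis=0)
        nz = np.flatnonzero(g > 0)
        calls[ind] = pd.DataFrame(
            {
                "chrom": [loci.chrom_names[c] for c in loci.chrom[nz]],
                "pos": loci.pos[nz],
                "ref": loci.ref[nz],
                "alt": loci.alt[nz],
                "gt": g[nz].astype(int),
            }
        )
    known_idx = np.flatnonzero(np.isin(loci.kind, ["poly", "marker"]))
    known = [loci.variant(int(i)) for i in known_idx]
    return calls, known


def genotypes_at(screen: ScreenResult, variant: Variant) -> dict[str, int]:
    """Genotype every pedigree member at one variant (the Sanger-style
    family genotyping used for co-segregation checks)."""
    idx = screen.loci.locate(variant.chromosome, variant.position)
    return {ind.id: screen.genotype(ind.id, idx) for ind in screen.pedigree}


# ---------------------------------------------------------------------------
# toy genomes for desk-scale studies


def make_test_gene(
    chromosome: str,
    cds_start: int,
    seed: int = 7,
    n_codons: int = 334,
    intron: tuple[int, int] = (300, 500),
) -> tuple[GeneModel, int, str, Variant]:
    """Construct a two-exon protein-coding gene whose codon 109 is AGG (Arg),
    so the variant c.325A>T produces the R109W missense change.

    Returns (gene, segment_start, segment_sequence, missense_variant); the
    segment covers the gene span plus UTRs and can be attached to a
    :class:`SequenceStore`.
    """
    rng = np.random.default_rng(seed)
    non_stop = [
        a + b + c
        for a in BASES for b in BASES for c in BASES
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codons = ["ATG"] + [non_stop[rng.integers(len(non_stop))] for _ in range(n_codons - 2)]
    codons.append("TAA")
    codons[108] = "AGG"  # codon 109
    cds = "".join(codons)
    split_at, intron_len = intron
    exon1 = cds[:split_at]
    exon2 = cds[split_at:]
    utr_len = 50
    utr5 = (cds_start - utr_len, cds_start - 1)
    cds1 = (cds_start, cds_start + len(exon1) - 1)
    cds2_start = cds1[1] + 1 + intron_len
    cds2 = (cds2_start, cds2_start + len(exon2) - 1)
    utr3 = (cds2[1] + 1, cds2[1] + utr_len)
    gene = GeneModel(
        "TOYG1", chromosome, "+",
        cds_intervals=(cds1, cds2),
        utr5_intervals=(utr5,),
        utr3_intervals=(utr3,),
    )
    intron_seq = "".join(BASES[i] for i in rng.integers(4, size=intron_len))
    utr5_seq = "".join(BASES[i] for i in rng.integers(4, size=utr_len))
    utr3_seq = "".join(BASES[i] for i in rng.integers(4, size=utr_len))
    segment = utr5_seq + exon1 + intron_seq + exon2 + utr3_seq
    # genomic position of CDS position 325 (codon 109, first base = A of AGG)
    variant_pos = cds2_start + (325 - 1 - split_at)
    variant = Variant(chromosome, variant_pos, "A", "T", origin_tag="enu")
    return gene, utr5[0], segment, variant


def toy_genome(
    n_chromosomes: int = 5,
    chromosome_length: int = 20_000_000,
    recomb_rate: float = 1.0,
    with_gene: bool = True,
    gene_chromosome_index: int = 2,
    gene_cds_start: int = 10_000_000,
    seed: int = 7,
) -> tuple[GenomeModel, Variant | None]:
    """A desk-scale genome (default 5 x 20 Mb) with, optionally, one crafted
    gene carrying the c.325A>T missense anchor.  Returns (genome, variant)."""
    chroms = [(f"chr{i + 1}", chromosome_length) for i in range(n_chromosomes)]
    genes: list[GeneModel] = []
    sequence: dict[str, SequenceStore] = {}
    variant = None
    if with_gene:
        chrom = chroms[gene_chromosome_index][0]
        gene, seg_start, seg, variant = make_test_gene(chrom, gene_cds_start, seed=seed)
        genes.append(gene)
        store = SequenceStore(chromosome_length)
        store.add_segment(seg_start, seg)
        sequence[chrom] = store
    genome = GenomeModel(chroms, genes, recomb_rate=recomb_rate, sequence=sequence)
    return genome, variant
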