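"""File formats: minimal VCF v4.2, PLINK-text PED/MAP, BED and TSV reports.

Coordinate dialects: VCF/PED/MAP/GFF are 1-based inclusive; BED is 0-based
half-open.  Conversion happens only through :func:`to_bed_interval` /
:func:`from_bed_interval`, property-tested in both directions.  Files written
by this module round-trip byte-identically through the readers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, GeneModel, GenomeModel, Individual, Pedigree, SequenceStore
from .linkage import GenotypeMatrix
from .simulate import ReadCountSet

__all__ = [
    "write_readcounts",
    "read_readcounts",
    "genome_to_config",
    "genome_from_config",
    "VcfParseError",
    "VcfRecord",
    "read_vcf",
    "write_vcf",
    "read_pedmap",
    "write_pedmap",
    "to_bed_interval",
    "from_bed_interval",
    "write_regions_bed",
    "write_tsv",
]

VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


class VcfParseError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        prefix = f"line {line_number}: " if line_number else ""
        super().__init__(prefix + message)
        self.line_number = line_number


@dataclass
class VcfRecord:
    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: str = "."
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    genotypes: dict[str, int | None] = field(default_factory=dict)  # sample -> 0/1/2/None
    allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict)


def _format_info(info: dict) -> str:
    if not info:
        return "."
    return ";".join(f"{k}={v}" if v is not None else k for k, v in info.items())


def _parse_info(text: str) -> dict:
    if text in (".", ""):
        return {}
    out = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = None
    return out


_GT_CODE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}
_CODE_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(records: list[VcfRecord], path, samples: list[str] | None = None) -> None:
    """Write a minimal VCF v4.2.  When any record carries genotypes or allele
    depths, a GT(:AD) FORMAT column is emitted for ``samples``."""
    if samples is None:
        seen: list[str] = []
        for r in records:
            for s in list(r.genotypes) + list(r.allele_depths):
                if s not in seen:
                    seen.append(s)
        samples = seen
    has_ad = any(r.allele_depths for r in records)
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##INFO=<ID=PP_DNM,Number=1,Type=Float,Description="De novo posterior">')
    lines.append('##INFO=<ID=PP_NULL,Number=1,Type=Float,Description="Mendelian posterior">')
    lines.append('##INFO=<ID=TRIO_ID,Number=1,Type=String,Description="Calling trio">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_ad:
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header = VCF_HEADER
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)
    fmt = "GT:AD" if has_ad else "GT"
    for r in records:
        row = [r.chrom, str(r.pos), r.id or ".", r.ref, r.alt, r.qual, r.filter,
               _format_info(r.info)]
        if samples:
            row.append(fmt)
            for s in samples:
                cell = _CODE_GT[r.genotypes.get(s)]
                if has_ad:
                    ad = r.allele_depths.get(s)
                    cell += ":" + (f"{ad[0]},{ad[1]}" if ad else ".")
                row.append(cell)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[list[VcfRecord], list[str]]:
    """Read a minimal VCF (optionally gzipped).  SNVs only: symbolic,
    multi-allelic or indel ALT alleles are rejected with the line number."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[VcfRecord] = []
    samples: list[str] = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    samples = cols[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise VcfParseError("fewer than 8 columns", ln)
            chrom, pos, vid, ref, alt, qual, filt, info = parts[:8]
            if ref not in BASES:
                raise VcfParseError(f"non-SNV REF {ref!r}", ln)
            if alt not in BASES:
                raise VcfParseError(f"non-SNV or symbolic ALT {alt!r}", ln)
            try:
                pos_i = int(pos)
            except ValueError:
                raise VcfParseError(f"bad POS {pos!r}", ln) from None
            rec = VcfRecord(chrom, pos_i, vid, ref, alt, qual, filt, _parse_info(info))
            if len(parts) > 9:
                fmt_keys = parts[8].split(":")
                for sample, cell in zip(samples, parts[9:]):
                    fields = dict(zip(fmt_keys, cell.split(":")))
                    gt = fields.get("GT", "./.")
                    rec.genotypes[sample] = _GT_CODE.get(gt)
                    ad = fields.get("AD")
                    if ad and ad != ".":
                        try:
                            ref_d, alt_d = (int(x) for x in ad.split(",")[:2])
                        except ValueError:
                            raise VcfParseError(f"bad AD field {ad!r}", ln) from None
                        rec.allele_depths[sample] = (ref_d, alt_d)
            records.append(rec)
    return records, samples


# ---------------------------------------------------------------------------
# PLINK-text PED/MAP

_SEX_OUT = {"M": "1", "F": "2"}
_SEX_IN = {"1": "M", "2": "F"}
_AFF_OUT = {True: "2", False: "1", None: "0"}
_AFF_IN = {"2": True, "1": False, "0": None, "-9": None}


def write_pedmap(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    ped_path,
    map_path,
    family_id: str = "FAM1",
) -> None:
    """Write PLINK-text PED/MAP.  Genotype codes become allele pairs (1=ref,
    2=alt); missing is "0 0"."""
    code_pair = {0: "1 1", 1: "1 2", 2: "2 2", -1: "0 0"}
    lines = []
    for ind in pedigree:
        row = [
            family_id, ind.id, ind.sire_id or "0", ind.dam_id or "0",
            _SEX_OUT[ind.sex], _AFF_OUT[ind.affected],
        ]
        if ind.id in matrix.individuals:
            g = matrix.column(ind.id)
            row += [code_pair[int(x)] for x in g]
        else:
            row += ["0 0"] * matrix.n_markers
        lines.append("\t".join(row))
    Path(ped_path).write_text("\n".join(lines) + "\n")
    map_lines = [
        "\t".join([str(r["chrom"]), f"m{j + 1}", "0", str(int(r["pos"]))])
        for j, (_, r) in enumerate(matrix.markers.iterrows())
    ]
    Path(map_path).write_text("\n".join(map_lines) + "\n")


def read_pedmap(ped_path, map_path) -> tuple[Pedigree, GenotypeMatrix]:
    """Read PLINK-text PED/MAP into (Pedigree, GenotypeMatrix).

    Individuals with unknown parents ("0") are founders; generation labels are
    not represented in PED and come back as "founder"/"G1"-agnostic defaults.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{map_path}: line {ln}: expected 4 columns")
        map_rows.append({"chrom": parts[0], "id": parts[1], "pos": int(parts[3])})
    markers = pd.DataFrame(map_rows)[["chrom", "pos"]]
    markers["ref"] = "A"
    markers["alt"] = "G"
    n_markers = len(markers)

    individuals: list[Individual] = []
    genotypes = []
    ids = []
    pair_code = {("1", "1"): 0, ("1", "2"): 1, ("2", "1"): 1, ("2", "2"): 2, ("0", "0"): -1}
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise ValueError(
                f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} fields, "
                f"got {len(parts)} (PED/MAP marker counts inconsistent)"
            )
        _, iid, sire, dam, sex, aff = parts[:6]
        individuals.append(
            Individual(
                iid,
                _SEX_IN.get(sex, "M"),
                None if sire == "0" else sire,
                None if dam == "0" else dam,
                affected=_AFF_IN.get(aff),
            )
        )
        alleles = parts[6:]
        row = [
            pair_code.get((alleles[2 * j], alleles[2 * j + 1]), -1)
            for j in range(n_markers)
        ]
        genotypes.append(row)
        ids.append(iid)
    geno = np.array(genotypes, dtype=np.int8).T if genotypes else np.zeros((n_markers, 0), np.int8)
    return Pedigree(individuals), GenotypeMatrix(markers, geno, ids)


# ---------------------------------------------------------------------------
# BED and TSV


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def write_regions_bed(regions, path) -> None:
    lines = []
    for r in regions:
        s, e = to_bed_interval(r.start, r.end)
        lines.append(f"{r.chromosome}\t{s}\t{e}\tLOD={r.peak_lod:.3f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_readcounts(counts: ReadCountSet, path) -> None:
    """Long-format read-count TSV: chrom, pos, individual, ref_count, alt_count."""
    write_tsv(counts.to_dataframe(), path)


def read_readcounts(path, chrom_names: list[str] | None = None) -> ReadCountSet:
    df = pd.read_csv(path, sep="\t")
    sites = df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    if chrom_names is None:
        chrom_names = list(dict.fromkeys(sites["chrom"]))
    code = {c: i for i, c in enumerate(chrom_names)}
    sites = sites.sort_values(["chrom", "pos"], key=lambda s: s.map(code) if s.name == "chrom" else s)
    rcs = ReadCountSet(
        chrom_names,
        sites["chrom"].map(code).to_numpy(),
        sites["pos"].to_numpy(),
        np.full(len(sites), "A"),
        np.full(len(sites), "G"),
    )
    key = {(c, int(p)): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))}
    for ind, grp in df.groupby("individual", sort=False):
        ref = np.zeros(len(sites), dtype=np.int16)
        alt = np.zeros(len(sites), dtype=np.int16)
        idx = [key[(c, int(p))] for c, p in zip(grp["chrom"], grp["pos"])]
        ref[idx] = grp["ref_count"].to_numpy()
        alt[idx] = grp["alt_count"].to_numpy()
        rcs.add_individual(str(ind), ref, alt)
    return rcs


# ---------------------------------------------------------------------------
# structured genome config (YAML)


def genome_to_config(genome: GenomeModel) -> dict:
    cfg = {
        "chromosomes": [{"name": n, "length": l} for n, l in genome.chromosomes],
        "recomb_rate": genome.recomb_rate,
        "genes": [
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "strand": g.strand,
                "cds": [list(iv) for iv in g.cds_intervals],
                "utr5": [list(iv) for iv in g.utr5_intervals],
                "utr3": [list(iv) for iv in g.utr3_intervals],
            }
            for g in genome.genes
        ],
        "sequence_segments": [
            {"chromosome": chrom, "start": start, "bases": bases}
            for chrom, store in genome.sequence.items()
            for start, bases in store._segments
        ],
    }
    return cfg


def genome_from_config(cfg: dict) -> GenomeModel:
    chroms = [(c["name"], int(c["length"])) for c in cfg["chromosomes"]]
    genes = [
        GeneModel(
            g["gene_id"], g["chromosome"], g["strand"],
            tuple(tuple(iv) for iv in g["cds"]),
            tuple(tuple(iv) for iv in g.get("utr5", [])),
            tuple(tuple(iv) for iv in g.get("utr3", [])),
        )
        for g in cfg.get("genes", [])
    ]
    lengths = dict(chroms)
    sequence: dict[str, SequenceStore] = {}
    for seg in cfg.get("sequence_segments", []):
        chrom = seg["chromosome"]
        store = sequence.setdefault(chrom, SequenceStore(lengths[chrom]))
        store.add_segment(int(seg["start"]), seg["bases"])
    return GenomeModel(chroms, genes, cfg.get("recomb_rate", 1.0), sequence)
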