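"""Causative-variant filtering cascade.

Five criteria applied in order to WGS call sets from affected and control
animals: (1) genotype pattern consistent with the inheritance mode,
(2) position inside a linkage region, (3) absence from the known-polymorphism
list, (4) protein-disrupting consequence (missense or nonsense), and
(5) complete co-segregation with the phenotype across the whole pedigree.
The stages are pure intersections, so their order changes only the per-stage
counts, never the final set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import Consequence, GenomeModel, Pedigree, Variant, consequence_annotate
from .linkage import LinkageRegion

__all__ = ["CandidateSet", "filter_cascade", "cosegregation_check", "CosegregationResult"]

STAGE_NAMES = (
    "inheritance_pattern",
    "linkage_region",
    "not_known_snp",
    "protein_disrupting",
    "cosegregation",
)

VKey = tuple[str, int, str, str]  # chrom, pos, ref, alt


@dataclass
class CandidateSet:
    """Per-stage surviving variants and the final annotated candidates."""

    stages: list[tuple[str, list[Variant]]]
    final: list[tuple[Variant, Consequence]]
    advisory: list[tuple[Variant, Consequence]] = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        rows = []
        prev = None
        for name, variants in self.stages:
            rows.append(
                {"stage": name, "n_before": prev if prev is not None else len(variants),
                 "n_after": len(variants)}
            )
            prev = len(variants)
        # n_before of stage k is n_after of stage k-1; first stage counts its input
        for i in range(1, len(rows)):
            rows[i]["n_before"] = rows[i - 1]["n_after"]
        return pd.DataFrame(rows, columns=["stage", "n_before", "n_after"])


@dataclass(frozen=True)
class CosegregationResult:
    consistent: bool
    n_informative: int
    n_discordant: int


def _callset_genotypes(calls: pd.DataFrame) -> dict[VKey, int]:
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): int(r.gt) for r in calls.itertuples()
    }


def cosegregation_check(
    genotypes: dict[str, int | None],
    affection: dict[str, bool | None],
    mode: str,
) -> CosegregationResult:
    """Full-penetrance co-segregation over a pedigree.

    Dominant: consistent iff every affected individual carries at least one alt
    allele and every unaffected carries none.  Recessive: every affected is
    alt-homozygous and no unaffected is.  Individuals with unknown genotype or
    phenotype are skipped; ``n_informative`` counts affected individuals and
    variant carriers (the individuals actually constraining the pattern).
    """
    if mode not in ("dominant", "recessive"):
        raise ValueError("mode must be dominant or recessive")
    n_disc = 0
    n_inf = 0
    for ind, g in genotypes.items():
        aff = affection.get(ind)
        if g is None or aff is None:
            continue
        carrier = g >= 1 if mode == "dominant" else g == 2
        if aff or carrier:
            n_inf += 1
        if aff != carrier:
            n_disc += 1
    return CosegregationResult(n_disc == 0, n_inf, n_disc)


def filter_cascade(
    affected_calls: dict[str, pd.DataFrame],
    control_calls: dict[str, pd.DataFrame],
    mode: str,
    regions: list[LinkageRegion],
    known_snps: list[Variant],
    genome: GenomeModel,
    pedigree: Pedigree | None = None,
    pedigree_genotypes: dict[VKey, dict[str, int]] | None = None,
) -> CandidateSet:
    """Apply the five-criteria cascade and return the per-stage audit trail.

    ``affected_calls`` needs at least two call sets and ``control_calls`` at
    least one (tables with chrom, pos, ref, alt, gt columns).  Stage 5 needs a
    phenotyped ``pedigree`` plus ``pedigree_genotypes`` (family-wide genotyping
    of each surviving variant); without them the co-segregation stage only
    re-checks the sequenced individuals.
    """
    if len(affected_calls) < 2:
        raise ValueError("need call sets for at least two affected individuals")
    if len(control_calls) < 1:
        raise ValueError("need at least one control call set")
    if mode not in ("dominant", "recessive"):
        raise ValueError("mode must be dominant or recessive")

    aff_geno = {ind: _callset_genotypes(df) for ind, df in affected_calls.items()}
    ctl_geno = {ind: _callset_genotypes(df) for ind, df in control_calls.items()}

    universe: dict[VKey, Variant] = {}
    for df in affected_calls.values():
        for r in df.itertuples():
            universe.setdefault(
                (r.chrom, int(r.pos), r.ref, r.alt),
                Variant(r.chrom, int(r.pos), r.ref, r.alt, origin_tag="enu"),
            )

    stages: list[tuple[str, list[Variant]]] = []

    # stage 1: inheritance pattern in the sequenced animals
    def fits_pattern(key: VKey) -> bool:
        if mode == "dominant":
            ok_aff = all(g.get(key, 0) == 1 for g in aff_geno.values())
            ok_ctl = all(g.get(key, 0) == 0 for g in ctl_geno.values())
        else:
            ok_aff = all(g.get(key, 0) == 2 for g in aff_geno.values())
            ok_ctl = all(g.get(key, 0) != 2 for g in ctl_geno.values())
        return ok_aff and ok_ctl

    surviving = [k for k in universe if fits_pattern(k)]
    stages.append((STAGE_NAMES[0], [universe[k] for k in surviving]))

    # stage 2: inside a linkage region
    def in_region(key: VKey) -> bool:
        return any(
            r.chromosome == key[0] and r.start <= key[1] <= r.end for r in regions
        )

    surviving = [k for k in surviving if in_region(k)]
    stages.append((STAGE_NAMES[1], [universe[k] for k in surviving]))

    # stage 3: not a known polymorphism (ref-agnostic chrom+pos+alt match)
    known = {v.key for v in known_snps}
    surviving = [k for k in surviving if (k[0], k[1], k[3]) not in known]
    stages.append((STAGE_NAMES[2], [universe[k] for k in surviving]))

    # stage 4: protein-disrupting consequence
    annotated = {k: consequence_annotate(universe[k], genome) for k in surviving}
    advisory = [
        (universe[k], c)
        for k, c in annotated.items()
        if c.klass in ("utr5", "utr3") or c.near_splice
    ]
    surviving = [k for k in surviving if annotated[k].klass in ("missense", "nonsense")]
    stages.append((STAGE_NAMES[3], [universe[k] for k in surviving]))

    # stage 5: complete co-segregation over the pedigree
    affection: dict[str, bool | None] = {}
    if pedigree is not None:
        affection = {ind.id: ind.affected for ind in pedigree}
    else:
        affection = {ind: True for ind in affected_calls}
        affection.update({ind: False for ind in control_calls})

    final_keys = []
    for k in surviving:
        if pedigree_genotypes is not None and k in pedigree_genotypes:
            genos: dict[str, int | None] = dict(pedigree_genotypes[k])
        else:
            genos = {ind: g.get(k, 0) for ind, g in {**aff_geno, **ctl_geno}.items()}
        res = cosegregation_check(genos, affection, mode)
        if res.consistent:
            final_keys.append(k)
    stages.append((STAGE_NAMES[4], [universe[k] for k in final_keys]))

    final = [(universe[k], annotated[k]) for k in final_keys]
    return CandidateSet(stages, final, advisory)
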