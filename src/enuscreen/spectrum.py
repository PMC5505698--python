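"""Substitution-spectrum classification and summaries.

ENU predominantly induces transitions at A:T and G:C pairs; the classifier
collapses complementary strands into the six canonical substitution classes and
the summary reports transition/transversion fractions and the genomic-region
distribution of a call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import BASES, COMPLEMENT, GenomeModel, Variant, consequence_annotate

__all__ = [
    "SUBSTITUTION_CLASSES",
    "TRANSITION_CLASSES",
    "MutationSpectrum",
    "classify_substitution",
    "SpectrumSummary",
    "summarize_spectrum",
]

SUBSTITUTION_CLASSES = (
    "A:T>G:C",
    "G:C>A:T",
    "A:T>C:G",
    "A:T>T:A",
    "G:C>C:G",
    "G:C>T:A",
)
TRANSITION_CLASSES = ("A:T>G:C", "G:C>A:T")

REGION_CLASSES = ("intergenic", "intron", "exon", "utr5", "utr3")

_PURINE_CLASS = {
    ("A", "G"): "A:T>G:C",
    ("G", "A"): "G:C>A:T",
    ("A", "C"): "A:T>C:G",
    ("A", "T"): "A:T>T:A",
    ("G", "C"): "G:C>C:G",
    ("G", "T"): "G:C>T:A",
}

# the two (ref, alt) strand representations of each collapsed class
CLASS_STRANDS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {}
for (r, a), cls in _PURINE_CLASS.items():
    CLASS_STRANDS[cls] = ((r, a), (COMPLEMENT[r], COMPLEMENT[a]))


class ClassificationError(ValueError):
    pass


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Return (strand-collapsed class, is_transition) for a single substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ClassificationError(f"cannot classify {ref}>{alt}")
    if ref in "CT":  # collapse to the purine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    cls = _PURINE_CLASS[(ref, alt)]
    return cls, cls in TRANSITION_CLASSES


def _default_probs() -> dict[str, float]:
    # Only the aggregate transition fraction (0.712) is a printed calibration;
    # this per-class split is the package's default, not a published breakdown.
    return {
        "G:C>A:T": 0.45,
        "A:T>G:C": 0.262,
        "A:T>C:G": 0.072,
        "A:T>T:A": 0.072,
        "G:C>C:G": 0.072,
        "G:C>T:A": 0.072,
    }


@dataclass(frozen=True)
class MutationSpectrum:
    """Probabilities over the six strand-collapsed substitution classes.

    The default is calibrated so that transitions carry 71.2% of the mass,
    dominated by G:C>A:T — the hallmark ENU spectrum.
    """

    class_probs: dict[str, float] = field(default_factory=_default_probs)

    def __post_init__(self):
        missing = set(SUBSTITUTION_CLASSES) - set(self.class_probs)
        if missing:
            raise ValueError(f"missing classes: {sorted(missing)}")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.class_probs.values()):
            raise ValueError("negative class probability")

    @property
    def transition_mass(self) -> float:
        return sum(self.class_probs[c] for c in TRANSITION_CLASSES)

    def probs_vector(self) -> list[float]:
        return [self.class_probs[c] for c in SUBSTITUTION_CLASSES]

    def conditional_probs(self, ref_base: str) -> dict[str, float]:
        """Class probabilities renormalized to classes compatible with ``ref_base``."""
        compat = {
            cls: p
            for cls, p in self.class_probs.items()
            if any(r == ref_base for r, _ in CLASS_STRANDS[cls])
        }
        total = sum(compat.values())
        return {c: p / total for c, p in compat.items()}

    def alt_for(self, cls: str, ref_base: str) -> str:
        for r, a in CLASS_STRANDS[cls]:
            if r == ref_base:
                return a
        raise ClassificationError(f"class {cls} incompatible with ref {ref_base}")


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    transition_fraction: float | None
    transversion_fraction: float | None
    region_counts: dict[str, int] | None = None

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def summarize_spectrum(
    variants: list[Variant], genome: GenomeModel | None = None
) -> SpectrumSummary:
    """Tally substitution classes of ``variants``; with ``genome``, also tally the
    genomic-region distribution (exon = any CDS consequence class)."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    n_ts = 0
    for v in variants:
        cls, is_ts = classify_substitution(v.ref, v.alt)
        counts[cls] += 1
        n_ts += is_ts
    total = sum(counts.values())
    ts_frac = n_ts / total if total else None
    tv_frac = 1 - ts_frac if ts_frac is not None else None

    region_counts = None
    if genome is not None:
        region_counts = {r: 0 for r in REGION_CLASSES}
        for v in variants:
            rec = consequence_annotate(v, genome)
            if rec.klass in ("synonymous", "missense", "nonsense"):
                region_counts["exon"] += 1
            elif rec.klass == "intronic":
                region_counts["intron"] += 1
            else:
                region_counts[rec.klass] += 1
    return SpectrumSummary(counts, ts_frac, tv_frac, region_counts)
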