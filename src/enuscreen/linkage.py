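"""Family-based parametric linkage mapping.

Marker QC (call rate, MAF), exact two-point LOD scores on screen pedigrees —
including the sire-daughter backcross loop, handled exactly by conditioning on
the sire's two-locus genotype — linkage-region extraction, and a case-control
allelic association test.

The likelihood at recombination fraction theta is the exact joint probability
of marker genotypes and affection status: founder two-locus diplotypes from
allele frequencies under linkage equilibrium, two-locus haplotype transmission
with recombination theta, and penetrance per individual.  LOD(theta) =
log10 L(theta) / L(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Pedigree, PedigreeError

__all__ = [
    "UnsupportedPedigreeError",
    "DiseaseModel",
    "GenotypeMatrix",
    "LODProfile",
    "LinkageRegion",
    "qc_markers",
    "two_point_lod",
    "genome_scan",
    "extract_regions",
    "allelic_association",
    "LinkageModel",
    "LinkageResults",
]

LOD_NEG_SENTINEL = -99.0
DEFAULT_THETA_GRID = np.round(np.arange(0, 0.501, 0.01), 2)


class UnsupportedPedigreeError(PedigreeError):
    """Pedigree contains a loop other than the sire-daughter backcross."""


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease model: penetrances (f0, f1, f2) by disease-allele
    count and founder disease-allele frequency q."""

    mode: str = "dominant"
    penetrances: tuple[float, float, float] | None = None
    q: float = 1e-4

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError("mode must be dominant or recessive")
        if self.penetrances is None:
            default = (0.0, 1.0, 1.0) if self.mode == "dominant" else (0.0, 0.0, 1.0)
            object.__setattr__(self, "penetrances", default)
        if any(not 0 <= f <= 1 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


class GenotypeMatrix:
    """Biallelic marker genotypes: ``markers`` table (chrom, pos, ref, alt,
    founder_freq) and an (n_markers, n_individuals) int8 array of alt-allele
    counts with -1 for missing."""

    def __init__(self, markers: pd.DataFrame, genotypes: np.ndarray, individuals: list[str]):
        self.markers = markers.reset_index(drop=True)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.individuals = list(individuals)
        if self.genotypes.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("genotype array shape mismatch")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"marker positions not increasing on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def call_rates(self) -> np.ndarray:
        return (self.genotypes >= 0).mean(axis=1)

    def mafs(self) -> np.ndarray:
        observed = self.genotypes >= 0
        n_obs = observed.sum(axis=1)
        alt = np.where(observed, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), np.nan)
        return np.fmin(freq, 1 - freq)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.loc[np.asarray(mask)], self.genotypes[mask], self.individuals
        )

    def column(self, ind_id: str) -> np.ndarray:
        return self.genotypes[:, self.individuals.index(ind_id)]


def qc_markers(
    matrix: GenotypeMatrix, call_rate_min: float = 0.90, maf_min: float = 0.05
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep markers with observed call rate >= call_rate_min and sample
    MAF >= maf_min; the report lists removals by reason."""
    if matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    cr = matrix.call_rates()
    maf = matrix.mafs()
    low_cr = cr < call_rate_min
    low_maf = ~low_cr & (np.isnan(maf) | (maf < maf_min))
    keep = ~(low_cr | low_maf)
    reasons = np.where(low_cr, "call_rate", np.where(low_maf, "maf", "kept"))
    report = pd.DataFrame(
        {
            "chrom": matrix.markers["chrom"],
            "pos": matrix.markers["pos"],
            "call_rate": cr,
            "maf": maf,
            "status": reasons,
        }
    )
    if not keep.any():
        import warnings

        warnings.warn("all markers removed by QC", stacklevel=2)
    return matrix.subset_markers(keep), report


# ---------------------------------------------------------------------------
# two-locus state machinery
#
# haplotype h = 2*m + d   (m marker alt allele, d disease allele)
# ordered diplotype state s = 4*h_pat + 4? no: s = 4*h1 + h2 with h1 paternal

_HAP_M = np.array([0, 0, 1, 1])
_HAP_D = np.array([0, 1, 0, 1])
_S_H1 = np.repeat(np.arange(4), 4)
_S_H2 = np.tile(np.arange(4), 4)
MARKER_GENO = _HAP_M[_S_H1] + _HAP_M[_S_H2]  # (16,)
DISEASE_GENO = _HAP_D[_S_H1] + _HAP_D[_S_H2]  # (16,)
CHILD_STATE = (4 * np.arange(4)[:, None] + np.arange(4)[None, :])  # [pat, mat] -> s


def _transmission(thetas: np.ndarray) -> np.ndarray:
    """Gamete tensor Tr[t, s, g]: probability a parent in ordered state s
    transmits haplotype g at recombination fraction theta_t."""
    T = len(thetas)
    Tr = np.zeros((T, 16, 4))
    for s in range(16):
        h1, h2 = _S_H1[s], _S_H2[s]
        m1, d1 = _HAP_M[h1], _HAP_D[h1]
        m2, d2 = _HAP_M[h2], _HAP_D[h2]
        for t, th in enumerate(thetas):
            Tr[t, s, 2 * m1 + d1] += 0.5 * (1 - th)
            Tr[t, s, 2 * m1 + d2] += 0.5 * th
            Tr[t, s, 2 * m2 + d2] += 0.5 * (1 - th)
            Tr[t, s, 2 * m2 + d1] += 0.5 * th
    return Tr


def _founder_prior(alt_freq: np.ndarray, q: float) -> np.ndarray:
    """F[m, 16]: linkage-equilibrium founder prior over ordered diplotypes."""
    p = np.asarray(alt_freq, dtype=float)[:, None]  # (M, 1)
    hap = np.where(_HAP_M[None, :] == 1, p, 1 - p) * np.where(
        _HAP_D[None, :] == 1, q, 1 - q
    )  # (M, 4)
    return hap[:, _S_H1] * hap[:, _S_H2]


class _Peeler:
    """Exact pedigree likelihood over (markers, thetas), by recursive
    conditioning on parental genotypes, sire first."""

    def __init__(
        self,
        pedigree: Pedigree,
        genotypes: dict[str, np.ndarray],  # id -> (M,) codes 0/1/2/-1
        alt_freq: np.ndarray,
        disease_model: DiseaseModel,
        thetas: np.ndarray,
    ):
        self.ped = pedigree
        self.M = len(alt_freq)
        self.T = len(thetas)
        self.Tr = _transmission(thetas)
        self.F = _founder_prior(alt_freq, disease_model.q)
        pen = np.asarray(disease_model.penetrances)

        self.penobs: dict[str, np.ndarray] = {}
        for ind in pedigree:
            if ind.affected is True:
                pvec = pen[DISEASE_GENO]
            elif ind.affected is False:
                pvec = 1 - pen[DISEASE_GENO]
            else:
                pvec = np.ones(16)
            g = genotypes.get(ind.id)
            if g is None:
                obs = np.ones((self.M, 16))
            else:
                g = np.asarray(g)
                obs = (MARKER_GENO[None, :] == g[:, None]) | (g[:, None] < 0)
            self.penobs[ind.id] = obs * pvec[None, :]  # (M, 16)

        self.families = pedigree.families()
        self.fams_by_parent: dict[str, list[int]] = {}
        for k, (s, d, _) in enumerate(self.families):
            self.fams_by_parent.setdefault(s, []).append(k)
            self.fams_by_parent.setdefault(d, []).append(k)
        self.founder_ids = {i.id for i in pedigree.founders()}
        self._processed: set[int] = set()

    def _child_gamete_value(self, sub: np.ndarray, has_ref: bool) -> np.ndarray:
        """Re-index a child subtree value by (paternal, maternal) gametes."""
        if has_ref:
            return sub[..., CHILD_STATE]  # (M, T, 16ref, 4, 4)
        return sub[..., CHILD_STATE]  # (M, T, 4, 4)

    def value(self, ind_id: str, ref_id: str | None) -> tuple[np.ndarray, bool]:
        """Subtree likelihood of ``ind_id`` as a function of its state
        (M, T, 16), or (M, T, 16ref, 16) when the backcross ties it to
        ``ref_id``."""
        arr = self.penobs[ind_id][:, None, :] * np.ones((1, self.T, 1))
        has_ref = False
        for k in list(self.fams_by_parent.get(ind_id, [])):
            if k in self._processed:
                continue
            sire, dam, children = self.families[k]
            i_is_sire = sire == ind_id
            spouse = dam if i_is_sire else sire
            if spouse in self.founder_ids and len(self.fams_by_parent.get(spouse, [])) == 1:
                self._processed.add(k)
                K = np.ones((self.M, self.T, 16, 16))  # (i, spouse)
                for c in children:
                    sub, sref = self.value(c, ref_id=ind_id)
                    Sg = self._child_gamete_value(sub, sref)
                    if sref:
                        eq = "tia,tsb,mtiab->mtis" if i_is_sire else "tsa,tib,mtiab->mtis"
                    else:
                        eq = "tia,tsb,mtab->mtis" if i_is_sire else "tsa,tib,mtab->mtis"
                    K *= np.einsum(eq, self.Tr, self.Tr, Sg, optimize=True)
                spouse_vec = self.F * self.penobs[spouse]  # (M, 16)
                arr = arr * np.einsum("ms,mtis->mti", spouse_vec, K)
            elif ref_id is not None and spouse == ref_id:
                self._processed.add(k)
                Kr = np.ones((self.M, self.T, 16, 16))  # (ref, i)
                for c in children:
                    sub, sref = self.value(c, ref_id=None)
                    if sref:
                        raise UnsupportedPedigreeError(
                            f"nested loop below {c} is not supported"
                        )
                    Sg = self._child_gamete_value(sub, False)
                    eq = "tra,tib,mtab->mtri" if not i_is_sire else "tia,trb,mtab->mtri"
                    Kr *= np.einsum(eq, self.Tr, self.Tr, Sg, optimize=True)
                arr = arr[..., None, :] * Kr if not has_ref else arr * Kr
                has_ref = True
            else:
                # processed from the spouse's side (backcross partner)
                continue
        return arr, has_ref

    def likelihood(self) -> np.ndarray:
        """L[m, t]; raises UnsupportedPedigreeError on structures the
        conditioning order cannot peel."""
        if not self.families:
            # founders only: product of marginals
            L = np.ones((self.M, self.T))
            for ind in self.ped:
                L *= (self.F * self.penobs[ind.id]).sum(axis=1)[:, None]
            return L
        # try founder parents as the conditioning root, central sires first,
        # until the recursion covers every family
        roots = []
        for s, d, _ in self.families:
            for cand in (s, d):
                if cand in self.founder_ids and cand not in roots:
                    roots.append(cand)
        roots.sort(key=lambda c: -len(self.fams_by_parent[c]))
        last_err: UnsupportedPedigreeError | None = None
        for root in roots:
            self._processed = set()
            try:
                val, has_ref = self.value(root, ref_id=None)
                if has_ref or len(self._processed) != len(self.families):
                    raise UnsupportedPedigreeError(
                        "pedigree contains a loop other than the sire-daughter backcross"
                    )
            except UnsupportedPedigreeError as err:
                last_err = err
                continue
            L = np.einsum("ms,mts->mt", self.F, val)
            covered = {root}
            for s, d, kids in self.families:
                covered |= {s, d, *kids}
            for ind in self.ped:  # childless, unconnected individuals
                if ind.id not in covered:
                    L *= (self.F * self.penobs[ind.id]).sum(axis=1)[:, None]
            return L
        raise last_err or UnsupportedPedigreeError("no peelable root founder found")


def _pedigree_lod(
    pedigree: Pedigree,
    genotypes: dict[str, np.ndarray],
    alt_freq: np.ndarray,
    disease_model: DiseaseModel,
    theta_grid: np.ndarray,
) -> np.ndarray:
    """LOD[m, t] over the theta grid (0.5 appended internally as reference)."""
    thetas = np.asarray(theta_grid, dtype=float)
    full = np.concatenate([thetas, [0.5]])
    L = _Peeler(pedigree, genotypes, alt_freq, disease_model, full).likelihood()
    L_ref = L[:, -1]
    L = L[:, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.log10(L) - np.log10(L_ref)[:, None]
    lod[np.isneginf(lod)] = LOD_NEG_SENTINEL
    lod[np.isnan(lod)] = 0.0  # data impossible at every theta: uninformative
    return lod


def two_point_lod(
    pedigree: Pedigree,
    genotypes: dict[str, int],
    disease_model: DiseaseModel,
    marker_alt_freq: float = 0.5,
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
) -> tuple[np.ndarray, float, float]:
    """Exact two-point parametric LOD for one marker.

    ``genotypes`` maps individual id to alt-allele count (0/1/2; omit or use
    -1 for missing).  Returns (LOD over theta_grid, max LOD, argmax theta).
    """
    gvec = {i: np.array([g]) for i, g in genotypes.items()}
    lod = _pedigree_lod(
        pedigree, gvec, np.array([marker_alt_freq]), disease_model, np.asarray(theta_grid)
    )[0]
    k = int(np.argmax(lod))
    return lod, float(lod[k]), float(np.asarray(theta_grid)[k])


@dataclass
class LODProfile:
    """Per-marker max-over-theta LOD scores."""

    table: pd.DataFrame  # chrom, pos, lod, theta_hat
    theta_grid: np.ndarray

    def max_lod(self) -> float:
        return float(self.table["lod"].max()) if len(self.table) else float("nan")


@dataclass(frozen=True)
class LinkageRegion:
    chromosome: str
    start: int
    end: int
    peak_lod: float
    peak_marker_pos: int


def genome_scan(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    disease_model: DiseaseModel,
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
    chunk_size: int = 64,
) -> LODProfile:
    """Two-point LOD at every marker of a QC'd genotype matrix."""
    thetas = np.asarray(theta_grid)
    rows = []
    freq_col = (
        matrix.markers["founder_freq"]
        if "founder_freq" in matrix.markers
        else pd.Series(np.nan, index=matrix.markers.index)
    )
    sample_freq = matrix.mafs()
    for start in range(0, matrix.n_markers, chunk_size):
        sl = slice(start, min(start + chunk_size, matrix.n_markers))
        freqs = freq_col.iloc[sl].to_numpy(dtype=float)
        fallback = sample_freq[sl]
        freqs = np.where(np.isnan(freqs), np.fmax(fallback, 0.01), freqs)
        genos = {
            ind: matrix.genotypes[sl, j] for j, ind in enumerate(matrix.individuals)
        }
        lod = _pedigree_lod(pedigree, genos, freqs, disease_model, thetas)
        kmax = lod.argmax(axis=1)
        k_ex = int(np.argmin(np.abs(thetas - 0.05)))  # exclusion-mapping theta
        for i, m in enumerate(range(sl.start, sl.stop)):
            rows.append(
                {
                    "chrom": matrix.markers["chrom"].iloc[m],
                    "pos": int(matrix.markers["pos"].iloc[m]),
                    "lod": float(lod[i, kmax[i]]),
                    "theta_hat": float(thetas[kmax[i]]),
                    "lod_exclusion": float(lod[i, k_ex]),
                }
            )
    return LODProfile(
        pd.DataFrame(rows, columns=["chrom", "pos", "lod", "theta_hat", "lod_exclusion"]),
        thetas,
    )


def extract_regions(
    profile: LODProfile,
    threshold: float = 3.0,
    merge_gap_markers: int = 2,
    exclusion_lod: float = -2.0,
) -> list[LinkageRegion]:
    """Support intervals around runs of markers with LOD >= threshold.

    A two-point profile mixes three kinds of markers: linked (LOD >=
    threshold), *excluding* (clear recombination evidence against tight
    linkage: LOD near theta = 0.05 at or below ``exclusion_lod``, the classic
    exclusion-mapping cut), and *uninformative* (e.g. the sire is homozygous;
    the marker could never reach the threshold and carries no evidence either
    way).  Uninformative markers pass freely through a run; up to
    ``merge_gap_markers`` consecutive excluding markers are tolerated inside
    it (genotyping artifacts).  Region bounds extend to the nearest excluding
    marker beyond each end of the run, or to the chromosome's outermost marker
    — which is how family studies end up reporting support intervals tens of
    Mb wide.

    Profiles lacking the ``lod_exclusion`` column fall back to treating every
    sub-threshold marker as excluding (the narrow flanking-marker convention).
    """
    regions = []
    for chrom, grp in profile.table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        lod = grp["lod"].to_numpy()
        if "lod_exclusion" in grp:
            excl_evidence = grp["lod_exclusion"].to_numpy() <= exclusion_lod
        else:
            excl_evidence = np.ones(len(lod), dtype=bool)
        above = lod >= threshold
        excluding = excl_evidence & ~above
        i = 0
        n = len(lod)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            end = i
            gap = 0
            while j + 1 < n:
                if above[j + 1]:
                    j += 1
                    end = j
                    gap = 0
                elif excluding[j + 1]:
                    if gap >= merge_gap_markers:
                        break
                    j += 1
                    gap += 1
                else:  # uninformative: free pass
                    j += 1
            left = i - 1
            while left >= 0 and not excluding[left]:
                left -= 1
            right = end + 1
            while right < n and not excluding[right]:
                right += 1
            start_bound = int(pos[left]) if left >= 0 else int(pos[0])
            end_bound = int(pos[right]) if right < n else int(pos[n - 1])
            seg = slice(i, end + 1)
            peak = int(np.argmax(lod[seg])) + i
            regions.append(
                LinkageRegion(chrom, start_bound, end_bound, float(lod[peak]), int(pos[peak]))
            )
            i = j + 1
    return regions


def allelic_association(
    case_genotypes: np.ndarray, control_genotypes: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 allele-count table at one marker.

    Genotypes are alt-allele counts with -1 for missing.  Returns
    (chi2, df=1, p); a zero marginal yields (nan, 1, nan).
    """
    case = np.asarray(case_genotypes)
    ctrl = np.asarray(control_genotypes)
    case = case[case >= 0]
    ctrl = ctrl[ctrl >= 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("need at least one case and one control with genotypes")
    a_alt, a_ref = case.sum(), 2 * len(case) - case.sum()
    b_alt, b_ref = ctrl.sum(), 2 * len(ctrl) - ctrl.sum()
    table = np.array([[a_alt, a_ref], [b_alt, b_ref]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (float("nan"), 1, float("nan"))
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# model/results presentation


class LinkageModel:
    """Parametric two-point linkage scan as a fitted model."""

    def __init__(
        self,
        pedigree: Pedigree,
        matrix: GenotypeMatrix,
        disease_model: DiseaseModel,
        qc: bool = True,
        call_rate_min: float = 0.90,
        maf_min: float = 0.05,
    ):
        self.pedigree = pedigree
        self.disease_model = disease_model
        if qc:
            self.matrix, self.qc_report = qc_markers(matrix, call_rate_min, maf_min)
        else:
            self.matrix, self.qc_report = matrix, None

    def fit(self, theta_grid: np.ndarray = DEFAULT_THETA_GRID) -> "LinkageResults":
        profile = genome_scan(self.pedigree, self.matrix, self.disease_model, theta_grid)
        return LinkageResults(self, profile)


class LinkageResults:
    def __init__(self, model: LinkageModel, profile: LODProfile):
        self.model = model
        self.profile = profile

    def regions(self, threshold: float = 3.0, merge_gap_markers: int = 2):
        return extract_regions(self.profile, threshold, merge_gap_markers)

    def summary(self, threshold: float = 3.0) -> str:
        t = self.profile.table
        lines = [
            f"Parametric linkage scan ({self.model.disease_model.mode} model)",
            "=" * 50,
            f"markers scanned:   {len(t)}",
            f"max LOD:           {self.profile.max_lod():.3f}",
        ]
        for r in self.regions(threshold):
            lines.append(
                f"  {r.chromosome}:{r.start}-{r.end}  peak LOD {r.peak_lod:.2f} "
                f"at {r.peak_marker_pos}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, threshold: float = 3.0):
        """LOD profile by chromosome (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0
        for chrom, grp in self.profile.table.groupby("chrom", sort=False):
            ax.plot(grp["pos"] + offset, grp["lod"], ".", ms=3, label=str(chrom))
            offset += grp["pos"].max()
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
        ax.set_xlabel("genome position")
        ax.set_ylabel("LOD")
        return ax
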