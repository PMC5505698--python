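import numpy as np
import pandas as pd
import pytest

from enuscreen.genome import Individual, Pedigree
from enuscreen.linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    GenotypeMatrix,
    LinkageModel,
    LODProfile,
    UnsupportedPedigreeError,
    _Peeler,
    allelic_association,
    extract_regions,
    qc_markers,
    two_point_lod,
)

from _oracles import pedigree_likelihood_oracle
from conftest import phase_known_pedigree


def _matrix(genos, positions=None, chrom="chr1", freq=0.5):
    """GenotypeMatrix from an (n_markers, n_ind) list of lists."""
    g = np.asarray(genos, dtype=np.int8)
    n = g.shape[0]
    positions = positions or list(range(1000, 1000 + 1000 * n, 1000))
    markers = pd.DataFrame({
        "chrom": [chrom] * n, "pos": positions,
        "ref": ["A"] * n, "alt": ["G"] * n, "founder_freq": [freq] * n,
    })
    return GenotypeMatrix(markers, g, [f"i{k}" for k in range(g.shape[1])])


class TestQc:
    def test_call_rate_removal(self):
        g = [[1] * 8 + [-1] * 2, [1] * 10]  # marker 0: call rate 0.8
        m = _matrix(g)
        kept, report = qc_markers(m)
        assert kept.n_markers == 1
        assert report["status"].tolist()[0] == "call_rate"

    def test_monomorphic_removed(self):
        m = _matrix([[0] * 10, [0, 1] * 5])
        kept, report = qc_markers(m)
        assert kept.n_markers == 1
        assert report["status"].tolist()[0] == "maf"

    def test_planted_failures_fixture(self):
        """100 markers, 7 planted failures: exactly 93 survive."""
        rng = np.random.default_rng(0)
        genos = rng.integers(0, 3, size=(100, 40)).astype(np.int8)
        bad_cr = [3, 17, 42, 55]
        bad_maf = [8, 61, 90]
        for i in bad_cr:
            genos[i, : 38] = -1
        for i in bad_maf:
            genos[i, :] = 2
        kept, report = qc_markers(_matrix(genos.tolist()))
        assert kept.n_markers == 93
        assert (report["status"] != "kept").sum() == 7


class TestTwoPointLod:
    def test_ten_meioses_no_recombinants(self):
        ped, genos = phase_known_pedigree(0)
        dm = DiseaseModel("dominant", q=1e-8)
        lod, mx, th = two_point_lod(ped, genos, dm)
        assert th == 0.0
        assert mx == pytest.approx(10 * np.log10(2), abs=1e-6)

    def test_one_recombinant_closed_form(self):
        ped, genos = phase_known_pedigree(1)
        dm = DiseaseModel("dominant", q=1e-8)
        lod, _, _ = two_point_lod(ped, genos, dm)
        expected = np.log10(0.1 * 0.9**9 / 0.5**10)
        assert lod[10] == pytest.approx(expected, abs=1e-6)

    def test_theta_half_lod_zero(self):
        ped, genos = phase_known_pedigree(2)
        dm = DiseaseModel("dominant")
        lod, _, _ = two_point_lod(ped, genos, dm)
        assert lod[-1] == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabel_invariance(self):
        ped, genos = phase_known_pedigree(1)
        dm = DiseaseModel("dominant", q=1e-4)
        lod1, _, _ = two_point_lod(ped, genos, dm, marker_alt_freq=0.3)
        flipped = {k: 2 - v for k, v in genos.items()}
        lod2, _, _ = two_point_lod(ped, flipped, dm, marker_alt_freq=0.7)
        assert np.allclose(lod1, lod2, atol=1e-10)

    @staticmethod
    def _random_pedigree(rng):
        """Random 4-6 member nuclear or backcross-looped pedigree."""
        kind = rng.integers(3)
        inds = [
            Individual("f", "M", generation="founder",
                       affected=bool(rng.integers(2))),
            Individual("m", "F", generation="founder",
                       affected=bool(rng.integers(2))),
        ]
        if kind < 2:  # nuclear with 2-4 children
            for k in range(int(rng.integers(2, 5))):
                inds.append(Individual(f"c{k}", "M", "f", "m", "G1",
                                       affected=bool(rng.integers(2))))
        else:  # sire-daughter backcross loop
            inds.append(Individual("d", "F", "f", "m", "G2",
                                   affected=bool(rng.integers(2))))
            for k in range(2):
                inds.append(Individual(f"x{k}", "M", "f", "d", "G3",
                                       affected=bool(rng.integers(2))))
        return Pedigree(inds[: min(len(inds), 6)])

    def test_matches_enumeration_oracle(self):
        """Exact equality with full-joint enumeration over all two-locus
        genotype configurations on random small pedigrees (loop included)."""
        rng = np.random.default_rng(7)
        thetas = np.array([0.0, 0.05, 0.2, 0.35, 0.5])
        n_checked = 0
        for _ in range(30):
            ped = self._random_pedigree(rng)
            genos = {i.id: int(rng.integers(-1, 3)) for i in ped}
            dm = DiseaseModel(
                "dominant" if rng.integers(2) else "recessive",
                penetrances=tuple(sorted(rng.random(3))),
                q=10.0 ** -rng.integers(1, 5),
            )
            freq = float(rng.uniform(0.1, 0.9))
            gvec = {k: np.array([v]) for k, v in genos.items() if v >= 0}
            L = _Peeler(ped, gvec, np.array([freq]), dm, thetas).likelihood()[0]
            Lo = pedigree_likelihood_oracle(ped, genos, freq, dm, thetas)
            assert np.allclose(L, Lo, rtol=1e-10, atol=1e-300)
            n_checked += 1
        assert n_checked == 30

    def test_rejects_non_backcross_loop(self):
        # full-sib mating: both parents of the loop child are non-founder sibs
        inds = [
            Individual("f", "M", generation="founder"),
            Individual("m", "F", generation="founder"),
            Individual("s1", "M", "f", "m", "G1"),
            Individual("s2", "F", "f", "m", "G1"),
            Individual("x", "M", "s1", "s2", "G2"),
        ]
        ped = Pedigree(inds)
        with pytest.raises(UnsupportedPedigreeError):
            two_point_lod(ped, {}, DiseaseModel("dominant"))


class TestRegions:
    def _profile(self, lods, positions=None, chrom="chr1"):
        n = len(lods)
        positions = positions or list(range(1_000_000, 1_000_000 * (n + 1), 1_000_000))
        return LODProfile(
            pd.DataFrame({"chrom": [chrom] * n, "pos": positions,
                          "lod": lods, "theta_hat": [0.0] * n}),
            DEFAULT_THETA_GRID,
        )

    def test_single_marker_region_spans_flanks(self):
        prof = self._profile([0.1, 4.0, 0.2])
        (r,) = extract_regions(prof)
        assert (r.start, r.end) == (1_000_000, 3_000_000)
        assert r.peak_marker_pos == 2_000_000

    def test_gap_merging(self):
        prof = self._profile([4.0, 1.0, 1.0, 4.0, 0.0])
        regions = extract_regions(prof, merge_gap_markers=2)
        assert len(regions) == 1
        regions = extract_regions(prof, merge_gap_markers=1)
        assert len(regions) == 2

    def test_threshold_above_max_empty(self):
        prof = self._profile([1.0, 2.0])
        assert extract_regions(prof, threshold=3.0) == []


class TestAssociation:
    def test_equal_frequencies_zero(self):
        chi2, df, p = allelic_association([1, 1, 0, 2], [1, 1, 0, 2])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation(self):
        """Cases carry 40 alt / 0 ref alleles, controls the reverse."""
        chi2, df, p = allelic_association([2] * 20, [0] * 20)
        assert chi2 == pytest.approx(80.0)
        assert p < 1e-6

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            allelic_association([], [1])


class TestScanIntegration:
    def test_planted_locus_recovered(self, dominant_screen):
        from enuscreen.simulate import emulate_snp_array

        screen, causative = dominant_screen
        fam = [i.id for i in screen.pedigree
               if i.generation in ("G1", "G2", "G3") or i.id.startswith("SOW-")]
        ped = screen.pedigree.subset(fam)
        matrix = emulate_snp_array(screen, individuals=fam, seed=2)
        res = LinkageModel(ped, matrix, DiseaseModel("dominant")).fit()
        regions = res.regions(3.0)
        assert regions, "no linkage region found"
        hit = [r for r in regions
               if r.chromosome == causative.chromosome
               and r.start <= causative.position <= r.end]
        assert hit, "no region contains the planted locus"
        assert all(r.chromosome == causative.chromosome for r in regions)
        assert "max LOD" in res.summary()
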