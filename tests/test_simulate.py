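import numpy as np
import pytest

from enuscreen.genome import GenomeModel, Variant
from enuscreen.simulate import (
    BreedingStructureError,
    LociIndex,
    PhenotypeModel,
    SimConfig,
    assign_phenotypes,
    breed_screen,
    emulate_rad,
    emulate_snp_array,
    emulate_wgs_calls,
    mutate_gamete,
    recombination_fraction,
    simulate_meiosis,
)
from enuscreen.spectrum import classify_substitution


class TestMutateGamete:
    def test_zero_rate_empty(self, bare_genome):
        assert mutate_gamete(bare_genome, 0.0, seed=1) == []

    def test_rate_bounds(self, bare_genome):
        with pytest.raises(ValueError):
            mutate_gamete(bare_genome, 0.01, seed=1)

    def test_binomial_mean_count(self):
        """Toy genome 1e7 bp at the high-dose rate: mean count ~= 58.6."""
        genome = GenomeModel([("chr1", 10_000_000)])
        counts = [len(mutate_gamete(genome, 5.86e-6, seed=s)) for s in range(200)]
        se = np.sqrt(58.6 / 200)  # Poisson-scale SE of the mean
        assert abs(np.mean(counts) - 58.6) < 3 * se

    def test_positions_unique_and_in_range(self, bare_genome):
        muts = mutate_gamete(bare_genome, 1e-4, seed=2)
        keys = {(m.chromosome, m.position) for m in muts}
        assert len(keys) == len(muts)
        for m in muts:
            assert 1 <= m.position <= bare_genome.lengths[m.chromosome]

    def test_transition_fraction_calibration(self):
        """>=50k spectrum draws land within binomial 3 SE of the configured
        71.2% transition mass."""
        genome = GenomeModel([("chr1", 100_000_000)])
        muts = mutate_gamete(genome, 5.5e-4, seed=7)
        assert len(muts) > 50_000
        ts = np.mean([classify_substitution(m.ref, m.alt)[1] for m in muts])
        se = np.sqrt(0.712 * 0.288 / len(muts))
        assert abs(ts - 0.712) < 3 * se

    def test_sequence_aware_ref_matches_genome(self, gene_genome):
        genome, _ = gene_genome
        rng = np.random.default_rng(3)
        for _ in range(5):
            muts = mutate_gamete(genome, 1e-4, seed=rng)
            for m in muts:
                known = genome.base(m.chromosome, m.position)
                if known is not None:
                    assert m.ref == known


class TestMeiosis:
    @staticmethod
    def _loci_two(genome, distance_bp):
        loci = LociIndex(genome)
        loci.add([0, 0], [1, 1 + distance_bp], ["A", "A"], ["G", "G"],
                 ["poly", "poly"], [0.5, 0.5])
        loci.finalize()
        return loci

    def test_zero_distance_cotransmitted(self, bare_genome):
        loci = self._loci_two(bare_genome, 1)
        dip = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = simulate_meiosis(dip, loci, bare_genome, rng)
            assert g[0] == g[1]  # 1 bp apart: theta ~ 1e-8

    def test_haldane_recombinant_fraction(self, bare_genome):
        """50 Mb at 1 cM/Mb = 0.5 Morgans: theta = (1-e^-1)/2 ~ 0.3161."""
        genome = GenomeModel([("chr1", 60_000_000)], recomb_rate=1.0)
        loci = self._loci_two(genome, 50_000_000)
        dip = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        rng = np.random.default_rng(1)
        n = 10_000
        rec = sum(
            g[0] != g[1] for g in (simulate_meiosis(dip, loci, genome, rng) for _ in range(n))
        )
        theta = 0.5 * (1 - np.exp(-1))
        se = np.sqrt(theta * (1 - theta) / n)
        assert abs(rec / n - theta) < 3 * se

    def test_unlinked_chromosomes_half(self, bare_genome):
        loci = LociIndex(bare_genome)
        loci.add([0, 1], [100, 100], ["A", "A"], ["G", "G"], ["poly", "poly"], [0.5, 0.5])
        loci.finalize()
        dip = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        rng = np.random.default_rng(2)
        n = 10_000
        rec = sum(
            g[0] != g[1] for g in (simulate_meiosis(dip, loci, bare_genome, rng) for _ in range(n))
        )
        assert abs(rec / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_recombination_fraction_closed_form(self):
        assert recombination_fraction(np.array([50_000_000]), 1.0)[0] == pytest.approx(
            0.5 * (1 - np.exp(-1))
        )
        assert recombination_fraction(np.array([0]), 1.0)[0] == 0.0


class TestBreedScreen:
    def test_structural_counts(self, bare_genome):
        cfg = SimConfig(
            genome=bare_genome, dose=65, n_g1=1, dams_per_g1=4,
            g2_dams_backcrossed=4, litter_size=8, array_marker_count=0,
            background_poly_rate=0.0, seed=5,
        )
        screen = breed_screen(cfg)
        ped = screen.pedigree
        assert len(ped.by_generation("G0")) == 2
        assert len(ped.by_generation("G1")) == 1
        assert len(ped.by_generation("G2")) >= 32
        assert len(ped.by_generation("G3")) == 32
        # every G3 is sired by the G1 boar on a G2 dam (the backcross)
        for ind in ped.by_generation("G3"):
            assert ind.sire_id == "G1-1"
            assert ped[ind.dam_id].generation == "G2"

    def test_insufficient_g2_females_raises(self, bare_genome):
        cfg = SimConfig(
            genome=bare_genome, dose=65, dams_per_g1=1, g2_dams_backcrossed=6,
            litter_size=1, max_extra_litters=1, array_marker_count=0,
            background_poly_rate=0.0, seed=5,
        )
        with pytest.raises(BreedingStructureError):
            breed_screen(cfg)

    def test_enu_sets_disjoint_across_g1(self, trio_family):
        by_g1 = trio_family.truth.groupby("g1_id")
        seen = {}
        for gid, grp in by_g1:
            for key in zip(grp["chrom"], grp["pos"]):
                assert key not in seen, "two G1 siblings share a planted mutation"
                seen[key] = gid

    def test_planted_variants_heterozygous_in_carrier_only(self, trio_family):
        loci = trio_family.loci
        for row in trio_family.truth.itertuples():
            idx = loci.locate(row.chrom, row.pos)
            for g1 in trio_family.pedigree.by_generation("G1"):
                expected = 1 if g1.id == row.g1_id else 0
                assert trio_family.genotype(g1.id, idx) == expected

    def test_determinism(self, bare_genome):
        cfg = dict(
            genome=bare_genome, dose=85, n_g1=2, dams_per_g1=2,
            g2_dams_backcrossed=2, litter_size=4, array_marker_count=50,
            background_poly_rate=1e-4, seed=9,
        )
        s1 = breed_screen(SimConfig(**cfg))
        s2 = breed_screen(SimConfig(**cfg))
        assert s1.truth.equals(s2.truth)
        assert s1.pedigree.ids == s2.pedigree.ids
        for ind in s1.pedigree.ids:
            assert np.array_equal(s1.diplotypes[ind], s2.diplotypes[ind])


class TestPhenotypes:
    @staticmethod
    def _toy_cross(bare_genome, n_offspring, parent_genotypes):
        """het x het single-locus cross without the full breeding machinery."""
        from enuscreen.genome import Individual, Pedigree
        from enuscreen.simulate import ScreenResult
        import pandas as pd

        loci = LociIndex(bare_genome)
        loci.add([0], [1000], ["A"], ["G"], ["phenotype"], [0.0])
        loci.finalize()
        rng = np.random.default_rng(11)
        inds = [
            Individual("f", "M", generation="founder"),
            Individual("m", "F", generation="founder"),
        ]
        dip = {
            "f": np.array([[parent_genotypes[0] >= 1], [parent_genotypes[0] == 2]], np.uint8),
            "m": np.array([[parent_genotypes[1] >= 1], [parent_genotypes[1] == 2]], np.uint8),
        }
        for k in range(n_offspring):
            cid = f"c{k}"
            inds.append(Individual(cid, "M", "f", "m", "G2"))
            pat = dip["f"][rng.integers(2), 0]
            mat = dip["m"][rng.integers(2), 0]
            dip[cid] = np.array([[pat], [mat]], np.uint8)
        ped = Pedigree(inds)
        cfg = SimConfig(genome=bare_genome, array_marker_count=0, background_poly_rate=0.0)
        truth = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "g1_id",
                                      "is_phenotype_locus"])
        return ScreenResult(ped, loci, dip, truth, cfg)

    def test_zero_penetrance_nobody_affected(self, bare_genome):
        screen = self._toy_cross(bare_genome, 100, (1, 1))
        model = PhenotypeModel(Variant("chr1", 1000, "A", "G"), "recessive", 0.0)
        out = assign_phenotypes(screen, model, seed=1)
        assert not any(i.affected for i in out.pedigree)

    def test_recessive_het_cross_quarter(self, bare_genome):
        screen = self._toy_cross(bare_genome, 4000, (1, 1))
        model = PhenotypeModel(Variant("chr1", 1000, "A", "G"), "recessive", 1.0)
        out = assign_phenotypes(screen, model, seed=2)
        frac = np.mean([i.affected for i in out.pedigree.by_generation("G2")])
        se = np.sqrt(0.25 * 0.75 / 4000)
        assert abs(frac - 0.25) < 3 * se

    def test_dominant_het_by_wildtype_half(self, bare_genome):
        screen = self._toy_cross(bare_genome, 4000, (1, 0))
        model = PhenotypeModel(Variant("chr1", 1000, "A", "G"), "dominant", 1.0)
        out = assign_phenotypes(screen, model, seed=3)
        frac = np.mean([i.affected for i in out.pedigree.by_generation("G2")])
        se = np.sqrt(0.25 / 4000)
        assert abs(frac - 0.5) < 3 * se


class TestEmulateRad:
    def test_zero_fraction_empty(self, trio_family):
        rad = emulate_rad(trio_family, rad_fraction=0.0, seed=1)
        assert rad.n_sites == 0

    def test_homref_error_rate(self, trio_family):
        rad = emulate_rad(
            trio_family, individuals=["G0-BOAR"], rad_fraction=0.005,
            mean_depth=20, seq_error=0.01, seed=4,
        )
        # background sites are hom-ref: mean alt reads = depth x epsilon = 0.2
        ref, alt = rad.counts["G0-BOAR"]
        loci_keys = set(zip(trio_family.loci.chrom, trio_family.loci.pos))
        mask = np.array(
            [(c, p) not in loci_keys for c, p in zip(rad.chrom, rad.pos)]
        )
        mean_alt = alt[mask].mean()
        se = np.sqrt(0.2 / mask.sum())
        assert abs(mean_alt - 0.2) < 4 * se

    def test_het_site_binomial_half(self, trio_family):
        """Alt-read fraction across the carrier's het sites averages 1/2
        (Binomial(depth, 1/2) per site)."""
        rad = emulate_rad(
            trio_family, individuals=["G1-1"], rad_fraction=1.0,
            mean_depth=30, seq_error=0.01, seed=6,
        )
        truth = trio_family.truth[trio_family.truth["g1_id"] == "G1-1"]
        code = {c: i for i, c in enumerate(trio_family.loci.chrom_names)}
        keys = rad.chrom.astype(np.int64) * (2**40) + rad.pos
        tk = np.array([code[c] * (2**40) + p
                       for c, p in zip(truth["chrom"], truth["pos"])])
        j = np.searchsorted(keys, tk)
        r, a = rad.counts["G1-1"]
        depth = (r[j] + a[j]).astype(float)
        frac = a[j][depth > 0] / depth[depth > 0]
        n = len(frac)
        assert n > 50
        assert abs(frac.mean() - 0.5) < 3 * 0.5 / np.sqrt(30 * n) + 0.02

    def test_shared_site_set(self, trio_family):
        rad = emulate_rad(trio_family, individuals=["G0-BOAR", "G1-1"],
                          rad_fraction=0.01, seed=5)
        assert rad.counts["G0-BOAR"][0].shape == rad.counts["G1-1"][0].shape


@pytest.fixture(scope="module")
def marker_screen(bare_genome):
    cfg = SimConfig(
        genome=bare_genome, dose=65, n_g1=1, dams_per_g1=2,
        g2_dams_backcrossed=2, litter_size=4, array_marker_count=100,
        background_poly_rate=1e-4, seed=21,
    )
    return breed_screen(cfg)


class TestArrayAndWgs:
    def test_full_missingness(self, marker_screen):
        m = emulate_snp_array(marker_screen, missing_rate=1.0, seed=1)
        assert (m.genotypes == -1).all()

    def test_no_missingness_full_call_rate(self, marker_screen):
        m = emulate_snp_array(marker_screen, missing_rate=0.0, seed=1)
        assert (m.call_rates() == 1.0).all()

    def test_marker_spacing(self, marker_screen):
        m = emulate_snp_array(marker_screen, missing_rate=0.0, seed=1)
        chr1 = m.markers[m.markers["chrom"] == "chr1"]["pos"].to_numpy()
        spacing = np.diff(chr1)
        assert np.allclose(spacing, spacing[0], atol=1)

    def test_wgs_known_list_never_contains_planted(self, marker_screen):
        calls, known = emulate_wgs_calls(marker_screen, ["G1-1"])
        planted = set(zip(marker_screen.truth["chrom"], marker_screen.truth["pos"]))
        for v in known:
            assert (v.chromosome, v.position) not in planted

    def test_wgs_zero_background_only_enu(self, bare_genome):
        cfg = SimConfig(
            genome=bare_genome, dose=85, n_g1=1, dams_per_g1=0,
            g2_dams_backcrossed=0, litter_size=0, array_marker_count=0,
            background_poly_rate=0.0, seed=13,
        )
        screen = breed_screen(cfg)
        calls, known = emulate_wgs_calls(screen, ["G1-1"])
        assert known == []
        planted = set(zip(screen.truth["chrom"], screen.truth["pos"]))
        got = set(zip(calls["G1-1"]["chrom"], calls["G1-1"]["pos"]))
        assert got == planted
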