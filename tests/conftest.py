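import numpy as np
import pytest

from enuscreen.genome import GenomeModel, Individual, Pedigree
from enuscreen.simulate import PhenotypeModel, SimConfig, breed_screen, toy_genome


@pytest.fixture(scope="session")
def gene_genome():
    """Small two-chromosome genome with the crafted R109W gene on chr2."""
    genome, variant = toy_genome(
        n_chromosomes=2, chromosome_length=2_000_000,
        gene_chromosome_index=1, gene_cds_start=1_000_000,
    )
    return genome, variant


@pytest.fixture(scope="session")
def bare_genome():
    return GenomeModel([("chr1", 10_000_000), ("chr2", 10_000_000)])


@pytest.fixture(scope="session")
def trio_family(bare_genome):
    """One mutagenized G0 boar, one sow, five G1 offspring (no breeding)."""
    cfg = SimConfig(
        genome=bare_genome, dose=85, n_g1=5, dams_per_g1=0,
        g2_dams_backcrossed=0, litter_size=0, array_marker_count=0,
        background_poly_rate=1e-3, seed=3,
    )
    return breed_screen(cfg)


@pytest.fixture(scope="session")
def dominant_screen():
    """Full three-generation dominant screen on the 5x20 Mb toy genome."""
    genome, causative = toy_genome()
    cfg = SimConfig(
        genome=genome, dose=85,
        phenotype_model=PhenotypeModel(causative, "dominant", 1.0),
        array_marker_count=500, background_poly_rate=1e-4, seed=1,
    )
    return breed_screen(cfg), causative


def phase_known_pedigree(n_recombinant=0, n_meioses=10):
    """Fully informative dominant pedigree with known phase: an affected
    grandfather homozygous for the marker alt allele fixes the phase of his
    affected, doubly heterozygous son, whose meioses carry all the linkage
    information."""
    inds = [
        Individual("GP", "M", generation="founder", affected=True),
        Individual("GM", "F", generation="founder", affected=False),
        Individual("S", "M", "GP", "GM", "G1", affected=True),
        Individual("W", "F", generation="founder", affected=False),
    ]
    genotypes = {"GP": 2, "GM": 0, "S": 1, "W": 0}
    for k in range(n_meioses):
        affected = k < n_meioses // 2
        recombinant = k < n_recombinant
        g = (1 if affected else 0) if not recombinant else (0 if affected else 1)
        inds.append(Individual(f"C{k}", "M", "S", "W", "G2", affected=affected))
        genotypes[f"C{k}"] = g
    return Pedigree(inds), genotypes
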