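"""Shared fixtures and independent oracles for the test suite."""
import numpy as np
import pytest

from mitopop.simulate import SimConfig, simulate_population_set

#: the published yeast mitochondrial genetic code (NCBI table 3), frozen
#: as a literal so translation is checked against the standard itself
TABLE3 = {
    "AAA": "K", "AAC": "N", "AAG": "K", "AAT": "N", "ACA": "T", "ACC": "T", "ACG": "T", "ACT": "T",
    "AGA": "R", "AGC": "S", "AGG": "R", "AGT": "S", "ATA": "M", "ATC": "I", "ATG": "M", "ATT": "I",
    "CAA": "Q", "CAC": "H", "CAG": "Q", "CAT": "H", "CCA": "P", "CCC": "P", "CCG": "P", "CCT": "P",
    "CGA": "R", "CGC": "R", "CGG": "R", "CGT": "R", "CTA": "T", "CTC": "T", "CTG": "T", "CTT": "T",
    "GAA": "E", "GAC": "D", "GAG": "E", "GAT": "D", "GCA": "A", "GCC": "A", "GCG": "A", "GCT": "A",
    "GGA": "G", "GGC": "G", "GGG": "G", "GGT": "G", "GTA": "V", "GTC": "V", "GTG": "V", "GTT": "V",
    "TAA": "*", "TAC": "Y", "TAG": "*", "TAT": "Y", "TCA": "S", "TCC": "S", "TCG": "S", "TCT": "S",
    "TGA": "W", "TGC": "C", "TGG": "W", "TGT": "C", "TTA": "L", "TTC": "F", "TTG": "L", "TTT": "F",
}


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.2) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(list("ATCG"), size=n, p=p))


@pytest.fixture(scope="session")
def small_sim():
    """4 populations x 2 strains, 45 kb genomes, default profiles."""
    cfg = SimConfig(n_strains_per_population=2, genome_length_target=45_000,
                    rng_seed=11)
    genomes, truth = simulate_population_set(cfg)
    return cfg, genomes, truth
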