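"""Shared fixtures: small synthetic genomes and populations.

Everything is generated programmatically with fixed seeds; the default
fixture genome (2 chromosomes x 100 cM x 10 Mb, 5000 markers each) keeps
each analysis step in the seconds range.
"""

import numpy as np
import pytest

from mpqtl import binning
from mpqtl import synthetic_population as sp


@pytest.fixture(scope="session")
def small_map():
    """Tiny 2-chromosome map for fast unit tests."""
    return sp.make_uniform_map(n_chrom=2, length_cm=60, length_bp=3_000_000,
                               n_markers=600)


@pytest.fixture(scope="session")
def default_map():
    """The default fixture genome."""
    return sp.make_uniform_map()


@pytest.fixture(scope="session")
def founders8(small_map):
    return sp.simulate_founders(8, small_map, divergence=0.5, seed=101)


@pytest.fixture(scope="session")
def founders24(default_map):
    return sp.simulate_founders(24, default_map, divergence=0.5, seed=102)


@pytest.fixture(scope="session")
def pseudo_pop(founders8, small_map):
    """Pseudoprogeny population: (truth mosaic, genotypes)."""
    return sp.simulate_pseudoprogeny(founders8, small_map, n_lines=40,
                                     n_segments=12, seed=103)


@pytest.fixture(scope="session")
def pedigree_pop():
    """Pedigree-simulated population on a single chromosome.

    200 lines, 24 founders, 8 inter-cross + 6 selfing generations; shared by
    the GWAS, binning and refinement tests.
    """
    gmap = sp.make_uniform_map(n_chrom=1, length_cm=60, length_bp=6_000_000,
                               n_markers=1500)
    founders = sp.simulate_founders(24, gmap, divergence=0.5, seed=21)
    truth, geno = sp.simulate_pedigree_population(
        founders, gmap, n_lines=200, n_intercross_gens=8, n_selfing_gens=6,
        seed=22)
    return gmap, founders, truth, geno


@pytest.fixture(scope="session")
def pedigree_bins(pedigree_pop):
    _, _, truth, _ = pedigree_pop
    return binning.build_bins(truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
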