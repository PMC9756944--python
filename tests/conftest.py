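import numpy as np
import pandas as pd
import pytest

from hyphachrom import simulate as S


@pytest.fixture(scope="session")
def spt_small():
    """Small lossless PALM simulation with both states populated."""
    cfg = S.SPTSimConfig(n_molecules=40, n_frames=60, p_bleach=0.0, p_blink=0.0,
                         switch_prob=0.05, seed=7)
    locs, truth = S.simulate_spt(cfg)
    return cfg, locs, truth


@pytest.fixture(scope="session")
def hypha_noisy():
    """Time-lapse with duplications and moderate noise."""
    # one duplication per hypha, far enough from the series end that the
    # post-split separation window is uncontaminated by later splits
    cfg = S.HyphaSimConfig(n_hyphae=15, n_frames=16, duplication_interval=8,
                           noise_sigma=5.0, seed=7)
    return cfg, *S.simulate_hyphae(cfg)


@pytest.fixture(scope="session")
def chip_enriched():
    """Two-condition fragment dataset with 8-fold enriched sites."""
    cfg = S.ChIPSimConfig(genome_length=60000, n_sites=10, library_sizes=25000,
                          enrichment_fold=8.0, dispersion=0.1, seed=11)
    frags, genome, truth = S.simulate_chip(cfg)
    return cfg, frags, genome, truth
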