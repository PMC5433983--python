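import numpy as np
import pytest

from dacemhc import fileio, pipeline, synthgen


@pytest.fixture(scope="session")
def published_counts():
    """The published site x allele copy-count table (six sites, 8 alleles)."""
    return fileio.bundled_counts_table()


@pytest.fixture(scope="session")
def catalog8():
    """Deterministic 8-allele synthetic catalog (236 bp, 16 segregating sites)."""
    return synthgen.gen_allele_pool(8, 207, 29, 16, seed=1)


@pytest.fixture(scope="session")
def small_noisy_run():
    """A small simulated + genotyped data set shared across tests
    (3 sites x 8 individuals, depth 150, moderate error)."""
    cfg = pipeline.PipelineConfig(seed=11, depth=150, sub_rate=0.003,
                                  hp_indel_rate=0.003,
                                  duplicate_fraction=0.25)
    cfg.sites = cfg.sites[:3]
    for s in cfg.sites:
        s.n_individuals = 8
    sim = pipeline.simulate(cfg)
    site_of = {t.individual_id: t.site_code for t in sim.truths}
    called, table = pipeline.genotype_readsets(sim.readsets, cfg, site_of)
    return cfg, sim, called, table
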