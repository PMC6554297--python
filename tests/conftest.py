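import numpy as np
import pytest

import bsascan as b


@pytest.fixture(scope="session")
def small_map():
    """One 10-Mb chromosome with SNPs every 100 kb."""
    return b.build_genome_map({"chr1": 10_000_000}, snp_spacing=100_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def qtl_sim():
    """A strong single-QTL experiment at study scale (n=178, bulks of 20)."""
    gm = b.build_genome_map({"chr6": 31_248_787}, snp_spacing=100_000)
    cfg = b.F2SimConfig(
        map=gm,
        qtls=(b.QTLSpec("chr6", 6_700_000, additive_effect=1.0),),
        n_individuals=178,
        heritability=0.8,
        bulk_size=20,
        depth_model=b.DepthModel("poisson", 22.0),
        sequencing_error=0.001,
        seed=7,
    )
    return b.simulate_experiment(cfg)
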