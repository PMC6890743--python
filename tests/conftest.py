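import numpy as np
import pytest

from lncmir.synthetic import (
    SimulationConfig,
    simulate_expression_matrix,
    simulate_transcriptome,
    write_fixture_bundle,
)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small full fixture shared by read-only tests."""
    cfg = SimulationConfig(
        seed=21, n_coding=6, n_lncrna=8, n_decoy=5, n_hairpins=3,
        n_etm_sites=3, noise_sd=0.0, n_de=3, n_corr_pairs=3,
    )
    return simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    expr = simulate_expression_matrix(small_sim)
    manifest = write_fixture_bundle(small_sim, expr, d)
    return d, small_sim, expr, manifest
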