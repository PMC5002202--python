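"""Shared fixtures: synthetic datasets are generated once per session."""

import numpy as np
import pytest

from exomesieve.simulate import SimulationConfig, simulate


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A compact study: 6 families, 12 genes, a few hundred sites."""
    kw = dict(
        n_genes=12,
        exons_per_gene=3,
        n_variants=400,
        n_noncoding=250,
        n_sv_events=80,
        n_known_positions=20,
        depth_flank=200,
    )
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def ds_small():
    return simulate(small_config())


@pytest.fixture(scope="session")
def cohort_small(ds_small):
    return ds_small.cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160827)
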