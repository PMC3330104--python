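import numpy as np
import pytest

import popeqtl as pq


def two_pop_specs(n=40, f=0.01):
    return (
        pq.PopulationSpec("POPA", n, f, ancestry="EUR"),
        pq.PopulationSpec("POPB", n, f, ancestry="AFR"),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete 3-population study with planted effects."""
    cfg = pq.StudyConfig(
        pops=(
            pq.PopulationSpec("CEU", 40, 0.005, ancestry="EUR"),
            pq.PopulationSpec("YRI", 40, 0.005, ancestry="AFR"),
            pq.PopulationSpec("MEX", 30, 0.005, admixture_props={"EUR": 0.6, "AFR": 0.4}),
        ),
        n_snps=800,
        n_probes=40,
        missing_rate=0.01,
        truth=pq.TruthConfig(n_eqtls=8, beta_min=0.8, n_hidden_factors=2),
    )
    return pq.simulate_study(cfg, seed=1234)


@pytest.fixture(scope="session")
def normalized_study(small_study):
    return pq.normalize(small_study.expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
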