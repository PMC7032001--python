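import numpy as np
import pandas as pd
import pytest

from lncnet.expression import compute_fpkm
from lncnet.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully-featured study: one module, modest transcriptome."""
    return SimulationConfig(
        n_mrna=400, n_lncrna=80, n_modules=1, module_size=(5, 20), seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_fpkm(small_study):
    b = small_study
    return compute_fpkm(
        b.counts, b.feature_lengths, b.design.set_index("sample_id")["library_size"]
    )


@pytest.fixture(scope="session")
def default_study():
    """The generator at its default study conditions."""
    return generate_study(SimulationConfig(seed=3))


@pytest.fixture
def toy_design():
    rows = []
    for geno in ("tolerant", "sensitive"):
        for trt in ("DS", "RW"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{trt}_{geno}_{rep}",
                        "genotype": geno,
                        "treatment": trt,
                        "replicate": rep,
                        "library_size": 1_000_000,
                    }
                )
    return pd.DataFrame(rows)


def nb_counts(rng, mu, phi, size=None):
    """Reference NB draw with Var = mu + phi mu^2."""
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.asarray(mu, float)), size=size)
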