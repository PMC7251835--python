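import numpy as np
import pandas as pd
import pytest

import seqgp


@pytest.fixture(scope="session")
def tiny_config():
    """Small but non-trivial study used by several module tests."""
    return seqgp.SimConfig(
        n_discovery={"Brahman": 150, "TropicalComposite": 150},
        n_prediction={"Brahman": 80, "SantaGertrudis": 80, "Droughtmaster": 80},
        n_variants_wgs=1500,
        panel_sizes={"6K": 150, "50K": 400, "800K": 800},
        n_chromosomes=5,
        n_qtl=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return seqgp.simulate_study(tiny_config)


@pytest.fixture
def random_genotypes():
    """5×10 integer-dosage GenotypeSet for round-trip tests."""
    rng = np.random.default_rng(0)
    from seqgp.iofmt import make_variant_table

    m = 10
    variants = make_variant_table(
        [f"v{i}" for i in range(m)], ["1"] * m, np.arange(1, m + 1) * 100,
        ["A"] * m, ["B"] * m,
    )
    dosages = rng.integers(0, 3, size=(5, m)).astype(float)
    return seqgp.GenotypeSet(
        [f"ind{i}" for i in range(5)], ["breed1"] * 5, dosages, variants
    )


def make_ma(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "SNP": [f"v{i}" for i in range(n)],
            "A1": ["A"] * n,
            "A2": ["B"] * n,
            "freq": rng.uniform(0.05, 0.95, n),
            "b": rng.normal(0, 1, n),
            "se": rng.uniform(0.1, 1.0, n),
            "p": rng.uniform(1e-8, 1, n),
            "N": 868,
        }
    )
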