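import numpy as np
import pandas as pd
import pytest

from pgcmasc.io import CountMatrix
from pgcmasc.simulate import SimConfig, gen_pgc_counts


def make_cm(counts: np.ndarray, sexes=None, doses=None, generations=None) -> CountMatrix:
    """Build a CountMatrix around a raw array with minimal metadata."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "generation": generations if generations is not None else ["F1"] * n,
            "sex": sexes if sexes is not None else ["M"] * n,
            "dose": doses if doses is not None else [0.0] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    df = pd.DataFrame(counts, index=[f"g{i:04d}" for i in range(counts.shape[0])], columns=samples)
    return CountMatrix(df, meta)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset with a strong masculinization effect."""
    cfg = SimConfig(
        n_genes=2000,
        universe_target=800,
        n_male_specific=80,
        n_female_specific=80,
        masc_effect=1.5,
        seed=101,
    )
    cm, truth = gen_pgc_counts(cfg)
    return cfg, cm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
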