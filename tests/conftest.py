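import numpy as np
import pandas as pd
import pytest

from coldregulon.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest planted dataset shared by read-only tests."""
    cfg = SynthConfig(n_genes=120, regulon_size=20, de_fraction=0.4, seed=20240901)
    return cfg, generate_dataset(cfg)


@pytest.fixture
def two_group_samples():
    idx = [f"A_{t}h_r{r}" for t in (0, 24) for r in (1, 2, 3)]
    return pd.DataFrame(
        [("A", t, r) for t in (0, 24) for r in (1, 2, 3)],
        index=idx,
        columns=["genotype", "timepoint_hr", "replicate"],
    )


def random_promoter(rng: np.random.Generator, length: int = 600):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
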