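import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A 100-gene synthetic study shared by the slower integration tests."""
    from cageprom.simulate import SyntheticConfig, generate_study

    cfg = SyntheticConfig(seed=7, n_genes=100)
    return generate_study(cfg)


@pytest.fixture
def simple_design():
    """10 subjects x 4 time points sample sheet."""
    rows = {}
    for i in range(10):
        for t in ("pre", "1h", "3h", "6h"):
            rows[f"S{i:02d}_{t}"] = dict(subject=f"S{i:02d}", time=t)
    return pd.DataFrame.from_dict(rows, orient="index")


def random_tag_table(rng, n_tags=100, span=2000, n_samples=3):
    positions = rng.integers(0, span, size=n_tags)
    strands = rng.choice(["+", "-"], size=n_tags)
    chroms = rng.choice(["chr1", "chr2"], size=n_tags)
    counts = rng.integers(0, 20, size=(n_tags, n_samples))
    df = pd.DataFrame(counts, columns=[f"s{j}" for j in range(n_samples)])
    df.insert(0, "chrom", chroms)
    df.insert(1, "pos", positions)
    df.insert(2, "strand", strands)
    return df[df[[f"s{j}" for j in range(n_samples)]].sum(axis=1) > 0].reset_index(
        drop=True
    )
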