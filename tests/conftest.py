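import numpy as np
import pandas as pd
import pytest

from cicerscan.core_io import GenotypeMatrix


def make_gm(
    dosages,
    positions=None,
    chrom="Ca1",
    populations=None,
    groups=None,
    market_types=None,
    sample_ids=None,
):
    """Build a GenotypeMatrix from a (samples x variants) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_s, n_v = dosages.shape
    if positions is None:
        positions = np.arange(1, n_v + 1) * 10
    if isinstance(chrom, str):
        chroms = [chrom] * n_v
    else:
        chroms = list(chrom)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ["A"] * n_v, "alt": ["T"] * n_v}
    )
    samples = pd.DataFrame(
        {
            "id": sample_ids or [f"s{i}" for i in range(n_s)],
            "population": populations or ["pop0"] * n_s,
            "group": groups or ["landrace"] * n_s,
            "market_type": market_types or ["NA"] * n_s,
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gm(rng):
    """60 samples x 40 variants, two populations, some missing calls."""
    p = rng.uniform(0.1, 0.9, 40)
    d = rng.binomial(2, p, size=(60, 40)).astype(np.int8)
    miss = rng.random(d.shape) < 0.05
    d[miss] = -1
    return make_gm(
        d,
        positions=np.sort(rng.choice(100_000, 40, replace=False)) + 1,
        populations=["popA"] * 30 + ["popB"] * 30,
        groups=["wild"] * 30 + ["landrace"] * 30,
    )
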