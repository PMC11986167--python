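import numpy as np
import pytest

import vinespec as vs


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: 3 maturity groups x 35 samples, 424 bands."""
    return vs.make_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A 3 x 10 dataset for fast model-fitting tests."""
    groups = [
        vs.GroupSpec(g.name, 10, An=g.An, TSS=g.TSS, TA=g.TA)
        for g in vs.default_groups()
    ]
    return vs.make_dataset(groups, seed=2)


def make_toy_spectra(n_samples=30, n_bands=12, seed=0, start=500, step=10):
    """Small random SpectraSet for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    wl = np.arange(start, start + step * n_bands, step)
    refl = rng.uniform(0.05, 0.9, size=(n_samples, n_bands))
    return vs.SpectraSet(wl, refl, [f"t{i}" for i in range(n_samples)],
                         ["NA"] * n_samples)


def make_toy_traits(sset, seed=0):
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = sset.n_samples
    df = pd.DataFrame({
        "An": rng.uniform(50, 900, n),
        "TSS": rng.uniform(9, 20, n),
        "TA": rng.uniform(0.4, 1.1, n),
    })
    return vs.TraitTable(sample_ids=list(sset.sample_ids), data=df,
                         groups=list(sset.groups))
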