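import numpy as np
import pandas as pd
import pytest

from seascapegen.containers import BathymetryGrid, GenotypeMatrix, LocationTable


def make_gm(calls, tag_ids=None, prefix="s"):
    calls = np.asarray(calls, dtype=float)
    n, L = calls.shape
    return GenotypeMatrix(
        [f"{prefix}{i}" for i in range(n)],
        [f"L{j}" for j in range(L)],
        calls,
        tag_ids,
    )


def make_loc(gm, labels, lon=None, lat=None, sex=None):
    n = gm.n_samples
    table = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "location_id": list(labels),
            "longitude": lon if lon is not None else [0.0] * n,
            "latitude": lat if lat is not None else [0.0] * n,
        }
    )
    if sex is not None:
        table["sex"] = list(sex)
    return LocationTable(table)


def two_deme_gm(rng, n_per=20, n_loci=300, p_a=None, p_b=None, spread=1.0):
    """Two demes with given (or random) allele frequency arrays."""
    if p_a is None:
        p = rng.uniform(0.2, 0.8, n_loci)
        dev = rng.normal(0, 0.08 * spread, n_loci)
        p_a = np.clip(p + dev, 0.01, 0.99)
        p_b = np.clip(p - dev, 0.01, 0.99)
    calls = np.vstack(
        [
            rng.binomial(2, p_a, (n_per, n_loci)),
            rng.binomial(2, p_b, (n_per, n_loci)),
        ]
    ).astype(float)
    gm = make_gm(calls)
    loc = make_loc(
        gm,
        ["A"] * n_per + ["B"] * n_per,
        lon=[0.0] * n_per + [0.5] * n_per,
    )
    return gm, loc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_sea():
    """11 x 11 all-water grid of uniform depth."""
    return BathymetryGrid(np.full((11, 11), -100.0), (0.0, 0.0), 0.01)
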