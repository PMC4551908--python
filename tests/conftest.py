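import numpy as np
import pandas as pd
import pytest

from threeca import PairedMatrix


def make_matrix(early, late, scale="log", meta=True):
    """Small PairedMatrix from (F, P) arrays with auto ids/metadata."""
    early = np.atleast_2d(np.asarray(early, dtype=float))
    late = np.atleast_2d(np.asarray(late, dtype=float))
    nf, npair = early.shape
    features = [f"f{i}" for i in range(nf)]
    pairs = [f"S{i}" for i in range(npair)]
    md = None
    if meta:
        md = pd.DataFrame(
            {"subject": pairs,
             "age_early": 40.0 + np.arange(npair),
             "age_late": 55.0 + np.arange(npair)},
            index=pd.Index(pairs, name="pair_id"))
    return PairedMatrix(feature_ids=features, pair_ids=pairs,
                        early=early, late=late, scale=scale, meta=md)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_matrix(rng):
    """8 features x 4 pairs of positive log-scale values."""
    early = rng.uniform(1.0, 10.0, size=(8, 4))
    late = rng.uniform(1.0, 10.0, size=(8, 4))
    return make_matrix(early, late, scale="log")
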