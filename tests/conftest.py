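import numpy as np
import pandas as pd
import pytest

from kinoprofile.affinity_io import AffinityMatrix


def make_affinity(values, censored=None, targets=None, inhibitors=None, limit=10000.0):
    """Build an AffinityMatrix from a plain nested list / array.

    ``values`` may contain NaN for absent cells; ``censored`` is an optional
    parallel boolean array.
    """
    arr = np.asarray(values, dtype=float)
    t, n = arr.shape
    targets = targets or [f"T{i + 1}" for i in range(t)]
    inhibitors = inhibitors or [f"i{j + 1}" for j in range(n)]
    vals = pd.DataFrame(arr, index=targets, columns=inhibitors)
    if censored is None:
        cens = pd.DataFrame(False, index=targets, columns=inhibitors)
    else:
        cens = pd.DataFrame(np.asarray(censored, dtype=bool), index=targets, columns=inhibitors)
    vals = vals.mask(cens.to_numpy())
    return AffinityMatrix(values=vals, censored=cens, limit_nM=limit)


def random_affinity(rng, t=8, n=12, censor_frac=0.2, absent_frac=0.0, limit=10000.0):
    """Random positive affinity matrix with some censored / absent cells."""
    log_kd = rng.normal(2.5, 1.2, size=(t, n))
    vals = 10.0 ** log_kd
    cens = rng.random((t, n)) < censor_frac
    m = make_affinity(vals, cens, limit=limit)
    if absent_frac:
        absent = (rng.random((t, n)) < absent_frac) & ~cens
        m.values.values[absent] = np.nan
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_matrix():
    # 3 targets x 4 inhibitors, one censored, one absent
    return make_affinity(
        [[3.0, 120.0, 5000.0, np.nan],
         [10.0, 90.0, np.nan, 2000.0],
         [400.0, 80.0, 60.0, 30.0]],
        censored=[[False, False, False, False],
                  [False, False, True, False],
                  [False, False, False, False]],
    )
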