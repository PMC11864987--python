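import itertools

import numpy as np
import pandas as pd
import pytest

from sctransport.container import AnnotatedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def annotated(values, prefix="o", meta=None, reps=None):
    """Build an AnnotatedMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    obs = [f"{prefix}{i}" for i in range(values.shape[0])]
    feats = [f"g{j}" for j in range(values.shape[1])]
    if meta is not None:
        meta = meta.copy()
        meta.index = obs
    return AnnotatedMatrix(values, obs, feats, meta, reps)


def with_coords(values, coords, prefix="o"):
    coords = np.asarray(coords, dtype=float)
    meta = pd.DataFrame(
        {f"spatial_{k}": coords[:, k] for k in range(coords.shape[1])}
    )
    return annotated(values, prefix=prefix, meta=meta)


def lp_transport_cost(C, a, b):
    """Exact OT cost for uniform square marginals by permutation enumeration."""
    C = np.asarray(C)
    n = C.shape[0]
    assert C.shape == (n, n)
    assert np.allclose(a, 1.0 / n, atol=1e-3) and np.allclose(b, 1.0 / n, atol=1e-3)
    best = min(
        sum(C[i, p[i]] for i in range(n))
        for p in itertools.permutations(range(n))
    )
    return best / n


def gw_objective_dense(Cx, Cy, P):
    """Quadruple-loop GW objective; the O(n^4) reference evaluation."""
    n, m = P.shape
    total = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(m):
                for l in range(m):
                    total += (Cx[i, j] - Cy[k, l]) ** 2 * P[i, k] * P[j, l]
    return total
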