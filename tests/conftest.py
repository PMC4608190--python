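import numpy as np
import pandas as pd
import pytest

from hetcube.cube import QIDS_RECODED_ITEMS, DataCube


def random_cube(seed: int, shape=(6, 5, 4)) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal(shape)


def triple_loop_reconstruct(A, B, C, G):
    """Independent literal evaluation of the trilinear model."""
    n, P = A.shape
    m, Q = B.shape
    T, R = C.shape
    out = np.zeros((n, m, T))
    for i in range(n):
        for j in range(m):
            for k in range(T):
                s = 0.0
                for p in range(P):
                    for q in range(Q):
                        for r in range(R):
                            s += A[i, p] * B[j, q] * C[k, r] * G[p, q, r]
                out[i, j, k] = s
    return out


def make_records(values: np.ndarray, items=None) -> pd.DataFrame:
    """Long records from an n x m x T integer array."""
    n, m, T = values.shape
    persons = [f"P{i + 1:03d}" for i in range(n)]
    if items is None:
        items = [f"item_{j + 1}" for j in range(m)]
    rows = [
        {"person_id": persons[i], "time": t + 1, "item": items[j],
         "score": int(values[i, j, t])}
        for i in range(n) for j in range(m) for t in range(T)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def small_ordinal_cube() -> DataCube:
    rng = np.random.default_rng(42)
    values = rng.integers(0, 3, size=(8, 12, 5)).astype(float)
    return DataCube(
        values,
        persons=[f"P{i:02d}" for i in range(8)],
        items=list(QIDS_RECODED_ITEMS),
        times=list(range(1, 6)),
    )
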