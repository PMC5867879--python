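"""Shared fixtures and independent oracle implementations.

The brute-force MRMD ranking here is deliberately naive (explicit Python
loops, no shared code with the package) so it can serve as an independent
cross-check of the vectorized implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest

from sap.featurize import FeatureMatrix
from sap.peptide_io import Peptide, PeptideDataset


@pytest.fixture
def tiny_dataset() -> PeptideDataset:
    return PeptideDataset(
        (
            Peptide("p1", "FLPIL", 1),
            Peptide("p2", "ACACA", 1),
            Peptide("p3", "KKKKW", 0),
            Peptide("p4", "GGSGG", 0),
        )
    )


def make_matrix(X: np.ndarray, y=None, names=None) -> FeatureMatrix:
    n, m = X.shape
    names = list(names) if names is not None else [f"f{i}" for i in range(m)]
    ids = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(X, index=ids, columns=names)
    ys = None if y is None else pd.Series(np.asarray(y, dtype=int), index=ids)
    return FeatureMatrix(X=frame, y=ys)


# ---------------------------------------------------------------------------
# brute-force MRMD oracle


def _brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return 0.0 if den == 0.0 else num / den


def brute_force_ranking(X: np.ndarray, y: np.ndarray):
    """Naive per-pair evaluation of the MRMD scores and the ranking order.

    Returns (order, scores) where order is the list of column indices sorted
    by descending MR+MD with ties broken by higher MR then input order.
    """
    n, m = X.shape
    yenc = [1.0 if v == 1 else -1.0 for v in y]
    mr = [abs(_brute_pearson(list(X[:, i]), yenc)) for i in range(m)]

    def dot(i, k):
        return sum(X[r, i] * X[r, k] for r in range(n))

    md = []
    for i in range(m):
        ed = cos = tc = 0.0
        for k in range(m):
            if k == i:
                continue
            ed += math.sqrt(sum((X[r, i] - X[r, k]) ** 2 for r in range(n)))
            ni = math.sqrt(dot(i, i))
            nk = math.sqrt(dot(k, k))
            if ni > 0 and nk > 0:
                cos += dot(i, k) / (ni * nk)
                den = dot(i, i) + dot(k, k) - dot(i, k)
                if den > 0:
                    tc += dot(i, k) / den
        md.append((ed / (m - 1) + cos / (m - 1) + tc / (m - 1)) / 3.0)

    scores = [mr[i] + md[i] for i in range(m)]
    order = sorted(range(m), key=lambda i: (-scores[i], -mr[i], i))
    return order, scores
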