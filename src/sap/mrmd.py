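"""Maximum relevance-maximum distance (MRMD) feature ranking and pruning.

Each feature column F_i gets a combined score MR_i + MD_i:

* MR_i — relevance: the absolute Pearson correlation between F_i and the
  class-label vector encoded +1/-1.
* MD_i — distance/redundancy term: the mean of three pairwise statistics
  over all other columns F_k (k != i) — mean Euclidean distance ED_i, mean
  cosine value COS_i, and mean Tanimoto coefficient
  TC_i = F_i.F_k / (||F_i||^2 + ||F_k||^2 - F_i.F_k); MD_i = (ED_i + COS_i
  + TC_i) / 3.

By default the cosine and Tanimoto terms enter MD exactly as the similarity
values above ("printed" orientation); an "inverted" orientation replacing
them by 1-cos and 1-TC is available since a distance blend of similarities
is a debatable convention.  Ranking is the static descending sort of the
combined scores with deterministic tie-breaking (higher MR, then input
column order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .featurize import FeatureMatrix

_ORIENTATIONS = ("printed", "inverted")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    A constant vector makes the correlation undefined; it is reported as 0.0
    with a warning so degenerate feature columns rank last rather than crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"pearson needs two equal-length 1-D vectors, got {x.shape} and {y.shape}"
        )
    if x.shape[0] < 2:
        raise ValidationError("pearson needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        warnings.warn(
            "correlation undefined for a constant vector; returning 0.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _require_labels(m: FeatureMatrix) -> np.ndarray:
    if m.y is None:
        raise ValidationError("relevance scores require a labeled matrix")
    y = m.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be represented")
    return np.where(y == 1, 1.0, -1.0)


def relevance_scores(m: FeatureMatrix) -> pd.Series:
    """MR_i = |pearson(feature column i, +1/-1 label encoding)| per feature."""
    yenc = _require_labels(m)
    if m.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    X = m.X.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = yenc - yenc.mean()
    ss_x = (Xc * Xc).sum(axis=0)
    ss_y = yc @ yc
    cov = Xc.T @ yc
    mr = np.zeros(m.n_features)
    nonconst = ss_x > 0
    if not nonconst.all():
        warnings.warn(
            "constant feature column(s) have undefined correlation; MR set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mr[nonconst] = np.abs(cov[nonconst] / np.sqrt(ss_x[nonconst] * ss_y))
    return pd.Series(np.clip(mr, 0.0, 1.0), index=m.X.columns, name="MR")


def distance_components(
    m: FeatureMatrix,
    orientation: str = "printed",
    minmax_scale: bool = False,
) -> pd.DataFrame:
    """Per-feature (ED_i, COS_i, TC_i, MD_i) over all other feature columns.

    Pairs involving a zero-norm column contribute 0 to the cosine and
    Tanimoto means (with a warning), since those similarities are undefined.
    With ``minmax_scale`` the columns are min-max scaled to [0, 1] before any
    distance is computed (the raw columns are the default).
    """
    if orientation not in _ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {_ORIENTATIONS}")
    M = m.n_features
    if M < 2:
        raise ValidationError("distance components need at least 2 features")
    X = m.X.to_numpy(dtype=float)
    if minmax_scale:
        span = X.max(axis=0) - X.min(axis=0)
        span[span == 0] = 1.0
        X = (X - X.min(axis=0)) / span

    ed_pair = squareform(pdist(X.T, metric="euclidean"))
    gram = X.T @ X
    sqnorm = np.diag(gram).copy()
    norm = np.sqrt(sqnorm)
    zero = norm == 0
    if zero.any():
        warnings.warn(
            "zero-norm feature column(s); cosine/Tanimoto pairs set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_pair = gram / np.outer(norm, norm)
        tc_den = sqnorm[:, None] + sqnorm[None, :] - gram
        tc_pair = np.where(tc_den > 0, gram / np.where(tc_den > 0, tc_den, 1.0), 0.0)
    cos_pair[zero, :] = 0.0
    cos_pair[:, zero] = 0.0
    tc_pair[zero, :] = 0.0
    tc_pair[:, zero] = 0.0
    if orientation == "inverted":
        # treat the similarity terms as genuine distances
        cos_pair = 1.0 - cos_pair
        tc_pair = 1.0 - tc_pair
        np.fill_diagonal(cos_pair, 0.0)
        np.fill_diagonal(tc_pair, 0.0)
    else:
        np.fill_diagonal(cos_pair, 0.0)
        np.fill_diagonal(tc_pair, 0.0)

    ed = ed_pair.sum(axis=1) / (M - 1)
    cos = cos_pair.sum(axis=1) / (M - 1)
    tc = tc_pair.sum(axis=1) / (M - 1)
    md = (ed + cos + tc) / 3.0
    return pd.DataFrame(
        {"ED": ed, "COS": cos, "TC": tc, "MD": md}, index=m.X.columns
    )


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by descending combined score MR_i + MD_i.

    ``table`` has one row per feature in rank order with columns
    feature, MR, ED, COS, TC, MD, score.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature", "MR", "ED", "COS", "TC", "MD", "score"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"ranking table must have columns {sorted(required)}")
        if self.table["feature"].duplicated().any():
            raise ValidationError("ranking covers a feature more than once")
        scores = self.table["score"].to_numpy()
        if np.any(np.diff(scores) > 1e-12):
            raise ValidationError("combined scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.table)

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(self.table["feature"].iloc[:k])


def rank_features(
    m: FeatureMatrix,
    orientation: str = "printed",
    minmax_scale: bool = False,
) -> FeatureRanking:
    """Rank all feature columns by MR_i + MD_i, descending, deterministically.

    Ties are broken by higher MR_i, then by input column order, so identical
    inputs yield identical rankings.
    """
    mr = relevance_scores(m)
    comps = distance_components(m, orientation=orientation, minmax_scale=minmax_scale)
    score = mr.to_numpy() + comps["MD"].to_numpy()
    order = sorted(
        range(m.n_features),
        key=lambda i: (-score[i], -mr.iloc[i], i),
    )
    table = pd.DataFrame(
        {
            "feature": [m.feature_names[i] for i in order],
            "MR": mr.to_numpy()[order],
            "ED": comps["ED"].to_numpy()[order],
            "COS": comps["COS"].to_numpy()[order],
            "TC": comps["TC"].to_numpy()[order],
            "MD": comps["MD"].to_numpy()[order],
            "score": score[order],
        }
    ).reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return FeatureRanking(table=table)


def select_top_k(m: FeatureMatrix, r: FeatureRanking, k: int) -> FeatureMatrix:
    """Restrict the matrix to the k top-ranked features.

    The original column order is preserved among the survivors; labels and
    sample ids are unchanged.
    """
    if not 1 <= k <= m.n_features:
        raise ValidationError(
            f"k={k} out of range 1..{m.n_features}"
        )
    keep = set(r.top(k))
    survivors = [name for name in m.feature_names if name in keep]
    return m.select_features(survivors)
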