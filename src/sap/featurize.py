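"""Sequence featurization: amino-acid composition, 400D consecutive-dipeptide
features, and g-gap dipeptide composition.

A peptide P = R_1 R_2 ... R_L is summarized by pair statistics over the 20
standard residues.  The 400D block records, for each of the 400 ordered pairs
AB, how often R_j R_{j+1} = AB (raw counts by default; a frequency mode divides
by L-1).  The g-gap composition generalizes this to pairs separated by exactly
g intervening residues:

    d_u^g = n_u^g / (L - g - 1)

where n_u^g counts positions j with (R_j, R_{j+g+1}) equal to the u-th ordered
pair; each g-gap block therefore sums to exactly 1, and g=0 reproduces the
frequency-mode 400D block.  Feature names are the fixed lexicographic
enumeration of ordered residue pairs, prefixed by block ("d400:AC", "g1:AC").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import TooShortError, ValidationError
from .peptide_io import AMINO_ACIDS, Peptide, PeptideDataset

logger = logging.getLogger(__name__)

#: Fixed lexicographic enumeration of the 400 ordered residue pairs.
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
_PAIR_INDEX = {pair: i for i, pair in enumerate(DIPEPTIDES)}

#: Default upper bound on the gap g; short peptides support gaps up to ~4.
DEFAULT_MAX_GAP = 4


@dataclass(frozen=True)
class FeatureVector:
    """Named, non-negative feature values for one sample."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != values.shape[0]:
            raise ValidationError(
                f"{len(self.names)} names but {values.shape[0]} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if np.any(values < 0):
            raise ValidationError("feature values must be non-negative")

    def __len__(self) -> int:
        return len(self.names)

    def concat(self, other: "FeatureVector") -> "FeatureVector":
        return FeatureVector(
            names=self.names + other.names,
            values=np.concatenate([self.values, other.values]),
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x named features with an aligned optional label vector.

    ``X`` is indexed by sample id with one column per feature; ``y`` (when
    present) is a 0/1 integer series on the same index.
    """

    X: pd.DataFrame
    y: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValidationError("feature names must be unique")
        if self.X.index.duplicated().any():
            raise ValidationError("sample ids must be unique")
        if self.y is not None:
            if len(self.y) != len(self.X):
                raise ValidationError("label count must equal row count")
            y = self.y
            if not y.index.equals(self.X.index):
                raise ValidationError("label index must match sample ids")
            if not set(np.unique(y)) <= {0, 1}:
                raise ValidationError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.X.index)

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise ValidationError(f"unknown feature names: {missing[:5]}")
        return FeatureMatrix(X=self.X[list(names)], y=self.y)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        X = self.X.loc[list(ids)]
        y = None if self.y is None else self.y.loc[list(ids)]
        return FeatureMatrix(X=X, y=y)


@dataclass(frozen=True)
class FeaturizationSpec:
    """Which feature blocks to compute and how.

    Defaults follow the hybrid representation: the 400D consecutive-pair
    block in raw-count mode plus one g-gap composition block for each
    g in 0..4.
    """

    include_400d: bool = True
    mode_400d: str = "count"
    gaps: tuple[int, ...] = (0, 1, 2, 3, 4)
    include_aac: bool = False
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        if self.mode_400d not in ("count", "frequency"):
            raise ValidationError(
                f"mode_400d must be 'count' or 'frequency', got {self.mode_400d!r}"
            )
        if not self.include_400d and not self.gaps and not self.include_aac:
            raise ValidationError("featurization spec selects no feature block")
        for g in self.gaps:
            if not 0 <= g <= self.max_gap:
                raise ValidationError(
                    f"gap {g} outside allowed range 0..{self.max_gap}"
                )

    @property
    def n_features(self) -> int:
        n = 400 * len(self.gaps)
        if self.include_400d:
            n += 400
        if self.include_aac:
            n += 20
        return n


def aac(p: Peptide) -> FeatureVector:
    """20-dim amino-acid composition: normalized residue frequencies f_i."""
    counts = np.zeros(20)
    for ch in p.sequence:
        counts[AMINO_ACIDS.index(ch)] += 1
    return FeatureVector(
        names=tuple(f"aac:{a}" for a in AMINO_ACIDS),
        values=counts / len(p),
    )


def _pair_counts(sequence: str, gap: int) -> np.ndarray:
    counts = np.zeros(400)
    for j in range(len(sequence) - gap - 1):
        counts[_PAIR_INDEX[sequence[j] + sequence[j + gap + 1]]] += 1
    return counts


def dipeptide_400d(p: Peptide, mode: str = "count") -> FeatureVector:
    """400-dim consecutive-dipeptide block (ordered pairs AB).

    ``count`` mode records occurrence times of each pair; ``frequency`` mode
    divides by the L-1 consecutive positions.  Counts sum to L-1.
    """
    if mode not in ("count", "frequency"):
        raise ValidationError(f"mode must be 'count' or 'frequency', got {mode!r}")
    if len(p) < 2:
        raise TooShortError(
            f"peptide {p.id!r}: length {len(p)} < 2, no consecutive pair exists"
        )
    counts = _pair_counts(p.sequence, gap=0)
    if mode == "frequency":
        counts = counts / (len(p) - 1)
    return FeatureVector(
        names=tuple(f"d400:{pair}" for pair in DIPEPTIDES), values=counts
    )


def g_gap_composition(p: Peptide, g: int, max_gap: int = DEFAULT_MAX_GAP) -> FeatureVector:
    """400-dim g-gap dipeptide composition d_u^g = n_u^g / (L - g - 1).

    Pairs (R_j, R_{j+g+1}) are separated by exactly g residues; g=0 recovers
    the adjacent-dipeptide frequencies.  The composition sums to exactly 1.
    """
    if not 0 <= g <= max_gap:
        raise ValidationError(f"gap g={g} outside allowed range 0..{max_gap}")
    if len(p) < g + 2:
        raise TooShortError(
            f"peptide {p.id!r}: length L={len(p)} < g+2={g + 2}, "
            f"no g-gap pair exists for g={g}"
        )
    counts = _pair_counts(p.sequence, gap=g)
    return FeatureVector(
        names=tuple(f"g{g}:{pair}" for pair in DIPEPTIDES),
        values=counts / (len(p) - g - 1),
    )


def hybrid_features(
    p: Peptide,
    gaps: Iterable[int] = (0, 1, 2, 3, 4),
    include_400d: bool = True,
    mode_400d: str = "count",
    include_aac: bool = False,
    max_gap: int = DEFAULT_MAX_GAP,
) -> FeatureVector:
    """Concatenate the requested feature blocks for one peptide.

    Block order: AAC (if requested), 400D (if requested), then one g-gap
    block per requested g in declared order.  Names carry block prefixes.
    """
    blocks: list[FeatureVector] = []
    if include_aac:
        blocks.append(aac(p))
    if include_400d:
        blocks.append(dipeptide_400d(p, mode=mode_400d))
    for g in gaps:
        blocks.append(g_gap_composition(p, g, max_gap=max_gap))
    if not blocks:
        raise ValidationError("no feature block requested")
    out = blocks[0]
    for block in blocks[1:]:
        out = out.concat(block)
    return out


def featurize_peptide(p: Peptide, spec: FeaturizationSpec) -> FeatureVector:
    return hybrid_features(
        p,
        gaps=spec.gaps,
        include_400d=spec.include_400d,
        mode_400d=spec.mode_400d,
        include_aac=spec.include_aac,
        max_gap=spec.max_gap,
    )


def featurize_dataset(
    d: PeptideDataset,
    spec: FeaturizationSpec = FeaturizationSpec(),
    skip_invalid: bool = False,
) -> FeatureMatrix:
    """Featurize every peptide into one matrix row, in dataset order.

    A peptide failing a block's length precondition aborts with its id
    unless ``skip_invalid`` is set, in which case it is logged and excluded.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[Optional[int]] = []
    names: Optional[tuple[str, ...]] = None
    for p in d:
        try:
            fv = featurize_peptide(p, spec)
        except TooShortError:
            if skip_invalid:
                logger.warning("skipping too-short peptide %r", p.id)
                continue
            raise
        if names is None:
            names = fv.names
        rows.append(fv.values)
        ids.append(p.id)
        labels.append(p.label)
    if not rows:
        raise ValidationError("no peptide survived featurization")
    X = pd.DataFrame(np.vstack(rows), index=ids, columns=list(names))
    y = None
    if d.is_labeled:
        y = pd.Series(labels, index=ids, dtype=int)
    return FeatureMatrix(X=X, y=y)
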