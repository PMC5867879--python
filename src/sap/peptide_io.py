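"""Reading, validating and writing labeled peptide datasets and feature matrices.

Peptides are sequences over the 20 standard amino-acid one-letter codes with an
optional binary class label (1 = anticancer peptide, 0 = non-ACP).  FASTA is
the on-disk sequence format; labels travel either in a header suffix token
(``>id|1`` / ``>id|ACP``) or in a sidecar two-column table.  Feature matrices
are delimited text with a header row of feature names and the label column
last.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlphabetError,
    DuplicateIdError,
    FastaParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, lexicographic order. Ambiguity and rare codes
#: (B, J, O, U, X, Z) are deliberately excluded.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Header tokens accepted as labels (case-insensitive for the word forms).
_POSITIVE_TOKENS = {"1", "ACP", "POS", "POSITIVE"}
_NEGATIVE_TOKENS = {"0", "NONACP", "NON-ACP", "NEG", "NEGATIVE"}


@dataclass(frozen=True)
class Peptide:
    """A single identified peptide, optionally labeled.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    sequence : str
        Residues R_1..R_L over the 20 standard one-letter codes.  Lowercase
        input is uppercased on construction; anything outside the standard
        alphabet raises :class:`AlphabetError` naming the 1-based position.
    label : int or None
        1 for the positive class (ACP), 0 for the negative class, None if
        unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("peptide id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValidationError(f"peptide {self.id!r}: empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in _AA_SET:
                raise AlphabetError(
                    f"peptide {self.id!r}: invalid residue {ch!r} at position "
                    f"{pos} (allowed: the 20 standard amino acids)"
                )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"peptide {self.id!r}: label must be 0, 1 or None, "
                f"got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideDataset:
    """An ordered collection of peptides with consistent labeling.

    Either every peptide is labeled (training mode) or none is (prediction
    mode); a mixture is rejected.  Ids are unique.
    """

    peptides: tuple[Peptide, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        if not self.peptides:
            raise ValidationError("dataset must contain at least one peptide")
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise DuplicateIdError(f"duplicate peptide id {p.id!r}")
            seen.add(p.id)
        labeled = [p.label is not None for p in self.peptides]
        if any(labeled) and not all(labeled):
            missing = next(p.id for p in self.peptides if p.label is None)
            raise ValidationError(
                "mixed labeling: dataset has both labeled and unlabeled "
                f"peptides (first unlabeled: {missing!r})"
            )

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.peptides)

    @property
    def is_labeled(self) -> bool:
        return self.peptides[0].label is not None

    @property
    def labels(self) -> Optional[tuple[int, ...]]:
        if not self.is_labeled:
            return None
        return tuple(p.label for p in self.peptides)  # type: ignore[misc]

    @property
    def n_pos(self) -> int:
        """Number of positive-class peptides (N+)."""
        labels = self.labels
        return 0 if labels is None else sum(labels)

    @property
    def n_neg(self) -> int:
        """Number of negative-class peptides (N-)."""
        labels = self.labels
        return 0 if labels is None else len(labels) - sum(labels)

    def subset(self, ids: Iterable[str]) -> "PeptideDataset":
        wanted = set(ids)
        return PeptideDataset(tuple(p for p in self.peptides if p.id in wanted))


def _parse_header_label(header_id: str) -> tuple[str, Optional[int]]:
    """Split a FASTA id on its final ``|`` token if that token is a label."""
    if "|" not in header_id:
        return header_id, None
    stem, _, token = header_id.rpartition("|")
    upper = token.upper()
    if upper in _POSITIVE_TOKENS:
        return stem, 1
    if upper in _NEGATIVE_TOKENS:
        return stem, 0
    return header_id, None


def _read_label_table(path: Path) -> dict[str, int]:
    """Read a two-column (id, label) sidecar table, comma or tab delimited."""
    labels: dict[str, int] = {}
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    for lineno, row in enumerate(csv.reader(text.splitlines(), delimiter=delimiter), 1):
        if not row or (lineno == 1 and row[-1].strip().lower() == "label"):
            continue
        if len(row) < 2:
            raise ValidationError(
                f"{path}: line {lineno}: expected two columns (id, label)"
            )
        pid, token = row[0].strip(), row[-1].strip().upper()
        if token in _POSITIVE_TOKENS:
            labels[pid] = 1
        elif token in _NEGATIVE_TOKENS:
            labels[pid] = 0
        else:
            raise ValidationError(
                f"{path}: line {lineno}: unrecognized label {row[-1]!r}"
            )
    return labels


def read_fasta(
    path: str | Path,
    labels_path: str | Path | None = None,
    skip_invalid: bool = False,
) -> PeptideDataset:
    """Read a FASTA file into a validated :class:`PeptideDataset`.

    Labels come from the header suffix token convention (``>id|1``,
    ``>id|ACP`` ...); a sidecar two-column label table given via
    ``labels_path`` overrides the header convention.  With
    ``skip_invalid=True``, peptides failing alphabet validation are logged
    and dropped instead of aborting the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    sidecar = _read_label_table(Path(labels_path)) if labels_path else None

    peptides: list[Peptide] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FastaParseError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")

    for rec in records:
        if sidecar is not None:
            pid, _ = _parse_header_label(rec.id)
            label = sidecar.get(pid, sidecar.get(rec.id))
        else:
            pid, label = _parse_header_label(rec.id)
        try:
            peptides.append(Peptide(id=pid, sequence=str(rec.seq), label=label))
        except AlphabetError:
            if skip_invalid:
                logger.warning("skipping invalid peptide %r", pid)
                continue
            raise
    if not peptides:
        raise ValidationError(f"{path}: every record was skipped as invalid")
    return PeptideDataset(tuple(peptides))


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    """Write a dataset as FASTA with label-bearing headers (``>id|1``)."""
    path = Path(path)
    with path.open("w") as fh:
        for p in dataset:
            header = p.id if p.label is None else f"{p.id}|{p.label}"
            fh.write(f">{header}\n{p.sequence}\n")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a feature matrix as delimited text.

    Layout: ``id`` column first, one named column per feature, ``label``
    column last (omitted for unlabeled matrices).  Delimiter is chosen by
    extension (tab for ``.tsv``, comma otherwise); names containing the
    delimiter are quoted per the CSV standard by pandas.
    """
    path = Path(path)
    if matrix.n_samples == 0:
        raise ValidationError("refusing to write a feature matrix with 0 samples")
    frame = matrix.X.copy()
    if matrix.y is not None:
        frame["label"] = matrix.y
    frame.index.name = "id"
    frame.to_csv(path, sep=_delimiter_for(path))


def read_feature_matrix(path: str | Path):
    """Read a delimited feature matrix written by :func:`write_feature_matrix`."""
    from .featurize import FeatureMatrix

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix file not found: {path}")
    frame = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = None
    y = None
    if "label" in frame.columns:
        if list(frame.columns)[-1] != "label":
            raise ValidationError(f"{path}: label column must be last")
        y = frame.pop("label").astype(int)
    return FeatureMatrix(X=frame, y=y)
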