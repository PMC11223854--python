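"""Amino-acid feature encoding for hexapeptide classification.

Each residue of a hexapeptide is mapped to a fixed-length numeric descriptor
vector through a :class:`FeatureTable`; a hexapeptide therefore becomes a
``6 x n_features`` matrix that the networks consume. The package ships a
curated default table of 36 descriptors per residue (atomic composition
computed from residue molecular formulas plus standard physicochemical scales:
hydropathy, volume, charge, secondary-structure propensities, ...). Any table
with the same layout can be substituted via :func:`load_feature_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
HEXAPEPTIDE_LENGTH = 6
N_FEATURES = 36

__all__ = [
    "CANONICAL_RESIDUES",
    "HEXAPEPTIDE_LENGTH",
    "N_FEATURES",
    "FeatureTable",
    "Hexapeptide",
    "EncodedWindow",
    "load_feature_table",
    "default_feature_table",
    "encode_hexapeptide",
    "encode_dataset",
]


@dataclass(frozen=True)
class FeatureTable:
    """Per-residue numeric descriptors: 20 canonical residues x 36 features."""

    residues: tuple[str, ...]
    feature_names: tuple[str, ...]
    matrix: np.ndarray  # (20, 36), row order follows `residues`
    provenance: str = "unspecified"
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.float64)
        if len(self.residues) != len(CANONICAL_RESIDUES):
            raise ValueError(
                f"feature table must have exactly {len(CANONICAL_RESIDUES)} "
                f"residue rows, got {len(self.residues)}"
            )
        missing = set(CANONICAL_RESIDUES) - set(self.residues)
        if missing:
            raise ValueError(f"missing residue rows: {sorted(missing)}")
        if len(set(self.residues)) != len(self.residues):
            dupes = sorted({r for r in self.residues if self.residues.count(r) > 1})
            raise ValueError(f"duplicate residue rows: {dupes}")
        if mat.shape != (len(self.residues), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {mat.shape} does not match "
                f"{len(self.residues)} residues x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(mat)):
            raise ValueError("feature table contains non-finite values")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(
            self, "_index", {r: i for i, r in enumerate(self.residues)}
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.residues)

    def vector(self, residue: str) -> np.ndarray:
        """Descriptor vector of a single one-letter residue code."""
        try:
            return self.matrix[self._index[residue]]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in feature table") from None

    def identifier(self) -> str:
        """Stable content hash binding trained models to their encoding."""
        import hashlib

        h = hashlib.sha256()
        h.update("".join(self.residues).encode())
        h.update("|".join(self.feature_names).encode())
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class Hexapeptide:
    """A six-residue peptide, optionally carrying an amyloid (1) / non (0) label."""

    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, expected_length=HEXAPEPTIDE_LENGTH)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodedWindow:
    """A hexapeptide encoded as a 6 x n_features matrix."""

    matrix: np.ndarray
    origin: tuple[str, int] | None = None  # (sequence id, 1-based start)

    @property
    def flat(self) -> np.ndarray:
        return np.asarray(self.matrix).reshape(-1)


def validate_sequence(
    seq: str, expected_length: int | None = None, alphabet: Sequence[str] = CANONICAL_RESIDUES
) -> str:
    """Validate a protein sequence against the canonical 20-letter alphabet.

    Raises ``ValueError`` naming the first offending position (1-based).
    """
    if not isinstance(seq, str) or not seq:
        raise ValueError("sequence must be a non-empty string")
    if expected_length is not None and len(seq) != expected_length:
        raise ValueError(
            f"sequence {seq!r} has length {len(seq)}, expected {expected_length}"
        )
    allowed = set(alphabet)
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"non-canonical residue {ch!r} at position {pos} in {seq!r}"
            )
    return seq


def load_feature_table(path: str | Path, provenance: str | None = None) -> FeatureTable:
    """Read a residue feature table from delimited text.

    Layout: header row of feature names, first column holds the one-letter
    residue code, exactly 20 rows. Tab- and comma-separated files are both
    accepted.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    residues = [str(r) for r in df.index]
    seen: set[str] = set()
    for r in residues:
        if r in seen:
            raise ValueError(f"duplicate residue row {r!r} in {path}")
        seen.add(r)
    missing = set(CANONICAL_RESIDUES) - seen
    if missing:
        raise ValueError(f"missing residue row(s) {sorted(missing)} in {path}")
    extra = seen - set(CANONICAL_RESIDUES)
    if extra:
        raise ValueError(f"unknown residue row(s) {sorted(extra)} in {path}")
    values = np.empty((len(residues), df.shape[1]), dtype=np.float64)
    for i, (res, row) in enumerate(df.iterrows()):
        if row.isna().any():
            bad = row.index[row.isna()][0]
            raise ValueError(f"row {res!r} is missing a value in column {bad!r}")
        for j, (col, cell) in enumerate(row.items()):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at row {res!r}, column {col!r}: {cell!r}"
                ) from None
    return FeatureTable(
        residues=tuple(residues),
        feature_names=tuple(str(c) for c in df.columns),
        matrix=values,
        provenance=provenance or f"loaded from {path.name}",
    )


def default_feature_table() -> FeatureTable:
    """The built-in default descriptor set shipped with the package."""
    with resources.as_file(
        resources.files("aprnet.data") / "aa_features_default.tsv"
    ) as p:
        table = load_feature_table(p, provenance="aprnet built-in default descriptor set")
    if table.n_features != N_FEATURES:
        raise RuntimeError("packaged feature table is corrupted")
    return table


def encode_hexapeptide(
    hexapeptide: Hexapeptide | str,
    table: FeatureTable,
    origin: tuple[str, int] | None = None,
) -> EncodedWindow:
    """Encode one hexapeptide as a 6 x n_features matrix (row i = residue i)."""
    seq = hexapeptide.sequence if isinstance(hexapeptide, Hexapeptide) else hexapeptide
    validate_sequence(seq, expected_length=HEXAPEPTIDE_LENGTH, alphabet=table.residues)
    mat = np.stack([table.vector(ch) for ch in seq])
    return EncodedWindow(matrix=mat, origin=origin)


def encode_dataset(
    hexapeptides: Sequence[Hexapeptide], table: FeatureTable
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-encode labeled hexapeptides.

    Returns ``(X, y)`` with ``X`` of shape ``(n, 6, n_features)`` and ``y`` a
    ``{0,1}`` integer vector, preserving input order. Every item must carry a
    label.
    """
    n = len(hexapeptides)
    X = np.empty((n, HEXAPEPTIDE_LENGTH, table.n_features), dtype=np.float64)
    y = np.empty(n, dtype=np.int64)
    for k, h in enumerate(hexapeptides):
        if h.label is None:
            raise ValueError(f"hexapeptide at index {k} is unlabeled")
        X[k] = encode_hexapeptide(h, table).matrix
        y[k] = h.label
    return X, y
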