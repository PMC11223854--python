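"""From window scores to per-residue aggregation profiles and APR calls.

A protein of length L is fragmented into the L-5 overlapping hexapeptide
windows (step one residue), each window is scored by the ensemble, and each
residue receives the mean score of the windows covering it — terminal
residues are covered by fewer than six windows and are averaged over their
actual coverage, with no padding. Aggregation-prone regions (APRs) are the
maximal runs of at least six consecutive residues at or above the threshold;
shorter above-threshold peaks are reported in the profile but not called as
APRs.

Coordinates in user-facing output are 1-based inclusive; internal arrays are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    HEXAPEPTIDE_LENGTH,
    FeatureTable,
    Hexapeptide,
    encode_hexapeptide,
    validate_sequence,
)
from .model import EnsembleModel

MIN_APR_LENGTH = 6

__all__ = [
    "ResidueProfile",
    "APRCall",
    "sequence_to_windows",
    "aggregate_per_residue",
    "profile_sequence",
    "call_aprs",
    "MIN_APR_LENGTH",
]


@dataclass
class ResidueProfile:
    """Per-residue aggregation scores for one protein sequence."""

    sequence_id: str
    sequence: str
    scores: np.ndarray  # (L,), each in [0, 1]
    coverage: np.ndarray  # (L,), number of windows covering each residue
    aux_channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        L = len(self.sequence)
        if self.scores.shape != (L,):
            raise ValueError("scores length must equal sequence length")
        if self.coverage.shape != (L,):
            raise ValueError("coverage length must equal sequence length")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        for name, ch in self.aux_channels.items():
            arr = np.asarray(ch, dtype=np.float64)
            if arr.shape != (L,):
                raise ValueError(f"aux channel {name!r} length must equal sequence length")
            self.aux_channels[name] = arr

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class APRCall:
    """One called aggregation-prone region, 1-based inclusive coordinates."""

    start: int
    end: int
    mean_score: float
    max_score: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 1:
            raise ValueError("end must not precede start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def sequence_to_windows(seq: str, sequence_id: str = "") -> list[Hexapeptide]:
    """All L-5 overlapping hexapeptide windows, in order of 1-based start."""
    validate_sequence(seq)
    if len(seq) < HEXAPEPTIDE_LENGTH:
        raise ValueError(
            f"sequence length {len(seq)} is shorter than a hexapeptide window"
        )
    return [
        Hexapeptide(seq[j:j + HEXAPEPTIDE_LENGTH])
        for j in range(len(seq) - HEXAPEPTIDE_LENGTH + 1)
    ]


def aggregate_per_residue(window_scores, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Average window scores onto residues.

    Residue i (0-based) is covered by windows j with j <= i <= j+5; its score
    is the plain mean over that covering set, so termini average over their
    reduced coverage. Returns (scores, coverage).
    """
    ws = np.asarray(window_scores, dtype=np.float64)
    n_windows = length - HEXAPEPTIDE_LENGTH + 1
    if ws.shape != (n_windows,):
        raise ValueError(
            f"expected {n_windows} window scores for length {length}, got {ws.shape}"
        )
    if np.any((ws < 0) | (ws > 1)):
        raise ValueError("window scores must lie in [0, 1]")
    scores = np.empty(length)
    coverage = np.empty(length, dtype=np.int64)
    for i in range(length):
        lo = max(0, i - (HEXAPEPTIDE_LENGTH - 1))
        hi = min(i, n_windows - 1)
        scores[i] = ws[lo:hi + 1].mean()
        coverage[i] = hi - lo + 1
    return scores, coverage


def profile_sequence(
    ensemble: EnsembleModel,
    table: FeatureTable,
    seq: str,
    sequence_id: str = "query",
    aux_channels: dict[str, np.ndarray] | None = None,
) -> ResidueProfile:
    """Window the sequence, score each window with the ensemble, aggregate."""
    seq = seq.upper()
    windows = sequence_to_windows(seq, sequence_id)
    X = np.stack([encode_hexapeptide(w, table).matrix for w in windows])
    window_scores = ensemble.predict_batch(X)
    scores, coverage = aggregate_per_residue(window_scores, len(seq))
    return ResidueProfile(
        sequence_id=sequence_id,
        sequence=seq,
        scores=scores,
        coverage=coverage,
        aux_channels=dict(aux_channels or {}),
    )


def call_aprs(
    profile: ResidueProfile,
    threshold: float,
    min_length: int = MIN_APR_LENGTH,
) -> list[APRCall]:
    """Maximal runs of >= min_length consecutive residues scoring >= threshold.

    Returned calls are disjoint and sorted by start (1-based inclusive).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if min_length < 1:
        raise ValueError("min_length must be positive")
    above = profile.scores >= threshold
    calls: list[APRCall] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                run = profile.scores[start:i]
                calls.append(APRCall(
                    start=start + 1, end=i,
                    mean_score=float(run.mean()),
                    max_score=float(run.max()),
                ))
            start = None
    return calls
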