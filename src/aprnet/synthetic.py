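"""Synthetic hexapeptide and annotated-protein generators.

These generators provide a statistical stand-in for curated amyloid data so
that the whole train -> profile -> evaluate pipeline can be exercised without
any download. The separating signal is compositional, not motif-exact:
amyloid-like positives are drawn residue-by-residue from a distribution
biased toward hydrophobic / beta-prone residues (I, V, L, F, Y, M, W), while
negatives are biased toward charged, proline- and glycine-rich compositions
that disfavour cross-beta assembly. A classifier therefore has to generalize
over composition rather than memorize sequences. The rule is recoverable by
construction: at zero label noise the mean Kyte-Doolittle hydropathy of a
6-mer already separates the classes with AuROCC >= 0.9.

Annotated proteins embed positive-composition segments (the "true" APRs,
6-20 residues, never longer than 50) into negative-composition background,
keeping the first and last six residues APR-free so terminal coverage effects
do not confound aggregation tests.

This is not a biophysical aggregation simulator; real hexapeptide data has
position-specific effects, gatekeeper residues and correlated labels that the
generators deliberately omit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import CANONICAL_RESIDUES, HEXAPEPTIDE_LENGTH, Hexapeptide
from .io import AnnotatedProtein

__all__ = [
    "SyntheticSpec",
    "POSITIVE_COMPOSITION",
    "NEGATIVE_COMPOSITION",
    "gen_hexapeptides",
    "gen_annotated_proteins",
    "hydropathy_score",
]

# residue-frequency biases of the generating rule (normalized at use)
POSITIVE_COMPOSITION = {
    "I": 14, "V": 14, "L": 12, "F": 12, "Y": 8, "M": 6, "W": 5, "A": 8,
    "T": 5, "C": 3, "S": 3, "G": 3, "N": 1.5, "Q": 1.5, "H": 1, "D": 1,
    "E": 1, "K": 1, "R": 1, "P": 0.5,
}
NEGATIVE_COMPOSITION = {
    "D": 10, "E": 10, "K": 10, "R": 9, "P": 9, "G": 10, "S": 9, "N": 8,
    "Q": 8, "H": 5, "T": 4, "A": 4, "I": 0.5, "V": 1, "L": 1, "F": 0.5,
    "Y": 1, "M": 0.5, "W": 0.5, "C": 1,
}

_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def hydropathy_score(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy; the generator's recoverable oracle."""
    return float(np.mean([_KD[c] for c in seq]))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic hexapeptide dataset."""

    n_hexapeptides: int = 500
    positive_fraction: float = 0.3
    noise: float = 0.0  # label-flip probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hexapeptides < 1:
            raise ValueError("n_hexapeptides must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError(
                f"positive_fraction must be in (0, 1), got {self.positive_fraction}"
            )
        if not 0.0 <= self.noise < 0.5:
            raise ValueError(f"noise must be in [0, 0.5), got {self.noise}")


def _composition_probs(weights: dict[str, float]) -> np.ndarray:
    w = np.array([weights[c] for c in CANONICAL_RESIDUES], dtype=np.float64)
    return w / w.sum()


def _draw_peptide(rng: np.random.Generator, probs: np.ndarray, length: int) -> str:
    idx = rng.choice(len(CANONICAL_RESIDUES), size=length, p=probs)
    return "".join(CANONICAL_RESIDUES[i] for i in idx)


def gen_hexapeptides(spec: SyntheticSpec) -> list[Hexapeptide]:
    """Generate a labeled hexapeptide dataset.

    Exactly ``round(positive_fraction * n)`` sequences are drawn from the
    positive composition before label noise; sequences are unique across the
    dataset; each label is then flipped independently with probability
    ``spec.noise``. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = round(spec.positive_fraction * spec.n_hexapeptides)
    p_pos = _composition_probs(POSITIVE_COMPOSITION)
    p_neg = _composition_probs(NEGATIVE_COMPOSITION)
    seqs: list[str] = []
    labels: list[int] = []
    seen: set[str] = set()
    for label, count, probs in ((1, n_pos, p_pos),
                                (0, spec.n_hexapeptides - n_pos, p_neg)):
        made = 0
        while made < count:
            s = _draw_peptide(rng, probs, HEXAPEPTIDE_LENGTH)
            if s in seen:
                continue
            seen.add(s)
            seqs.append(s)
            labels.append(label)
            made += 1
    order = rng.permutation(spec.n_hexapeptides)
    flips = rng.random(spec.n_hexapeptides) < spec.noise
    return [
        Hexapeptide(seqs[i], int(labels[i]) ^ int(flips[i]))
        for i in order
    ]


def gen_annotated_proteins(
    n: int,
    length_range: tuple[int, int] = (80, 160),
    apr_length_range: tuple[int, int] = (6, 20),
    n_aprs_range: tuple[int, int] = (1, 2),
    seed: int = 0,
) -> list[AnnotatedProtein]:
    """Generate proteins with embedded positive-composition APR segments.

    Background residues come from the negative composition; each protein gets
    ``n_aprs`` segments (positions recorded as 1-based inclusive intervals),
    placed so they never touch the first or last six residues and stay at
    least six residues apart.
    """
    if n < 1:
        raise ValueError("n must be positive")
    lo_len, hi_len = length_range
    lo_apr, hi_apr = apr_length_range
    if lo_apr < HEXAPEPTIDE_LENGTH:
        raise ValueError("APR length must be at least 6")
    if hi_apr > 50:
        raise ValueError("APR length must not exceed 50")
    if hi_apr + 2 * HEXAPEPTIDE_LENGTH > lo_len:
        raise ValueError(
            f"APR of length {hi_apr} cannot be embedded in a protein of "
            f"length {lo_len} away from both termini"
        )
    rng = np.random.default_rng(seed)
    p_pos = _composition_probs(POSITIVE_COMPOSITION)
    p_neg = _composition_probs(NEGATIVE_COMPOSITION)
    proteins: list[AnnotatedProtein] = []
    for i in range(n):
        L = int(rng.integers(lo_len, hi_len + 1))
        n_aprs = int(rng.integers(n_aprs_range[0], n_aprs_range[1] + 1))
        seq = list(_draw_peptide(rng, p_neg, L))
        intervals: list[tuple[int, int]] = []
        for _ in range(n_aprs):
            placed = False
            for _attempt in range(200):
                alen = int(rng.integers(lo_apr, hi_apr + 1))
                # 0-based start; keep 6 background residues at each terminus
                start = int(rng.integers(HEXAPEPTIDE_LENGTH,
                                         L - HEXAPEPTIDE_LENGTH - alen + 1))
                end = start + alen  # half-open
                if all(start >= e + HEXAPEPTIDE_LENGTH or end + HEXAPEPTIDE_LENGTH <= s
                       for (s, e) in intervals):
                    intervals.append((start, end))
                    seq[start:end] = _draw_peptide(rng, p_pos, alen)
                    placed = True
                    break
            if not placed:
                break  # protein too crowded; keep the APRs placed so far
        proteins.append(AnnotatedProtein(
            id=f"synth_{i:03d}",
            sequence="".join(seq),
            aprs=tuple(sorted((s + 1, e) for (s, e) in intervals)),
        ))
    return proteins
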