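"""Readers and writers for the on-disk formats.

Formats:
  * protein sequences: FASTA (multi-record, line-wrapped);
  * hexapeptide datasets: CSV with header ``sequence,label`` (label 0/1);
  * APR annotations: JSON records ``{"id", "sequence", "aprs": [[start, end], ...]}``
    with 1-based inclusive coordinates, plus a BED adapter (0-based half-open);
  * per-residue profiles: CSV with columns (sequence_id, position, residue,
    aggregation_score, coverage, in_apr) and a JSON variant;
  * APR calls: BED-like tab-delimited intervals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .encoding import Hexapeptide, validate_sequence
from .profiling import APRCall, ResidueProfile

__all__ = [
    "HexDatasetFile",
    "AnnotatedProtein",
    "AnnotatedProteinFile",
    "read_fasta",
    "write_fasta",
    "read_hexdataset",
    "write_hexdataset",
    "read_annotations",
    "write_annotations",
    "annotations_to_bed",
    "annotations_from_bed",
    "apr_mask",
    "write_profile",
    "read_profile",
    "write_apr_calls",
]


@dataclass
class HexDatasetFile:
    """Labeled hexapeptides read from (or destined for) a CSV file."""

    records: list[Hexapeptide]
    source: str = ""

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein sequence with annotated APR intervals (1-based inclusive)."""

    id: str
    sequence: str
    aprs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        for (start, end) in self.aprs:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"APR interval [{start}, {end}] out of bounds for "
                    f"{self.id!r} (length {len(self.sequence)})"
                )


@dataclass
class AnnotatedProteinFile:
    entries: list[AnnotatedProtein]
    source: str = ""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA records as (id, upper-cased sequence) pairs.

    Performs an integrity pre-scan so malformed files fail with a line
    number: content before the first header, empty headers and records with
    no sequence are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_line = None
    has_seq = False
    any_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if any_header and not has_seq:
                raise ValueError(
                    f"{path}:{header_line}: record with empty sequence"
                )
            if not line[1:].strip():
                raise ValueError(f"{path}:{lineno}: empty FASTA header")
            any_header = True
            header_line = lineno
            has_seq = False
        else:
            if not any_header:
                raise ValueError(
                    f"{path}:{lineno}: sequence data before the first '>' header"
                )
            has_seq = True
    if not any_header:
        raise ValueError(f"{path}: no FASTA records found")
    if not has_seq:
        raise ValueError(f"{path}:{header_line}: record with empty sequence")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def read_hexdataset(path: str | Path) -> HexDatasetFile:
    """Read a ``sequence,label`` CSV of hexapeptides.

    Conflicting duplicate sequences (same 6-mer, different labels) are an
    error; identical duplicates are kept as-is.
    """
    path = Path(path)
    records: list[Hexapeptide] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["sequence", "label"]:
            raise ValueError(f"{path}:1: expected header 'sequence,label'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            seq = row[0].strip().upper()
            try:
                label = int(row[1])
                h = Hexapeptide(seq, label)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if seq in seen and seen[seq] != label:
                raise ValueError(
                    f"{path}:{lineno}: duplicate sequence {seq!r} with "
                    f"conflicting labels {seen[seq]} and {label}"
                )
            seen[seq] = label
            records.append(h)
    return HexDatasetFile(records=records, source=str(path))


def write_hexdataset(records: Sequence[Hexapeptide], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence", "label"])
        for r in records:
            if r.label is None:
                raise ValueError(f"cannot write unlabeled hexapeptide {r.sequence!r}")
            writer.writerow([r.sequence, r.label])
    return path


def read_annotations(path: str | Path) -> AnnotatedProteinFile:
    """Read APR annotations from JSON (list of records, 1-based inclusive)."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON list of annotation records")
    entries = []
    for i, rec in enumerate(data):
        try:
            entries.append(AnnotatedProtein(
                id=str(rec["id"]),
                sequence=str(rec["sequence"]).upper(),
                aprs=tuple((int(a), int(b)) for a, b in rec.get("aprs", [])),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: record {i}: {exc}") from None
    return AnnotatedProteinFile(entries=entries, source=str(path))


def write_annotations(entries: Sequence[AnnotatedProtein], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"id": e.id, "sequence": e.sequence, "aprs": [list(iv) for iv in e.aprs]}
        for e in entries
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def annotations_to_bed(entries: Sequence[AnnotatedProtein], path: str | Path) -> Path:
    """Write APR intervals as BED3 (0-based half-open)."""
    path = Path(path)
    with path.open("w") as fh:
        for e in entries:
            for (start, end) in e.aprs:
                fh.write(f"{e.id}\t{start - 1}\t{end}\n")
    return path


def annotations_from_bed(
    bed_path: str | Path, sequences: dict[str, str]
) -> AnnotatedProteinFile:
    """Read BED3 intervals back into 1-based inclusive annotations.

    ``sequences`` supplies the protein sequences (BED carries none).
    """
    bed_path = Path(bed_path)
    intervals: dict[str, list[tuple[int, int]]] = {sid: [] for sid in sequences}
    with bed_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 BED columns")
            sid, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if sid not in intervals:
                raise ValueError(f"{bed_path}:{lineno}: unknown sequence id {sid!r}")
            intervals[sid].append((start0 + 1, end0))
    entries = [
        AnnotatedProtein(id=sid, sequence=seq, aprs=tuple(sorted(intervals[sid])))
        for sid, seq in sequences.items()
    ]
    return AnnotatedProteinFile(entries=entries, source=str(bed_path))


def apr_mask(entry: AnnotatedProtein) -> np.ndarray:
    """Per-residue 0/1 ground truth as the union of the annotated intervals."""
    mask = np.zeros(len(entry.sequence), dtype=np.int64)
    for (start, end) in entry.aprs:
        mask[start - 1:end] = 1
    return mask


def write_profile(
    profile: ResidueProfile,
    calls: Sequence[APRCall],
    path: str | Path,
    fmt: str = "csv",
) -> Path:
    """Write a per-residue profile (CSV or JSON) with an in-APR flag column."""
    path = Path(path)
    in_apr = np.zeros(len(profile), dtype=np.int64)
    for c in calls:
        in_apr[c.start - 1:c.end] = 1
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([
                "sequence_id", "position", "residue",
                "aggregation_score", "coverage", "in_apr",
            ])
            for i, ch in enumerate(profile.sequence):
                writer.writerow([
                    profile.sequence_id, i + 1, ch,
                    f"{profile.scores[i]:.10g}", int(profile.coverage[i]),
                    int(in_apr[i]),
                ])
    elif fmt == "json":
        payload = {
            "sequence_id": profile.sequence_id,
            "sequence": profile.sequence,
            "scores": [float(s) for s in profile.scores],
            "coverage": [int(c) for c in profile.coverage],
            "in_apr": [int(v) for v in in_apr],
            "aprs": [
                {"start": c.start, "end": c.end,
                 "mean_score": c.mean_score, "max_score": c.max_score}
                for c in calls
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown profile format {fmt!r}")
    return path


def read_profile(path: str | Path) -> ResidueProfile:
    """Read a CSV profile back (inverse of the CSV writer, minus APR calls)."""
    path = Path(path)
    ids, residues, scores, coverage = [], [], [], []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            ids.append(row["sequence_id"])
            residues.append(row["residue"])
            scores.append(float(row["aggregation_score"]))
            coverage.append(int(row["coverage"]))
    if not ids:
        raise ValueError(f"{path}: empty profile")
    if len(set(ids)) != 1:
        raise ValueError(f"{path}: multiple sequence ids in one profile file")
    return ResidueProfile(
        sequence_id=ids[0],
        sequence="".join(residues),
        scores=np.array(scores),
        coverage=np.array(coverage),
    )


def write_apr_calls(
    calls_by_id: dict[str, Sequence[APRCall]], path: str | Path
) -> Path:
    """BED-like APR intervals: sequence_id, start, end, mean_score.

    Coordinate convention is stated in the header line.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# sequence_id\tstart\tend\tmean_score (1-based inclusive coordinates)\n")
        for sid, calls in calls_by_id.items():
            for c in calls:
                fh.write(f"{sid}\t{c.start}\t{c.end}\t{c.mean_score:.6f}\n")
    return path
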