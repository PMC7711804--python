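"""Protein records, FASTA I/O, the length-stratified split, and synthetic data.

Labeled two-class sets of protein sequences are the raw material of
immunogenicity modelling: positives are experimentally validated protective
immunogens, negatives are proteins from the same species with no similarity
to any positive.  This module handles reading such sets from FASTA (with
labels in a ``|label=`` header suffix or a sidecar TSV), the length-stratified
train/test split used to hold out an external evaluation set, and a synthetic
generator that produces two-class sequence sets with a controllable
compositional signal so the whole pipeline can be exercised without any
external download.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "SplitSpec",
    "LabeledDataset",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_label_sidecar",
    "attach_labels",
    "load_labeled_fasta",
    "length_stratified_split",
    "write_split_manifest",
    "generate_synthetic_dataset",
    "SYNTHETIC_TILT_RESIDUES",
]


class FastaParseError(ValueError):
    """Malformed FASTA input (junk before first header, duplicate or empty records)."""


@dataclass
class ProteinRecord:
    """One protein: identifier, free-text description, sequence, optional label.

    ``label`` is 1 for an immunogen, 0 for a non-immunogen, ``None`` when
    unknown (e.g. a proteome to be screened).
    """

    id: str
    sequence: str
    description: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SplitSpec:
    """Parameters of the length-stratified train/test split.

    Records are sorted by length, cut into ``n_groups`` contiguous groups of
    near-equal size, and within each group a seeded shuffle assigns
    ``ceil(test_fraction * group_size)`` records to the test set.
    """

    n_groups: int = 28
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be a positive integer")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class LabeledDataset:
    """Feature matrix with aligned binary labels and record identifiers."""

    features: np.ndarray
    labels: np.ndarray | None
    ids: list[str]
    feature_ordering_tag: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.ids) != self.features.shape[0]:
            raise ValueError("ids and feature rows disagree in count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.features.shape[0],):
                raise ValueError("labels and feature rows disagree in count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            labels=None if self.labels is None else self.labels[idx],
            ids=[self.ids[i] for i in idx],
            feature_ordering_tag=self.feature_ordering_tag,
        )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _as_text_stream(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _parse_label_suffix(header: str) -> tuple[str, int | None]:
    """Split a ``...|label=0/1`` suffix off a FASTA id, if present."""
    if "|label=" in header:
        base, _, value = header.rpartition("|label=")
        if value in ("0", "1"):
            return base, int(value)
        raise FastaParseError(f"record {base!r}: label suffix must be 0 or 1, got {value!r}")
    return header, None


def read_fasta(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Parse FASTA into records, preserving order.

    Multi-line sequences are concatenated and upper-cased.  Labels embedded as
    a ``|label=0/1`` id suffix are picked up; otherwise labels stay unset.
    Structural problems (sequence data before the first header, duplicate
    ids, a header with no sequence) raise :class:`FastaParseError` naming the
    offending line or id.
    """
    stream = _as_text_stream(source)
    close = isinstance(source, (str, Path))
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()

    # Structural validation pass with line numbers; Biopython then does the
    # actual record assembly on the validated text.
    header_lines: dict[str, int] = {}
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError(f"line {lineno}: sequence data before first '>' header")

    records: list[ProteinRecord] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        rec_id, label = _parse_label_suffix(rec.id)
        if rec_id in seen_ids:
            raise FastaParseError(f"duplicate record id {rec_id!r}")
        seen_ids.add(rec_id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec_id!r}: header with no sequence")
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec_id, sequence=seq, description=description, label=label))
    return records


def write_fasta(records: Iterable[ProteinRecord], destination: str | Path | TextIO,
                embed_labels: bool = False, width: int = 60) -> None:
    """Write records as wrapped FASTA, optionally embedding ``|label=`` suffixes."""
    stream = _as_text_stream(destination) if not isinstance(destination, (str, Path)) else open(destination, "w", encoding="utf-8")
    close = isinstance(destination, (str, Path))
    try:
        for rec in records:
            rec_id = rec.id
            if embed_labels and rec.label is not None:
                rec_id = f"{rec.id}|label={rec.label}"
            header = f">{rec_id}" + (f" {rec.description}" if rec.description else "")
            stream.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                stream.write(rec.sequence[start:start + width] + "\n")
    finally:
        if close:
            stream.close()


def read_label_sidecar(source: str | Path | TextIO) -> dict[str, int]:
    """Read a two-column (id, label) TSV into a mapping."""
    stream = _as_text_stream(source)
    close = isinstance(source, (str, Path))
    labels: dict[str, int] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ValueError(f"label sidecar line {lineno}: expected 2 tab-separated columns")
            rec_id, value = parts
            if value not in ("0", "1"):
                raise ValueError(f"label sidecar line {lineno}: label must be 0 or 1, got {value!r}")
            labels[rec_id] = int(value)
    finally:
        if close:
            stream.close()
    return labels


def attach_labels(records: list[ProteinRecord], labels: dict[str, int]) -> list[ProteinRecord]:
    """Return records with sidecar labels applied; the sidecar wins on conflict."""
    out = []
    for rec in records:
        label = labels.get(rec.id, rec.label)
        out.append(ProteinRecord(rec.id, rec.sequence, rec.description, label))
    return out


def load_labeled_fasta(fasta: str | Path | TextIO,
                       sidecar: str | Path | TextIO | None = None) -> list[ProteinRecord]:
    """Read FASTA and apply an optional label sidecar (sidecar wins on conflict)."""
    records = read_fasta(fasta)
    if sidecar is not None:
        records = attach_labels(records, read_label_sidecar(sidecar))
    return records


# ---------------------------------------------------------------------------
# Length-stratified train/test split
# ---------------------------------------------------------------------------

def length_stratified_split(records: list[ProteinRecord],
                            spec: SplitSpec | None = None,
                            ) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split labeled records into train/test sets stratified by sequence length.

    Records are stably sorted by (length, id) and cut into ``spec.n_groups``
    contiguous groups of near-equal size; within each group a shuffle driven
    by ``spec.seed`` assigns ``ceil(test_fraction * group_size)`` records to
    the test set.  The two outputs partition the input exactly and the split
    is deterministic for a fixed seed.
    """
    spec = spec or SplitSpec()
    if any(rec.label is None for rec in records):
        raise ValueError("length_stratified_split requires every record to be labeled")
    labels = {rec.label for rec in records}
    if labels != {0, 1}:
        raise ValueError("both classes must be present in the records to split")
    if spec.n_groups > len(records):
        raise ValueError(
            f"n_groups={spec.n_groups} exceeds record count {len(records)}")

    ordered = sorted(records, key=lambda r: (len(r.sequence), r.id))
    groups = np.array_split(np.arange(len(ordered)), spec.n_groups)
    rng = np.random.default_rng(spec.seed)
    train: list[ProteinRecord] = []
    test: list[ProteinRecord] = []
    for group in groups:
        perm = rng.permutation(len(group))
        n_test = math.ceil(spec.test_fraction * len(group))
        chosen = set(group[perm[:n_test]].tolist())
        for idx in group:
            (test if idx in chosen else train).append(ordered[idx])
    return train, test


def write_split_manifest(train: list[ProteinRecord], test: list[ProteinRecord],
                         train_path: str | Path, test_path: str | Path) -> None:
    """Write the two id lists of a split as plain-text manifests."""
    Path(train_path).write_text("".join(rec.id + "\n" for rec in train), encoding="utf-8")
    Path(test_path).write_text("".join(rec.id + "\n" for rec in test), encoding="utf-8")


# ---------------------------------------------------------------------------
# Synthetic two-class sequence generator
# ---------------------------------------------------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Hydrophobic/small residues that carry the synthetic class signal (the seven
# residues with positive Kyte-Doolittle hydropathy); the complement
# (polar/charged residues) is tilted the opposite way.  A sign-consistent
# hydrophobic set keeps the class contrast visible to covariance features,
# which an inconsistent set (e.g. one including G or P) would cancel.
SYNTHETIC_TILT_RESIDUES = frozenset("ACFILMV")


def _class_composition(signal_strength: float, positive: bool) -> np.ndarray:
    sign = 1.0 if positive else -1.0
    weights = np.array(
        [1.0 + sign * signal_strength if aa in SYNTHETIC_TILT_RESIDUES
         else 1.0 - sign * signal_strength
         for aa in _AA_ALPHABET]
    )
    return weights / weights.sum()


def generate_synthetic_dataset(n_pos: int = 250, n_neg: int = 250,
                               length_range: tuple[int, int] = (30, 200),
                               signal_strength: float = 0.8,
                               seed: int = 0) -> list[ProteinRecord]:
    """Generate a labeled two-class set with a compositional class signal.

    Positives draw residues from a composition tilted toward hydrophobic and
    small amino acids by ``signal_strength``; negatives use the complementary
    tilt.  At ``signal_strength`` 0 the two classes are identically
    distributed (the null case).  Lengths are uniform over ``length_range``;
    output is reproducible for a fixed seed and always encodable under the
    strict residue policy.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must each be at least 1")
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"invalid length_range {length_range}: min exceeds max")
    if lo < 9:
        raise ValueError("minimum length must be >= 9 so records are admissible at lag 8")
    if not 0.0 <= signal_strength <= 1.0:
        raise ValueError("signal_strength must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_AA_ALPHABET))
    records: list[ProteinRecord] = []
    for label, count, prefix in ((1, n_pos, "pos"), (0, n_neg, "neg")):
        comp = _class_composition(signal_strength, positive=bool(label))
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=comp))
            records.append(ProteinRecord(
                id=f"{prefix}_{i:04d}",
                sequence=seq,
                description=f"synthetic {'immunogen' if label else 'non-immunogen'}",
                label=label,
            ))
    return records
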