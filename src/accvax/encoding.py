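"""E-descriptor encoding and the auto-cross covariance (ACC) transform.

A protein of length ``n`` is first written as a 5 x n matrix of E-descriptor
values — five principal-component scores per amino acid summarizing 237
physicochemical properties (E1 ~ hydrophobicity, E2 ~ size/sterics, E3 ~
helix propensity, E4 ~ partial specific volume / codon usage / composition,
E5 ~ strand propensity).  Because proteins differ in length, the matrix is
then collapsed into a fixed-length vector of lagged auto- and
cross-covariance terms

    A_jj(L) = sum_{i=1..n-L} E_{j,i} * E_{j,i+L} / (n - L)
    C_jk(L) = sum_{i=1..n-L} E_{j,i} * E_{k,i+L} / (n - L),   j != k

for lags L = 1..lag_max, giving 25 terms per lag (5 auto + 20 cross) and a
feature vector of length 25 * lag_max independent of n.  No centering or
scaling happens inside the transform: the sums are over raw descriptor
values, and any standardization is a model-side concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

from .data import LabeledDataset, ProteinRecord

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "DescriptorTable",
    "EncodedSequence",
    "ACCVector",
    "EncodingError",
    "SequenceLengthError",
    "POLICIES",
    "default_descriptor_table",
    "encode_sequence",
    "acc_transform",
    "ordering_tag",
    "feature_names",
    "build_feature_matrix",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue policies: ``strict`` rejects any non-standard residue;``skip-unknown``
#: deletes non-standard residues (X, B, Z, U, O, *, ...) before encoding.
POLICIES = ("strict", "skip-unknown")

# Five-component E-descriptor scales of Venkatarajan & Braun (2001), one row
# per standard residue, columns E1..E5.
_E_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.008, 0.134, -0.475, -0.039, 0.181),
    "R": (0.171, -0.361, 0.107, -0.258, -0.364),
    "N": (0.255, 0.038, 0.117, 0.118, -0.055),
    "D": (0.303, -0.057, -0.014, 0.225, 0.156),
    "C": (-0.132, 0.174, 0.070, 0.565, -0.374),
    "Q": (0.149, -0.184, -0.030, 0.035, -0.112),
    "E": (0.221, -0.280, -0.315, 0.157, 0.303),
    "G": (0.218, 0.562, -0.024, 0.018, 0.106),
    "H": (0.023, -0.177, 0.041, 0.280, -0.021),
    "I": (-0.353, 0.071, -0.088, -0.195, -0.107),
    "L": (-0.267, 0.018, -0.265, -0.274, 0.206),
    "K": (0.243, -0.339, -0.044, -0.325, -0.027),
    "M": (-0.239, -0.141, -0.155, 0.321, 0.077),
    "F": (-0.329, -0.023, 0.072, -0.002, 0.208),
    "P": (0.173, 0.286, 0.407, -0.215, 0.384),
    "S": (0.199, 0.238, -0.015, -0.068, -0.196),
    "T": (0.068, 0.147, -0.015, -0.132, -0.274),
    "W": (-0.296, -0.186, 0.389, 0.083, 0.297),
    "Y": (-0.141, -0.057, 0.425, -0.096, -0.091),
    "V": (-0.274, 0.136, -0.187, -0.196, -0.299),
}


class EncodingError(ValueError):
    """A sequence cannot be encoded under the requested residue policy."""


class SequenceLengthError(ValueError):
    """A sequence is too short for the requested maximum lag."""


@dataclass(frozen=True)
class DescriptorTable:
    """Map from each of the 20 standard residues to an ordered 5-tuple of scores.

    The default table ships the E-descriptor scales; alternative five-scale
    sets (e.g. z-scales padded to five components) can be injected, and the
    table ``name`` is embedded in the feature ordering tag so models trained
    on one scale set refuse features built with another.
    """

    values: dict[str, tuple[float, ...]]
    name: str = "custom"

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AMINO_ACIDS):
            missing = set(STANDARD_AMINO_ACIDS) - keys
            extra = keys - set(STANDARD_AMINO_ACIDS)
            raise ValueError(
                f"descriptor table must cover exactly the 20 standard residues; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}")
        for aa, row in self.values.items():
            if len(row) != 5:
                raise ValueError(f"descriptor row for {aa!r} must have 5 components")
            if not all(np.isfinite(v) for v in row):
                raise ValueError(f"descriptor row for {aa!r} contains non-finite values")

    def as_matrix(self) -> np.ndarray:
        """Return the table as a (20, 5) array in canonical residue order."""
        return np.array([self.values[aa] for aa in STANDARD_AMINO_ACIDS], dtype=float)

    @classmethod
    def from_file(cls, source: str | Path | TextIO, name: str | None = None) -> "DescriptorTable":
        """Load a table from 6-column delimited text (residue, E1..E5).

        Blank lines and ``#`` comments are ignored; columns may be separated
        by tabs or spaces.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
            default_name = Path(source).stem
        else:
            text = source.read()
            default_name = "stream"
        values: dict[str, tuple[float, ...]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace("\t", " ").split()
            if len(parts) != 6:
                raise ValueError(f"descriptor file line {lineno}: expected 6 columns, got {len(parts)}")
            aa = parts[0].upper()
            if aa in values:
                raise ValueError(f"descriptor file line {lineno}: duplicate residue {aa!r}")
            values[aa] = tuple(float(v) for v in parts[1:])
        return cls(values=values, name=name or default_name)


def default_descriptor_table() -> DescriptorTable:
    """The built-in E-descriptor table (five PCA scales per residue)."""
    return DescriptorTable(values=dict(_E_SCALES), name="E-descriptors-v1")


@dataclass
class EncodedSequence:
    """A protein as a 5 x n matrix of descriptor values (row j = scale E_j)."""

    matrix: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (5, self.n) or self.n < 1:
            raise ValueError(f"encoded matrix must be 5 x n with n >= 1, got {self.matrix.shape}")


@dataclass
class ACCVector:
    """The fixed-length ACC feature vector of one protein."""

    values: np.ndarray
    lag_max: int
    ordering_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (25 * self.lag_max,):
            raise ValueError(
                f"ACC vector must have length 25 * lag_max = {25 * self.lag_max}")
        if not np.isfinite(self.values).all():
            raise ValueError("ACC vector contains non-finite values")


def encode_sequence(sequence: str, table: DescriptorTable | None = None,
                    policy: str = "strict") -> EncodedSequence:
    """Encode an amino-acid string as a 5 x n descriptor matrix.

    Under ``strict`` any residue outside the 20-letter alphabet raises
    :class:`EncodingError` naming its (1-based) position; under
    ``skip-unknown`` such residues are deleted before encoding, so ``n``
    reflects the reduced length.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")
    table = table or default_descriptor_table()
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise EncodingError("sequence is empty")

    if policy == "strict":
        for pos, aa in enumerate(seq, start=1):
            if aa not in table.values:
                raise EncodingError(
                    f"non-standard residue {aa!r} at position {pos} (strict policy)")
        kept = seq
    else:
        kept = "".join(aa for aa in seq if aa in table.values)
        if not kept:
            raise EncodingError("sequence is empty after removing non-standard residues")

    matrix = np.array([table.values[aa] for aa in kept], dtype=float).T
    return EncodedSequence(matrix=matrix, n=len(kept))


def ordering_tag(table: DescriptorTable, lag_max: int) -> str:
    """Canonical feature-ordering identifier for ACC features.

    Lag-major layout: for each lag L = 1..lag_max the 25 ordered descriptor
    pairs (j, k), j outer, k inner; (j, j) is the auto term A_jj(L) and
    (j, k), j != k, the cross term C_jk(L).
    """
    return f"acc-lagmajor-25:{table.name}:lag{lag_max}"


def feature_names(lag_max: int) -> list[str]:
    """Human-readable names for the canonical ACC ordering."""
    names = []
    for lag in range(1, lag_max + 1):
        for j in range(1, 6):
            for k in range(1, 6):
                kind = "A" if j == k else "C"
                names.append(f"{kind}{j}{k}_lag{lag}")
    return names


def acc_transform(encoded: EncodedSequence, lag_max: int = 8,
                  tag: str | None = None) -> ACCVector:
    """Collapse a 5 x n descriptor matrix into the 25 * lag_max ACC vector.

    Requires ``n >= lag_max + 1`` so every averaging denominator ``n - L`` is
    at least one.
    """
    if lag_max < 1:
        raise ValueError("lag_max must be a positive integer")
    n = encoded.n
    if n <= lag_max:
        raise SequenceLengthError(
            f"sequence length {n} is too short for lag_max={lag_max}; "
            f"minimum admissible length is {lag_max + 1}")
    E = encoded.matrix
    blocks = []
    for lag in range(1, lag_max + 1):
        # (5, 5) matrix of averaged lagged products: row j, column k holds
        # sum_i E_{j,i} E_{k,i+L} / (n - L); diagonal = auto terms.
        block = (E[:, : n - lag] @ E[:, lag:].T) / (n - lag)
        blocks.append(block.ravel())
    values = np.concatenate(blocks)
    return ACCVector(values=values, lag_max=lag_max,
                     ordering_tag=tag if tag is not None else f"acc-lagmajor-25:custom:lag{lag_max}")


def build_feature_matrix(records: list[ProteinRecord],
                         table: DescriptorTable | None = None,
                         lag_max: int = 8,
                         policy: str = "strict") -> LabeledDataset:
    """ACC-encode a list of records into a LabeledDataset.

    Row r of the matrix is ``acc_transform(encode_sequence(records[r]))``;
    input order is preserved and labels/ids are carried through.  Any record
    that fails encoding or the length rule contributes to one aggregated
    :class:`EncodingError` listing every offending record — nothing is
    silently dropped.  Labels must be all present or all absent.
    """
    if not records:
        raise ValueError("cannot build a feature matrix from an empty record list")
    table = table or default_descriptor_table()
    tag = ordering_tag(table, lag_max)

    rows: list[np.ndarray] = []
    failures: list[str] = []
    for rec in records:
        try:
            encoded = encode_sequence(rec.sequence, table, policy)
            rows.append(acc_transform(encoded, lag_max, tag=tag).values)
        except (EncodingError, SequenceLengthError) as exc:
            failures.append(f"{rec.id}: {exc}")
    if failures:
        raise EncodingError(
            "failed to encode %d record(s):\n  %s" % (len(failures), "\n  ".join(failures)))

    label_values = [rec.label for rec in records]
    if any(lbl is None for lbl in label_values):
        if not all(lbl is None for lbl in label_values):
            raise ValueError("records are partially labeled; label all or none")
        labels = None
    else:
        labels = np.array(label_values, dtype=int)

    return LabeledDataset(
        features=np.vstack(rows),
        labels=labels,
        ids=[rec.id for rec in records],
        feature_ordering_tag=tag,
    )
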