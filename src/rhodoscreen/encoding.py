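"""Physicochemical encoding of aligned rhodopsin sequences.

A rhodopsin's absorption maximum is largely tuned by the residues lining the
retinal-binding pocket.  This module turns an aligned sequence into a fixed
numeric representation: for each of ``N`` pocket alignment columns (24 by
default, given in bacteriorhodopsin numbering) the residue is looked up in a
table of ``M`` physicochemical scales (18 by default), and the values are
concatenated position-major into a length ``N * M`` vector (432 with the
default configuration).

The bundled pocket-position list and feature table are documented defaults of
widely used residue positions and amino-acid scales; both are plain TSV files
and can be replaced by study-specific configuration at run time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-X")

WAVELENGTH_RANGE = (300.0, 700.0)

GAP_POLICIES = ("error", "zero", "training_mean")


class AlignmentError(ValueError):
    """Raised for ragged alignments, duplicate ids or bad metadata."""


class EncodingError(ValueError):
    """Raised when a record cannot be encoded (gaps, unknown residues)."""


@dataclass(frozen=True)
class AlignedRecord:
    """One aligned sequence, optionally labelled with subfamily and λmax (nm)."""

    id: str
    aligned_seq: str
    subfamily: str | None = None
    lambda_max: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_max is not None:
            lo, hi = WAVELENGTH_RANGE
            if not np.isfinite(self.lambda_max) or not lo <= self.lambda_max <= hi:
                raise AlignmentError(
                    f"record {self.id!r}: lambda_max {self.lambda_max!r} outside "
                    f"[{lo:.0f}, {hi:.0f}] nm"
                )


@dataclass(frozen=True)
class PocketPositions:
    """Alignment columns of the retinal pocket (0-based, order preserved)."""

    columns: tuple[int, ...]
    reference_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("pocket columns contain duplicates")
        if any(c < 0 for c in self.columns):
            raise ValueError("pocket columns must be non-negative")

    def __len__(self) -> int:
        return len(self.columns)

    def validate_width(self, alignment_width: int) -> None:
        bad = [c for c in self.columns if c >= alignment_width]
        if bad:
            raise ValueError(
                f"pocket columns {bad} exceed alignment width {alignment_width}"
            )


@dataclass(frozen=True)
class FeatureTable:
    """Per-amino-acid values for M physicochemical scales."""

    feature_names: tuple[str, ...]
    values: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        m = len(self.feature_names)
        for aa in AMINO_ACIDS:
            if aa not in self.values:
                raise ValueError(f"feature table missing canonical residue {aa!r}")
        for aa, vec in self.values.items():
            if len(vec) != m or not np.all(np.isfinite(vec)):
                raise ValueError(f"feature table row {aa!r} malformed")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def lookup(self, aa: str) -> np.ndarray:
        try:
            return self.values[aa]
        except KeyError:
            raise EncodingError(f"residue {aa!r} absent from feature table") from None


@dataclass(frozen=True)
class EncodedSample:
    """Feature vector for one sequence, position-major: all M features of
    pocket position 1, then position 2, ..."""

    id: str
    x: np.ndarray
    lambda_max: float | None = None
    subfamily: str | None = None
    pocket_string: str | None = None
    standardizer_hash: str | None = None


@dataclass(frozen=True)
class Standardizer:
    """Per-coordinate z-scoring fitted on training encodings.

    Uses the population SD; coordinates with zero training variance get
    scale 1 and pass through centered.
    """

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise ValueError("standardizer scales must be strictly positive")

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.center, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.scale, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.center


# ---------------------------------------------------------------------------
# readers


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rhodoscreen.data") / name))


def read_alignment(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | None = None,
) -> list[AlignedRecord]:
    """Read an aligned FASTA, optionally joined with per-id metadata.

    The metadata table (TSV/CSV, header required) is keyed by ``id`` and may
    carry ``lambda_max`` and ``subfamily`` columns.  All sequences must have
    the same length; ragged input and duplicate ids are rejected.
    """
    seqs: dict[str, str] = {}
    width: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate sequence id {rec.id!r}")
        s = str(rec.seq).upper()
        if width is None:
            width = len(s)
        elif len(s) != width:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(s)}, expected {width}"
            )
        seqs[rec.id] = s
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")

    meta: dict[str, dict] = {}
    if metadata is not None:
        df = metadata if isinstance(metadata, pd.DataFrame) else _read_table(metadata)
        if "id" not in df.columns:
            raise AlignmentError("metadata table must have an 'id' column")
        unknown = set(df["id"].astype(str)) - set(seqs)
        if unknown:
            raise AlignmentError(f"metadata ids not in alignment: {sorted(unknown)}")
        for _, row in df.iterrows():
            entry: dict = {}
            if "lambda_max" in df.columns and pd.notna(row["lambda_max"]):
                try:
                    entry["lambda_max"] = float(row["lambda_max"])
                except (TypeError, ValueError):
                    raise AlignmentError(
                        f"non-numeric lambda_max for id {row['id']!r}"
                    ) from None
            if "subfamily" in df.columns and pd.notna(row["subfamily"]):
                entry["subfamily"] = str(row["subfamily"])
            meta[str(row["id"])] = entry

    return [
        AlignedRecord(id=sid, aligned_seq=s, **meta.get(sid, {}))
        for sid, s in seqs.items()
    ]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_feature_table(path: str | Path | None = None) -> FeatureTable:
    """Read an amino-acid × scales table (rows: residue, columns: scales).

    With no path, the bundled default of 18 standard physicochemical scales
    is used.
    """
    if path is None:
        path = _data_path("feature_table.tsv")
    df = _read_table(path)
    aa_col = df.columns[0]
    names = tuple(df.columns[1:])
    values = {
        str(row[aa_col]).upper(): np.asarray(row[1:], dtype=float)
        for _, row in df.iterrows()
    }
    return FeatureTable(feature_names=names, values=values)


def read_pocket_positions(
    path: str | Path | None = None,
    reference: AlignedRecord | None = None,
) -> PocketPositions:
    """Read pocket positions from a one-column table.

    The header keyword fixes the convention: ``column0`` (raw 0-based
    alignment columns), ``column1`` (raw 1-based columns), or ``br_position``
    (1-based residue numbers on an ungapped reference sequence, converted to
    alignment columns through ``reference`` — required in that case).  The
    bundled default file lists 24 BR-numbered pocket residues.
    """
    if path is None:
        path = _data_path("pocket_positions.tsv")
    df = _read_table(path)
    header = df.columns[0].strip().lower()
    raw = [int(v) for v in df.iloc[:, 0]]
    labels = tuple(str(v) for v in raw)
    if header == "column0":
        cols = tuple(raw)
    elif header == "column1":
        cols = tuple(v - 1 for v in raw)
    elif header == "br_position":
        if reference is None:
            raise ValueError(
                "br_position pocket files need a reference AlignedRecord to map "
                "residue numbering onto alignment columns"
            )
        cols = tuple(residue_to_column(reference, v) for v in raw)
    else:
        raise ValueError(
            f"unrecognised pocket header {header!r}; expected column0, column1 "
            "or br_position"
        )
    return PocketPositions(columns=cols, reference_labels=labels)


def residue_to_column(reference: AlignedRecord, residue_number: int) -> int:
    """Map a 1-based ungapped residue number on ``reference`` to the 0-based
    alignment column it occupies."""
    n = 0
    for col, ch in enumerate(reference.aligned_seq):
        if ch != "-":
            n += 1
            if n == residue_number:
                return col
    raise ValueError(
        f"reference {reference.id!r} has only {n} residues; "
        f"residue {residue_number} out of range"
    )


def read_base_wavelengths(path: str | Path | None = None) -> dict[str, float]:
    """Subfamily → base wavelength (nm) map; bundled default carries the
    representative wavelengths of the seven ion-pump subfamilies."""
    if path is None:
        path = _data_path("base_wavelengths.tsv")
    df = _read_table(path)
    out = {}
    lo, hi = WAVELENGTH_RANGE
    for _, row in df.iterrows():
        lb = float(row.iloc[1])
        if not lo <= lb <= hi:
            raise ValueError(f"base wavelength {lb} for {row.iloc[0]!r} out of range")
        out[str(row.iloc[0])] = lb
    return out


# ---------------------------------------------------------------------------
# encoding


def pocket_string(record: AlignedRecord, pocket: PocketPositions) -> str:
    return "".join(record.aligned_seq[c] for c in pocket.columns)


def encode(
    record: AlignedRecord,
    pocket: PocketPositions,
    table: FeatureTable,
    gap_policy: str = "error",
    fill_values: np.ndarray | None = None,
) -> EncodedSample:
    """Encode one aligned record into its pocket feature vector.

    ``x[M*i + j]`` is scale ``j`` of the residue at pocket column ``i``.  A
    gap or 'X' at a pocket column is handled per ``gap_policy``: ``error``
    rejects the record, ``zero`` writes zeros for that position's features,
    ``training_mean`` copies the corresponding entries of ``fill_values``
    (coordinate means of the encoded training set).
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    pocket.validate_width(len(record.aligned_seq))
    m = table.n_features
    x = np.empty(m * len(pocket), dtype=float)
    for i, col in enumerate(pocket.columns):
        aa = record.aligned_seq[col]
        if aa in GAP_CHARS:
            if gap_policy == "error":
                raise EncodingError(
                    f"record {record.id!r}: gap/unknown residue {aa!r} at pocket "
                    f"column {col} (pocket position {i})"
                )
            if gap_policy == "zero":
                x[m * i : m * (i + 1)] = 0.0
            else:
                if fill_values is None:
                    raise EncodingError(
                        "gap_policy='training_mean' requires fill_values"
                    )
                x[m * i : m * (i + 1)] = fill_values[m * i : m * (i + 1)]
        else:
            x[m * i : m * (i + 1)] = table.lookup(aa)
    if not np.all(np.isfinite(x)):
        raise EncodingError(f"record {record.id!r}: non-finite encoding")
    return EncodedSample(
        id=record.id,
        x=x,
        lambda_max=record.lambda_max,
        subfamily=record.subfamily,
        pocket_string=pocket_string(record, pocket),
    )


def encode_dataset(
    records: Iterable[AlignedRecord],
    pocket: PocketPositions,
    table: FeatureTable,
    gap_policy: str = "error",
    fill_values: np.ndarray | None = None,
    on_error: str = "raise",
) -> list[EncodedSample]:
    """Encode many records; ``on_error='skip'`` drops un-encodable records
    (pipeline mode) instead of raising."""
    out = []
    for rec in records:
        try:
            out.append(encode(rec, pocket, table, gap_policy, fill_values))
        except EncodingError:
            if on_error == "raise":
                raise
    return out


def fit_standardizer(samples: Sequence[EncodedSample]) -> Standardizer:
    """Fit per-coordinate center/scale (population SD) on training samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit a standardizer")
    X = np.stack([s.x for s in samples])
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD, ddof=0
    scale = np.where(scale > 0, scale, 1.0)
    return Standardizer(center=center, scale=scale)


def apply_standardizer(
    standardizer: Standardizer, samples: Sequence[EncodedSample]
) -> list[EncodedSample]:
    h = standardizer.hash
    return [
        replace(s, x=standardizer.transform(s.x), standardizer_hash=h)
        for s in samples
    ]


def encoded_to_frame(samples: Sequence[EncodedSample]) -> pd.DataFrame:
    """Tabulate encoded samples (one row per sample, x_0001.. columns)."""
    if not samples:
        return pd.DataFrame()
    d = len(samples[0].x)
    cols = [f"x_{j + 1:04d}" for j in range(d)]
    df = pd.DataFrame([s.x for s in samples], columns=cols)
    df.insert(0, "id", [s.id for s in samples])
    df.insert(1, "subfamily", [s.subfamily for s in samples])
    df.insert(2, "lambda_max", [s.lambda_max for s in samples])
    return df


def frame_to_encoded(df: pd.DataFrame) -> list[EncodedSample]:
    xcols = [c for c in df.columns if c.startswith("x_")]
    out = []
    for _, row in df.iterrows():
        lam = row.get("lambda_max")
        sub = row.get("subfamily")
        out.append(
            EncodedSample(
                id=str(row["id"]),
                x=np.asarray(row[xcols], dtype=float),
                lambda_max=None if pd.isna(lam) else float(lam),
                subfamily=None if pd.isna(sub) else str(sub),
            )
        )
    return out
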