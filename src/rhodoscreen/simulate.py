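"""Synthetic aligned-sequence datasets with known sparse linear ground truth.

The generator emulates the statistical structure the screening model
assumes: pocket residues drawn from column-specific amino-acid
distributions (so encoded features are non-degenerate and correlated within
a position), filler columns the model never sees, and wavelengths generated
from a sparse linear model on the standardized pocket features plus
Gaussian noise.  It writes files in exactly the formats the encoding reader
accepts, so every downstream module is testable end to end without any
external download.

The bundled Table-1 outcomes of the 39 experimentally expressed rhodopsins
are exposed through :func:`table1_fixture` for the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    AMINO_ACIDS,
    AlignedRecord,
    EncodedSample,
    FeatureTable,
    PocketPositions,
    Standardizer,
    _data_path,
    apply_standardizer,
    encode_dataset,
    fit_standardizer,
    read_feature_table,
)
from .evaluation import ScreenOutcome, read_outcomes

_DEFAULT_OFFSETS = {"simA": -5.0, "simB": 0.0, "simC": 5.0}


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs of the generator; defaults mirror the screening problem's shape
    (24 pocket positions × 18 features = 432 coefficients, λ intercept in the
    green-absorbing range, nm-scale effects and noise)."""

    n_train: int = 300
    n_candidates: int = 50
    n_pocket_positions: int = 24
    n_features: int = 18
    n_nonzero_coefficients: int = 10
    coefficient_scale: float = 10.0  # nm per standardized unit
    noise_sd: float = 5.0  # nm
    intercept: float = 540.0  # nm
    n_filler_columns: int = 30
    alphabet_per_column: int = 6
    subfamily_base_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonzero_coefficients > self.n_pocket_positions * self.n_features:
            raise ValueError("more nonzero coefficients than coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_train < 2:
            raise ValueError("need at least 2 training records")


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters, on the standardized feature scale."""

    true_mu: float
    true_beta: np.ndarray
    noiseless_lambda: dict[str, float]
    support: tuple[int, ...]


@dataclass(frozen=True)
class SimulatedDataset:
    train_records: tuple[AlignedRecord, ...]
    candidate_records: tuple[AlignedRecord, ...]
    pocket: PocketPositions
    feature_table: FeatureTable
    standardizer: Standardizer
    train_encoded: tuple[EncodedSample, ...]
    candidate_encoded: tuple[EncodedSample, ...]
    base_wavelengths: dict[str, float]
    ground_truth: GroundTruth
    spec: SimulationSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA + metadata + pocket + feature-table + base-wavelength
        files in the formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "train_fasta": outdir / "train.fasta",
            "train_meta": outdir / "train_meta.tsv",
            "candidates_fasta": outdir / "candidates.fasta",
            "candidates_meta": outdir / "candidates_meta.tsv",
            "pocket": outdir / "pocket.tsv",
            "features": outdir / "features.tsv",
            "base": outdir / "base_wavelengths.tsv",
        }
        _write_fasta(self.train_records, paths["train_fasta"])
        pd.DataFrame(
            {
                "id": [r.id for r in self.train_records],
                "lambda_max": [r.lambda_max for r in self.train_records],
                "subfamily": [r.subfamily for r in self.train_records],
            }
        ).to_csv(paths["train_meta"], sep="\t", index=False)
        _write_fasta(self.candidate_records, paths["candidates_fasta"])
        pd.DataFrame(
            {
                "id": [r.id for r in self.candidate_records],
                "subfamily": [r.subfamily for r in self.candidate_records],
            }
        ).to_csv(paths["candidates_meta"], sep="\t", index=False)
        pd.DataFrame({"column0": list(self.pocket.columns)}).to_csv(
            paths["pocket"], sep="\t", index=False
        )
        ft = pd.DataFrame(
            {aa: self.feature_table.values[aa] for aa in AMINO_ACIDS},
            index=list(self.feature_table.feature_names),
        ).T
        ft.index.name = "aa"
        ft.to_csv(paths["features"], sep="\t")
        pd.DataFrame(
            {
                "subfamily": list(self.base_wavelengths),
                "lambda_base_nm": list(self.base_wavelengths.values()),
            }
        ).to_csv(paths["base"], sep="\t", index=False)
        return paths


def _write_fasta(records: Sequence[AlignedRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.aligned_seq}\n")


def simulate_dataset(spec: SimulationSpec | None = None) -> SimulatedDataset:
    """Generate a dataset with known sparse linear ground truth.

    Pocket columns each use a private alphabet of ``alphabet_per_column``
    residues with Dirichlet-weighted frequencies; filler columns are uniform
    over all twenty residues and carry no signal.  λmax is
    ``intercept + Σ_s coefficient_scale·sign_s·z_s + N(0, noise_sd²)`` over
    the sampled support, where z are standardized encoded features, so
    refitting the emitted files reproduces the truth.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)

    table = _simulation_feature_table(spec.n_features)
    n_cols = spec.n_pocket_positions + spec.n_filler_columns
    pocket_cols = np.sort(
        rng.choice(n_cols, size=spec.n_pocket_positions, replace=False)
    )
    pocket = PocketPositions(columns=tuple(int(c) for c in pocket_cols))

    # column-specific residue distributions for pocket columns
    aa = np.array(list(AMINO_ACIDS))
    col_alphabets = [
        rng.choice(20, size=spec.alphabet_per_column, replace=False)
        for _ in range(spec.n_pocket_positions)
    ]
    col_weights = [
        rng.dirichlet(np.full(spec.alphabet_per_column, 2.0))
        for _ in range(spec.n_pocket_positions)
    ]

    def draw_seq() -> str:
        chars = rng.choice(aa, size=n_cols)
        for i, col in enumerate(pocket.columns):
            chars[col] = aa[rng.choice(col_alphabets[i], p=col_weights[i])]
        return "".join(chars)

    subfams = list(spec.subfamily_base_offsets)
    train_plain = [
        AlignedRecord(
            id=f"train_{k:04d}",
            aligned_seq=draw_seq(),
            subfamily=subfams[k % len(subfams)] if subfams else None,
        )
        for k in range(spec.n_train)
    ]
    cand_plain = [
        AlignedRecord(
            id=f"cand_{k:04d}",
            aligned_seq=draw_seq(),
            subfamily=subfams[k % len(subfams)] if subfams else None,
        )
        for k in range(spec.n_candidates)
    ]

    enc_train = encode_dataset(train_plain, pocket, table)
    std = fit_standardizer(enc_train)
    z_train = apply_standardizer(std, enc_train)
    Z = np.stack([s.x for s in z_train])

    p = spec.n_pocket_positions * spec.n_features
    informative = np.flatnonzero(Z.std(axis=0) > 1e-9)
    if len(informative) < spec.n_nonzero_coefficients:
        raise ValueError("too few non-degenerate coordinates for the support")
    support = np.sort(
        rng.choice(informative, size=spec.n_nonzero_coefficients, replace=False)
    )
    beta = np.zeros(p)
    beta[support] = spec.coefficient_scale * rng.choice(
        [-1.0, 1.0], size=spec.n_nonzero_coefficients
    )

    noiseless = spec.intercept + Z @ beta
    lam = noiseless + rng.normal(0.0, spec.noise_sd, size=spec.n_train)
    lam = np.clip(lam, 300.0, 700.0)

    train_records = tuple(
        AlignedRecord(
            id=r.id,
            aligned_seq=r.aligned_seq,
            subfamily=r.subfamily,
            lambda_max=float(v),
        )
        for r, v in zip(train_plain, lam)
    )
    # re-encode with wavelengths attached
    enc_train = encode_dataset(train_records, pocket, table)
    z_train = apply_standardizer(std, enc_train)
    enc_cand = encode_dataset(cand_plain, pocket, table)
    z_cand = apply_standardizer(std, enc_cand)

    base = {
        sf: spec.intercept + off for sf, off in spec.subfamily_base_offsets.items()
    }
    truth = GroundTruth(
        true_mu=spec.intercept,
        true_beta=beta,
        noiseless_lambda={r.id: float(v) for r, v in zip(train_plain, noiseless)},
        support=tuple(int(s) for s in support),
    )
    return SimulatedDataset(
        train_records=train_records,
        candidate_records=tuple(cand_plain),
        pocket=pocket,
        feature_table=table,
        standardizer=std,
        train_encoded=tuple(z_train),
        candidate_encoded=tuple(z_cand),
        base_wavelengths=base,
        ground_truth=truth,
        spec=spec,
    )


def _simulation_feature_table(n_features: int) -> FeatureTable:
    """The bundled 18-scale table, truncated/extended to ``n_features`` so
    small-instance simulations still exercise the real encoder."""
    full = read_feature_table()
    if n_features == full.n_features:
        return full
    if n_features < full.n_features:
        return FeatureTable(
            feature_names=full.feature_names[:n_features],
            values={a: v[:n_features] for a, v in full.values.items()},
        )
    reps = -(-n_features // full.n_features)
    return FeatureTable(
        feature_names=tuple(
            f"{nm}_{r}" for r in range(reps) for nm in full.feature_names
        )[:n_features],
        values={a: np.tile(v, reps)[:n_features] for a, v in full.values.items()},
    )


def table1_fixture() -> list[ScreenOutcome]:
    """The 39 experimentally expressed candidates with their subfamily base
    wavelengths, expected gains at selection time and observed λmax."""
    return read_outcomes(_data_path("table1_screen.tsv"))
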