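"""Encode an aligned FASTA into pocket feature vectors.

Builds a small synthetic alignment on disk, reads it back with its λmax
metadata, extracts the pocket columns and prints the shape and the first
few standardized coordinates of the resulting design matrix.
"""

import tempfile
from pathlib import Path

import numpy as np

import rhodoscreen as rs

with tempfile.TemporaryDirectory() as tmp:
    ds = rs.simulate_dataset(
        rs.SimulationSpec(n_train=40, n_candidates=5, n_pocket_positions=8,
                          n_features=6, n_nonzero_coefficients=4, seed=0))
    paths = ds.write(Path(tmp))

    records = rs.read_alignment(paths["train_fasta"], paths["train_meta"])
    pocket = rs.read_pocket_positions(paths["pocket"])
    table = rs.read_feature_table(paths["features"])

    encoded = rs.encode_dataset(records, pocket, table)
    std = rs.fit_standardizer(encoded)
    z = rs.apply_standardizer(std, encoded)

    X = np.stack([s.x for s in z])
    print(f"{len(records)} aligned records, {len(pocket)} pocket columns, "
          f"{table.n_features} scales -> design matrix {X.shape}")
    print("first record:", z[0].id, "lambda_max =", f"{z[0].lambda_max:.1f} nm")
    print("first 6 standardized features:", np.round(X[0, :6], 3))

# Each row is one sequence; each block of M consecutive coordinates holds the
# physicochemical scale values of one pocket residue, z-scored on the
# training set so the global LASSO shrinkage acts on a common scale.
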