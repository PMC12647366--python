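"""Shared helpers: seeding, deterministic TSV output, small checks."""

from __future__ import annotations

import numpy as np
import pandas as pd

# All TSV output uses this float format so that reruns with the same seed are
# byte-identical across platforms.
FLOAT_FORMAT = "%.6g"


def rng_from_seed(seed) -> np.random.Generator:
    """Return a Generator from an int seed or pass an existing Generator through."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit integer seed is required for reproducibility")
    return np.random.default_rng(int(seed))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one parent seed."""
    rng = np.random.default_rng(int(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a DataFrame as deterministic TSV (fixed float format, LF endings)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def check_symmetric(M: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> None:
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=tol):
        raise ValueError(f"{name} must be square and symmetric")


def as_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    check_symmetric(D, "dissimilarity matrix")
    if np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return D
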