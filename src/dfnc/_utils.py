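"""Shared helpers: seeding, pair vectorization, small numerics."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *labels) -> int:
    """Derive a stage/subject child seed (< 2**31) deterministically.

    Labels are folded in through a process-independent CRC so the same
    (seed, labels) pair yields the same stream in every interpreter run.
    """
    key = [int(seed)] + [
        zlib.crc32(str(lab).encode("utf-8")) & 0x7FFFFFFF for lab in labels
    ]
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *labels))


def pair_index(n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the strict upper triangle, the canonical pair order."""
    return np.triu_indices(n_components, k=1)


def n_pairs(n_components: int) -> int:
    return n_components * (n_components - 1) // 2


def vec_upper(mat: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix."""
    i, j = pair_index(mat.shape[0])
    return mat[i, j]


def unvec_upper(vec: np.ndarray, n_components: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vec_upper`, producing a symmetric matrix."""
    m = np.full((n_components, n_components), diag, dtype=float)
    i, j = pair_index(n_components)
    m[i, j] = vec
    m[j, i] = vec
    return m


def fisher_z(r: np.ndarray | float, clamp: float = 1.0 - 1e-7):
    """Variance-stabilizing atanh transform with |r| clamped below 1."""
    r = np.clip(np.asarray(r, dtype=float), -clamp, clamp)
    return np.arctanh(r)


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise ValueError("covariance has non-positive diagonal")
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_spd_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite unit-diagonal matrix.

    Eigenvalue clipping followed by diagonal rescaling; adequate for
    constructing simulation correlation targets (not a Higham iteration).
    """
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    spd = (v * w) @ v.T
    return cov_to_corr(spd)
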