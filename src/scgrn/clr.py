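"""Mutual information and context likelihood of relatedness (CLR).

Regulator preselection scores each TF-gene pair by the mutual information of
their equal-width-binned joint distribution, then corrects for background by
z-scoring within the regulator row and the gene column, clamping negative
z-scores to zero, and combining as the root sum of squares (the canonical
Stouffer-like CLR).  Adding a constant to every MI entry leaves CLR scores
unchanged.
"""

from __future__ import annotations

import numpy as np


def _bin_columns(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin indices per column over each column's observed range."""
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    width = np.where(hi > lo, (hi - lo) / n_bins, 1.0)
    idx = np.floor((values - lo) / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def mutual_information_matrix(
    regulators: np.ndarray, genes: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """MI in bits between every regulator column and every gene column.

    ``regulators`` is samples x K, ``genes`` samples x G; returns K x G.
    Joint counts are accumulated through a one-hot matrix product so the
    whole matrix is a single BLAS call.
    """
    n = regulators.shape[0]
    if genes.shape[0] != n:
        raise ValueError("sample counts differ")
    if n < n_bins:
        raise ValueError("need at least n_bins samples")
    K, G = regulators.shape[1], genes.shape[1]
    ub = _bin_columns(regulators, n_bins)
    vb = _bin_columns(genes, n_bins)
    onehot_u = np.zeros((n, K * n_bins), dtype=np.float64)
    onehot_u[np.arange(n)[:, None], ub + np.arange(0, K * n_bins, n_bins)[None, :]] = 1.0
    onehot_v = np.zeros((n, G * n_bins), dtype=np.float64)
    onehot_v[np.arange(n)[:, None], vb + np.arange(0, G * n_bins, n_bins)[None, :]] = 1.0
    joint = onehot_u.T @ onehot_v  # (K*bins) x (G*bins)
    joint = joint.reshape(K, n_bins, G, n_bins).transpose(0, 2, 1, 3) / n  # K,G,bu,bv
    pu = joint.sum(axis=3)  # K,G,bu
    pv = joint.sum(axis=2)  # K,G,bv
    denom = pu[:, :, :, None] * pv[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / denom)
    mi = np.nansum(terms, axis=(2, 3))
    return np.maximum(mi, 0.0)


def mutual_information(u: np.ndarray, v: np.ndarray, n_bins: int = 10) -> float:
    """MI in bits between two sample vectors (equal-width binning)."""
    u = np.asarray(u, dtype=float).reshape(-1, 1)
    v = np.asarray(v, dtype=float).reshape(-1, 1)
    if u.shape[0] != v.shape[0]:
        raise ValueError("vectors must have equal length")
    return float(mutual_information_matrix(u, v, n_bins)[0, 0])


def clr_matrix(mi: np.ndarray) -> np.ndarray:
    """Background-corrected CLR scores from a TFs x genes MI matrix."""
    mi = np.asarray(mi, dtype=float)
    if not np.all(np.isfinite(mi)) or np.any(mi < 0):
        raise ValueError("MI matrix must be finite and non-negative")

    def _z(axis: int) -> np.ndarray:
        mean = mi.mean(axis=axis, keepdims=True)
        sd = mi.std(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (mi - mean) / sd, 0.0)
        return np.maximum(z, 0.0)

    zrow = _z(axis=1)  # standardized within each regulator row
    zcol = _z(axis=0)  # standardized within each gene column
    return np.sqrt(zrow**2 + zcol**2)
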