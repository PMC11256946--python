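"""Primitives of the linear mixing model of bulk gene expression.

A bulk transcriptome is modelled as a non-negative linear combination of
cell-type reference profiles, ``Y = X C + eps``, with ``X`` (genes x cell
types) the reference matrix, ``Y`` (genes x samples) the bulk matrix and
``C`` (cell types x samples) the cellular composition.  All profiles are
compared on the scale of per-gene fractions: every column of ``X`` and
``Y`` is normalized to sum to one, so that the entries of ``C`` (plus any
background weight) add up to roughly one per sample.

This module provides column normalization, the gene-weighted non-negative
least-squares estimator of ``C``, the naive (EPIC-style) estimate of the
hidden background proportion, and gene-wise rescaling of bulk data onto a
reference platform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "DegenerateInputError",
    "normalize_columns",
    "align_genes",
    "weighted_nnls",
    "naive_hidden_proportion",
    "rescale_bulk_to_reference",
]

#: absolute tolerance for "column sums to one"
NORMALIZATION_ATOL = 1e-8


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (e.g. an all-zero column)."""


def _column_labels(M, ncols: int):
    if isinstance(M, pd.DataFrame):
        return list(M.columns)
    return list(range(ncols))


def normalize_columns(M):
    """Normalize every column of a non-negative matrix to sum to one.

    Parameters
    ----------
    M : ndarray or DataFrame, shape (p, m)
        Non-negative matrix; columns are profiles (samples or cell types).

    Returns
    -------
    Same type as ``M`` with each column divided by its sum.

    Raises
    ------
    DegenerateInputError
        If any column sums to zero; the offending column is named.
    """
    values = np.asarray(M, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    if np.any(values < 0):
        raise ValueError("matrix must be non-negative")
    sums = values.sum(axis=0)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        labels = _column_labels(M, values.shape[1])
        raise DegenerateInputError(
            f"column(s) {[labels[i] for i in bad]} sum to zero and cannot be normalized"
        )
    out = values / sums
    if squeeze:
        out = out[:, 0]
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def align_genes(X: pd.DataFrame, Y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect reference and bulk frames on their gene index.

    Gene order follows ``X``.  Raises if the intersection is empty.
    """
    common = [g for g in X.index if g in set(Y.index)]
    if not common:
        raise DegenerateInputError("reference and bulk share no gene identifiers")
    return X.loc[common], Y.loc[common]


def weighted_nnls(X, Y, gamma=None) -> np.ndarray:
    """Gene-weighted non-negative least squares estimate of the composition.

    Solves, independently for each bulk column ``i``,

        min_{C_.i >= 0}  sum_j gamma_j (Y_ji - sum_k X_jk C_ki)^2

    Parameters
    ----------
    X : (p, q) array-like
        Reference matrix.
    Y : (p, n) array-like
        Bulk matrix with the same gene order as ``X``.
    gamma : (p,) array-like, optional
        Non-negative per-gene weights (squared gene weights, g_j^2).
        Defaults to all ones (plain NNLS).

    Returns
    -------
    C : (q, n) ndarray
        Non-negative composition estimates.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} genes but Y has {Y.shape[0]}; gene spaces must match"
        )
    p, q = X.shape
    n = Y.shape[1]
    if gamma is None:
        gamma = np.ones(p)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (p,):
        raise ValueError(f"gamma must have shape ({p},), got {gamma.shape}")
    if np.any(gamma < 0):
        raise ValueError("gamma must be non-negative")
    if not np.any(gamma > 0):
        warnings.warn(
            "all gene weights are zero; any composition is a minimizer, returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros((q, n))
    w = np.sqrt(gamma)
    A = X * w[:, None]
    B = Y * w[:, None]
    C = np.empty((q, n))
    for i in range(n):
        C[:, i], _ = nnls(A, B[:, i])
    return C


def naive_hidden_proportion(C_hat) -> np.ndarray:
    """EPIC-style hidden proportion: ``c_i = max(0, 1 - sum_k C_ki)``.

    On normalized data the composition entries of a fully characterised
    sample sum to one; any shortfall is attributed to cells not represented
    in the reference.
    """
    C_hat = np.asarray(C_hat, dtype=float)
    return np.maximum(0.0, 1.0 - C_hat.sum(axis=0))


def rescale_bulk_to_reference(Y_bulk, train_pseudobulk_mean, control_mean):
    """Gene-wise rescaling of a bulk matrix onto the reference platform.

    Each gene row of ``Y_bulk`` is multiplied by the ratio of its mean
    expression in reference-platform pseudo-bulks to its mean in control
    bulks of the target platform, compensating systematic cross-platform
    differences.  Genes whose control mean is zero cannot be rescaled and
    are dropped.

    Returns
    -------
    (Y_rescaled, kept, dropped)
        ``Y_rescaled`` contains only the kept gene rows (same type as the
        input); ``kept``/``dropped`` are integer index arrays into the
        original gene order.
    """
    values = np.asarray(Y_bulk, dtype=float)
    train_mean = np.asarray(train_pseudobulk_mean, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    p = values.shape[0]
    if train_mean.shape != (p,) or control_mean.shape != (p,):
        raise ValueError("mean vectors must match the bulk gene dimension")
    kept = np.flatnonzero(control_mean > 0)
    dropped = np.flatnonzero(control_mean <= 0)
    if dropped.size:
        warnings.warn(
            f"dropped {dropped.size} gene(s) with zero control mean during rescaling",
            RuntimeWarning,
            stacklevel=2,
        )
    factors = train_mean[kept] / control_mean[kept]
    out = values[kept] * factors[:, None]
    if isinstance(Y_bulk, pd.DataFrame):
        return (
            pd.DataFrame(out, index=Y_bulk.index[kept], columns=Y_bulk.columns),
            kept,
            dropped,
        )
    return out, kept, dropped
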