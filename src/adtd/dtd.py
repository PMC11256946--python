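"""Loss-function learning of gene weights for deconvolution (DTD).

Given training mixtures ``Y_train`` with known compositions ``C_train`` and
a reference matrix ``X``, learn a non-negative gene-weight vector ``g``
(unit L2 norm) such that the weighted non-negative least-squares estimate

    C_hat(g) = argmin_{C >= 0} || diag(g) (Y_train - X C) ||_F^2

maximizes the Pearson correlation between estimated and true compositions,
cell type by cell type.  The outer loss is

    L(g) = - sum_j cor(C_train[j, :], C_hat[j, :](g)),

so a perfect fit on q cell types attains -q.

Optimization strategy
---------------------
The loss is minimized over the squared weights ``gamma = g**2 >= 0`` (the
loss is invariant to the overall scale of gamma, so the unit-norm
constraint on g can be applied after the fact).  During optimization the
inner problem is replaced by its unconstrained weighted least-squares
solution, for which the gradient of the outer loss has a closed form; the
non-negativity of the inner fit is restored at evaluation time.  The best
iterate under the exact (non-negativity-constrained) outer loss is
returned, so the fitted weights never do worse than the uniform
initialization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import weighted_nnls

__all__ = ["outer_loss", "DTDModel", "DTDResults"]

logger = logging.getLogger(__name__)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two (q, n) matrices.

    Rows where either side has zero variance yield NaN.
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", Ac, Bc) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def outer_loss(g, X, Y_train, C_train) -> float:
    """Exact outer loss ``-sum_j cor(C_j, C_hat_j(g))`` with C_hat >= 0.

    The inner composition estimate uses the non-negativity-constrained
    weighted NNLS with per-gene weights ``gamma_j = g_j**2``.  Cell types
    whose true proportions are constant across the training mixtures are
    excluded (correlation undefined); an estimated row with zero variance
    contributes 0 and is logged.
    """
    g = np.asarray(g, dtype=float)
    X = np.asarray(X, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    C_train = np.asarray(C_train, dtype=float)
    C_hat = weighted_nnls(X, Y_train, g**2)
    r = _pearson_rows(C_train, C_hat)
    true_var = np.ptp(C_train, axis=1) > 0
    est_const = (np.isnan(r)) & true_var
    if np.any(est_const):
        logger.info(
            "outer_loss: %d estimated composition row(s) constant; contributing 0",
            int(est_const.sum()),
        )
    return -float(np.nansum(np.where(true_var, r, np.nan)))


@dataclass
class DTDResults:
    """Fitted gene weights and fit diagnostics."""

    gene_weights: np.ndarray  #: unit-L2, non-negative, length p
    loss: float  #: exact outer loss at the returned weights
    loss_init: float  #: exact outer loss at the uniform initialization
    n_active_celltypes: int  #: cell types with non-constant true proportions
    converged: bool
    n_iter: int
    message: str = ""
    gene_ids: list | None = None

    @property
    def gamma(self) -> np.ndarray:
        """Squared weights, the per-gene weighting of the NNLS residuals."""
        return self.gene_weights**2

    def summary(self) -> str:
        lines = [
            "DTD gene-weight learning",
            "=" * 40,
            f"genes:                  {self.gene_weights.size}",
            f"active cell types:      {self.n_active_celltypes}",
            f"outer loss (initial):   {self.loss_init:.6f}",
            f"outer loss (fitted):    {self.loss:.6f}",
            f"mean corr. per type:    {-self.loss / max(self.n_active_celltypes, 1):.4f}",
            f"converged:              {self.converged} ({self.n_iter} iterations)",
        ]
        if not self.converged and self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


@dataclass
class DTDModel:
    """Learn deconvolution gene weights from mixtures of known composition.

    Parameters
    ----------
    X : (p, q) array-like
        Reference matrix (column-normalized).
    Y_train : (p, n) array-like
        Training bulk mixtures, same gene order as ``X``.
    C_train : (q, n) array-like
        Known compositions of the training mixtures.  Needs at least
        ``q + 2`` mixtures and non-constant proportions per cell type for
        the correlation loss to be informative.
    """

    X: np.ndarray
    Y_train: np.ndarray
    C_train: np.ndarray
    gene_ids: list | None = None
    _active: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y_train = np.asarray(self.Y_train, dtype=float)
        self.C_train = np.asarray(self.C_train, dtype=float)
        p, q = self.X.shape
        if self.Y_train.shape[0] != p:
            raise ValueError("X and Y_train must share the gene dimension")
        n = self.Y_train.shape[1]
        if self.C_train.shape != (q, n):
            raise ValueError(f"C_train must have shape ({q}, {n})")
        if n < q + 2:
            raise ValueError(
                f"need at least q + 2 = {q + 2} training mixtures, got {n}"
            )
        self._active = np.ptp(self.C_train, axis=1) > 0
        if not np.all(self._active):
            dropped = int((~self._active).sum())
            logger.warning(
                "%d cell type(s) have constant training proportions and are "
                "excluded from the loss",
                dropped,
            )
        if not np.any(self._active):
            raise ValueError("every cell-type row of C_train is constant")

    # -- smooth surrogate used during optimization --------------------------

    def _surrogate_loss_grad(self, gamma: np.ndarray) -> tuple[float, np.ndarray]:
        """Loss and gradient using the unconstrained inner WLS solution."""
        X, Y, C = self.X, self.Y_train, self.C_train
        p, q = X.shape
        M = (X * gamma[:, None]).T @ X  # q x q
        # tiny jitter keeps M invertible when gamma is sparse
        M = M + 1e-12 * np.eye(q) * max(np.trace(M), 1.0)
        N = (X * gamma[:, None]).T @ Y  # q x n
        C_hat = np.linalg.solve(M, N)
        R = Y - X @ C_hat  # p x n residuals

        Cc = C - C.mean(axis=1, keepdims=True)
        Zc = C_hat - C_hat.mean(axis=1, keepdims=True)
        nu = np.linalg.norm(Cc, axis=1)
        nz = np.linalg.norm(Zc, axis=1)
        ok = self._active & (nz > 1e-300)
        loss = 0.0
        W = np.zeros_like(C_hat)  # dloss/dC_hat
        for k in np.flatnonzero(ok):
            u, z = Cc[k], Zc[k]
            a = float(u @ z)
            denom = nu[k] * nz[k]
            loss -= a / denom
            W[k] = -(u / denom - a * z / (nu[k] * nz[k] ** 2))
        S = np.linalg.solve(M, W)  # q x n  (M symmetric)
        grad = np.einsum("jk,jk->j", X, R @ S.T)
        return loss, grad

    # -- public fitting API --------------------------------------------------

    def fit(self, max_iter: int = 5000, tol: float = 1e-6, seed: int | None = None
            ) -> DTDResults:
        """Minimize the outer loss over non-negative gene weights.

        ``seed`` is accepted for interface stability; the optimizer is
        deterministic from its uniform initialization.
        """
        del seed  # deterministic fit
        p = self.X.shape[0]
        gamma0 = np.full(p, 1.0 / p)

        res = minimize(
            self._surrogate_loss_grad,
            gamma0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * p,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
        )
        # L-BFGS-B reports ABNORMAL when the line search hits float
        # precision; the monotone acceptance below makes that benign, so
        # only exhausting the iteration budget counts as non-convergence
        converged = bool(res.success) or int(res.nit) < max_iter
        if not converged:
            warnings.warn(
                f"gene-weight optimization stopped without convergence: {res.message}",
                RuntimeWarning,
                stacklevel=2,
            )
        elif not res.success:
            logger.info("gene-weight optimizer stopped early: %s", res.message)

        g_init = np.sqrt(gamma0)
        g_init /= np.linalg.norm(g_init)
        loss_init = outer_loss(g_init, self.X, self.Y_train, self.C_train)

        gamma_fit = np.maximum(res.x, 0.0)
        if gamma_fit.sum() <= 0:
            gamma_fit = gamma0
        g_fit = np.sqrt(gamma_fit)
        g_fit /= np.linalg.norm(g_fit)
        loss_fit = outer_loss(g_fit, self.X, self.Y_train, self.C_train)

        # monotone acceptance: never return weights worse than the start
        if loss_fit <= loss_init:
            g_best, loss_best = g_fit, loss_fit
        else:
            g_best, loss_best = g_init, loss_init

        return DTDResults(
            gene_weights=g_best,
            loss=loss_best,
            loss_init=loss_init,
            n_active_celltypes=int(self._active.sum()),
            converged=converged,
            n_iter=int(res.nit),
            message=str(res.message),
            gene_ids=self.gene_ids,
        )
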