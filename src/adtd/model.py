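"""Adaptive digital tissue deconvolution (ADTD).

Extends the weighted-NNLS mixing model in two directions, estimated
jointly from a set of bulk profiles:

* a single *hidden background profile* ``x`` (a point on the gene
  simplex) with a per-sample weight ``c_i``, capturing cellular
  contributions not represented by any reference column, and
* a multiplicative *rescaling matrix* ``Delta`` (genes x cell types)
  adapting the reference ``X`` to the analyzed tissue; entries deviating
  from 1 are read as cell-type-specific gene regulation.

The objective, with ``G = diag(g)`` the gene weights and ``A = Delta o X``
(Hadamard product),

    L(C, x, Delta) = || G (Y - A C - x (1_n' - 1_p' A C)) ||_F^2
                     + lambda1 ||C - C0||_F^2 + lambda2 ||J - Delta||_F^2

is minimized by block-coordinate descent over ``C`` (per-sample quadratic
programs with non-negativity and the budget constraint
``colsum(A C) <= 1``), ``x`` (an exactly solvable diagonal quadratic
program on the simplex), and the rows of ``Delta`` (small non-negative
least-squares problems).  ``C0`` is the plain weighted-NNLS composition
and anchors the solution; ``lambda1 -> inf`` reproduces the naive
pipeline, ``lambda2 -> inf`` freezes ``Delta`` at all ones.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import align_genes, normalize_columns, weighted_nnls

__all__ = [
    "adtd_loss",
    "solve_C_subproblem",
    "solve_x_subproblem",
    "solve_delta_row",
    "lambda2_for_group_size",
    "ADTDModel",
    "ADTDResults",
]

logger = logging.getLogger(__name__)


def lambda2_for_group_size(n_samples: int, base: float = 1e-5) -> float:
    """Group-size-scaled Delta penalty, ``base * n / 1000``.

    When several sample groups (e.g. disease subtypes) are fitted
    separately but their regulation estimates must be comparable, the
    Delta penalty is scaled with the group size so that the per-sample
    regularization pressure is constant across groups.
    """
    return base * n_samples / 1000.0


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def adtd_loss(C, x, Delta, X, Y, g, lambda1, lambda2, C0) -> float:
    """Evaluate the ADTD objective at ``(C, x, Delta)``.

    Infinite penalties are treated as hard constraints (``C = C0`` /
    ``Delta = J``) whose penalty term contributes zero.
    """
    C = np.asarray(C, dtype=float)
    x = np.asarray(x, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(g, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    p, q = X.shape
    n = Y.shape[1]
    if C.shape != (q, n) or x.shape != (p,) or Delta.shape != (p, q):
        raise ValueError("inconsistent shapes in adtd_loss")
    A = Delta * X
    AC = A @ C
    h = 1.0 - AC.sum(axis=0)  # hidden weights 1_n' - 1_p' A C
    R = (Y - AC - np.outer(x, h)) * g[:, None]
    loss = float(np.sum(R * R))
    if np.isfinite(lambda1):
        loss += lambda1 * float(np.sum((C - C0) ** 2))
    if np.isfinite(lambda2):
        loss += lambda2 * float(np.sum((1.0 - Delta) ** 2))
    return loss


# ---------------------------------------------------------------------------
# C update: per-sample QP with non-negativity and budget constraint
# ---------------------------------------------------------------------------

def _eq_constrained_nnls(B: np.ndarray, d: np.ndarray, a: np.ndarray) -> np.ndarray:
    """min ||B c - d||^2  s.t.  a'c = 1, c >= 0, by active-set enumeration.

    Exact for the small q of deconvolution problems: the optimum is the
    best feasible stationary point over subsets of free coordinates.
    """
    q = B.shape[1]
    if q > 14:  # enumeration would explode; unreachable for realistic q
        raise ValueError("equality-constrained NNLS limited to q <= 14")
    best_c, best_obj = None, np.inf
    BtB = B.T @ B
    Btd = B.T @ d
    for free in itertools.chain.from_iterable(
        itertools.combinations(range(q), r) for r in range(1, q + 1)
    ):
        F = list(free)
        aF = a[F]
        if not np.any(aF != 0):
            continue
        k = len(F)
        KKT = np.zeros((k + 1, k + 1))
        KKT[:k, :k] = 2.0 * BtB[np.ix_(F, F)]
        KKT[:k, k] = aF
        KKT[k, :k] = aF
        rhs = np.concatenate([2.0 * Btd[F], [1.0]])
        try:
            sol = np.linalg.solve(KKT, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
        cF = sol[:k]
        if np.any(cF < -1e-10):
            continue
        c = np.zeros(q)
        c[F] = np.maximum(cF, 0.0)
        s = float(a @ c)
        if s > 0:
            c /= s  # exact equality after clipping round-off
        r = B @ c - d
        obj = float(r @ r)
        if obj < best_obj:
            best_obj, best_c = obj, c
    if best_c is None:  # a == 0: constraint unsatisfiable, fall back to NNLS
        best_c, _ = nnls(B, d)
    return best_c


def solve_C_subproblem(Y, X_eff, x, g, lambda1, C0, budget: float = 1.0
                       ) -> np.ndarray:
    """Exact per-sample minimization of the loss over ``C``.

    With ``A = X_eff`` and ``a = A' 1_p`` (effective column sums), each
    sample solves

        min_{c >= 0, a'c <= 1} ||G[(y - x) - (A - x a')c]||^2
                               + lambda1 ||c - c0||^2.

    The unconstrained-budget NNLS solution is accepted when it satisfies
    the budget; otherwise the budget is active and the equality-constrained
    problem is solved exactly.
    """
    Y = np.asarray(Y, dtype=float)
    X_eff = np.asarray(X_eff, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    if not np.isfinite(lambda1):
        raise ValueError("solve_C_subproblem requires finite lambda1 "
                         "(infinite lambda1 fixes C = C0)")
    p, q = X_eff.shape
    n = Y.shape[1]
    a = X_eff.sum(axis=0)
    B = (X_eff - np.outer(x, a)) * g[:, None]
    sl = np.sqrt(lambda1)
    Bs = np.vstack([B, sl * np.eye(q)])
    D = (Y - x[:, None]) * g[:, None]
    C = np.empty((q, n))
    for i in range(n):
        d = np.concatenate([D[:, i], sl * C0[:, i]])
        c, _ = nnls(Bs, d)
        if float(a @ c) > budget + 1e-9:
            c = _eq_constrained_nnls(Bs, d, a / budget)
        C[:, i] = c
    return C


# ---------------------------------------------------------------------------
# x update: diagonal QP on the probability simplex, solved exactly
# ---------------------------------------------------------------------------

def solve_x_subproblem(Y, X_eff, C, g) -> np.ndarray:
    """Exact minimization of the residual term over the background profile.

    With hidden weights ``h_i = 1 - colsum(X_eff C)_i`` the objective in
    ``x`` is separable per gene,

        sum_j [ (sum_i h_i^2) g_j^2 x_j^2 - 2 g_j^2 (sum_i h_i r_ji) x_j ],

    a diagonal quadratic program on the simplex solved by bisection on
    the dual variable of the sum constraint (exact water-filling).
    When no sample carries hidden mass the profile is unidentifiable and
    the uniform profile is returned with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    X_eff = np.asarray(X_eff, dtype=float)
    C = np.asarray(C, dtype=float)
    g = np.asarray(g, dtype=float)
    p = Y.shape[0]
    AC = X_eff @ C
    h = 1.0 - AC.sum(axis=0)
    hh = float(h @ h)
    g2 = g**2
    if hh <= 1e-14 or not np.any(g2 > 0):
        warnings.warn(
            "all hidden weights are (near) zero; background profile is "
            "unidentifiable, returning the uniform profile",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(p, 1.0 / p)
    w = hh * g2
    b = g2 * ((Y - AC) @ h)
    pos = w > 0
    x = np.zeros(p)
    x[pos] = _simplex_diag_qp(w[pos], b[pos])
    return x


def _simplex_diag_qp(w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min sum_j w_j x_j^2 - 2 b_j x_j  s.t.  x >= 0, sum x = 1 (w > 0)."""
    lo = float(np.min(b - w))
    hi = float(np.max(b))

    def mass(mu):
        return np.sum(np.maximum(0.0, (b - mu) / w))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mass(mid) > 1.0:
            lo = mid
        else:
            hi = mid
    mu = 0.5 * (lo + hi)
    x = np.maximum(0.0, (b - mu) / w)
    s = x.sum()
    if s <= 0:  # numerically empty support: put mass on the best gene
        x = np.zeros_like(w)
        x[int(np.argmax(b / w))] = 1.0
        return x
    return x / s


# ---------------------------------------------------------------------------
# Delta update: one non-negative row at a time
# ---------------------------------------------------------------------------

def _delta_row_qp(P: np.ndarray, qvec: np.ndarray) -> np.ndarray:
    """min d' P d + 2 q'd  s.t.  d >= 0, via a Cholesky-to-NNLS reduction."""
    qdim = P.shape[0]
    jitter = 1e-12 * max(np.trace(P), 1.0)
    for _ in range(3):
        try:
            R = np.linalg.cholesky(P + jitter * np.eye(qdim)).T
            break
        except np.linalg.LinAlgError:
            jitter *= 1e3
    z = np.linalg.solve(R.T, -qvec)
    d, _ = nnls(R, z)
    return d


def _delta_row_terms(k, Y, X, C, x, g, AC_row_k, c_bar, T, G2X2):
    """Quadratic coefficients (P without lambda2, qvec without lambda2) of
    the loss restricted to Delta row ``k``; see solve_delta_row."""
    g2 = g**2
    M = C * X[k][:, None]  # q x n, M_li = X_kl C_li
    alpha = (G2X2 - g2[k] * x[k] ** 2) + g2[k] * (1.0 - x[k]) ** 2
    b_k = Y[k] - x[k] * c_bar
    # sum_{j != k} g_j^2 x_j b_ji  =  T_i - g_k^2 x_k (Y_ki - AC_ki)
    #                                - (G2X2 - g_k^2 x_k^2) c_bar_i
    s = T - g2[k] * x[k] * (Y[k] - AC_row_k) - (G2X2 - g2[k] * x[k] ** 2) * c_bar
    beta = s - g2[k] * (1.0 - x[k]) * b_k
    P = alpha * (M @ M.T)
    qvec = M @ beta
    return P, qvec, M


def _constrained_delta_row(P, qvec, M, b, old, unconstrained):
    """Row update under the budget couplings ``delta' M_i <= b_i``.

    Tries an exact-gradient SLSQP solve warm-started from the feasible
    current row; falls back to a convex line search from ``old`` toward
    the unconstrained optimum.  The returned row is feasible and never
    has a larger row objective than ``old`` (monotone sweep guarantee).
    """
    from scipy.optimize import minimize as _minimize

    def obj(d):
        return float(d @ P @ d + 2.0 * (qvec @ d))

    def jac(d):
        return 2.0 * (P @ d) + 2.0 * qvec

    cons = {"type": "ineq", "fun": lambda d: b - d @ M,
            "jac": lambda d: -M.T}
    res = _minimize(obj, old, jac=jac, method="SLSQP",
                    bounds=[(0.0, None)] * P.shape[0], constraints=[cons],
                    options={"maxiter": 200, "ftol": 1e-16})
    candidates = []
    if res.x is not None:
        d = np.maximum(res.x, 0.0)
        if np.all(d @ M - b <= 1e-9):
            candidates.append(d)
    # line search old -> unconstrained optimum, clipped to the feasible set
    step = unconstrained - old
    sM = step @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        tmax = np.where(sM > 0, (b - old @ M) / sM, np.inf)
    t = float(min(1.0, max(0.0, np.min(tmax))))
    candidates.append(old + t * step)
    best = min(candidates, key=obj)
    return best if obj(best) <= obj(old) else old


def solve_delta_row(k, Y, X, C, x, g, lambda2, Delta) -> np.ndarray:
    """Exact minimization of the loss over row ``k`` of ``Delta``.

    All other rows are held fixed.  Writing ``delta`` for the row, the
    residual of every gene is affine in ``delta`` (through the hidden
    weights ``h_i``, which couple all genes), so the restricted problem is
    a non-negative quadratic program in q variables solved exactly.
    The budget constraint is not enforced here; it is restored by the
    following C update (and holds at convergence).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if not np.isfinite(lambda2):
        return np.ones(X.shape[1])
    A = Delta * X
    AC = A @ C
    c_full = 1.0 - AC.sum(axis=0)
    c_bar = c_full + AC[k]  # hidden weights with row k's contribution removed
    g2x = g**2 * x
    T = g2x @ (Y - AC)
    # T above subtracts the *current* row-k contribution; terms helper corrects
    G2X2 = float(np.sum(g**2 * x**2))
    P, qvec, _ = _delta_row_terms(k, Y, X, C, x, g, AC[k], c_bar, T, G2X2)
    P = P + lambda2 * np.eye(X.shape[1])
    qvec = qvec - lambda2 * np.ones(X.shape[1])
    return _delta_row_qp(P, qvec)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class ADTDResults:
    """Solution of the ADTD optimization.

    Attributes
    ----------
    C : (q, n) ndarray
        Estimated compositions of the reference cell types.
    x : (p,) ndarray
        Hidden background profile (on the gene simplex).
    Delta : (p, q) ndarray
        Reference rescaling factors; deviation from 1 indicates
        cell-type-specific regulation.
    hidden_weights : (n,) ndarray
        Per-sample background weights, clipped to [0, 1]; the raw values
        are kept in ``hidden_weights_raw``.
    """

    C: np.ndarray
    x: np.ndarray
    Delta: np.ndarray
    hidden_weights: np.ndarray
    hidden_weights_raw: np.ndarray
    C0: np.ndarray
    loss_trace: np.ndarray  #: objective after each outer iteration
    block_loss_trace: list  #: (stage, loss) after every block update
    converged: bool
    n_iter: int
    gene_weights: np.ndarray
    lambda1: float
    lambda2: float
    gene_ids: list | None = None
    celltype_ids: list | None = None
    sample_ids: list | None = None

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])

    def constraint_report(self, tol: float = 1e-6) -> dict:
        """Residuals of the constraint set at the returned solution."""
        colsum = (self.Delta * self._X_cache @ self.C).sum(axis=0) \
            if hasattr(self, "_X_cache") else None
        return {
            "min_C": float(self.C.min()),
            "min_x": float(self.x.min()),
            "sum_x_minus_1": float(self.x.sum() - 1.0),
            "min_Delta": float(self.Delta.min()),
            "max_budget": None if colsum is None else float(colsum.max()),
            "tol": tol,
        }

    def composition_frame(self) -> pd.DataFrame:
        idx = self.celltype_ids or list(range(self.C.shape[0]))
        cols = self.sample_ids or list(range(self.C.shape[1]))
        return pd.DataFrame(self.C, index=idx, columns=cols)

    def summary(self) -> str:
        p, q = self.Delta.shape
        n = self.C.shape[1]
        dev = np.abs(self.Delta - 1.0).max(axis=1)
        top = np.argsort(-dev)[:5]
        gid = self.gene_ids or [f"gene{j}" for j in range(p)]
        lines = [
            "Adaptive digital tissue deconvolution",
            "=" * 46,
            f"genes: {p}   cell types: {q}   samples: {n}",
            f"lambda1 = {self.lambda1:g}   lambda2 = {self.lambda2:g}",
            f"converged: {self.converged} after {self.n_iter} iterations",
            f"final loss: {self.loss:.6e}",
            f"mean hidden weight: {self.hidden_weights.mean():.4f}",
            "top |Delta - 1| genes: "
            + ", ".join(f"{gid[j]} ({dev[j]:.3f})" for j in top),
        ]
        return "\n".join(lines)


class ADTDModel:
    """Deconvolve bulk profiles with hidden background and adaptive reference.

    Parameters
    ----------
    Y : (p, n) array-like or DataFrame
        Bulk expression matrix (genes x samples).  Columns are normalized
        to sum to one internally.
    X : (p, q) array-like or DataFrame
        Reference matrix (genes x cell types), normalized internally.
        DataFrames are intersected with ``Y`` on their gene index (order
        follows ``X``).
    gene_weights : (p,) array-like, optional
        Non-negative gene weights ``g`` (normalized to unit L2 norm);
        uniform if omitted.  Typically learned with :class:`~adtd.dtd.DTDModel`.
    lambda1 : float, default 0.1
        Anchor penalty toward the plain weighted-NNLS composition ``C0``;
        ``inf`` fixes ``C = C0`` (naive limit).
    lambda2 : float, default 1e-8
        Penalty of deviations of ``Delta`` from 1; ``inf`` (or
        ``adapt_reference=False``) freezes ``Delta`` at all ones.
    adapt_reference : bool, default True
        Whether to adapt the reference via ``Delta``.
    max_iter : int, default 1000
        Maximum number of outer block-coordinate iterations.
    tol : float, default 1e-7
        Relative loss-change convergence threshold.
    n_starts : int, default 1
        Number of starts of the block-coordinate descent.  The first is
        the canonical deterministic start (budget-projected naive
        composition, all-ones ``Delta``, uniform background); additional
        starts are random (seeded by ``seed``) and the lowest-loss
        solution is returned.  The objective is non-convex, so extra
        starts guard against poor local minima on small problems.
    seed : int, optional
        Seed for the random restarts (ignored when ``n_starts == 1``).
    """

    def __init__(self, Y, X, gene_weights=None, lambda1: float = 0.1,
                 lambda2: float = 1e-8, adapt_reference: bool = True,
                 max_iter: int = 1000, tol: float = 1e-7,
                 n_starts: int = 1, seed: int | None = None):
        if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
            X, Y = align_genes(X, Y)
            self.gene_ids = list(X.index)
            self.celltype_ids = list(X.columns)
            self.sample_ids = list(Y.columns)
        else:
            self.gene_ids = list(X.index) if isinstance(X, pd.DataFrame) else None
            self.celltype_ids = (
                list(X.columns) if isinstance(X, pd.DataFrame) else None
            )
            self.sample_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the gene dimension")
        self.X = normalize_columns(X)
        self.Y = normalize_columns(Y)
        p = X.shape[0]
        if gene_weights is None:
            g = np.full(p, 1.0 / np.sqrt(p))
        else:
            g = np.asarray(gene_weights, dtype=float)
            if g.shape != (p,):
                raise ValueError(f"gene_weights must have shape ({p},)")
            if np.any(g < 0):
                raise ValueError("gene_weights must be non-negative")
            nrm = np.linalg.norm(g)
            if nrm <= 0:
                raise ValueError("gene_weights must not be all zero")
            g = g / nrm
        self.g = g
        if lambda1 < 0 or lambda2 < 0:
            raise ValueError("penalties must be non-negative")
        self.lambda1 = float(lambda1)
        self.lambda2 = float("inf") if not adapt_reference else float(lambda2)
        self.adapt_reference = adapt_reference and np.isfinite(self.lambda2)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.n_starts = int(n_starts)
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        self.seed = seed
        if (np.isfinite(self.lambda1) and self.lambda1 < 1e-7
                and np.isfinite(self.lambda2) and self.lambda2 < 1e-7):
            warnings.warn(
                "both penalties are below 1e-7; the fit may overfit the bulk "
                "profiles and degrade composition estimates",
                UserWarning,
                stacklevel=2,
            )

    @staticmethod
    def _maybe_update_x(Y, A, C, g, x_current):
        """x update that keeps the current profile when the background is
        unidentifiable (no hidden mass): resetting it would be arbitrary
        and could increase the loss."""
        h = 1.0 - (A @ C).sum(axis=0)
        if float(h @ h) <= 1e-14:
            return x_current
        return solve_x_subproblem(Y, A, C, g)

    # -- fast Delta sweep with incremental bookkeeping ----------------------

    def _delta_sweep(self, Y, X, C, x, g, lambda2, Delta, budget: float = 1.0):
        """One pass of exact row minimizations of Delta.

        The budget constraint colsum((Delta o X) C) <= 1 couples the rows;
        it is enforced here (constrained row QP when binding, with a
        feasible-line-search guard), so every sweep keeps the iterate
        feasible and the loss non-increasing.
        """
        p, q = X.shape
        g2 = g**2
        g2x = g2 * x
        G2X2 = float(np.sum(g2 * x**2))
        A = Delta * X
        AC = A @ C
        colsum = AC.sum(axis=0)
        c_full = 1.0 - colsum
        T = g2x @ (Y - AC)
        eye = lambda2 * np.eye(q)
        ones = lambda2 * np.ones(q)
        for k in range(p):
            c_bar = c_full + AC[k]
            P, qvec, M = _delta_row_terms(k, Y, X, C, x, g, AC[k], c_bar, T, G2X2)
            Pfull = P + eye
            qfull = qvec - ones
            old = Delta[k]
            new = _delta_row_qp(Pfull, qfull)
            # per-sample budget headroom for this row: delta' M_i <= b_i
            b = budget - (colsum - old @ M)
            viol = new @ M - b
            if np.any(viol > 1e-12):
                new = _constrained_delta_row(Pfull, qfull, M, b, old, new)
            diff = new - old
            if np.any(diff != 0):
                drow = diff @ M  # change of (AC)_k across samples
                AC[k] += drow
                colsum += drow
                c_full -= drow
                T -= g2x[k] * drow
                Delta[k] = new
        return Delta

    def _descend(self, C, x, Delta, C0, budget, max_iter):
        """Block-coordinate descent at a fixed budget bound.

        Returns the iterate, the traces and the convergence flag.  Every
        block update is an exact constrained minimization over a set
        containing the current point, so the loss is non-increasing.
        """
        X, Y, g = self.X, self.Y, self.g
        l1, l2 = self.lambda1, self.lambda2
        update_C = np.isfinite(l1)
        update_Delta = self.adapt_reference
        block_trace = [("init", adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0))]
        loss_trace = []
        prev = block_trace[0][1]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            A = Delta * X
            if update_C:
                C = solve_C_subproblem(Y, A, x, g, l1, C0, budget)
                block_trace.append(
                    ("C", adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0)))
            x = self._maybe_update_x(Y, A, C, g, x)
            block_trace.append(
                ("x", adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0)))
            if update_Delta:
                Delta = self._delta_sweep(Y, X, C, x, g, l2, Delta, budget)
                block_trace.append(
                    ("Delta", adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0)))
            cur = block_trace[-1][1]
            loss_trace.append(cur)
            if abs(prev - cur) <= self.tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = cur
        return C, x, Delta, block_trace, loss_trace, converged, it

    def fit(self) -> ADTDResults:
        """Run the block-coordinate descent and return the solution.

        The iteration starts from the budget-projected naive composition,
        all-ones ``Delta`` and the uniform background.  If the descent
        terminates in the degenerate fully-saturated state (every sample's
        budget active, so the background never receives mass and carries
        no gradient), the fit is repeated through a budget continuation —
        a first phase with a tightened budget that forces background mass
        so that ``x`` can form, then a final phase at the true budget —
        and the lower-loss solution is returned.
        """
        X, Y, g = self.X, self.Y, self.g
        p, q = X.shape
        l1, l2 = self.lambda1, self.lambda2

        C0 = weighted_nnls(X, Y, g**2)
        Delta0 = np.ones((p, q))
        x0 = np.full(p, 1.0 / p)

        def saturated(C, Delta):
            return np.all(1.0 - ((Delta * X) @ C).sum(axis=0) <= 1e-8)

        with warnings.catch_warnings():
            # the x update warns when hidden mass is zero; report it once
            warnings.simplefilter("once", RuntimeWarning)
            # infinite lambda1 is the hard constraint C = C0; otherwise C
            # starts at C0 projected into the budget set (feasible start)
            Cinit = (C0 if not np.isfinite(l1)
                     else C0 / np.maximum(1.0, (X @ C0).sum(axis=0)))
            C, x, Delta, block_trace, loss_trace, converged, it = self._descend(
                Cinit.copy(), x0.copy(), Delta0.copy(), C0, 1.0, self.max_iter)
            if saturated(C, Delta) and np.isfinite(l1):
                relax = 0.85
                Cr = C0 / np.maximum(1.0, (X @ C0).sum(axis=0) / relax)
                Cr, xr, Dr, *_ = self._descend(
                    Cr, x0.copy(), Delta0.copy(), C0, relax,
                    min(200, self.max_iter))
                out = self._descend(Cr, xr, Dr, C0, 1.0, self.max_iter)
                if out[4] and out[4][-1] < loss_trace[-1] - 1e-15:
                    C, x, Delta, block_trace, loss_trace, converged, it = out
            if self.n_starts > 1:
                q_ = X.shape[1]
                n_ = Y.shape[1]
                rng = np.random.default_rng(self.seed)
                for _ in range(self.n_starts - 1):
                    Cs = (rng.uniform(0.0, 0.5, (q_, n_))
                          if np.isfinite(l1) else C0.copy())
                    xs = rng.dirichlet(np.ones(p))
                    Ds = (rng.uniform(0.5, 1.5, (p, q_))
                          if self.adapt_reference else Delta0.copy())
                    f = float(((Ds * X) @ Cs).sum(axis=0).max())
                    if f > 1.0:
                        Cs /= f
                    out = self._descend(Cs, xs, Ds, C0, 1.0, self.max_iter)
                    if out[4] and out[4][-1] < loss_trace[-1] - 1e-15:
                        C, x, Delta, block_trace, loss_trace, converged, it = out
            # restore budget feasibility / final polish after the last sweep
            if self.adapt_reference:
                A = Delta * X
                if np.isfinite(l1):
                    C = solve_C_subproblem(Y, A, x, g, l1, C0)
                    block_trace.append(
                        ("C", adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0)))
                x = self._maybe_update_x(Y, A, C, g, x)
                final = adtd_loss(C, x, Delta, X, Y, g, l1, l2, C0)
                block_trace.append(("x", final))
                loss_trace.append(final)

        if not converged:
            warnings.warn(
                f"ADTD did not reach tol={self.tol:g} within "
                f"{self.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        raw = 1.0 - ((Delta * X) @ C).sum(axis=0)
        res = ADTDResults(
            C=C,
            x=x,
            Delta=Delta,
            hidden_weights=np.clip(raw, 0.0, 1.0),
            hidden_weights_raw=raw,
            C0=C0,
            loss_trace=np.asarray(loss_trace),
            block_loss_trace=block_trace,
            converged=converged,
            n_iter=it,
            gene_weights=g,
            lambda1=l1,
            lambda2=l2,
            gene_ids=self.gene_ids,
            celltype_ids=self.celltype_ids,
            sample_ids=self.sample_ids,
        )
        res._X_cache = X
        logger.info(
            "ADTD fit: %d iterations, converged=%s, loss=%.6e, "
            "constraints=%s", it, converged, res.loss, res.constraint_report()
        )
        return res
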