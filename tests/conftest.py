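"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize


def brute_force_nnls(A, b, gamma=None):
    """Exact weighted NNLS by enumerating all active sets.

    For every subset F of free coefficients solve the unconstrained
    weighted least squares restricted to F and keep the best feasible
    candidate.  Exponential in q; only for q <= 3 test instances.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    p, q = A.shape
    w = np.ones(p) if gamma is None else np.sqrt(np.asarray(gamma, float))
    Aw = A * w[:, None]
    bw = b * w

    def obj(c):
        r = Aw @ c - bw
        return float(r @ r)

    best_c, best_obj = np.zeros(q), obj(np.zeros(q))
    for r_ in range(1, q + 1):
        for F in itertools.combinations(range(q), r_):
            F = list(F)
            sol, *_ = np.linalg.lstsq(Aw[:, F], bw, rcond=None)
            if np.any(sol < -1e-12):
                continue
            c = np.zeros(q)
            c[F] = np.maximum(sol, 0.0)
            if obj(c) < best_obj:
                best_obj, best_c = obj(c), c
    return best_c, best_obj


def elementwise_adtd_loss(C, x, Delta, X, Y, g, lam1, lam2, C0):
    """Scalar-loop recomputation of the ADTD objective (independent of the
    package's vectorized implementation)."""
    p, q = X.shape
    n = Y.shape[1]
    total = 0.0
    for i in range(n):
        h = 1.0
        for j in range(p):
            for k in range(q):
                h -= Delta[j][k] * X[j][k] * C[k][i]
        for j in range(p):
            fit = 0.0
            for k in range(q):
                fit += Delta[j][k] * X[j][k] * C[k][i]
            r = g[j] * (Y[j][i] - fit - x[j] * h)
            total += r * r
    for k in range(q):
        for i in range(n):
            total += lam1 * (C[k][i] - C0[k][i]) ** 2
    for j in range(p):
        for k in range(q):
            total += lam2 * (1.0 - Delta[j][k]) ** 2
    return total


def slsqp_full_loss_oracle(X, Y, g, lam1, lam2, C0, n_starts, rng):
    """Generic constrained minimization of the full objective from random
    starting points (independent of the block-coordinate solver)."""
    p, q = X.shape
    n = Y.shape[1]

    def unpack(z):
        return (z[:q * n].reshape(q, n), z[q * n:q * n + p],
                z[q * n + p:].reshape(p, q))

    def loss(z):
        C, x, D = unpack(z)
        A = D * X
        AC = A @ C
        h = 1.0 - AC.sum(axis=0)
        R = (Y - AC - np.outer(x, h)) * g[:, None]
        return float((R * R).sum() + lam1 * ((C - C0) ** 2).sum()
                     + lam2 * ((1.0 - D) ** 2).sum())

    cons = [
        {"type": "eq", "fun": lambda z: unpack(z)[1].sum() - 1.0},
        {"type": "ineq",
         "fun": lambda z: 1.0 - ((unpack(z)[2] * X) @ unpack(z)[0]).sum(axis=0)},
    ]
    best = np.inf
    nv = q * n + p + p * q
    for _ in range(n_starts):
        z0 = np.concatenate([
            rng.uniform(0.0, 0.5, q * n),
            rng.dirichlet(np.ones(p)),
            rng.uniform(0.5, 1.5, p * q),
        ])
        res = minimize(loss, z0, method="SLSQP", bounds=[(0.0, None)] * nv,
                       constraints=cons,
                       options={"maxiter": 500, "ftol": 1e-14})
        C, x, D = unpack(res.x)
        if (res.fun < best and abs(x.sum() - 1.0) < 1e-3
                and ((D * X) @ C).sum(axis=0).max() < 1.0001):
            best = res.fun
    return best


def tiny_onmodel_instance(rng):
    """A small instance drawn from the generative mixing model with
    moderate hidden mass (the solver's operating regime)."""
    p = int(rng.integers(3, 6))
    q = int(rng.integers(1, 3))
    n = int(rng.integers(2, 4))
    X = rng.uniform(0.05, 1.0, (p, q))
    X /= X.sum(axis=0)
    w = rng.dirichlet(np.ones(q)) if q > 1 else np.ones(1)
    scale = rng.uniform(0.7, 0.85, n)
    C_true = np.outer(w, scale) * rng.uniform(0.7, 1.3, (q, n))
    x_true = rng.dirichlet(np.ones(p))
    h_true = 1.0 - (X @ C_true).sum(axis=0)
    Y = X @ C_true + np.outer(x_true, h_true)
    Y = np.maximum(Y + rng.normal(0.0, 0.01, Y.shape), 1e-6)
    Y /= Y.sum(axis=0)
    g = rng.uniform(0.2, 1.0, p)
    g /= np.linalg.norm(g)
    return X, Y, g, C_true, x_true, h_true


@pytest.fixture(scope="session")
def study_fixture():
    """One seed-fixed synthetic study at the standard desk scale,
    shared across tests that only read from it."""
    from adtd.io import RunConfig
    from adtd.pipeline import run_pipeline

    cfg = RunConfig(p=200, q=4, n=200, n_train=300, separation=4.0, seed=3)
    return run_pipeline(cfg, write=False)
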