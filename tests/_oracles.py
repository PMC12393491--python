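"""Independent brute-force oracles used to cross-check the analysis code.

These deliberately take different computational routes from the package:
the control oracle discretizes the control problem as an
equality-constrained quadratic program over piecewise-constant inputs
and solves its KKT system; the clustering oracle enumerates every
possible medoid subset.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import expm


def control_energy_oracle(
    a: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    horizon: float = 1.0,
    rho: float = 1.0,
    state_cost: np.ndarray | None = None,
    n_segments: int = 1000,
) -> float:
    """Total control energy by direct minimization over piecewise-constant u.

    The dynamics are discretized exactly per segment (matrix exponential);
    the state cost uses trapezoid weights on the segment grid; the
    resulting quadratic program with terminal equality constraint is
    solved through its sparse KKT system. Converges to the continuous
    optimum as O(dt^2).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    n = a.shape[0]
    s = np.eye(n) if state_cost is None else np.asarray(state_cost, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    xf = np.asarray(xf, dtype=float)
    nseg = n_segments
    dt = horizon / nseg
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = a
    aug[:n, n:] = np.eye(n)
    e = expm(aug * dt)
    ad, bd = e[:n, :n], e[:n, n:]

    nx = nseg * n  # x_1..x_nseg
    nu = nseg * n  # u_0..u_{nseg-1}
    w = np.ones(nseg + 1)
    w[0] = w[-1] = 0.5
    p_mat = sp.lil_matrix((nx + nu, nx + nu))
    q = np.zeros(nx + nu)
    for k in range(1, nseg + 1):
        blk = slice((k - 1) * n, k * n)
        p_mat[blk, blk] = 2.0 * dt * w[k] * s
        q[blk] = -2.0 * dt * w[k] * (s @ xf)
    for j in range(nseg):
        blk = slice(nx + j * n, nx + (j + 1) * n)
        p_mat[blk, blk] = 2.0 * rho * dt * np.eye(n)
    c_mat = sp.lil_matrix((nseg * n + n, nx + nu))
    b = np.zeros(nseg * n + n)
    for k in range(nseg):
        row = slice(k * n, (k + 1) * n)
        c_mat[row, k * n:(k + 1) * n] = np.eye(n)
        if k > 0:
            c_mat[row, (k - 1) * n:k * n] = -ad
        else:
            b[row] = ad @ x0
        c_mat[row, nx + k * n:nx + (k + 1) * n] = -bd
    c_mat[nseg * n:, (nseg - 1) * n:nseg * n] = np.eye(n)
    b[nseg * n:] = xf
    kkt = sp.bmat([[p_mat, c_mat.T], [c_mat, None]], format="csc")
    rhs = np.concatenate([-q, b])
    sol = spla.spsolve(kkt, rhs)
    u = sol[nx:nx + nu].reshape(nseg, n)
    return float(rho * dt * np.sum(u**2))


def brute_force_kmedoids(distance_matrix: np.ndarray, k: int) -> float:
    """Globally optimal total within-cluster distance by enumerating all
    medoid subsets (feasible only for small T)."""
    d = np.asarray(distance_matrix, dtype=float)
    t = d.shape[0]
    best = np.inf
    for subset in itertools.combinations(range(t), k):
        obj = d[list(subset)].min(axis=0).sum()
        best = min(best, obj)
    return float(best)


def pairwise_correlation_distances(x: np.ndarray) -> np.ndarray:
    """T x T correlation-distance table via numpy.corrcoef on columns."""
    d = 1.0 - np.corrcoef(x.T)
    np.fill_diagonal(d, 0.0)
    return d
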