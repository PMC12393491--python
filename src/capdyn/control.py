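"""Optimal-control transition energies on structural connectomes.

Neural activity is modelled as linear time-invariant dynamics on the
(stabilized) structural connectome, dx/dt = A x + B u, steered between
brain-state vectors by an external control input u(t). The control cost
minimized over a fixed horizon T is

    J = int_0^T [ (x - xf)' S (x - xf) + rho * u' u ] dt,

with x(0) = x0 and x(T) = xf as hard boundary conditions. The solver
uses the Hamiltonian (state/costate) two-point boundary-value
formulation: the stationarity condition u = -B'p / (2 rho) closes the
system

    dx/dt =  A x - (B B' / 2 rho) p
    dp/dt = -2 S x - A' p + 2 S xf,

which is linear with a constant forcing term, so one matrix exponential
of the augmented (2N+1) system propagates it exactly; the unknown
initial costate p(0) is recovered from the terminal condition by a
linear solve. Transition energy is the time integral of the squared
control input (trapezoid rule on the sampled trajectory), per node and
in total; energies are in arbitrary units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, expm

from .datatypes import Connectome, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedSystem:
    """Stabilized dimensionless dynamics matrix for one connectome."""

    a_norm: np.ndarray
    normalization_constant: float
    source_connectome_id: str


def normalize_adjacency(
    connectome: Connectome | np.ndarray, c: float = 1.0
) -> NormalizedSystem:
    """Stabilize a connectome: a_norm = A / (lambda_max(A) + c) - I.

    For a symmetric nonnegative A the spectral radius equals lambda_max,
    so every eigenvalue of a_norm lies in [-2, 0): the system is stable.
    ``c`` (default 1) sets how far below zero the slowest mode sits; the
    offset is absolute, so rescaling the weights and ``c`` together
    leaves the system unchanged (a_norm(s*A, s*c) = a_norm(A, c)).
    """
    if isinstance(connectome, Connectome):
        a = connectome.weights
        source = connectome.subject_id
    else:
        a = np.asarray(connectome, dtype=float)
        source = "array"
    if c <= 0:
        raise ValidationError("normalization constant c must be positive")
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValidationError("adjacency must be symmetric")
    lam_max = float(eigh(a, eigvals_only=True, subset_by_index=(a.shape[0] - 1,) * 2)[0])
    if lam_max <= 0:
        raise ValidationError("all-zero (or non-positive-spectrum) adjacency")
    a_norm = a / (lam_max + c) - np.eye(a.shape[0])
    return NormalizedSystem(
        a_norm=a_norm, normalization_constant=lam_max + c,
        source_connectome_id=source,
    )


@dataclass
class ControlTask:
    """Boundary states and cost configuration for one transition.

    Defaults follow the standard optimal-control configuration: uniform
    full control set (B = I, m = N), unit control weight rho = 1,
    identity trajectory constraint S = I, continuous horizon T = 1.
    """

    x0: np.ndarray
    xf: np.ndarray
    horizon_T: float = 1.0
    rho: float = 1.0
    control_set_B: np.ndarray | None = None
    state_cost_S: np.ndarray | None = None
    n_time_steps: int = 1001

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.xf = np.asarray(self.xf, dtype=float)
        if not (np.all(np.isfinite(self.x0)) and np.all(np.isfinite(self.xf))):
            raise ValidationError("boundary states must be finite")
        if self.horizon_T <= 0 or self.rho <= 0:
            raise ValidationError("horizon_T and rho must be positive")
        if self.n_time_steps < 2:
            raise ValidationError("n_time_steps must be >= 2")


@dataclass
class ControlResult:
    """Optimal trajectory, control signals and energies for one transition."""

    trajectory: np.ndarray  # n_t x N
    controls: np.ndarray  # n_t x m
    times: np.ndarray
    nodal_energy: np.ndarray  # m, integral of u_i^2 dt
    total_energy: float
    terminal_error: float


def solve_optimal_control(
    system: NormalizedSystem | np.ndarray,
    task: ControlTask,
    terminal_tolerance: float | None = None,
) -> ControlResult:
    """Solve the linear-quadratic two-point boundary-value problem.

    Raises on a numerically singular boundary block (target unreachable
    within the horizon) and when the terminal state misses ``xf`` by
    more than ``1e-6 * (1 + ||xf||)``.
    """
    a = system.a_norm if isinstance(system, NormalizedSystem) else np.asarray(system, dtype=float)
    n = a.shape[0]
    if task.x0.shape != (n,) or task.xf.shape != (n,):
        raise ValidationError("boundary state dimension does not match system")
    b = np.eye(n) if task.control_set_B is None else np.asarray(task.control_set_B, dtype=float)
    s = np.eye(n) if task.state_cost_S is None else np.asarray(task.state_cost_S, dtype=float)
    m = b.shape[1]
    rho, horizon = task.rho, task.horizon_T

    big = np.zeros((2 * n + 1, 2 * n + 1))
    big[:n, :n] = a
    big[:n, n: 2 * n] = -(b @ b.T) / (2.0 * rho)
    big[n: 2 * n, :n] = -2.0 * s
    big[n: 2 * n, n: 2 * n] = -a.T
    big[n: 2 * n, -1] = 2.0 * s @ task.xf

    e_full = expm(big * horizon)
    e11 = e_full[:n, :n]
    e12 = e_full[:n, n: 2 * n]
    e13 = e_full[:n, -1]
    rhs = task.xf - e11 @ task.x0 - e13
    cond = np.linalg.cond(e12)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"boundary block is numerically singular (cond={cond:.3e}); "
            "target unreachable within the horizon"
        )
    p0 = np.linalg.solve(e12, rhs)

    n_t = task.n_time_steps
    dt = horizon / (n_t - 1)
    e_step = expm(big * dt)
    z = np.empty((n_t, 2 * n + 1))
    z[0] = np.concatenate([task.x0, p0, [1.0]])
    for j in range(1, n_t):
        z[j] = e_step @ z[j - 1]
    trajectory = z[:, :n]
    controls = -(z[:, n: 2 * n] @ b) / (2.0 * rho)
    times = np.linspace(0.0, horizon, n_t)

    tol = terminal_tolerance
    if tol is None:
        tol = 1e-6 * (1.0 + np.linalg.norm(task.xf))
    terminal_error = float(np.linalg.norm(trajectory[-1] - task.xf))
    if terminal_error > tol:
        raise ValidationError(
            f"terminal error {terminal_error:.3e} exceeds tolerance {tol:.3e} "
            f"(cond(E12)={cond:.3e})"
        )
    nodal = np.trapezoid(controls**2, dx=dt, axis=0)
    return ControlResult(
        trajectory=trajectory,
        controls=controls,
        times=times,
        nodal_energy=nodal,
        total_energy=float(nodal.sum()),
        terminal_error=terminal_error,
    )


def transition_energy_matrix(
    system: NormalizedSystem | Connectome | np.ndarray,
    centroids: np.ndarray,
    horizon_T: float = 1.0,
    rho: float = 1.0,
    n_time_steps: int = 1001,
    state_scale: str = "raw",
) -> tuple[np.ndarray, np.ndarray]:
    """Total and nodal transition energies between all state pairs.

    Entry (i, j) is the energy of steering the system from centroid i to
    centroid j. Diagonal (self-maintenance) entries are computed too but
    are reported separately by downstream exit/enter means. A failed
    solve leaves NaN in that entry and the run continues.
    ``state_scale="unit"`` rescales each centroid to unit norm first
    (energy scales quadratically with state magnitude).
    """
    if isinstance(system, (Connectome, np.ndarray)) and not isinstance(
        system, NormalizedSystem
    ):
        system = normalize_adjacency(system)
    centroids = np.asarray(centroids, dtype=float)
    k, n = centroids.shape
    if n != system.a_norm.shape[0]:
        raise ValidationError("centroid dimension does not match connectome")
    if state_scale == "unit":
        norms = np.linalg.norm(centroids, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        centroids = centroids / norms
    elif state_scale != "raw":
        raise ValidationError("state_scale must be 'raw' or 'unit'")
    totals = np.full((k, k), np.nan)
    nodal = np.full((k, k, n), np.nan)
    for i in range(k):
        for j in range(k):
            task = ControlTask(
                x0=centroids[i], xf=centroids[j], horizon_T=horizon_T,
                rho=rho, n_time_steps=n_time_steps,
            )
            try:
                res = solve_optimal_control(system, task)
            except ValidationError as exc:
                logger.warning("transition %d->%d failed: %s", i + 1, j + 1, exc)
                continue
            totals[i, j] = res.total_energy
            nodal[i, j] = res.nodal_energy
    return totals, nodal


@dataclass
class EnergyLandscape:
    """Exit/enter energy characterization of the state space.

    A state whose exit energy exceeds its enter energy sits at the
    bottom of a local minimum (sink-like: cheap to fall into, costly to
    leave); the opposite pattern marks a local maximum (source-like).
    ``depth_rank`` orders states by mean(exit, enter) ascending, so
    higher ranks are deeper/higher features of the landscape.
    """

    exit_energy: np.ndarray
    enter_energy: np.ndarray
    classification: list[str]
    depth_rank: np.ndarray
    degenerate: bool = False
    has_missing: bool = False

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": np.arange(1, self.exit_energy.size + 1),
            "exit_energy": self.exit_energy,
            "enter_energy": self.enter_energy,
            "classification": self.classification,
            "depth_rank": self.depth_rank,
        })


def exit_enter_energies(energy_matrix: np.ndarray) -> EnergyLandscape:
    """Exit/enter energies per state from a K x K transition-energy matrix.

    Exit(i) is the mean of row i over the other states; enter(i) the
    mean of column i over the other states (diagonal self-maintenance
    entries are excluded). Missing (NaN) entries are averaged over what
    is available and flagged.
    """
    e = np.asarray(energy_matrix, dtype=float)
    k = e.shape[0]
    if e.ndim != 2 or e.shape[1] != k or k < 2:
        raise ValidationError("energy matrix must be square with K >= 2")
    off = ~np.eye(k, dtype=bool)
    has_missing = bool(np.isnan(e[off]).any())
    if has_missing:
        logger.warning("energy matrix has missing entries; means use available values")
    with np.errstate(invalid="ignore"):
        exit_e = np.array([np.nanmean(e[i, off[i]]) for i in range(k)])
        enter_e = np.array([np.nanmean(e[off[:, i], i]) for i in range(k)])
    degenerate = bool(np.allclose(exit_e, enter_e, rtol=1e-9, atol=1e-12))
    if degenerate:
        logger.warning("exit and enter energies coincide; classification degenerate")
    classification = [
        "sink-like" if exit_e[i] > enter_e[i] else "source-like" for i in range(k)
    ]
    mean_energy = (exit_e + enter_e) / 2.0
    depth_rank = np.empty(k, dtype=int)
    depth_rank[np.argsort(mean_energy)] = np.arange(1, k + 1)
    return EnergyLandscape(
        exit_energy=exit_e,
        enter_energy=enter_e,
        classification=classification,
        depth_rank=depth_rank,
        degenerate=degenerate,
        has_missing=has_missing,
    )
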