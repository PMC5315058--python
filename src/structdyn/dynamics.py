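"""Forward model: linear multi-region state equation and observation model.

Regional states x (rescaled gray-matter volumes) evolve as

    dx/dt = A x + C u(t)

where A holds self- and between-region connection rates (1/years) and C the
regional sensitivities to each input.  The system is integrated with the
forward Euler method on a uniform age grid (default step 0.1 years).
Observations are the states sampled at scan ages plus linear confound
effects (TICV, site indicators) and i.i.d. Gaussian noise per region.

A state-independent cubic polynomial per region is provided as the
conventional reference model, and :func:`decay_time` converts a negative
self-connection into the time needed to lose a given percentage of volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inputs import InputTrajectory

__all__ = [
    "ConnectivityMatrix",
    "SensitivityMatrix",
    "StateTrajectory",
    "ObservationModel",
    "CubicPolyParams",
    "integrate_system",
    "decay_time",
    "predict_observations",
    "cubic_poly_predict",
    "stability_check",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.1


@dataclass
class ConnectivityMatrix:
    """Connection-rate matrix A (1/years) with structural metadata.

    ``mask`` marks the free entries; ``sign_constraint`` applies to the
    off-diagonal coupling class ('negative', 'positive' or 'unconstrained';
    self-connections are negative by convention); ``symmetric`` asserts
    A == A.T exactly.
    """

    A: np.ndarray
    mask: np.ndarray | None = None
    sign_constraint: str = "negative"
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.mask is None:
            self.mask = np.ones_like(self.A, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.A.shape:
            raise ValueError("mask shape must match A")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A must be finite")
        if self.symmetric and not np.array_equal(self.A, self.A.T):
            raise ValueError("symmetric flag set but A != A.T")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


@dataclass
class SensitivityMatrix:
    """Regional input sensitivities C (D x J); masked-out entries are zero."""

    C: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.mask is None:
            self.mask = np.ones_like(self.C, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.C.shape:
            raise ValueError("mask shape must match C")
        if np.any(self.C[~self.mask] != 0.0):
            raise ValueError("masked-out sensitivities must be exactly zero")


@dataclass
class StateTrajectory:
    """States X (D x T) on a uniform age grid with initial states x0."""

    time_grid: np.ndarray
    X: np.ndarray
    x0: np.ndarray

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.X.shape != (self.x0.size, self.time_grid.size):
            raise ValueError("X must be (D, T) matching x0 and the grid")
        if not np.allclose(self.X[:, 0], self.x0):
            raise ValueError("X[:, 0] must equal x0")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])


@dataclass
class ObservationModel:
    """Linear confound model: predictions = states(scan ages) + X0 @ b0.

    ``confound_matrix`` is scans x Q (e.g. centred TICV and site
    indicators), ``b0`` is Q x D.
    """

    confound_matrix: np.ndarray
    b0: np.ndarray
    noise_precision: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.confound_matrix = np.atleast_2d(np.asarray(self.confound_matrix, dtype=float))
        self.b0 = np.atleast_2d(np.asarray(self.b0, dtype=float))
        if self.confound_matrix.shape[1] != self.b0.shape[0]:
            raise ValueError("confound matrix columns must match rows of b0")
        if self.noise_precision is not None:
            self.noise_precision = np.asarray(self.noise_precision, dtype=float)
            if np.any(self.noise_precision <= 0):
                raise ValueError("noise precisions must be positive")


@dataclass
class CubicPolyParams:
    """Per-region cubic coefficients B (D x 4), b_{i r} for powers r = 0..3."""

    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.B.shape[1] != 4:
            raise ValueError("B must have 4 columns (cubic coefficients)")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("coefficients must be finite")


def _input_matrix(inputs: list[InputTrajectory] | None, grid: np.ndarray) -> np.ndarray:
    """Stack input trajectories into a (J, T) matrix, validating the grid."""
    if not inputs:
        return np.zeros((0, grid.size))
    rows = []
    for traj in inputs:
        if traj.time_grid.shape != grid.shape or not np.allclose(traj.time_grid, grid):
            raise ValueError(f"input '{traj.label}' is tabulated on a different grid")
        rows.append(traj.values)
    return np.vstack(rows)


def integrate_system(
    A: ConnectivityMatrix | np.ndarray,
    C: SensitivityMatrix | np.ndarray | None,
    inputs: list[InputTrajectory] | None,
    x0: np.ndarray,
    grid: np.ndarray,
) -> StateTrajectory:
    """Integrate dx/dt = A x + C u with forward Euler on a uniform grid.

    The update is x[t + dt] = x[t] + dt * (A x[t] + C u[t]); states are not
    clipped.  Inputs must be tabulated on the same grid.
    """
    Amat = A.A if isinstance(A, ConnectivityMatrix) else np.asarray(A, dtype=float)
    grid = np.asarray(grid, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(Amat)) or not np.all(np.isfinite(x0)):
        raise ValueError("non-finite parameters")
    U = _input_matrix(inputs, grid)
    if C is None:
        Cmat = np.zeros((x0.size, U.shape[0]))
    else:
        Cmat = C.C if isinstance(C, SensitivityMatrix) else np.atleast_2d(np.asarray(C, dtype=float))
    if Cmat.shape != (x0.size, U.shape[0]):
        raise ValueError(
            f"C has shape {Cmat.shape}, expected ({x0.size}, {U.shape[0]})"
        )
    X = euler_trajectories(Amat[None], Cmat[None], x0[None], U, grid)[0]
    return StateTrajectory(time_grid=grid, X=X, x0=x0)


def euler_trajectories(
    A: np.ndarray, C: np.ndarray, x0: np.ndarray, U: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Vectorised forward-Euler integration over a batch of parameter sets.

    A: (P, D, D); C: (P, D, J); x0: (P, D); U: (J, T) shared, or (P, J, T)
    per batch member.  Returns states of shape (P, D, T).
    """
    P, D = x0.shape
    T = grid.size
    dt = float(grid[1] - grid[0]) if T > 1 else 0.0
    X = np.empty((P, D, T))
    x = x0.copy()
    X[:, :, 0] = x
    per_batch_u = U.ndim == 3
    for t in range(T - 1):
        drive = np.einsum("pij,pj->pi", A, x)
        if U.shape[-2]:
            u_t = U[:, :, t] if per_batch_u else U[:, t]
            drive = drive + (
                np.einsum("pij,pj->pi", C, u_t) if per_batch_u else C @ u_t
            )
        x = x + dt * drive
        X[:, :, t + 1] = x
    return X


def decay_time(a_ii: float, L: float) -> float:
    """Years to lose L percent of volume under self-connection a_ii < 0.

    t(L) = (1 / a_ii) * ln(1 - L/100); e.g. a_ii = -0.005 gives a 10% loss
    in about 21 years, a_ii = -0.02 the same loss in about 5.3 years.
    """
    if not a_ii < 0:
        raise ValueError(f"self-connection must be negative, got {a_ii}")
    if not 0 < L < 100:
        raise ValueError(f"percent loss must lie in (0, 100), got {L}")
    return (1.0 / a_ii) * math.log(1.0 - L / 100.0)


def sample_indices(grid: np.ndarray, scan_ages: np.ndarray) -> np.ndarray:
    """Nearest-grid-point index for each scan age; ages must lie on the grid range."""
    grid = np.asarray(grid, dtype=float)
    scan_ages = np.asarray(scan_ages, dtype=float)
    dt = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
    lo, hi = grid[0] - dt / 2, grid[-1] + dt / 2
    bad = (scan_ages < lo) | (scan_ages > hi)
    if np.any(bad):
        k = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"scan {k} at age {scan_ages[k]:.3f} lies outside the integration "
            f"grid [{grid[0]:.2f}, {grid[-1]:.2f}]"
        )
    return np.clip(np.rint((scan_ages - grid[0]) / dt).astype(int), 0, grid.size - 1)


def predict_observations(
    traj: StateTrajectory, scan_ages: np.ndarray, obs: ObservationModel | None = None
) -> np.ndarray:
    """Predicted volumes per scan: state at the nearest grid age plus confounds."""
    idx = sample_indices(traj.time_grid, np.asarray(scan_ages, dtype=float))
    pred = traj.X[:, idx].T  # scans x D
    if obs is not None:
        pred = pred + obs.confound_matrix @ obs.b0
    return pred


def cubic_poly_predict(scan_ages: np.ndarray, params: CubicPolyParams, t0: float = 0.0) -> np.ndarray:
    """Reference model: per-region cubic in (age - t0), independent across regions."""
    t = np.asarray(scan_ages, dtype=float) - t0
    powers = np.vander(t, N=4, increasing=True)  # scans x 4
    return powers @ params.B.T  # scans x D


def stability_check(A: ConnectivityMatrix | np.ndarray, dt: float = DEFAULT_DT):
    """Spectral abscissa of A and whether forward Euler at step dt is stable.

    Euler stability requires |1 + dt*lambda| < 1 for every eigenvalue.
    Returns (abscissa, euler_stable).
    """
    Amat = A.A if isinstance(A, ConnectivityMatrix) else np.asarray(A, dtype=float)
    eigs = np.linalg.eigvals(Amat)
    abscissa = float(np.max(eigs.real))
    stable = bool(np.all(np.abs(1.0 + dt * eigs) < 1.0))
    return abscissa, stable
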