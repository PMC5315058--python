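"""Developmental input functions driving the structural dynamics.

Three kinds of inputs are supported:

* a *manifest* puberty input, the temporal derivative of a sigmoid
  pubertal-transition curve fitted to questionnaire scores;
* a *latent* growth factor with alpha-function (critically damped
  second-order) dynamics, parametrised by a single peak-response time
  ``tau``;
* a parametric Gaussian growth impulse with a free mean per group and a
  shared spread.

All inputs are tabulated on a uniform age grid as :class:`InputTrajectory`
objects and consumed by :mod:`structdyn.dynamics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidParams",
    "AlphaGrowthParams",
    "GaussianGrowthParams",
    "InputTrajectory",
    "SigmoidFit",
    "REFERENCE_SIGMOID_PARAMS",
    "sigmoid_transition",
    "puberty_input",
    "fit_sigmoid",
    "alpha_growth",
    "gaussian_growth",
    "rescale_puberty_scores",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid pubertal transition h(t) = 1/(1+10^((p1-t) p2)).

    p1 is the age of strongest change (inflection, years); p2 the slope
    (1/years).
    """

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p1):
            raise ValueError("inflection age p1 must be finite")
        if not (np.isfinite(self.p2) and self.p2 > 0):
            raise ValueError(f"slope p2 must be positive and finite, got {self.p2}")


#: Group-level pubertal-transition parameters fitted to a large US pediatric
#: cohort; used as the default manifest puberty input per gender group.
REFERENCE_SIGMOID_PARAMS: dict[str, SigmoidParams] = {
    "F": SigmoidParams(p1=12.66, p2=0.21),
    "M": SigmoidParams(p1=14.34, p2=0.22),
}


@dataclass(frozen=True)
class AlphaGrowthParams:
    """Alpha-function latent growth: peak-response time tau (years) and onset age."""

    tau: float
    onset_age: float = 6.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"peak-response time tau must be > 0, got {self.tau}")
        if not np.isfinite(self.onset_age):
            raise ValueError("onset_age must be finite")


@dataclass(frozen=True)
class GaussianGrowthParams:
    """Gaussian growth impulse: mean age m_g (years) and shared spread sigma."""

    m_g: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.m_g):
            raise ValueError("m_g must be finite")


@dataclass
class InputTrajectory:
    """An input function u_j tabulated on a uniform age grid."""

    time_grid: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_grid.ndim != 1 or self.time_grid.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if self.values.shape != self.time_grid.shape:
            raise ValueError("values and time grid must have matching shapes")
        if self.time_grid.size > 1:
            steps = np.diff(self.time_grid)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
                raise ValueError("time grid spacing must be constant")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("input values must be finite")

    @property
    def dt(self) -> float:
        if self.time_grid.size < 2:
            return 0.0
        return float(self.time_grid[1] - self.time_grid[0])


def sigmoid_transition(t, params: SigmoidParams):
    """Sigmoid pubertal transition level h(t) = 1 / (1 + 10^((p1 - t) * p2)).

    Strictly increasing in t, with limits 0 and 1 and h(p1) = 1/2.
    Accepts scalar or array ages.
    """
    t = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + np.power(10.0, (params.p1 - t) * params.p2))
    return out if out.ndim else float(out)


def puberty_input(grid, params: SigmoidParams) -> InputTrajectory:
    """Puberty input u1(t) = dh/dt, the analytic sigmoid derivative.

    u1 = ln(10) * p2 * h * (1 - h): unimodal, symmetric about p1, with
    maximum ln(10)*p2/4 at t = p1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    h = sigmoid_transition(grid, params)
    u = math.log(10.0) * params.p2 * h * (1.0 - h)
    return InputTrajectory(time_grid=grid, values=u, label="puberty")


@dataclass
class SigmoidFit:
    """Result of a nonlinear least-squares sigmoid fit with asymptotic CIs."""

    params: SigmoidParams
    stderr: tuple[float, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    rss: float = np.nan
    n_obs: int = 0
    converged: bool = True


def fit_sigmoid(ages, scores) -> SigmoidFit:
    """Fit the sigmoid transition to (age, score) pairs by least squares.

    Uses multi-start Levenberg-Marquardt (starts at p1 in {10,12,14,16},
    p2 in {0.1, 0.3}) to avoid local minima.  Asymptotic 95% confidence
    intervals come from the Jacobian at the optimum.

    Requires at least 10 observations with non-constant scores in [0, 1].
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if ages.shape != scores.shape or ages.ndim != 1:
        raise ValueError("ages and scores must be 1-D arrays of equal length")
    if ages.size < 10:
        raise ValueError(f"need at least 10 observations, got {ages.size}")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate data: all scores are equal")

    def model(t, p1, p2):
        return 1.0 / (1.0 + np.power(10.0, (p1 - t) * p2))

    best = None
    last_err: Exception | None = None
    for p1_0 in (10.0, 12.0, 14.0, 16.0):
        for p2_0 in (0.1, 0.3):
            try:
                popt, pcov = curve_fit(
                    model, ages, scores, p0=(p1_0, p2_0),
                    bounds=((-np.inf, 1e-8), (np.inf, np.inf)), maxfev=10_000,
                )
            except RuntimeError as err:  # pragma: no cover - rare non-convergence
                last_err = err
                continue
            rss = float(np.sum((scores - model(ages, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError(f"sigmoid fit failed to converge from all starts: {last_err}")
    popt, pcov, rss = best
    stderr = np.sqrt(np.diag(pcov))
    half = 1.959963984540054 * stderr
    params = SigmoidParams(p1=float(popt[0]), p2=float(popt[1]))
    return SigmoidFit(
        params=params,
        stderr=(float(stderr[0]), float(stderr[1])),
        ci95={
            "p1": (params.p1 - half[0], params.p1 + half[0]),
            "p2": (params.p2 - half[1], params.p2 + half[1]),
        },
        rss=rss,
        n_obs=int(ages.size),
    )


def rescale_puberty_scores(stage_means, already_scaled: bool = False) -> np.ndarray:
    """Map raw 1-4 pubertal stage means linearly onto [0, 1]: (mean - 1) / 3."""
    x = np.asarray(stage_means, dtype=float)
    if already_scaled:
        return x
    return (x - 1.0) / 3.0


def alpha_growth(grid, params: AlphaGrowthParams) -> InputTrajectory:
    """Latent alpha-function growth integrated with forward Euler on ``grid``.

    The growth variable u2 obeys a critically damped second-order system

        du2/dt = v2,   dv2/dt = -(2/tau) v2 - u2/tau^2 + (20/tau) delta,

    with u2 = 1 and v2 = 0 at onset; the delta impulse is an instantaneous
    increment of v2 by 20/tau at the first grid point at or after
    ``onset_age``.  Ages before onset carry u2 = 0.  The continuous-time
    solution is u2(t) = e^{-t/tau} (1 + 21 t/tau), peaking at (20/21) tau
    after onset.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    tau = params.tau
    values = np.zeros_like(grid)
    active = grid >= params.onset_age - 1e-12
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return InputTrajectory(time_grid=grid, values=values, label="alpha")
    dt = float(grid[1] - grid[0]) if grid.size > 1 else 0.0
    u, v = 1.0, 20.0 / tau
    values[idx[0]] = u
    for k in idx[1:]:
        u_new = u + dt * v
        v_new = v + dt * (-(2.0 / tau) * v - u / tau**2)
        u, v = u_new, v_new
        values[k] = u
    return InputTrajectory(time_grid=grid, values=values, label="alpha")


def alpha_growth_closed_form(t, tau: float, onset_age: float = 0.0):
    """Exact critically damped solution u2(t) = e^{-s/tau}(1 + 21 s/tau), s = t - onset."""
    s = np.asarray(t, dtype=float) - onset_age
    out = np.where(s >= 0, np.exp(-s / tau) * (1.0 + 21.0 * s / tau), 0.0)
    return out if out.ndim else float(out)


def gaussian_growth(grid, params: GaussianGrowthParams) -> InputTrajectory:
    """Gaussian growth impulse exp(-(t - m_g)^2 / (2 sigma^2)), peak value 1."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    u = np.exp(-((grid - params.m_g) ** 2) / (2.0 * params.sigma**2))
    return InputTrajectory(time_grid=grid, values=u, label="gaussian")
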