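"""Variational Laplace model inversion and free-energy computation.

The posterior over the free parameters is assumed Gaussian and optimised
by Gauss-Newton ascent on the Laplace free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL(q(theta) || p(theta)) - KL(q(lambda) || p(lambda))

with independent Gaussian observation noise per region whose
log-precisions lambda_i are updated by Newton steps inside each outer
iteration.  A Levenberg-Marquardt damping schedule guarantees that a step
is only accepted when it increases F relative to the best estimate so
far, so the iteration trace is non-decreasing by construction.

For a model that is linear in its free parameters (e.g. the cubic
reference model with fixed noise) the Laplace assumptions are exact and F
coincides with the log marginal likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward import ForwardModel
from .io import LongitudinalCohort
from .parameters import ModelSpec, ParameterMap

__all__ = ["Posterior", "variational_laplace", "free_energy", "kl_gaussian"]

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class Posterior:
    """Gaussian posterior over free parameters for one fitted model."""

    mean: np.ndarray
    cov: np.ndarray
    noise_log_precisions: np.ndarray
    noise_logprec_var: np.ndarray
    free_energy: float
    trace: list = field(default_factory=list)
    converged: bool = True
    pmap: ParameterMap | None = None
    spec: ModelSpec | None = None
    data_fingerprint: str = ""
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")

    @property
    def n_free(self) -> int:
        return self.mean.size

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def credible_interval(self, level: float = 0.95):
        """Central credible interval per free parameter (unconstrained space)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.mean - z * self.sd, self.mean + z * self.sd

    def natural_mean(self) -> np.ndarray:
        """Posterior mean pushed through the parameter transforms."""
        return self.pmap.natural_matrix(self.mean)[0]


def kl_gaussian(m_q, S_q, m_p, S_p) -> float:
    """KL(N(m_q, S_q) || N(m_p, S_p)) for full or diagonal covariances."""
    m_q, m_p = np.atleast_1d(np.asarray(m_q, float)), np.atleast_1d(np.asarray(m_p, float))
    n = m_q.size
    S_q = np.atleast_2d(np.asarray(S_q, float))
    S_p = np.atleast_2d(np.asarray(S_p, float))
    d = m_q - m_p
    Sp_inv = np.linalg.inv(S_p)
    _, logdet_q = np.linalg.slogdet(S_q)
    _, logdet_p = np.linalg.slogdet(S_p)
    return 0.5 * (
        np.trace(Sp_inv @ S_q) + d @ Sp_inv @ d - n + logdet_p - logdet_q
    )


def _chol_inverse(H: np.ndarray):
    """Cholesky solve helpers with jitter fallback; returns (solve, logdet)."""
    n = H.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            c, low = cho_factor(H + jitter * np.eye(n), lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            return (lambda b: cho_solve((c, low), b)), logdet
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * np.trace(H) / n)
    raise np.linalg.LinAlgError("Gauss-Newton curvature matrix is not positive definite")


class _FEngine:
    """Shared pieces of the free-energy computation for one (model, data) pair."""

    def __init__(self, fm: ForwardModel, y: np.ndarray,
                 fixed_noise_precision=None, hyper_mean=None, hyper_var=None):
        self.fm = fm
        self.y = y
        self.S, self.D = y.shape
        pm = fm.pmap
        self.mu_p = pm.prior_mean
        self.var_p = pm.prior_var
        self.prec_p = 1.0 / pm.prior_var
        pr = fm.spec.priors
        self.hyper_mean = pr.noise_logprec_mean if hyper_mean is None else hyper_mean
        self.hyper_var = pr.noise_logprec_var if hyper_var is None else hyper_var
        if fixed_noise_precision is not None:
            fixed = np.broadcast_to(
                np.asarray(fixed_noise_precision, float), (self.D,)
            ).copy()
            if np.any(fixed <= 0):
                raise ValueError("fixed noise precisions must be positive")
            self.fixed_lam = np.log(fixed)
        else:
            self.fixed_lam = None

    def residual_stats(self, theta):
        f = self.fm.predict(theta)
        e = self.y - f
        return e, np.sum(e**2, axis=0)

    def accuracy(self, rss, tr, lam):
        pi = np.exp(lam)
        return float(np.sum(-0.5 * pi * (rss + tr) + 0.5 * self.S * (lam - LOG2PI)))

    def kl_theta(self, theta, Sigma, logdet_Sigma):
        d = theta - self.mu_p
        return 0.5 * (
            float(np.sum(np.diag(Sigma) * self.prec_p))
            + float(np.sum(d * d * self.prec_p))
            - theta.size
            + float(np.sum(np.log(self.var_p)))
            - logdet_Sigma
        )

    def kl_noise(self, lam, lam_var):
        if self.fixed_lam is not None:
            return 0.0
        v0 = self.hyper_var
        d = lam - self.hyper_mean
        return float(np.sum(0.5 * (lam_var / v0 + d * d / v0 - 1.0 + np.log(v0 / lam_var))))

    def update_noise(self, lam, rss, tr, n_newton: int = 4):
        """Newton ascent of F in the per-region log-precisions (closed-form curvature)."""
        if self.fixed_lam is not None:
            return self.fixed_lam, np.full(self.D, 1e-12)
        v0 = self.hyper_var
        for _ in range(n_newton):
            pi = np.exp(lam)
            grad = -0.5 * pi * (rss + tr) + 0.5 * self.S - (lam - self.hyper_mean) / v0
            hess = -0.5 * pi * (rss + tr) - 1.0 / v0
            lam = lam - grad / hess
        pi = np.exp(lam)
        lam_var = 1.0 / (0.5 * pi * (rss + tr) + 1.0 / v0)
        return lam, lam_var


def variational_laplace(
    spec: ModelSpec,
    cohort: LongitudinalCohort,
    *,
    max_iter: int = 128,
    tol: float = 1e-3,
    fixed_noise_precision=None,
    fd_rel_step: float = 1e-4,
    init_mean: np.ndarray | None = None,
) -> Posterior:
    """Fit one model to a cohort by Gauss-Newton ascent on the free energy.

    Stops when the accepted-step improvement in F falls below ``tol`` nats
    or after ``max_iter`` iterations (the best iterate is then returned
    with ``converged=False``).  ``fixed_noise_precision`` freezes the
    observation noise (scalar or per-region), which makes F the exact log
    evidence for models linear in their parameters.
    """
    for g in cohort.groups:
        if np.unique(cohort.ages[cohort.group_rows(g)]).size < 2:
            raise ValueError(f"group '{g}' has fewer than 2 distinct scan ages")
    fm = ForwardModel(spec, cohort)
    y = cohort.volumes
    eng = _FEngine(fm, y, fixed_noise_precision=fixed_noise_precision)
    n = fm.n_free
    S, D = y.shape

    theta = eng.mu_p.copy() if init_mean is None else np.asarray(init_mean, float).copy()
    if eng.fixed_lam is not None:
        lam = eng.fixed_lam.copy()
        lam_var = np.full(D, 1e-12)
    else:
        # moment-matched start: precision of the raw data per region
        lam = -np.log(np.maximum(y.var(axis=0), 1e-6))
        lam_var = np.full(D, eng.hyper_var)

    best: dict | None = None
    nu = 0.0  # LM damping
    trace: list[float] = []
    converged = False
    n_fail = 0

    for it in range(max_iter):
        f = fm.predict(theta)
        e = y - f
        rss = np.sum(e**2, axis=0)
        finite = np.all(np.isfinite(rss))
        if finite:
            J = fm.jacobian(theta, rel_step=fd_rel_step)  # (S, D, n)
            JtJ = np.einsum("sin,sim->inm", J, J)  # (D, n, n)
            finite = np.all(np.isfinite(JtJ))
        if finite:
            # noise / covariance fixed point for the current linearisation
            for _ in range(2):
                pi = np.exp(lam)
                H = np.tensordot(pi, JtJ, axes=1)
                H[np.diag_indices(n)] += eng.prec_p
                solve, neg_logdet_Sigma = _chol_inverse(H)
                Sigma = solve(np.eye(n))
                tr = np.einsum("inm,nm->i", JtJ, Sigma)
                lam, lam_var = eng.update_noise(lam, rss, tr)
            logdet_Sigma = -neg_logdet_Sigma
            F_cur = (
                eng.accuracy(rss, tr, lam)
                - eng.kl_theta(theta, Sigma, logdet_Sigma)
                - eng.kl_noise(lam, lam_var)
            )
        else:
            F_cur = np.nan
        if not np.isfinite(F_cur):
            if best is None:
                raise FloatingPointError(
                    f"non-finite free energy at iteration {it}; "
                    f"max |prediction| = {np.max(np.abs(f)):.3e}"
                )
            F_cur = -np.inf  # a diverged trial step counts as a rejection

        if best is None or F_cur > best["F"]:
            # accept: cache the linearisation at the new best estimate
            improvement = np.inf if best is None else F_cur - best["F"]
            pi = np.exp(lam)
            g_vec = np.einsum("sin,si,i->n", J, e, pi) - eng.prec_p * (theta - eng.mu_p)
            best = {
                "F": F_cur, "theta": theta.copy(), "lam": lam.copy(),
                "lam_var": lam_var.copy(), "Sigma": Sigma, "JtJ": JtJ, "g": g_vec,
            }
            trace.append(F_cur)
            nu = nu / 8.0 if nu > 8e-6 else 0.0
            n_fail = 0
            if improvement < tol:
                converged = True
                break
        else:
            # reject: revert to the best estimate and increase damping
            n_fail += 1
            lam = best["lam"].copy()
            lam_var = best["lam_var"].copy()
            nu = max(nu * 8.0, 1e-4)
            if n_fail >= 8:
                converged = True
                break

        # damped Gauss-Newton step from the best estimate
        Hd = np.tensordot(np.exp(best["lam"]), best["JtJ"], axes=1)
        Hd[np.diag_indices(n)] += eng.prec_p
        if nu > 0:
            Hd[np.diag_indices(n)] += nu * np.diag(Hd).copy()
        solve_d, _ = _chol_inverse(Hd)
        theta = best["theta"] + solve_d(best["g"])
        logger.debug("VL iter %d: F=%.4f nu=%.2e", it, best["F"], nu)

    F_best = best["F"]
    theta_b, lam_b = best["theta"], best["lam"]
    lam_var_b, Sigma_b = best["lam_var"], best["Sigma"]
    post = Posterior(
        mean=theta_b,
        cov=0.5 * (Sigma_b + Sigma_b.T),
        noise_log_precisions=lam_b,
        noise_logprec_var=lam_var_b,
        free_energy=F_best,
        trace=trace,
        converged=converged,
        pmap=fm.pmap,
        spec=spec,
        data_fingerprint=cohort.fingerprint(),
        n_iter=len(trace),
    )
    if not converged:
        logger.warning("VL did not converge after %d iterations (model %s)",
                       max_iter, spec.label)
    return post


def free_energy(
    spec: ModelSpec,
    cohort: LongitudinalCohort,
    free_vector: np.ndarray,
    covariance: np.ndarray,
    noise_log_precisions,
    noise_logprec_var=None,
) -> float:
    """Laplace free energy at a given posterior (mean, covariance, noise).

    Accuracy is the expected log likelihood under the Gaussian posterior
    (the trace correction uses the finite-difference Jacobian at the
    mean); complexity is the closed-form Gaussian KL to the prior, plus
    the noise-hyperparameter KL when posterior variances for the
    log-precisions are supplied.
    """
    covariance = np.asarray(covariance, dtype=float)
    cond = np.linalg.cond(covariance)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular posterior covariance (condition number {cond:.3e})")
    fm = ForwardModel(spec, cohort)
    y = cohort.volumes
    lam = np.broadcast_to(np.asarray(noise_log_precisions, float), (y.shape[1],))
    fixed = noise_logprec_var is None
    eng = _FEngine(fm, y, fixed_noise_precision=np.exp(lam) if fixed else None)
    theta = np.asarray(free_vector, dtype=float)
    e, rss = eng.residual_stats(theta)
    J = fm.jacobian(theta)
    JtJ = np.einsum("sin,sim->inm", J, J)
    tr = np.einsum("inm,nm->i", JtJ, covariance)
    _, logdet_Sigma = np.linalg.slogdet(covariance)
    F = eng.accuracy(rss, tr, lam) - eng.kl_theta(theta, covariance, logdet_Sigma)
    if not fixed:
        F -= eng.kl_noise(lam, np.asarray(noise_logprec_var, float))
    return float(F)
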