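"""Independent closed-form oracles used by the unit and acceptance tests."""

import numpy as np
from scipy.stats import multivariate_normal

import structdyn as sd


def conjugate_cubic_oracle(cohort, spec, pmap, sigma):
    """Exact Bayesian linear regression for the cubic reference model.

    The cubic model is linear in its coefficients and factorises over
    (group, region), so the posterior and the log marginal likelihood have
    closed forms.  Returns (mean, cov, log_evidence) in the free-vector
    ordering of ``pmap``.
    """
    prec = 1.0 / sigma**2
    y = cohort.volumes
    n = pmap.n_free
    mean = np.zeros(n)
    cov = np.zeros((n, n))
    log_ev = 0.0
    for g in cohort.groups:
        rows = cohort.group_rows(g)
        X = np.vander(cohort.ages[rows] - spec.onset_age, N=4, increasing=True)
        for i, roi in enumerate(cohort.roi_names):
            cols = [k for k, e in enumerate(pmap.entries)
                    if e.block == "B" and any(
                        t[0] == g and t[1] == "B"
                        and t[2] // 4 == i for t in e.targets)]
            assert len(cols) == 4
            m0 = pmap.prior_mean[cols]
            S0 = np.diag(pmap.prior_var[cols])
            yy = y[rows, i]
            marg_cov = sigma**2 * np.eye(len(rows)) + X @ S0 @ X.T
            log_ev += multivariate_normal.logpdf(yy, mean=X @ m0, cov=marg_cov)
            Sn = np.linalg.inv(X.T @ X * prec + np.linalg.inv(S0))
            mn = Sn @ (X.T @ yy * prec + np.linalg.inv(S0) @ m0)
            mean[cols] = mn
            cov[np.ix_(cols, cols)] += Sn
    return mean, cov, log_ev


def fit_and_check_conjugate(cohort, sigma=1.5):
    """Fit the cubic model by VL with fixed noise and return (posterior, oracle)."""
    spec = sd.ModelSpec(family="cubic", inputs=(), include_confounds=False,
                        group_sharing={"B": "per_group"})
    post = sd.variational_laplace(
        spec, cohort, fixed_noise_precision=1.0 / sigma**2, tol=1e-9, max_iter=50)
    oracle = conjugate_cubic_oracle(cohort, spec, post.pmap, sigma)
    return post, oracle
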