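"""Bayesian model comparison and goodness-of-fit summaries.

Free-energy differences between models fitted to the identical data table
are log Bayes factors; under a uniform model prior the posterior model
probabilities are the softmax of the free energies.  Fit quality is
summarised per region by the root-mean-square error and compared between
model classes with a two-sample F test for equal residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forward import ForwardModel
from .io import LongitudinalCohort
from .vl import Posterior

__all__ = ["ModelComparison", "compare_models", "FitReport", "evaluate_fit",
           "f_test_equal_variance"]


@dataclass
class ModelComparison:
    """Free energies, log Bayes factors and model probabilities."""

    names: list
    free_energies: np.ndarray
    probabilities: np.ndarray
    best_index: int

    def log_bayes_factor(self, i: int, j: int) -> float:
        """log BF of model i over model j: F_i - F_j."""
        return float(self.free_energies[i] - self.free_energies[j])

    @property
    def best_name(self):
        return self.names[self.best_index]

    def table(self) -> pd.DataFrame:
        order = np.argsort(-self.free_energies)
        return pd.DataFrame({
            "model": [self.names[i] for i in order],
            "free_energy": self.free_energies[order],
            "log_bf_vs_best": self.free_energies[order]
            - self.free_energies[self.best_index],
            "probability": self.probabilities[order],
        })


def compare_models(posteriors: list[Posterior], names: list | None = None) -> ModelComparison:
    """Fixed-effects Bayesian model comparison over fitted posteriors.

    All posteriors must have been fitted to the identical data table
    (checked via the data fingerprint).  Ties in the best model are broken
    by the lowest free-parameter count.
    """
    if not posteriors:
        raise ValueError("no posteriors to compare")
    prints = {p.data_fingerprint for p in posteriors}
    if len(prints) > 1:
        raise ValueError("posteriors were fitted to different data tables")
    if names is None:
        names = [p.spec.label if p.spec is not None else f"model_{i}"
                 for i, p in enumerate(posteriors)]
    F = np.array([p.free_energy for p in posteriors], dtype=float)
    z = F - F.max()
    probs = np.exp(z) / np.sum(np.exp(z))
    best_F = F.max()
    candidates = [i for i in range(len(F)) if F[i] == best_F]
    best = min(candidates, key=lambda i: posteriors[i].n_free)
    return ModelComparison(names=list(names), free_energies=F,
                           probabilities=probs, best_index=best)


@dataclass
class FitReport:
    """Residual summaries for one fitted model."""

    rmse: pd.DataFrame  # rows: ROI, columns: groups + 'all'
    residuals: np.ndarray  # scans x D
    predictions: np.ndarray  # scans x D
    groups: tuple = ()


def evaluate_fit(posterior: Posterior, cohort: LongitudinalCohort) -> FitReport:
    """Per-region, per-group RMSE of posterior-mean predictions."""
    fm = ForwardModel(posterior.spec, cohort, pmap=posterior.pmap)
    pred = fm.predict(posterior.mean)
    resid = cohort.volumes - pred
    cols = {}
    for g in cohort.groups:
        rows = cohort.group_rows(g)
        cols[g] = np.sqrt(np.mean(resid[rows] ** 2, axis=0))
    cols["all"] = np.sqrt(np.mean(resid**2, axis=0))
    rmse = pd.DataFrame(cols, index=list(cohort.roi_names))
    return FitReport(rmse=rmse, residuals=resid, predictions=pred,
                     groups=cohort.groups)


def f_test_equal_variance(res_a: np.ndarray, res_b: np.ndarray):
    """Two-sample, two-sided F test for equal residual variances per region.

    Returns (F statistics, p-values); with 2-D inputs the test is applied
    column-wise (one test per ROI).  Identical residual sets give F = 1,
    p = 1.
    """
    res_a = np.atleast_2d(np.asarray(res_a, dtype=float).T).T
    res_b = np.atleast_2d(np.asarray(res_b, dtype=float).T).T
    n_a, n_b = res_a.shape[0], res_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two residuals per sample")
    var_a = res_a.var(axis=0, ddof=1)
    var_b = res_b.var(axis=0, ddof=1)
    F = var_a / var_b
    dist = stats.f(n_a - 1, n_b - 1)
    p = 2.0 * np.minimum(dist.cdf(F), dist.sf(F))
    p = np.minimum(p, 1.0)
    if F.size == 1:
        return float(F[0]), float(p[0])
    return F, p
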