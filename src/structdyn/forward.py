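"""Batched forward predictions for a model specification on a cohort.

The :class:`ForwardModel` binds a :class:`~structdyn.parameters.ModelSpec`
to a cohort: it owns the integration grid (model time zero anchored at the
onset age), the per-group scan lookup indices, the confound design matrix
(mean-centred TICV and site indicators with the first site as reference)
and the parameter map.  Predictions are produced for batches of free
vectors at once, which makes the finite-difference Jacobian a single
vectorised integration sweep.
"""

from __future__ import annotations

import numpy as np

from .dynamics import euler_trajectories, sample_indices, StateTrajectory
from .inputs import gaussian_growth, puberty_input
from .io import LongitudinalCohort
from .parameters import (
    CohortMeta,
    ModelSpec,
    ParameterMap,
    build_parameter_map,
)

__all__ = ["ForwardModel", "cohort_meta", "alpha_batch"]


def cohort_meta(cohort: LongitudinalCohort, spec: ModelSpec) -> CohortMeta:
    """Derive the parameter-map metadata (groups, ROIs, confounds, x0 priors).

    The x0 prior means are the per-ROI means of the earliest-age tertile of
    scans, per group and pooled.
    """
    groups = cohort.groups
    ages = cohort.ages
    vols = cohort.volumes
    x0_means: dict[str, np.ndarray] = {}
    for g in groups:
        rows = cohort.group_rows(g)
        cut = np.quantile(ages[rows], 1.0 / 3.0)
        early = rows[ages[rows] <= cut]
        x0_means[g] = vols[early].mean(axis=0)
    cut = np.quantile(ages, 1.0 / 3.0)
    x0_means["__pooled__"] = vols[ages <= cut].mean(axis=0)
    confound_names: tuple[str, ...] = ()
    if spec.include_confounds:
        confound_names = ("ticv",) + tuple(f"site:{s}" for s in cohort.sites[1:])
    return CohortMeta(
        groups=groups,
        roi_names=cohort.roi_names,
        confound_names=confound_names,
        x0_prior_mean=x0_means,
    )


def confound_matrix(cohort: LongitudinalCohort, spec: ModelSpec) -> np.ndarray:
    """Scans x Q design of confounds: centred TICV, one-hot sites (first dropped)."""
    if not spec.include_confounds:
        return np.zeros((cohort.n_scans, 0))
    ticv = cohort.data["ticv"].to_numpy(dtype=float)
    cols = [ticv - ticv.mean()]
    site = cohort.data["site"].astype(str).to_numpy()
    for s in cohort.sites[1:]:
        cols.append((site == s).astype(float))
    return np.column_stack(cols)


def alpha_batch(grid: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Forward-Euler alpha-function trajectories for a batch of taus.

    The grid starts at the onset age; u2 starts at 1 with the impulse
    realised as v2(0) = 20/tau.  Returns (P, T).
    """
    taus = np.asarray(taus, dtype=float)
    T = grid.size
    dt = float(grid[1] - grid[0]) if T > 1 else 0.0
    u = np.ones_like(taus)
    v = 20.0 / taus
    out = np.empty((taus.size, T))
    out[:, 0] = u
    for t in range(T - 1):
        u_new = u + dt * v
        v = v + dt * (-(2.0 / taus) * v - u / taus**2)
        u = u_new
        out[:, t + 1] = u
    return out


class ForwardModel:
    """Predicts scan-level ROI volumes from a free parameter vector."""

    def __init__(self, spec: ModelSpec, cohort: LongitudinalCohort,
                 pmap: ParameterMap | None = None):
        self.spec = spec
        self.cohort = cohort
        self.meta = cohort_meta(cohort, spec) if pmap is None else pmap.meta
        self.pmap = pmap if pmap is not None else build_parameter_map(spec, self.meta)
        n_steps = int(round((spec.t_max - spec.onset_age) / spec.dt))
        self.grid = spec.onset_age + spec.dt * np.arange(n_steps + 1)
        self.confounds = confound_matrix(cohort, spec)
        ages = cohort.ages
        self._group_rows = {g: cohort.group_rows(g) for g in self.meta.groups}
        self._scan_idx = {
            g: sample_indices(self.grid, ages[rows])
            for g, rows in self._group_rows.items()
        }
        # manifest puberty input is fixed per group
        self._puberty = {
            g: puberty_input(self.grid, spec.sigmoid_for(g)).values
            for g in self.meta.groups
        } if "puberty" in spec.inputs else {}
        self._cubic_powers = {
            g: np.vander(ages[rows] - spec.onset_age, N=4, increasing=True)
            for g, rows in self._group_rows.items()
        } if spec.family == "cubic" else {}

    @property
    def n_free(self) -> int:
        return self.pmap.n_free

    # -- prediction -------------------------------------------------------
    def _group_inputs(self, nat: np.ndarray, group: str) -> np.ndarray:
        """Input matrix for one group: (J, T) if fixed, (P, J, T) if batched."""
        spec = self.spec
        P = nat.shape[0]
        T = self.grid.size
        if spec.n_inputs == 0:
            return np.zeros((0, T))
        batched = ("alpha" in spec.inputs) or ("gaussian" in spec.inputs)
        if not batched:
            return np.vstack([self._puberty[group]])
        U = np.empty((P, spec.n_inputs, T))
        for j, name in enumerate(spec.inputs):
            if name == "puberty":
                U[:, j, :] = self._puberty[group][None, :]
            elif name == "alpha":
                taus = self.pmap.scatter_batch(nat, group, "tau")
                U[:, j, :] = alpha_batch(self.grid, taus)
            else:  # gaussian
                mg = self.pmap.scatter_batch(nat, group, "m_g")
                sg = self.pmap.scatter_batch(nat, group, "sigma")
                U[:, j, :] = np.exp(
                    -((self.grid[None, :] - mg[:, None]) ** 2) / (2.0 * sg[:, None] ** 2)
                )
        return U

    def predict_batch(self, free: np.ndarray) -> np.ndarray:
        """Predicted volumes for P free vectors: returns (P, scans, D)."""
        nat = self.pmap.natural_matrix(free)
        P = nat.shape[0]
        S, D = self.cohort.n_scans, self.meta.n_regions
        pred = np.empty((P, S, D))
        for g in self.meta.groups:
            rows = self._group_rows[g]
            if self.spec.family == "cubic":
                B = self.pmap.scatter_batch(nat, g, "B")  # (P, D, 4)
                pred[:, rows, :] = np.einsum("st,pdt->psd", self._cubic_powers[g], B)
            else:
                A = self.pmap.scatter_batch(nat, g, "A")
                C = self.pmap.scatter_batch(nat, g, "C")
                x0 = self.pmap.scatter_batch(nat, g, "x0")
                U = self._group_inputs(nat, g)
                X = euler_trajectories(A, C, x0, U, self.grid)  # (P, D, T)
                pred[:, rows, :] = X[:, :, self._scan_idx[g]].transpose(0, 2, 1)
        if self.confounds.shape[1]:
            b0 = self.pmap.scatter_batch(nat, self.meta.groups[0], "b0")  # (P, Q, D)
            pred += np.einsum("sq,pqd->psd", self.confounds, b0)
        return pred

    def predict(self, free: np.ndarray) -> np.ndarray:
        return self.predict_batch(np.atleast_2d(free))[0]

    def jacobian(self, free: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
        """Central finite-difference Jacobian of predictions: (scans, D, n_free)."""
        free = np.asarray(free, dtype=float)
        n = free.size
        h = rel_step * (1.0 + np.abs(free))
        pert = np.repeat(free[None, :], 2 * n, axis=0)
        pert[np.arange(n), np.arange(n)] += h
        pert[n + np.arange(n), np.arange(n)] -= h
        F = self.predict_batch(pert)  # (2n, S, D)
        J = (F[:n] - F[n:]) / (2.0 * h)[:, None, None]
        return np.ascontiguousarray(J.transpose(1, 2, 0))

    def trajectories(self, free: np.ndarray) -> dict:
        """Noise-free state trajectories per group at the given free vector."""
        if self.spec.family == "cubic":
            raise ValueError("cubic reference model has no state trajectory")
        nat = self.pmap.natural_matrix(free)
        out = {}
        for g in self.meta.groups:
            A = self.pmap.scatter_batch(nat, g, "A")
            C = self.pmap.scatter_batch(nat, g, "C")
            x0 = self.pmap.scatter_batch(nat, g, "x0")
            U = self._group_inputs(nat, g)
            X = euler_trajectories(A, C, x0, U, self.grid)[0]
            out[g] = StateTrajectory(time_grid=self.grid, X=X, x0=x0[0])
        return out
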