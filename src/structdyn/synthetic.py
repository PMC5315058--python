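"""Synthetic longitudinal cohorts with the statistical structure the model assumes.

The generator emulates the repeated-measures design of a large open
pediatric neuroimaging sample: 2-3 scans per subject at irregular ages
between 6 and 22 years, two gender groups, multi-site acquisition with
site offsets, a total-intracranial-volume (TICV) confound, regional
volumes on a [0, 100] scale, and i.i.d. Gaussian observation noise per
region.  Group trajectories are produced by the package's own forward
model, so estimation and model comparison can be validated against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import integrate_system, sample_indices, stability_check
from .inputs import (
    AlphaGrowthParams,
    GaussianGrowthParams,
    alpha_growth,
    gaussian_growth,
    puberty_input,
)
from .io import LongitudinalCohort
from .parameters import GroupParams, ModelSpec, SubnetworkSpec

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "SCENARIOS",
    "ROI_NAMES_26",
    "ANTERIOR_SUBNET",
    "POSTERIOR_SUBNET",
    "make_default_truth",
    "generate_cohort",
]

#: The 26 bilateral gray-matter ROIs of the probabilistic atlas parcellation.
ROI_NAMES_26 = (
    "Ins", "AntCinG", "PosCinG", "FroG", "InfFroG", "MidFroG", "SupFroG",
    "PrcG", "RecG", "AntMedTemL", "AntLatTemL", "SupTemG", "InfMidTemG",
    "FusG", "PosTemL", "PoCG", "LatParL", "SupParG", "Cun", "LatOccL",
    "LinG", "Hip", "Amy", "Put", "CauNuc", "Tha",
)

#: Anterior (executive-control) and posterior (default-mode) co-activation
#: subnetworks used for the a-priori coupling hypotheses.
ANTERIOR_SUBNET = ("AntCinG", "MidFroG", "SupFroG", "CauNuc", "Tha")
POSTERIOR_SUBNET = ("PosCinG", "Cun", "LatParL", "SupParG")

SCENARIOS = (
    "no_input", "puberty_only", "alpha_only", "gaussian_only",
    "puberty_plus_alpha", "coupled_within", "coupled_between",
)


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of a synthetic longitudinal cohort.

    Defaults emulate the reference pediatric sample: two gender groups,
    entry ages uniform over childhood/adolescence, 2-3 annual scans, six
    acquisition sites with small additive offsets, log-normal TICV with a
    weak age trend and a small per-region TICV coefficient, and Gaussian
    observation noise of sd 2 on the [0, 100] volume scale.
    """

    n_subjects: tuple = (100, 100)
    groups: tuple = ("F", "M")
    visit_prob3: float = 0.25
    target_scans: int | None = None
    entry_age_range: tuple = (6.0, 19.0)
    interval: float = 1.0
    sites: tuple = ("s1", "s2", "s3", "s4", "s5", "s6")
    site_offsets: tuple = (0.0, 0.8, -0.5, 0.3, -0.2, 0.5)
    ticv_mean: float = 1450.0
    ticv_log_sd: float = 0.05
    ticv_age_slope: float = 4.0
    ticv_coef: float = 0.004
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_subjects) != len(self.groups):
            raise ValueError("n_subjects must match groups")
        if len(self.site_offsets) != len(self.sites):
            raise ValueError("site_offsets must match sites")
        if not 0.0 <= self.visit_prob3 <= 1.0:
            raise ValueError("visit_prob3 must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Generating parameters (per group) together with their model spec."""

    spec: ModelSpec
    params: dict  # group label -> GroupParams
    roi_names: tuple
    b0: np.ndarray | None = None
    scenario: str = ""


def _subnets_for(roi_names: tuple) -> SubnetworkSpec:
    if tuple(roi_names) == ROI_NAMES_26:
        return SubnetworkSpec(anterior=ANTERIOR_SUBNET, posterior=POSTERIOR_SUBNET)
    D = len(roi_names)
    if D < 4:
        raise ValueError("coupled scenarios need at least 4 regions")
    half = 3 if D >= 6 else 2
    return SubnetworkSpec(
        anterior=tuple(roi_names[:half]), posterior=tuple(roi_names[half:2 * half])
    )


def make_default_truth(D: int = 8, scenario: str = "puberty_plus_alpha",
                       groups: tuple = ("F", "M"), onset_age: float = 6.0) -> GroundTruth:
    """Plausible generating parameters for each study scenario.

    Self-connections span [-0.03, -0.003] 1/years (slowest decay assigned
    to the designated puberty-sensitive regions), the latent growth
    sensitivity decreases along the region index (an anterior-to-posterior
    gradient), the puberty sensitivity is concentrated in the last two
    regions (the hippocampus/amygdala analogue), and the growth latency is
    shorter for the first group (girls earlier than boys).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario '{scenario}'; choose from {SCENARIOS}")
    if D < 2:
        raise ValueError("need at least 2 regions")
    roi_names = ROI_NAMES_26 if D == 26 else tuple(f"roi_{i+1:02d}" for i in range(D))

    inputs = {
        "no_input": (),
        "puberty_only": ("puberty",),
        "alpha_only": ("alpha",),
        "gaussian_only": ("gaussian",),
        "puberty_plus_alpha": ("puberty", "alpha"),
        "coupled_within": ("puberty", "alpha"),
        "coupled_between": ("puberty", "alpha"),
    }[scenario]
    coupling = {"coupled_within": "within_subnets",
                "coupled_between": "between_subnets"}.get(scenario, "self_only")
    subnets = _subnets_for(roi_names) if coupling != "self_only" else None
    spec = ModelSpec(
        inputs=inputs, coupling=coupling, subnetworks=subnets,
        coupling_sign="negative", onset_age=onset_age,
        include_confounds=False, name=scenario,
    )

    a_diag_first = np.linspace(-0.030, -0.005, D)
    x0 = np.linspace(72.0, 48.0, D)
    J = len(inputs)
    C = np.zeros((D, J))
    for j, name in enumerate(inputs):
        if name == "puberty":
            C[max(D - 2, 0):, j] = 2.0
        else:  # alpha or gaussian growth, anterior-posterior gradient
            C[:, j] = np.linspace(0.6, 0.1, D)

    name_to_idx = {r: i for i, r in enumerate(roi_names)}
    params: dict[str, GroupParams] = {}
    for gi, g in enumerate(groups):
        scale = 1.0 if gi == 0 else 0.6  # second group: weaker decay
        A = np.diag(a_diag_first * scale)
        if coupling != "self_only":
            ant = [name_to_idx[r] for r in subnets.anterior]
            post = [name_to_idx[r] for r in subnets.posterior]
            # strongest coupling inside the stability envelope of the blocks
            min_decay = np.min(np.abs(a_diag_first[sorted(set(ant) | set(post))]))
            cpl = -min(0.006, 0.5 * min_decay) * scale
            if coupling == "within_subnets":
                pairs = [(i, k) for blk in (ant, post)
                         for i in blk for k in blk if i < k]
            else:
                pairs = [(i, k) for i in ant for k in post]
            for i, k in pairs:
                A[i, k] = A[k, i] = cpl
        gp = GroupParams(A=A, C=C.copy(), x0=x0.copy(),
                         b0=np.zeros((0, D)))
        if "alpha" in inputs:
            gp.tau = 2.0 if gi == 0 else 3.0
        if "gaussian" in inputs:
            gp.m_g = 7.0 if gi == 0 else 8.0
            gp.sigma = 2.0
        abscissa, stable = stability_check(A, dt=spec.dt)
        if not stable or abscissa >= 0:
            raise ValueError(f"generating dynamics unstable for group {g}")
        params[g] = gp
    return GroundTruth(spec=spec, params=params, roi_names=roi_names,
                       scenario=scenario)


def _group_trajectory(truth: GroundTruth, group: str, grid: np.ndarray):
    spec = truth.spec
    gp = truth.params[group]
    inputs = []
    for name in spec.inputs:
        if name == "puberty":
            inputs.append(puberty_input(grid, spec.sigmoid_for(group)))
        elif name == "alpha":
            inputs.append(alpha_growth(
                grid, AlphaGrowthParams(tau=gp.tau, onset_age=spec.onset_age)))
        else:
            inputs.append(gaussian_growth(
                grid, GaussianGrowthParams(m_g=gp.m_g, sigma=gp.sigma)))
    return integrate_system(gp.A, gp.C if inputs else None, inputs, gp.x0, grid)


def generate_cohort(design: CohortDesign, truth: GroundTruth,
                    seed: int | None = None):
    """Generate a tidy cohort table from the ground-truth model.

    Integrates the generating model per group, samples each subject's scan
    ages at the nearest grid point, adds site offsets, the TICV confound
    effect and Gaussian noise.  The same seed always yields the identical
    table.  Returns (cohort, truth) where the returned truth record also
    carries the confound coefficient matrix actually applied.
    """
    spec = truth.spec
    rng = np.random.default_rng(design.seed if seed is None else seed)
    max_age = design.entry_age_range[1] + 2 * design.interval
    if design.entry_age_range[0] < spec.onset_age or max_age > spec.t_max + 1e-9:
        raise ValueError(
            f"design scan ages [{design.entry_age_range[0]}, {max_age}] fall "
            f"outside the integration window [{spec.onset_age}, {spec.t_max}]"
        )
    n_steps = int(round((spec.t_max - spec.onset_age) / spec.dt))
    grid = spec.onset_age + spec.dt * np.arange(n_steps + 1)
    trajectories = {g: _group_trajectory(truth, g, grid) for g in design.groups}

    n_total = int(sum(design.n_subjects))
    # visits per subject: 2 or 3
    if design.target_scans is not None:
        n3 = design.target_scans - 2 * n_total
        if not 0 <= n3 <= n_total:
            raise ValueError("target_scans not reachable with 2-3 visits per subject")
        visits = np.full(n_total, 2, dtype=int)
        visits[rng.choice(n_total, size=n3, replace=False)] = 3
    else:
        visits = 2 + (rng.random(n_total) < design.visit_prob3).astype(int)

    D = len(truth.roi_names)
    rows = []
    subj = 0
    for gi, g in enumerate(design.groups):
        traj = trajectories[g]
        for _ in range(design.n_subjects[gi]):
            v = visits[subj]
            entry = rng.uniform(*design.entry_age_range)
            ages = entry + design.interval * np.arange(v)
            site_i = rng.integers(len(design.sites))
            ticv_base = design.ticv_mean * np.exp(
                rng.normal(0.0, design.ticv_log_sd))
            idx = sample_indices(grid, ages)
            states = traj.X[:, idx].T  # v x D
            for k in range(v):
                ticv = ticv_base + design.ticv_age_slope * (ages[k] - 12.0)
                vol = (
                    states[k]
                    + design.site_offsets[site_i]
                    + design.ticv_coef * (ticv - design.ticv_mean)
                )
                rows.append({
                    "subject_id": f"{g}{subj + 1:04d}",
                    "group": g,
                    "site": design.sites[site_i],
                    "age_years": float(ages[k]),
                    "ticv": round(float(ticv), 2),
                    **{roi: vol[d] for d, roi in enumerate(truth.roi_names)},
                })
            subj += 1
    df = pd.DataFrame(rows)
    noise = rng.normal(0.0, 1.0, size=(len(df), D)) * np.broadcast_to(
        np.asarray(design.noise_sd, dtype=float), (D,)
    )
    df.loc[:, list(truth.roi_names)] = df.loc[:, list(truth.roi_names)].to_numpy() + noise
    cohort = LongitudinalCohort(data=df, roi_names=truth.roi_names)
    # record the confound coefficients implied by the design
    Q = 1 + max(len(design.sites) - 1, 0)
    b0 = np.zeros((Q, D))
    b0[0, :] = design.ticv_coef
    for q, off in enumerate(design.site_offsets[1:], start=1):
        b0[q, :] = off - design.site_offsets[0]
    truth_out = replace_truth_b0(truth, b0)
    return cohort, truth_out


def replace_truth_b0(truth: GroundTruth, b0: np.ndarray) -> GroundTruth:
    return GroundTruth(spec=truth.spec, params=truth.params,
                       roi_names=truth.roi_names, b0=b0, scenario=truth.scenario)
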