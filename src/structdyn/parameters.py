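"""Model specification and the mapping between free and natural parameters.

A :class:`ModelSpec` declares one candidate generative model: which
developmental inputs it uses, the coupling topology of the connection
matrix (with optional subnetwork restriction, symmetry and sign
constraints), which parameter blocks are shared across groups, the onset
age anchoring model time zero, and the priors.

The :class:`ParameterMap` is a bijection between the unconstrained free
vector optimised during inversion and the structured natural parameters
{A, C, tau or (m_g, sigma), x(0), confound coefficients} per group.  Sign
constraints are enforced through exponential transforms: a
negative-constrained entry is -exp(lambda), a positive one +exp(lambda).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .inputs import REFERENCE_SIGMOID_PARAMS, SigmoidParams

__all__ = [
    "PriorSpec",
    "SubnetworkSpec",
    "ModelSpec",
    "FreeParameter",
    "ParameterMap",
    "GroupParams",
    "CohortMeta",
    "build_parameter_map",
    "transform_parameters",
    "structured_to_free",
    "spec_from_dict",
]

COUPLINGS = ("self_only", "within_subnets", "between_subnets", "full")
SIGNS = ("negative", "positive", "unconstrained")
SHARINGS = ("shared", "per_group")
INPUT_NAMES = ("puberty", "alpha", "gaussian")


@dataclass(frozen=True)
class PriorSpec:
    """Prior means/variances in the unconstrained space, per parameter block.

    Self-connections are -exp(lambda) with lambda ~ N(ln 0.01, 1); couplings
    +/-exp(lambda) with lambda ~ N(ln 0.001, 1) (identity-scale N(0, 1e-4)
    when unconstrained); sensitivities N(0, 1) on the identity scale; the
    alpha latency tau = exp(lambda) with lambda ~ N(ln 2, 0.25); Gaussian
    growth mean on the identity scale; initial states N(tertile mean, 25);
    confound coefficients N(0, 100).  The per-region noise log-precision
    hyperprior is N(0, 16) (very weak).
    """

    self_log_mean: float = math.log(0.01)
    self_log_var: float = 1.0
    coupling_log_mean: float = math.log(0.001)
    coupling_log_var: float = 1.0
    coupling_id_var: float = 1e-4
    sens_mean: float = 0.0
    sens_var: float = 1.0
    tau_log_mean: float = math.log(2.0)
    tau_log_var: float = 0.25
    mg_offset: float = 2.0  # prior mean of m_g is onset_age + this
    mg_var: float = 4.0
    sigma_log_mean: float = math.log(2.0)
    sigma_log_var: float = 0.25
    x0_var: float = 25.0
    b0_var: float = 100.0
    cubic_var: tuple[float, float, float, float] = (25.0, 4.0, 0.25, 0.01)
    noise_logprec_mean: float = 0.0
    noise_logprec_var: float = 16.0

    def __post_init__(self) -> None:
        for name in ("self_log_var", "coupling_log_var", "sens_var", "tau_log_var",
                     "mg_var", "sigma_log_var", "x0_var", "b0_var", "noise_logprec_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior variance {name} must be positive")


@dataclass(frozen=True)
class SubnetworkSpec:
    """Two a-priori ROI subnetworks restricting the coupling topology."""

    anterior: tuple[str, ...]
    posterior: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.anterior) & set(self.posterior):
            raise ValueError("subnetworks must be disjoint")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model."""

    inputs: tuple[str, ...] = ("puberty", "alpha")
    coupling: str = "self_only"
    subnetworks: SubnetworkSpec | None = None
    coupling_sign: str = "negative"
    symmetric: bool = True
    group_sharing: dict = field(
        default_factory=lambda: {"x0": "per_group", "A": "per_group",
                                 "C": "shared", "latency": "per_group"}
    )
    onset_age: float = 6.0
    t_max: float = 22.0
    dt: float = 0.1
    include_confounds: bool = True
    family: str = "dynamical"  # or "cubic"
    sigmoid_params: dict | None = None  # group label -> SigmoidParams
    priors: PriorSpec = field(default_factory=PriorSpec)
    name: str = ""

    def __post_init__(self) -> None:
        inputs = tuple(i for i in self.inputs if i != "none")
        object.__setattr__(self, "inputs", inputs)
        unknown = set(inputs) - set(INPUT_NAMES)
        if unknown:
            raise ValueError(f"unknown inputs: {sorted(unknown)}")
        if "alpha" in inputs and "gaussian" in inputs:
            raise ValueError("at most one latent growth input (alpha or gaussian)")
        if self.coupling not in COUPLINGS:
            raise ValueError(f"unknown coupling '{self.coupling}'")
        if self.coupling_sign not in SIGNS:
            raise ValueError(f"unknown sign constraint '{self.coupling_sign}'")
        if self.family not in ("dynamical", "cubic"):
            raise ValueError(f"unknown model family '{self.family}'")
        for block, mode in self.group_sharing.items():
            if mode not in SHARINGS:
                raise ValueError(f"group sharing for '{block}' must be one of {SHARINGS}")
        if self.coupling in ("within_subnets", "between_subnets") and self.subnetworks is None:
            raise ValueError(f"coupling '{self.coupling}' requires subnetwork definitions")
        if not (self.onset_age < self.t_max):
            raise ValueError("onset_age must precede t_max")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def sharing(self, block: str) -> str:
        return self.group_sharing.get(block, "shared")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def sigmoid_for(self, group: str) -> SigmoidParams:
        table = self.sigmoid_params or REFERENCE_SIGMOID_PARAMS
        if group in table:
            return table[group]
        # single shared curve fallback
        if len(table) == 1:
            return next(iter(table.values()))
        raise KeyError(f"no sigmoid parameters for group '{group}'")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        ins = "+".join(self.inputs) if self.inputs else "none"
        return f"{self.family}:{ins}:{self.coupling}"


TRANSFORMS = ("identity", "neg_exp", "pos_exp")


@dataclass(frozen=True)
class FreeParameter:
    """One entry of the free vector with its prior and scatter targets.

    ``targets`` is a list of (group_label, field, flat_index); a shared
    parameter targets every group, a symmetric coupling targets both (i, k)
    and (k, i).
    """

    name: str
    block: str
    transform: str
    prior_mean: float
    prior_var: float
    targets: tuple

    def natural(self, value: float) -> float:
        if self.transform == "neg_exp":
            return -math.exp(value)
        if self.transform == "pos_exp":
            return math.exp(value)
        return value

    def free_from_natural(self, value: float) -> float:
        if self.transform == "neg_exp":
            if value >= 0:
                raise ValueError(f"{self.name}: negative-constrained value must be < 0")
            return math.log(-value)
        if self.transform == "pos_exp":
            if value <= 0:
                raise ValueError(f"{self.name}: positive-constrained value must be > 0")
            return math.log(value)
        return value


@dataclass
class GroupParams:
    """Structured natural parameters for one group."""

    A: np.ndarray
    C: np.ndarray
    x0: np.ndarray
    b0: np.ndarray
    tau: float | None = None
    m_g: float | None = None
    sigma: float | None = None
    B: np.ndarray | None = None


@dataclass
class CohortMeta:
    """The cohort-side information a parameter map needs."""

    groups: tuple[str, ...]
    roi_names: tuple[str, ...]
    confound_names: tuple[str, ...] = ()
    x0_prior_mean: dict = field(default_factory=dict)  # group -> (D,) array

    @property
    def n_regions(self) -> int:
        return len(self.roi_names)

    @property
    def n_confounds(self) -> int:
        return len(self.confound_names)


class ParameterMap:
    """Ordered free parameters plus vectorised scatter machinery."""

    def __init__(self, entries: list[FreeParameter], meta: CohortMeta, spec: ModelSpec):
        self.entries = list(entries)
        self.meta = meta
        self.spec = spec
        self.names = [e.name for e in self.entries]
        self.prior_mean = np.array([e.prior_mean for e in self.entries])
        self.prior_var = np.array([e.prior_var for e in self.entries])
        self._neg = np.array([e.transform == "neg_exp" for e in self.entries])
        self._pos = np.array([e.transform == "pos_exp" for e in self.entries])
        # scatter index lists: (group, field) -> (param_idx array, flat target array)
        self._scatter: dict = {}
        for j, e in enumerate(self.entries):
            for (group, fieldname, flat) in e.targets:
                key = (group, fieldname)
                self._scatter.setdefault(key, ([], []))
                self._scatter[key][0].append(j)
                self._scatter[key][1].append(flat)
        self._scatter = {
            k: (np.asarray(p, dtype=int), np.asarray(t, dtype=int))
            for k, (p, t) in self._scatter.items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_free(self) -> int:
        return len(self.entries)

    def natural_matrix(self, free: np.ndarray) -> np.ndarray:
        """Apply the per-parameter transforms columnwise; free is (P, n) or (n,)."""
        free = np.atleast_2d(np.asarray(free, dtype=float))
        if free.shape[1] != self.n_free:
            raise ValueError(
                f"free vector has length {free.shape[1]}, map expects {self.n_free}"
            )
        nat = free.copy()
        if self._neg.any():
            nat[:, self._neg] = -np.exp(free[:, self._neg])
        if self._pos.any():
            nat[:, self._pos] = np.exp(free[:, self._pos])
        return nat

    def field_shape(self, fieldname: str) -> tuple:
        D = self.meta.n_regions
        J = self.spec.n_inputs
        Q = self.meta.n_confounds if self.spec.include_confounds else 0
        return {
            "A": (D, D), "C": (D, J), "x0": (D,), "b0": (Q, D),
            "tau": (), "m_g": (), "sigma": (), "B": (D, 4),
        }[fieldname]

    def scatter_batch(self, nat: np.ndarray, group: str, fieldname: str) -> np.ndarray:
        """Build the batched natural array (P, *shape) for one group field."""
        P = nat.shape[0]
        shape = self.field_shape(fieldname)
        size = int(np.prod(shape)) if shape else 1
        out = np.zeros((P, size))
        key = (group, fieldname)
        if key in self._scatter:
            pidx, tidx = self._scatter[key]
            out[:, tidx] = nat[:, pidx]
        return out.reshape((P,) + shape) if shape else out[:, 0]


def _x0_prior_mean(meta: CohortMeta, group: str | None) -> np.ndarray:
    D = meta.n_regions
    if group is not None and group in meta.x0_prior_mean:
        return np.asarray(meta.x0_prior_mean[group], dtype=float)
    if "__pooled__" in meta.x0_prior_mean:
        return np.asarray(meta.x0_prior_mean["__pooled__"], dtype=float)
    if meta.x0_prior_mean:
        return np.mean([np.asarray(v, float) for v in meta.x0_prior_mean.values()], axis=0)
    return np.full(D, 50.0)


def _coupling_pairs(spec: ModelSpec, roi_names: tuple[str, ...]) -> list[tuple[int, int]]:
    """Unordered (i < k) region pairs that carry a free coupling parameter."""
    if spec.coupling == "self_only":
        return []
    name_to_idx = {r: i for i, r in enumerate(roi_names)}
    if spec.subnetworks is not None:
        missing = [r for r in (*spec.subnetworks.anterior, *spec.subnetworks.posterior)
                   if r not in name_to_idx]
        if missing:
            raise ValueError(f"subnetwork ROIs not in cohort: {missing}")
        ant = [name_to_idx[r] for r in spec.subnetworks.anterior]
        post = [name_to_idx[r] for r in spec.subnetworks.posterior]
    else:
        if spec.coupling in ("within_subnets", "between_subnets"):
            raise ValueError(f"coupling '{spec.coupling}' requires subnetworks")
        ant, post = list(range(len(roi_names))), []
    if spec.coupling == "within_subnets":
        pairs = list(itertools.combinations(sorted(ant), 2))
        pairs += list(itertools.combinations(sorted(post), 2))
    elif spec.coupling == "between_subnets":
        pairs = [(min(i, k), max(i, k)) for i in ant for k in post]
    else:  # full coupling over the union of subnetwork ROIs (or all ROIs)
        domain = sorted(set(ant) | set(post))
        pairs = list(itertools.combinations(domain, 2))
    return sorted(set(pairs))


def build_parameter_map(spec: ModelSpec, meta: CohortMeta) -> ParameterMap:
    """Enumerate the free parameters implied by a model specification.

    The count is: D initial states per x0 binding, the masked connection
    entries (diagonal always free for dynamical models; symmetric couplings
    counted once) per A binding, the D x J sensitivities per C binding, one
    latency per latent-input binding, and Q x D confound coefficients.
    """
    pr = spec.priors
    D = meta.n_regions
    groups = meta.groups
    rois = meta.roi_names
    entries: list[FreeParameter] = []

    def bindings(block: str):
        if spec.sharing(block) == "per_group":
            return [(g, (g,)) for g in groups]
        return [(None, tuple(groups))]

    def flat(fieldname: str, idx: tuple) -> int:
        shape = {"A": (D, D), "C": (D, spec.n_inputs), "x0": (D,),
                 "b0": (len(meta.confound_names), D), "B": (D, 4)}[fieldname]
        return int(np.ravel_multi_index(idx, shape))

    if spec.family == "cubic":
        for label, targets in bindings("B"):
            suffix = f"[{label}]" if label else ""
            for i, roi in enumerate(rois):
                for r in range(4):
                    mean = _x0_prior_mean(meta, label)[i] if r == 0 else 0.0
                    entries.append(FreeParameter(
                        name=f"B_{roi}_t{r}{suffix}", block="B", transform="identity",
                        prior_mean=float(mean), prior_var=pr.cubic_var[r],
                        targets=tuple((g, "B", flat("B", (i, r))) for g in targets),
                    ))
    else:
        # initial states
        for label, targets in bindings("x0"):
            suffix = f"[{label}]" if label else ""
            m = _x0_prior_mean(meta, label)
            for i, roi in enumerate(rois):
                entries.append(FreeParameter(
                    name=f"x0_{roi}{suffix}", block="x0", transform="identity",
                    prior_mean=float(m[i]), prior_var=pr.x0_var,
                    targets=tuple((g, "x0", i) for g in targets),
                ))
        # self-connections (always free, negative)
        for label, targets in bindings("A"):
            suffix = f"[{label}]" if label else ""
            for i, roi in enumerate(rois):
                entries.append(FreeParameter(
                    name=f"a_{roi}_{roi}{suffix}", block="A", transform="neg_exp",
                    prior_mean=pr.self_log_mean, prior_var=pr.self_log_var,
                    targets=tuple((g, "A", flat("A", (i, i))) for g in targets),
                ))
        # between-region couplings
        pairs = _coupling_pairs(spec, rois)
        if spec.coupling_sign == "negative":
            tr, cmean, cvar = "neg_exp", pr.coupling_log_mean, pr.coupling_log_var
        elif spec.coupling_sign == "positive":
            tr, cmean, cvar = "pos_exp", pr.coupling_log_mean, pr.coupling_log_var
        else:
            tr, cmean, cvar = "identity", 0.0, pr.coupling_id_var
        for label, targets in bindings("A"):
            suffix = f"[{label}]" if label else ""
            for (i, k) in pairs:
                if spec.symmetric:
                    tgt = tuple((g, "A", flat("A", idx)) for g in targets
                                for idx in ((i, k), (k, i)))
                    entries.append(FreeParameter(
                        name=f"a_{rois[i]}_{rois[k]}{suffix}", block="A", transform=tr,
                        prior_mean=cmean, prior_var=cvar, targets=tgt,
                    ))
                else:
                    for idx in ((i, k), (k, i)):
                        entries.append(FreeParameter(
                            name=f"a_{rois[idx[0]]}_{rois[idx[1]]}{suffix}", block="A",
                            transform=tr, prior_mean=cmean, prior_var=cvar,
                            targets=tuple((g, "A", flat("A", idx)) for g in targets),
                        ))
        # sensitivities
        for label, targets in bindings("C"):
            suffix = f"[{label}]" if label else ""
            for j, input_name in enumerate(spec.inputs):
                for i, roi in enumerate(rois):
                    entries.append(FreeParameter(
                        name=f"c_{roi}_{input_name}{suffix}", block="C",
                        transform="identity", prior_mean=pr.sens_mean,
                        prior_var=pr.sens_var,
                        targets=tuple((g, "C", flat("C", (i, j))) for g in targets),
                    ))
        # latent-input latency parameters
        if "alpha" in spec.inputs:
            for label, targets in bindings("latency"):
                suffix = f"[{label}]" if label else ""
                entries.append(FreeParameter(
                    name=f"tau{suffix}", block="tau", transform="pos_exp",
                    prior_mean=pr.tau_log_mean, prior_var=pr.tau_log_var,
                    targets=tuple((g, "tau", 0) for g in targets),
                ))
        if "gaussian" in spec.inputs:
            for label, targets in bindings("latency"):
                suffix = f"[{label}]" if label else ""
                entries.append(FreeParameter(
                    name=f"m_g{suffix}", block="m_g", transform="identity",
                    prior_mean=spec.onset_age + pr.mg_offset, prior_var=pr.mg_var,
                    targets=tuple((g, "m_g", 0) for g in targets),
                ))
            entries.append(FreeParameter(
                name="sigma_g", block="sigma", transform="pos_exp",
                prior_mean=pr.sigma_log_mean, prior_var=pr.sigma_log_var,
                targets=tuple((g, "sigma", 0) for g in groups),
            ))
    # confound coefficients (shared across groups by construction)
    if spec.include_confounds:
        for q, cname in enumerate(meta.confound_names):
            for i, roi in enumerate(rois):
                entries.append(FreeParameter(
                    name=f"b0_{cname}_{roi}", block="b0", transform="identity",
                    prior_mean=0.0, prior_var=pr.b0_var,
                    targets=tuple((g, "b0", flat("b0", (q, i))) for g in groups),
                ))
    return ParameterMap(entries, meta, spec)


def transform_parameters(free_vector: np.ndarray, pmap: ParameterMap) -> dict:
    """Map a free vector to structured natural parameters per group."""
    nat = pmap.natural_matrix(free_vector)
    out: dict[str, GroupParams] = {}
    spec = pmap.spec
    for g in pmap.meta.groups:
        gp = GroupParams(
            A=pmap.scatter_batch(nat, g, "A")[0],
            C=pmap.scatter_batch(nat, g, "C")[0],
            x0=pmap.scatter_batch(nat, g, "x0")[0],
            b0=pmap.scatter_batch(nat, g, "b0")[0],
        )
        if "alpha" in spec.inputs:
            gp.tau = float(pmap.scatter_batch(nat, g, "tau")[0])
        if "gaussian" in spec.inputs:
            gp.m_g = float(pmap.scatter_batch(nat, g, "m_g")[0])
            gp.sigma = float(pmap.scatter_batch(nat, g, "sigma")[0])
        if spec.family == "cubic":
            gp.B = pmap.scatter_batch(nat, g, "B")[0]
        out[g] = gp
    return out


def structured_to_free(params_by_group: dict, pmap: ParameterMap) -> np.ndarray:
    """Inverse of :func:`transform_parameters` on the constraint set."""
    free = np.empty(pmap.n_free)
    for j, e in enumerate(pmap.entries):
        group, fieldname, flat = e.targets[0]
        gp = params_by_group[group]
        value = getattr(gp, fieldname)
        if fieldname in ("tau", "m_g", "sigma"):
            nat = float(value)
        else:
            nat = float(np.asarray(value).ravel()[flat])
        free[j] = e.free_from_natural(nat)
    return free


def spec_from_dict(d: dict) -> ModelSpec:
    """Build a ModelSpec from a plain (e.g. YAML-loaded) dictionary."""
    d = dict(d)
    if "subnetworks" in d and d["subnetworks"] is not None and not isinstance(
        d["subnetworks"], SubnetworkSpec
    ):
        sn = d["subnetworks"]
        d["subnetworks"] = SubnetworkSpec(
            anterior=tuple(sn["anterior"]), posterior=tuple(sn["posterior"])
        )
    if "inputs" in d:
        d["inputs"] = tuple(d["inputs"])
    if "sigmoid_params" in d and d["sigmoid_params"] is not None:
        d["sigmoid_params"] = {
            g: v if isinstance(v, SigmoidParams) else SigmoidParams(**v)
            for g, v in d["sigmoid_params"].items()
        }
    if "priors" in d and d["priors"] is not None and not isinstance(d["priors"], PriorSpec):
        d["priors"] = PriorSpec(**d["priors"])
    return ModelSpec(**d)
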