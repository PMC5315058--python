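"""Cohort table reading, writing, validation and ROI rescaling.

The cohort dialect is a UTF-8, comma-delimited table with a header row and
columns ``subject_id, group, site, age_years, ticv`` followed by one column
per ROI volume.  ROI column order defines the state index order and is
preserved in all outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalCohort",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_puberty_table",
    "rescale_rois",
]

REQUIRED_COLUMNS = ("subject_id", "group", "site", "age_years", "ticv")


@dataclass
class LongitudinalCohort:
    """Scan-level longitudinal table: one row per scan, one column per ROI.

    ``scaling`` records the per-ROI affine map applied by
    :func:`rescale_rois`: scaled = (raw - offset) * factor, so raw values
    can be recovered exactly.
    """

    data: pd.DataFrame
    roi_names: tuple[str, ...]
    scaling: dict | None = None  # roi -> (offset, factor)

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        missing = [c for c in (*REQUIRED_COLUMNS, *self.roi_names)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        ages = pd.to_numeric(self.data["age_years"], errors="coerce")
        if ages.isna().any():
            rows = list(self.data.index[ages.isna()][:5])
            raise ValueError(f"non-numeric age_years in rows {rows}")
        for roi in self.roi_names:
            vol = pd.to_numeric(self.data[roi], errors="coerce")
            if vol.isna().any():
                rows = list(self.data.index[vol.isna()][:5])
                raise ValueError(f"non-numeric volumes for ROI '{roi}' in rows {rows}")
        dup = self.data.duplicated(subset=["subject_id", "age_years"])
        if dup.any():
            rows = list(self.data.index[dup][:5])
            raise ValueError(f"duplicate (subject_id, age_years) rows: {rows}")
        if not ((ages > 0) & (ages < 120)).all():
            rows = list(self.data.index[~((ages > 0) & (ages < 120))][:5])
            raise ValueError(f"implausible ages in rows {rows}")

    # -- convenient views -------------------------------------------------
    @property
    def n_scans(self) -> int:
        return len(self.data)

    @property
    def n_regions(self) -> int:
        return len(self.roi_names)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["group"].astype(str).unique()))

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["site"].astype(str).unique()))

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_years"].to_numpy(dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        """Scans x D matrix of ROI volumes in ROI-name order."""
        return self.data.loc[:, list(self.roi_names)].to_numpy(dtype=float)

    def group_rows(self, group: str) -> np.ndarray:
        return np.nonzero((self.data["group"].astype(str) == group).to_numpy())[0]

    def fingerprint(self) -> str:
        """Hash of the modelled data (ages, groups, volumes), for comparison checks."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.ages).tobytes())
        h.update(",".join(self.data["group"].astype(str)).encode())
        h.update(np.ascontiguousarray(self.volumes).tobytes())
        return h.hexdigest()[:16]


def read_cohort(path, roi_names=None) -> LongitudinalCohort:
    """Read and validate a cohort table.

    ROI columns are auto-detected as every column after the required five,
    unless an explicit ``roi_names`` list is given.  Malformed input is
    rejected rather than coerced.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table at {path} is missing columns: {missing}")
    if roi_names is None:
        roi_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not roi_names:
        raise ValueError(f"cohort table at {path} has no ROI columns")
    return LongitudinalCohort(data=df, roi_names=tuple(roi_names))


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    cols = list(REQUIRED_COLUMNS) + list(cohort.roi_names)
    cohort.data.loc[:, cols].to_csv(path, index=False)


def read_puberty_table(path, already_scaled: bool = False) -> pd.DataFrame:
    """Read a pubertal-status table (subject_id, group, age_years, score).

    Raw 1-4 stage means are rescaled to [0, 1] via (mean - 1)/3 unless
    ``already_scaled`` is set.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "group", "age_years", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"puberty table missing columns: {missing}")
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        rows = list(df.index[score.isna()][:5])
        raise ValueError(f"non-numeric scores in rows {rows}")
    if not already_scaled:
        df = df.assign(score=(score - 1.0) / 3.0)
    if ((df["score"] < -1e-9) | (df["score"] > 1 + 1e-9)).any():
        raise ValueError("scores outside [0,1] after rescaling; check the scaling flag")
    return df


def rescale_rois(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Per-ROI linear min-max rescaling of raw volumes onto [0, 100].

    The (offset, factor) constants are stored on the returned cohort so the
    mapping can be inverted: raw = scaled / factor + offset.
    """
    df = cohort.data.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for roi in cohort.roi_names:
        col = df[roi].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            raise ValueError(f"ROI '{roi}' is constant; cannot rescale")
        factor = 100.0 / (hi - lo)
        df[roi] = (col - lo) * factor
        scaling[roi] = (lo, factor)
    return LongitudinalCohort(data=df, roi_names=cohort.roi_names, scaling=scaling)


def inverse_rescale(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Undo :func:`rescale_rois` using the stored constants."""
    if not cohort.scaling:
        raise ValueError("cohort carries no scaling constants")
    df = cohort.data.copy()
    for roi, (offset, factor) in cohort.scaling.items():
        df[roi] = df[roi].to_numpy(dtype=float) / factor + offset
    return LongitudinalCohort(data=df, roi_names=cohort.roi_names, scaling=None)
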