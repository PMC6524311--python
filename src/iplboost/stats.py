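"""Displacement summary statistics.

Per-axis (signed) and radial (Euclidean 3D distance) displacement
statistics of a trajectory set, pooled over all fractions and patients
with every sample weighted equally, or stratified by patient. The ten
statistics are mean, standard deviation, min, the 5/25/50/75/95 %
quantiles, max and root mean square.

Quantiles use linear interpolation between order statistics (the
"type 7" convention, numpy's default); standard deviation is the
sample standard deviation (ddof=1). Neither choice is forced by the
science — they are fixed so results reproduce bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .trajectories import TrajectorySet

__all__ = [
    "DisplacementSample",
    "SummaryStats",
    "radial_distance",
    "summarize",
    "displacement_table",
    "STAT_NAMES",
    "AXIS_NAMES",
]

#: Row order of every statistics table produced by this module.
STAT_NAMES = ["mean", "std", "min", "q05", "q25", "median", "q75", "q95", "max", "rms"]

#: Column order of displacement tables (mirrors the usual reporting layout).
AXIS_NAMES = ["longitudinal", "lateral", "vertical", "radial"]

_AXIS_TO_COLUMN = {
    "longitudinal": "long_mm",
    "lateral": "lat_mm",
    "vertical": "vert_mm",
}


@dataclass(frozen=True)
class DisplacementSample:
    """One time-stamped 3D displacement of the prostate centre.

    ``lat``, ``long`` and ``vert`` are signed displacements in mm from
    the start-of-fraction position; ``t`` is elapsed seconds. The
    radial distance ``d`` is always derived, never stored.
    """

    patient_id: object
    fraction_id: object
    t: float
    lat: float
    long: float
    vert: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise DataError("elapsed time must be >= 0")

    @property
    def d(self) -> float:
        """Euclidean 3D distance from the starting position, in mm."""
        return math.sqrt(self.lat**2 + self.long**2 + self.vert**2)


def radial_distance(sample) -> float:
    """Euclidean 3D distance ('vector length') of a displacement.

    Accepts a :class:`DisplacementSample` or any (lat, long, vert)
    triple.
    """
    if isinstance(sample, DisplacementSample):
        return sample.d
    lat, lon, vert = sample
    return math.sqrt(lat**2 + lon**2 + vert**2)


@dataclass(frozen=True)
class SummaryStats:
    """The ten summary statistics, in the input's units."""

    mean: float
    std: float
    min: float
    q05: float
    q25: float
    median: float
    q75: float
    q95: float
    max: float
    rms: float

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in STAT_NAMES})


def summarize(values) -> SummaryStats:
    """Compute all ten summary statistics of a non-empty sample."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise DataError("cannot summarize an empty sample")
    q = np.quantile(arr, [0.05, 0.25, 0.5, 0.75, 0.95], method="linear")
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(arr.mean()),
        std=std,
        min=float(arr.min()),
        q05=float(q[0]),
        q25=float(q[1]),
        median=float(q[2]),
        q75=float(q[3]),
        q95=float(q[4]),
        max=float(arr.max()),
        rms=float(np.sqrt(np.mean(arr**2))),
    )


def _axis_table(ts: TrajectorySet) -> pd.DataFrame:
    cols = {}
    for axis, col in _AXIS_TO_COLUMN.items():
        cols[axis] = summarize(ts.data[col].to_numpy(dtype=float)).as_series()
    cols["radial"] = summarize(ts.radial()).as_series()
    table = pd.DataFrame(cols)[AXIS_NAMES]
    table.index.name = "statistic"
    return table

def displacement_table(
    trajectories: TrajectorySet,
    group_by: str | None = None,
    include_anchor: bool = True,
) -> pd.DataFrame:
    """Summary statistics per axis and for the radial distance.

    Pooled over all samples with equal weight (``group_by=None``) or
    stratified per patient (``group_by="patient"``, returning a frame
    with a (patient_id, statistic) MultiIndex). ``include_anchor``
    controls whether the t=0 reference sample of each fraction enters
    the pool; it is a recorded position and included by default.
    """
    if group_by not in (None, "patient"):
        raise DataError(f"group_by must be None or 'patient', got {group_by!r}")
    if not include_anchor:
        trajectories = trajectories.drop_anchor_samples()
    if group_by is None:
        return _axis_table(trajectories)
    parts = {pid: _axis_table(sub) for pid, sub in trajectories.iter_patients()}
    return pd.concat(parts, names=["patient_id", "statistic"])
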