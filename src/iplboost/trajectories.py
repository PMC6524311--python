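"""Container for prostate displacement trajectories.

A trajectory set holds time-stamped 3D displacements of the prostate
centre from its start-of-fraction position (as verified by kV-CBCT and
then tracked, e.g. by 4D ultrasound), grouped by patient and fraction.
It is the pooled unit of every downstream analysis: motion statistics,
coverage fractions and dose–volume histograms all consume it.

Axis convention (fixed for file-format stability; downstream math uses
only the Euclidean norm):

* ``lat_mm``  — lateral (left–right, + = patient left)
* ``long_mm`` — longitudinal (cranial–caudal, + = cranial)
* ``vert_mm`` — vertical (anterior–posterior, + = anterior)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataError

#: Mandatory column contract of the trajectory CSV format.
COLUMNS = ["patient_id", "fraction_id", "t_seconds", "lat_mm", "long_mm", "vert_mm"]

AXIS_COLUMNS = ["lat_mm", "long_mm", "vert_mm"]


@dataclass(frozen=True)
class TrajectorySet:
    """Displacement samples for one or more patients and fractions.

    Wraps a :class:`pandas.DataFrame` with the columns of
    :data:`COLUMNS`. Rows are ordered by patient, fraction and elapsed
    time. Displacements are in mm relative to the start-of-fraction
    position, so the first sample of every fraction is (0, 0, 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise DataError(f"trajectory data missing columns: {missing}")
        if len(self.data) == 0:
            raise DataError("trajectory set is empty")
        t = self.data["t_seconds"].to_numpy(dtype=float)
        if np.any(t < 0):
            raise DataError("negative elapsed times in trajectory data")
        # t must be non-decreasing within each fraction
        for (_, _), grp in self.data.groupby(["patient_id", "fraction_id"], sort=False):
            tt = grp["t_seconds"].to_numpy(dtype=float)
            if np.any(np.diff(tt) < 0):
                raise DataError("elapsed time decreases within a fraction")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patients(self) -> list:
        """Patient identifiers in order of first appearance."""
        return list(self.data["patient_id"].unique())

    @property
    def n_fractions(self) -> int:
        return self.data.groupby(["patient_id", "fraction_id"]).ngroups

    def displacements(self) -> np.ndarray:
        """(N, 3) array of (lat, long, vert) displacements in mm."""
        return self.data[AXIS_COLUMNS].to_numpy(dtype=float)

    def radial(self) -> np.ndarray:
        """Euclidean 3D distance of every sample from the origin, in mm."""
        xyz = self.displacements()
        return np.sqrt(np.einsum("ij,ij->i", xyz, xyz))

    def for_patient(self, patient_id) -> "TrajectorySet":
        """Sub-set restricted to one patient."""
        sub = self.data[self.data["patient_id"] == patient_id]
        if len(sub) == 0:
            raise DataError(f"unknown patient: {patient_id!r}")
        return TrajectorySet(sub.reset_index(drop=True))

    def iter_patients(self) -> Iterator[tuple[object, "TrajectorySet"]]:
        for pid in self.patients:
            yield pid, self.for_patient(pid)

    def drop_anchor_samples(self) -> "TrajectorySet":
        """Remove the t=0 reference sample of every fraction."""
        keep = self.data.groupby(["patient_id", "fraction_id"], sort=False).cumcount() > 0
        sub = self.data[keep]
        if len(sub) == 0:
            raise DataError("no samples left after dropping anchors")
        return TrajectorySet(sub.reset_index(drop=True))

    # -- serialization ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the delimited-text trajectory file (header mandatory)."""
        self.data.to_csv(path, index=False, columns=COLUMNS, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySet":
        """Read a trajectory file written by :meth:`to_csv` (or any real
        tracking export honouring the same column contract)."""
        try:
            df = pd.read_csv(path)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise DataError(f"cannot read trajectory file {path}: {exc}") from exc
        return cls(df)
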