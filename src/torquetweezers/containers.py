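"""In-memory containers for traces and curves.

Arrays are plain numpy; tabular serialization lives in :mod:`.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ScheduleStep", "BeadTrace", "AngleTrace", "RotationCurve",
           "AveragedCurve", "CurveFeatures"]

# segment_flag values in BeadTrace
FLAG_DWELL = 0
FLAG_MOVING = 1


@dataclass(frozen=True)
class ScheduleStep:
    """One dwell of the magnet turn schedule."""
    index: int
    turns: float
    t_start: float
    t_end: float


@dataclass
class BeadTrace:
    """Raw tracked bead positions plus the magnet turn schedule.

    t (s), x/y/z (nm) are equal-length series; segment_flag marks each
    sample as dwell (0) or magnet-moving (1); schedule lists the dwell
    steps (index, applied turns N, start/end time).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    bead_id: str
    segment_flag: np.ndarray
    schedule: list[ScheduleStep]

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z)
                == len(self.segment_flag) == n):
            raise DataError("BeadTrace series must have equal lengths")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("BeadTrace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t, "bead_id": self.bead_id,
            "x_nm": self.x, "y_nm": self.y, "z_nm": self.z,
            "segment_flag": self.segment_flag.astype(int),
        })

    def schedule_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step_index": [s.index for s in self.schedule],
            "turns": [s.turns for s in self.schedule],
            "t_start_s": [s.t_start for s in self.schedule],
            "t_end_s": [s.t_end for s in self.schedule],
        })


@dataclass
class AngleTrace:
    """Unwrapped rotation angle about the tether axis.

    theta is continuous (unwrapped) in rad; step_index maps each sample to
    a schedule step (-1 for magnet-moving/unassigned samples); center and
    radius come from the circle fit.  flags marks unreliable samples
    (radial excursion < 0.2 * radius).  z carries the simultaneous axial
    position when available (needed for the extension channel downstream).
    """

    t: np.ndarray
    theta: np.ndarray
    step_index: np.ndarray
    center: tuple[float, float]
    radius: float
    flags: np.ndarray
    turns: Optional[float] = None        # applied N when this is a single-step segment
    z: Optional[np.ndarray] = None
    frame_rate: Optional[float] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DataError("radius must be > 0")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.t, "theta_rad": self.theta,
             "step_index": self.step_index, "flag": self.flags.astype(int)}
        if self.z is not None:
            d["z_nm"] = self.z
        return pd.DataFrame(d)


@dataclass
class RotationCurve:
    """Per-molecule extension and torque versus applied turns."""

    bead_id: str
    N: np.ndarray
    extension: np.ndarray
    extension_se: np.ndarray
    torque: np.ndarray
    torque_se: np.ndarray
    force: float
    k_rot: float = float("nan")
    lk0: float = 0.0
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.N) > 1 and not np.all(np.diff(self.N) > 0):
            raise DataError("RotationCurve N must be strictly increasing")

    def __len__(self) -> int:
        return len(self.N)

    def shifted(self, dN: float, dz: float = 0.0) -> "RotationCurve":
        """Return a copy shifted along the turns axis by dN and in extension by dz."""
        return RotationCurve(
            bead_id=self.bead_id, N=self.N + dN,
            extension=self.extension + dz, extension_se=self.extension_se,
            torque=self.torque, torque_se=self.torque_se, force=self.force,
            k_rot=self.k_rot, lk0=self.lk0 + dN, flags=self.flags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bead_id": self.bead_id, "N_turns": self.N,
            "extension_nm": self.extension, "extension_se": self.extension_se,
            "torque_pNnm": self.torque, "torque_se": self.torque_se,
            "force_pN": self.force, "k_rot": self.k_rot,
        })


@dataclass
class AveragedCurve:
    """Aligned, population-averaged rotation curve with per-bin statistics."""

    N: np.ndarray                 # bin centers (low force) or turn values
    extension: np.ndarray
    extension_std: np.ndarray
    extension_sem: np.ndarray
    torque: np.ndarray
    torque_std: np.ndarray
    torque_sem: np.ndarray
    n_molecules: np.ndarray       # contributing molecules per bin
    force: float
    condition: str = ""
    binned: bool = False

    def __len__(self) -> int:
        return len(self.N)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "N_turns": self.N,
            "extension_nm": self.extension,
            "extension_std": self.extension_std,
            "extension_sem": self.extension_sem,
            "torque_pNnm": self.torque,
            "torque_std": self.torque_std,
            "torque_sem": self.torque_sem,
            "n_molecules": self.n_molecules,
            "force_pN": self.force,
        })


@dataclass
class CurveFeatures:
    """Observables extracted from one averaged curve."""

    force: float
    condition: str = ""
    n_buck_pos: float = float("nan")
    n_buck_neg: float = float("nan")
    sigma_buck: float = float("nan")
    slope_post: float = float("nan")      # nm/turn, negative
    tau_buck: float = float("nan")        # pN·nm
    tau_melt_obs: float = float("nan")    # pN·nm
    n_molecules: int = 0

    def to_row(self) -> dict:
        return {"force_pN": self.force, "condition": self.condition,
                "n_buck": self.n_buck_pos, "n_buck_neg": self.n_buck_neg,
                "sigma_buck": self.sigma_buck,
                "slope_post_nm_per_turn": self.slope_post,
                "tau_buck_pNnm": self.tau_buck,
                "tau_melt_pNnm": self.tau_melt_obs,
                "n_molecules": self.n_molecules}
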