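"""Tabular file formats and run configuration.

All interchange files are tab-delimited text with a header row, '#'
comment lines, and a format-version comment as the first line:

    # torquetweezers-table v1.0 type=<kind>

Readers reject unknown major versions.  Column names carry unit suffixes
(time_s, x_nm, torque_pNnm, ...); angles are serialized in radians, turns
as signed numbers, forces in pN, lengths in nm.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import AveragedCurve, BeadTrace, RotationCurve, ScheduleStep
from .errors import DataError, SchemaError

__all__ = [
    "FORMAT_VERSION", "RunConfig", "load_config", "dump_config",
    "write_table", "read_table",
    "write_trace", "read_trace_table", "read_schedule_table",
    "write_rotation_curve", "read_rotation_curve",
    "write_averaged_curve", "read_averaged_curve",
]

FORMAT_VERSION = "1.0"

TRACE_COLUMNS = ["time_s", "bead_id", "x_nm", "y_nm", "z_nm", "segment_flag"]
SCHEDULE_COLUMNS = ["step_index", "turns", "t_start_s", "t_end_s"]
CURVE_COLUMNS = ["bead_id", "N_turns", "extension_nm", "extension_se",
                 "torque_pNnm", "torque_se", "force_pN", "k_rot"]


def _header(kind: str, extra: str = "") -> str:
    line = f"# torquetweezers-table v{FORMAT_VERSION} type={kind}"
    if extra:
        line += f" {extra}"
    return line


def write_table(df: pd.DataFrame, path, kind: str, extra: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(kind, extra) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _check_version(path: Path) -> str:
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("# torquetweezers-table v"):
        raise SchemaError(f"{path}: missing format-version header")
    ver = first.split("v", 1)[1].split()[0]
    major = ver.split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise SchemaError(f"{path}: unsupported format major version {ver}")
    return first


def read_table(path, required: Optional[list[str]] = None) -> pd.DataFrame:
    """Read a tab-delimited package table, validating version and columns."""
    path = Path(path)
    _check_version(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed table: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def write_trace(trace: BeadTrace, trace_path, schedule_path) -> None:
    write_table(trace.to_frame(), trace_path, "beadtrace",
                extra=f"bead_id={trace.bead_id}")
    write_table(trace.schedule_frame(), schedule_path, "schedule",
                extra=f"bead_id={trace.bead_id}")


def read_schedule_table(path) -> list[ScheduleStep]:
    df = read_table(path, required=SCHEDULE_COLUMNS)
    return [ScheduleStep(index=int(r.step_index), turns=float(r.turns),
                         t_start=float(r.t_start_s), t_end=float(r.t_end_s))
            for r in df.itertuples()]


def read_trace_table(path, schedule_path=None) -> BeadTrace:
    """Read a bead trace table (and its schedule) into a BeadTrace.

    Rows failing numeric validation are reported with their line numbers;
    a missing required column raises a SchemaError naming it, and
    non-monotonic time a DataError.
    """
    path = Path(path)
    df = read_table(path, required=[c for c in TRACE_COLUMNS
                                    if c != "segment_flag"])
    if "segment_flag" not in df.columns:
        df["segment_flag"] = 0
    bad = df[["time_s", "x_nm", "y_nm", "z_nm"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 3).tolist()   # +1 header comment, +1 header, 1-based
        raise DataError(f"{path}: malformed rows at lines {lines[:20]}")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        i = int(np.argmin(np.diff(t)))
        raise DataError(f"{path}: time not strictly increasing near row {i + 1}")
    schedule = read_schedule_table(schedule_path) if schedule_path else []
    bead_id = str(df["bead_id"].iloc[0]) if len(df) else "bead"
    return BeadTrace(t=t, x=df["x_nm"].to_numpy(float),
                     y=df["y_nm"].to_numpy(float),
                     z=df["z_nm"].to_numpy(float), bead_id=bead_id,
                     segment_flag=df["segment_flag"].to_numpy(int),
                     schedule=schedule)


def write_rotation_curve(curve: RotationCurve, path) -> None:
    write_table(curve.to_frame(), path, "rotationcurve")


def read_rotation_curve(path) -> RotationCurve:
    df = read_table(path, required=CURVE_COLUMNS)
    return RotationCurve(
        bead_id=str(df["bead_id"].iloc[0]),
        N=df["N_turns"].to_numpy(float),
        extension=df["extension_nm"].to_numpy(float),
        extension_se=df["extension_se"].to_numpy(float),
        torque=df["torque_pNnm"].to_numpy(float),
        torque_se=df["torque_se"].to_numpy(float),
        force=float(df["force_pN"].iloc[0]),
        k_rot=float(df["k_rot"].iloc[0]))


def write_averaged_curve(avg: AveragedCurve, path) -> None:
    write_table(avg.to_frame(), path, "averagedcurve",
                extra=f"force_pN={avg.force} condition={avg.condition or '-'}")


def read_averaged_curve(path) -> AveragedCurve:
    df = read_table(path, required=["N_turns", "extension_nm", "torque_pNnm"])
    def col(name, default=np.nan):
        return (df[name].to_numpy(float) if name in df.columns
                else np.full(len(df), default))
    return AveragedCurve(
        N=df["N_turns"].to_numpy(float),
        extension=df["extension_nm"].to_numpy(float),
        extension_std=col("extension_std"), extension_sem=col("extension_sem"),
        torque=df["torque_pNnm"].to_numpy(float),
        torque_std=col("torque_std"), torque_sem=col("torque_sem"),
        n_molecules=col("n_molecules", 1).astype(int),
        force=float(df["force_pN"].iloc[0]) if "force_pN" in df.columns else float("nan"))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (serializes to YAML unchanged)."""

    # physical constants / DNA parameters
    model: dict = field(default_factory=dict)       # ModelParams overrides
    bead: dict = field(default_factory=dict)        # BeadParams overrides
    sim: dict = field(default_factory=dict)         # SimConfig overrides
    # analysis settings
    low_force_threshold_pN: float = 1.0
    high_force_threshold_pN: float = 6.0
    bin_width_turns: float = 2.0
    fit_window_turns: Optional[float] = None        # None -> auto selection
    equilibration_discard_s: float = 5.0
    seed: int = 0
    out_dir: str = "out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the serialized config, embedded in output headers."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.to_yaml())
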