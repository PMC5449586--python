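"""Rotation-angle tracking from (X,Y) bead positions.

The bead center orbits the tether axis on a circle; a circle fit to the
recorded (X,Y) trace yields the axis position and orbit radius, and each
sample's polar angle about that center is the bead's rotation angle.
Consecutive raw angles are unwrapped (±2π corrections at jumps > π) to a
continuous rotation angle, then segmented by the magnet turn schedule.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .containers import FLAG_DWELL, AngleTrace, BeadTrace
from .errors import CircleFitError, InvalidInputError

__all__ = ["fit_circle", "to_polar_angle", "segment_by_schedule",
           "track_bead"]

#: samples closer to the fitted center than this fraction of the radius are
#: flagged unreliable (angle poorly defined near the axis)
RADIAL_FLAG_FRACTION = 0.2

MIN_ARC_SPAN_RAD = math.radians(45.0)


def fit_circle(x, y) -> tuple[tuple[float, float], float, float]:
    """Least-squares circle through 2-D points.

    Algebraic (Kåsa) fit on the linearized circle equation, refined by one
    geometric Gauss-Newton pass on the radial residuals.  Returns
    ``((x0, y0), radius, rms_residual)``.

    Raises
    ------
    CircleFitError
        For < 3 points or (near-)collinear/degenerate input, with a
        diagnostic; the fit never guesses on degenerate data.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise CircleFitError(f"need >= 3 (x, y) points, got {len(x)}")

    # Kåsa: minimize ||x^2+y^2 - 2a x - 2b y - c||.
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-12 * sv[0]:
        raise CircleFitError(
            "degenerate point set (collinear or coincident points): "
            f"design-matrix singular values {sv}")
    x0, y0 = sol[0], sol[1]
    r2 = sol[2] + x0 * x0 + y0 * y0
    if r2 <= 0:
        raise CircleFitError("algebraic fit produced non-positive radius")
    r = math.sqrt(r2)

    # One Gauss-Newton step on r_i(x0, y0, r) = dist_i - r.
    for _ in range(1):
        dx, dy = x - x0, y - y0
        d = np.hypot(dx, dy)
        if np.any(d < 1e-12):
            break
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        res = d - r
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:
            break
        x0, y0, r = x0 + step[0], y0 + step[1], r + step[2]
        if r <= 0:
            raise CircleFitError("Gauss-Newton refinement collapsed the radius")

    d = np.hypot(x - x0, y - y0)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))

    ang = np.unwrap(np.arctan2(y - y0, x - x0))
    span = float(ang.max() - ang.min())
    if span < MIN_ARC_SPAN_RAD:
        warnings.warn(f"points span only {math.degrees(span):.1f} deg of arc "
                      "(< 45 deg); circle parameters may be poorly constrained")
    return (float(x0), float(y0)), float(r), rms


def to_polar_angle(trace: BeadTrace,
                   center: tuple[float, float] | None = None,
                   radius: float | None = None) -> AngleTrace:
    """Convert (X,Y) positions to an unwrapped rotation angle.

    Theta = atan2(y - y0, x - x0), unwrapped by adding ±2π whenever
    consecutive raw angles jump by more than π.  When center/radius are not
    supplied they are obtained from :func:`fit_circle` on the whole trace.
    Samples whose radial distance from the center is below
    0.2 * radius are flagged unreliable.
    """
    if center is None or radius is None:
        center, radius, _ = fit_circle(trace.x, trace.y)
    x0, y0 = center
    dx, dy = trace.x - x0, trace.y - y0
    theta = np.unwrap(np.arctan2(dy, dx))
    flags = np.hypot(dx, dy) < RADIAL_FLAG_FRACTION * radius

    step_index = np.full(len(trace), -1, dtype=int)
    for step in trace.schedule:
        in_step = ((trace.t >= step.t_start) & (trace.t < step.t_end)
                   & (trace.segment_flag == FLAG_DWELL))
        step_index[in_step] = step.index

    fr = None
    if len(trace) > 1:
        dts = np.diff(trace.t)
        fr = 1.0 / float(np.median(dts))
    return AngleTrace(t=trace.t, theta=theta, step_index=step_index,
                      center=(float(x0), float(y0)), radius=float(radius),
                      flags=flags, z=trace.z, frame_rate=fr)


def segment_by_schedule(angle: AngleTrace, schedule,
                        discard_s: float = 5.0,
                        min_samples: int = 100) -> list[AngleTrace]:
    """Split an angle trace into per-dwell segments tagged with applied turns.

    Only dwell samples (step_index >= 0) are retained and the first
    ``discard_s`` seconds of each dwell are discarded as equilibration.
    Steps retaining fewer than ``min_samples`` samples are flagged
    low-confidence with a warning.  All samples excluded (e.g. everything
    flagged magnet-moving) yields an empty list with a warning.
    """
    if discard_s < 0:
        raise InvalidInputError("discard_s must be >= 0")
    segments: list[AngleTrace] = []
    for step in schedule:
        sel = (angle.step_index == step.index) & (angle.t >= step.t_start + discard_s)
        n = int(np.count_nonzero(sel))
        if n == 0:
            continue
        low = n < min_samples
        if low:
            warnings.warn(f"step {step.index} (N={step.turns}) retains only "
                          f"{n} samples; flagged low-confidence")
        segments.append(AngleTrace(
            t=angle.t[sel], theta=angle.theta[sel],
            step_index=angle.step_index[sel], center=angle.center,
            radius=angle.radius, flags=angle.flags[sel],
            turns=float(step.turns),
            z=None if angle.z is None else angle.z[sel],
            frame_rate=angle.frame_rate, low_confidence=low))
    if not segments:
        warnings.warn("no dwell samples retained; returning empty segment list")
    return segments


def track_bead(trace: BeadTrace, discard_s: float = 5.0) -> list[AngleTrace]:
    """Full tracking pass: circle fit, polar conversion, segmentation."""
    angle = to_polar_angle(trace)
    return segment_by_schedule(angle, trace.schedule, discard_s=discard_s)
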