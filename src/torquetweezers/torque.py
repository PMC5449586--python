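"""Trap calibration, torque extraction and torsional-stiffness fitting.

The angular trap is harmonic, so equipartition calibrates its stiffness
from the dwell fluctuations,

    k_ROT = kBT / Var(Theta),                                        (trap)

and the molecular torque after N applied turns follows from the shift of
the mean angle relative to the torsionally relaxed reference step,

    Gamma_mol(N) = -k_ROT * (<Theta_N> - Theta_0),                   (torque)

where angles are taken in the rotating magnet frame (the 2*pi*N rigid
rotation of the trap is subtracted, so only the molecular twist strain
contributes to the shift).  The effective torsional stiffness is the slope
of the linear (pre-buckling, pre-melting) part of the torque-turns curve,

    C_eff = L_C / (2*pi*kBT) * dGamma/dN.                            (C_eff)

Standard errors of per-step torques use an effective sample size
n_eff = n / (2 * tau_c * frame_rate) to account for the OU autocorrelation
of the angle trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import AngleTrace, RotationCurve
from .errors import FitError, InvalidInputError
from .params import KBT_DEFAULT, ModelParams

__all__ = [
    "TrapCalibration", "TorquePoint", "CeffEstimate",
    "equipartition_std", "calibrate_trap", "fit_autocorrelation_time",
    "torque_at_step", "build_torque_curve", "select_linear_region",
    "fit_ceff", "force_from_transverse",
]


def equipartition_std(k_rot: float, kBT: float = KBT_DEFAULT) -> float:
    """Stationary angular fluctuation Std(Theta) in rad for a given trap stiffness."""
    if k_rot <= 0:
        raise InvalidInputError("k_rot must be > 0")
    return math.sqrt(kBT / k_rot)


@dataclass(frozen=True)
class TrapCalibration:
    """Rotational-trap calibration from one dwell segment.

    k_rot = kBT / Var(Theta) exactly; theta0 is the magnet-frame mean angle
    of the relaxed reference step.
    """

    k_rot: float
    theta0: float
    n_samples: int
    std_theta: float
    tau_c: float = float("nan")
    frame_rate: float = float("nan")


def fit_autocorrelation_time(theta: np.ndarray, frame_rate: float,
                             max_lag_s: float = 5.0) -> float:
    """Exponential-decay time (s) of the empirical angle autocorrelation.

    Log-linear fit to the normalized autocovariance over lags where it
    stays above 0.05.  Falls back to one frame time if the decay is
    unresolvable (e.g. white input).
    """
    x = np.asarray(theta, float) - np.mean(theta)
    n = len(x)
    if n < 10:
        return 1.0 / frame_rate
    max_lag = min(n - 2, int(max_lag_s * frame_rate))
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0 / frame_rate
    lags = np.arange(1, max_lag + 1)
    acf = np.array([np.dot(x[:-k], x[k:]) / ((n - k) * var) for k in lags])
    # fit only the well-resolved part of the decay (down to ~1/e): longer
    # lags are noise-dominated and bias the log-linear slope
    keep = acf > 0.3
    if keep.any():
        last = int(np.argmin(keep)) if not keep.all() else len(keep)
        lags, acf = lags[:max(last, 2)], acf[:max(last, 2)]
        acf = np.clip(acf, 1e-6, None)
    else:
        return 1.0 / frame_rate
    slope = np.polyfit(lags / frame_rate, np.log(acf), 1)[0]
    if slope >= 0:
        return 1.0 / frame_rate
    return max(-1.0 / slope, 1.0 / frame_rate)


def _magnet_frame_mean(segment: AngleTrace) -> float:
    if segment.turns is None:
        raise InvalidInputError("segment must be tagged with applied turns N")
    return float(np.mean(segment.theta)) - 2.0 * math.pi * segment.turns


def calibrate_trap(segment: AngleTrace, kBT: float = KBT_DEFAULT,
                   ) -> TrapCalibration:
    """Calibrate the rotational trap stiffness from a dwell segment.

    k_rot = kBT / Var(Theta); theta0 is the segment's magnet-frame mean
    angle (meaningful as the trap equilibrium when the segment is the
    torsionally relaxed reference step).
    """
    n = len(segment)
    if n < 100:
        warnings.warn(f"only {n} samples for trap calibration; "
                      "dwells should span >= 100 relaxation times")
    var = float(np.var(segment.theta))
    if var == 0.0:
        raise InvalidInputError("degenerate trace: zero angular variance")
    fr = segment.frame_rate or float("nan")
    tau_c = (fit_autocorrelation_time(segment.theta, fr)
             if np.isfinite(fr) else float("nan"))
    return TrapCalibration(k_rot=kBT / var, theta0=_magnet_frame_mean(segment),
                           n_samples=n, std_theta=math.sqrt(var),
                           tau_c=tau_c, frame_rate=fr)


@dataclass(frozen=True)
class TorquePoint:
    """Molecular torque at one applied-turn step."""

    N: float
    gamma: float        # pN·nm
    gamma_se: float
    mean_theta: float   # magnet-frame mean angle, rad


def torque_at_step(segment: AngleTrace, cal: TrapCalibration) -> TorquePoint:
    """Molecular torque from the mean-angle shift of one dwell segment.

    gamma = -k_rot * (<Theta_N> - Theta_0) with the magnet rotation 2*pi*N
    removed from <Theta_N>; the standard error uses the
    autocorrelation-corrected effective sample size.
    """
    if cal is None:
        raise InvalidInputError("missing trap calibration")
    mean_rel = _magnet_frame_mean(segment)
    gamma = -cal.k_rot * (mean_rel - cal.theta0)
    n = len(segment)
    std = float(np.std(segment.theta))
    fr = segment.frame_rate or cal.frame_rate
    if fr and np.isfinite(fr):
        tau_c = fit_autocorrelation_time(segment.theta, fr)
        n_eff = max(n / (2.0 * tau_c * fr), 1.0)
    else:
        n_eff = n
    se = cal.k_rot * std / math.sqrt(n_eff)
    return TorquePoint(N=float(segment.turns), gamma=float(gamma),
                       gamma_se=float(se), mean_theta=mean_rel)


def build_torque_curve(segments: Sequence[AngleTrace], force: float,
                       kBT: float = KBT_DEFAULT,
                       strategy: str = "per-step",
                       reference_N: float = 0.0,
                       bead_id: str = "bead") -> RotationCurve:
    """Assemble a per-molecule torque/extension rotation curve.

    strategy 'per-step' (default) calibrates k_rot from each dwell's own
    fluctuations (the same angle traces serve calibration and torque
    measurement); 'reference-only' reuses the reference step's k_rot for
    every step.  Theta_0 always comes from the reference step (the dwell
    whose N equals ``reference_N``; falls back to the closest step).
    The extension channel is the per-step mean and SEM of z.
    """
    if strategy not in ("per-step", "reference-only"):
        raise InvalidInputError(f"unknown strategy: {strategy!r}")
    if not segments:
        raise InvalidInputError("no segments supplied")
    turns = np.array([s.turns for s in segments], dtype=float)
    if np.any(np.isnan(turns)):
        raise InvalidInputError("all segments must be tagged with N")
    i_ref = int(np.argmin(np.abs(turns - reference_N)))
    if abs(turns[i_ref] - reference_N) > 0.5:
        warnings.warn(f"no step at reference N={reference_N}; using "
                      f"closest step N={turns[i_ref]}")
    ref_cal = calibrate_trap(segments[i_ref], kBT)

    order = np.argsort(turns)
    N, gam, gse, ext, ese = [], [], [], [], []
    for i in order:
        seg = segments[i]
        cal = ref_cal if strategy == "reference-only" else TrapCalibration(
            k_rot=calibrate_trap(seg, kBT).k_rot, theta0=ref_cal.theta0,
            n_samples=len(seg), std_theta=float(np.std(seg.theta)),
            tau_c=ref_cal.tau_c, frame_rate=seg.frame_rate or ref_cal.frame_rate)
        tp = torque_at_step(seg, cal)
        N.append(tp.N)
        gam.append(tp.gamma)
        gse.append(tp.gamma_se)
        if seg.z is not None:
            ext.append(float(np.mean(seg.z)))
            ese.append(float(np.std(seg.z) / math.sqrt(len(seg))))
        else:
            ext.append(float("nan"))
            ese.append(float("nan"))
    return RotationCurve(bead_id=bead_id, N=np.array(N),
                         extension=np.array(ext), extension_se=np.array(ese),
                         torque=np.array(gam), torque_se=np.array(gse),
                         force=force, k_rot=ref_cal.k_rot)


def select_linear_region(curve: RotationCurve, center: float = 0.0,
                         min_halfwidth: float = 3.0) -> tuple[float, float]:
    """Largest symmetric window about ``center`` where the torque is linear.

    Each side of the curve is partitioned into a linear rise followed by a
    constant plateau at the SSE-optimal breakpoint (the signature of
    buckling, melting or the overwinding transition saturating the
    torque); the window ends one turn before the earlier of the two
    plateau onsets.  A side with no resolvable plateau leaves the window
    unbounded on that side's account.  The window is symmetric, as the
    linear regime of the torque response is centered on the relaxed state.

    Returns (N_min, N_max) of the selected window.
    """
    from .curves import _line_then_plateau   # shared partition machinery

    dist = np.abs(curve.N - center)
    if len(curve.N) < 5:
        raise FitError("not enough points to select a linear region")
    w_max = dist.max()
    for sgn in (1.0, -1.0):
        onside = sgn * (curve.N - center) > 0
        if onside.sum() < 5:
            continue
        try:
            # permissive SSE threshold: missing a real plateau biases the
            # slope, a spurious one only trims a point or two of window
            onset, _ = _line_then_plateau(dist[onside], curve.torque[onside],
                                          sse_ratio=0.995)
        except FitError:
            continue                         # side is linear throughout
        w_max = min(w_max, onset - 2.0)
    w_max = max(w_max, min_halfwidth)
    return (center - w_max, center + w_max)


@dataclass
class CeffEstimate:
    """Effective torsional stiffness from the torque-turns slope."""

    c_eff: float            # nm
    c_eff_se: float
    slope: float            # pN·nm per turn
    slope_se: float
    intercept: float        # pN·nm at N = 0 (QC metric; not forced to zero)
    fit_region: tuple[float, float]
    n_points: int

    def summary(self) -> str:
        return ("Effective torsional stiffness fit\n"
                "---------------------------------\n"
                f"fit region: N in [{self.fit_region[0]:.1f}, "
                f"{self.fit_region[1]:.1f}]  ({self.n_points} points)\n"
                f"slope     : {self.slope:8.4f} ± {self.slope_se:.4f} pN·nm/turn\n"
                f"intercept : {self.intercept:8.4f} pN·nm (QC)\n"
                f"C_eff     : {self.c_eff:8.2f} ± {self.c_eff_se:.2f} nm")


def fit_ceff(curve: RotationCurve, params: ModelParams,
             fit_region: Optional[tuple[float, float]] = None,
             center: float = 0.0) -> CeffEstimate:
    """Fit C_eff from the linear regime of a torque-rotation curve.

    fit_region fixes the window (N_min, N_max) explicitly (the protocol
    keeps it constant for each force); when omitted the window is chosen
    by :func:`select_linear_region` about ``center``.  The line is a
    weighted least-squares fit with a free intercept (reported as a QC
    metric); C_eff = L_C / (2*pi*kBT) * slope.
    """
    if fit_region is None:
        fit_region = select_linear_region(curve, center=center)
    lo, hi = fit_region
    sel = (curve.N >= lo) & (curve.N <= hi) & np.isfinite(curve.torque)
    if sel.sum() < 3:
        raise FitError(f"fewer than 3 points in fit region [{lo}, {hi}]")
    N, tau = curve.N[sel], curve.torque[sel]
    se = curve.torque_se[sel]
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se ** 2
    else:
        w = np.ones_like(tau)
    X = np.column_stack([N, np.ones_like(N)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ tau)
    slope, intercept = float(beta[0]), float(beta[1])
    if np.all(np.isfinite(se)) and np.all(se > 0):
        slope_se = math.sqrt(cov[0, 0])
    else:  # unweighted: scale by residual variance
        resid = tau - X @ beta
        dof = max(len(N) - 2, 1)
        slope_se = math.sqrt(cov[0, 0] * float(resid @ resid) / dof)
    scale = params.contour_length / (2.0 * math.pi * params.kBT)
    return CeffEstimate(c_eff=scale * slope, c_eff_se=scale * slope_se,
                        slope=slope, slope_se=slope_se, intercept=intercept,
                        fit_region=(float(lo), float(hi)),
                        n_points=int(sel.sum()))


def force_from_transverse(x_series, extension: float,
                          kBT: float = KBT_DEFAULT) -> float:
    """Stretching force (pN) from transverse bead fluctuations.

    Inverted-pendulum relation F = kBT * extension / Var(x_perp), with
    x_perp the bead excursion transverse to the field direction and
    ``extension`` the tether extension (bead-radius corrected upstream if
    configured).
    """
    if extension <= 0:
        raise InvalidInputError("extension must be > 0")
    var = float(np.var(np.asarray(x_series, float)))
    if var == 0.0:
        raise InvalidInputError("zero transverse variance")
    return kBT * extension / var
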