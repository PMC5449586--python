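"""Multi-molecule curve averaging and supercoiling-observable extraction.

Implements the averaging protocol for extension-rotation and
torque-rotation curves and the extraction of buckling observables:

* low force (< 1 pN, symmetric curves): each molecule's relaxed linking
  offset Lk0 is the center of a Gaussian fitted to its extension-rotation
  curve; curves are shifted by -Lk0, pooled into 2-turn bins (edges
  [2k-1, 2k+1), centers on even turns) and averaged with per-bin STD/SEM;
* high force (> 1 pN, asymmetric): each curve's buckling point is detected
  as the first extension value falling below the pre-buckling plateau line
  by more than its own standard error; curves are aligned to the mean
  buckling point (integer shifts), extension offsets at zero turns are
  equalized, and data are averaged per turn value;
* observables: buckling point n_B, supercoiling density sigma, post-
  buckling slope, buckling torque (mean of the post-buckling plateau) and
  the torque plateau of the melting branch.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .containers import AveragedCurve, CurveFeatures, RotationCurve
from .errors import FitError, InvalidInputError
from .params import ModelParams

__all__ = [
    "fit_lk0", "detect_buckling", "align_and_average",
    "post_buckling_slope", "buckling_torque", "torque_plateau",
    "supercoiling_density", "qc_classify", "fit_power_law",
    "extract_features",
]

LOW_FORCE_THRESHOLD = 1.0   # pN; below: symmetric curves, Lk0 alignment
BIN_WIDTH = 2.0             # turns, low-force binning


def _bin_center(N: np.ndarray) -> np.ndarray:
    """Map turns to 2-turn bin centers: edges [2k-1, 2k+1) -> center 2k."""
    return 2.0 * np.floor((np.asarray(N, float) + 1.0) / 2.0)


def _wline(x: np.ndarray, y: np.ndarray, se: Optional[np.ndarray] = None,
           ) -> tuple[float, float, float]:
    """Weighted least-squares line y = a + b x; returns (b, a, se_b)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if se is not None and np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se ** 2
        scaled = False
    else:
        w = np.ones_like(y)
        scaled = True
    X = np.column_stack([x, np.ones_like(x)])
    cov = np.linalg.inv((X.T * w) @ X)
    beta = cov @ ((X.T * w) @ y)
    se_b = math.sqrt(cov[0, 0])
    if scaled:
        resid = y - X @ beta
        dof = max(len(x) - 2, 1)
        se_b *= math.sqrt(float(resid @ resid) / dof)
    return float(beta[0]), float(beta[1]), se_b


def fit_lk0(curve: RotationCurve, shift: bool = False):
    """Relaxed-linking-number offset from a symmetric extension curve.

    Fits a Gaussian (amplitude, center, width and baseline all free) to
    the extension-rotation data; Lk0 is the fitted center.  Intended for
    the symmetric low-force regime (caller-asserted).  Returns lk0, or
    ``(lk0, shifted_curve)`` when ``shift`` is true.

    Raises
    ------
    FitError
        If the fit does not converge or the curve has no resolvable peak
        (e.g. the flat response of a nicked tether), with residual
        diagnostics.
    """
    N, z = curve.N, curve.extension
    amp0 = float(z.max() - z.min())
    se = curve.extension_se
    noise = float(np.nanmedian(se)) if np.any(np.isfinite(se)) else 0.0
    if amp0 <= max(5.0 * noise, 1e-9):
        raise FitError("extension curve is flat (no peak to fit); "
                       f"amplitude {amp0:.3g} nm vs noise {noise:.3g} nm")

    def gauss(n, a, c, w, b):
        return b + a * np.exp(-0.5 * ((n - c) / w) ** 2)

    p0 = [amp0, float(N[np.argmax(z)]), (N.max() - N.min()) / 4.0, float(z.min())]
    try:
        popt, _ = curve_fit(gauss, N, z, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian Lk0 fit did not converge: {exc}") from exc
    a, c, w, b = popt
    resid = z - gauss(N, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if a <= max(5.0 * noise, 0.0) or not (N.min() - 5 <= c <= N.max() + 5):
        raise FitError(
            f"Lk0 fit degenerate: amplitude {a:.3g} nm, center {c:.3g} turns, "
            f"rms residual {rms:.3g} nm")
    lk0 = float(c)
    if shift:
        return lk0, curve.shifted(-lk0)
    return lk0


def _two_segment_fit(dist: np.ndarray, z: np.ndarray,
                     ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """SSE-optimal flat-then-line partition of a one-sided curve.

    Returns (breakpoint distance, (slope, intercept) of the plateau line,
    (slope, intercept) of the post-breakpoint line), all in the signed-
    distance coordinate.
    """
    order = np.argsort(dist)
    d, y = dist[order], z[order]
    best = (float(d[-1]), (0.0, float(np.mean(y))), (0.0, float(np.mean(y))))
    best_sse = float(np.var(y) * len(y))
    for i in range(2, len(d) - 1):
        m = float(np.mean(y[:i]))
        sse = float(np.var(y[:i]) * i)
        b, a, _ = _wline(d[i:], y[i:])
        sse += float(np.sum((y[i:] - (a + b * d[i:])) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = (float(d[i]), (0.0, m), (float(b), float(a)))
    return best


def _curve_arrays(curve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = np.asarray(curve.N, float)
    z = np.asarray(curve.extension, float)
    se = getattr(curve, "extension_sem", None)
    if se is None:
        se = getattr(curve, "extension_se")
    return N, z, np.asarray(se, float)


def detect_buckling(curve, side: str = "positive", se_mult: float = 1.0,
                    center: float = 0.0, refine: bool = False,
                    ) -> Optional[float]:
    """Buckling point (turns) of an extension-rotation curve.

    A line is fitted to the constant (pre-buckling) region — all points
    with |N - center| <= 0.5 * a coarse two-segment first guess — and the
    curve is scanned outward in |N| on the chosen side; the first point
    whose extension falls below the line by more than ``se_mult`` times its
    own standard error is the buckling point.  With ``refine=True`` the
    returned value is the intersection of the plateau line with a line
    fitted to the post-buckling points (a continuous, binning-insensitive
    estimate); otherwise it is the first departing turn value (the
    detection rule verbatim).

    Returns ``None`` when no point qualifies (no buckling, e.g. at forces
    where supercoiling does not occur).
    """
    if side not in ("positive", "negative"):
        raise InvalidInputError("side must be 'positive' or 'negative'")
    N, z, se = _curve_arrays(curve)
    sgn = 1.0 if side == "positive" else -1.0
    d_signed = sgn * (N - center)
    onside = d_signed >= 0
    if onside.sum() < 3:
        raise InvalidInputError(f"too few points on {side} side")

    guess, _, post_line = _two_segment_fit(d_signed[onside], z[onside])
    plateau_sel = np.abs(N - center) <= max(0.5 * guess, 1.0)
    if plateau_sel.sum() < 2:
        plateau_sel = np.abs(N - center) <= np.sort(np.abs(N - center))[2]
    b, a, _ = _wline(N[plateau_sel], z[plateau_sel],
                     se[plateau_sel] if np.all(se[plateau_sel] > 0) else None)

    if refine:
        # Continuous, noise-robust estimate: intersect the plateau line
        # with the SSE-optimal post-breakpoint line.  Buckling exists only
        # if the post branch falls significantly below the plateau.
        b2_d, a2_d = post_line
        resid = z[plateau_sel] - (a + b * N[plateau_sel])
        noise = max(float(np.sqrt(np.mean(resid ** 2))),
                    float(np.nanmedian(se[onside])) if np.any(np.isfinite(se[onside])) else 0.0,
                    1e-9)
        d_max = d_signed[onside].max()
        drop = (a + b * (center + sgn * d_max)) - (a2_d + b2_d * d_max)
        if b2_d >= 0.0 or drop < 5.0 * noise:
            return None
        b2 = sgn * b2_d                      # convert to N coordinates
        a2 = a2_d - b2 * center
        if abs(b2 - b) < 1e-12:
            return None
        return float((a - a2) / (b2 - b))

    # verbatim rule: scan outward beyond the fitted constant region for the
    # first point falling below the plateau line by its own error
    order = np.argsort(d_signed)
    for i in order:
        if not onside[i] or d_signed[i] <= 0.5 * guess:
            continue
        line = a + b * N[i]
        tol = se_mult * (se[i] if np.isfinite(se[i]) else 0.0)
        tol = max(tol, 1e-9 * max(abs(line), 1.0))   # noiseless-data guard
        if z[i] < line - tol:
            return float(N[i])
    return None


def align_and_average(curves: Sequence[RotationCurve],
                      force_regime: Optional[str] = None,
                      min_molecules_per_bin: int = 2,
                      condition: str = "") -> AveragedCurve:
    """Align and average rotation curves from independent molecules.

    force_regime 'low' (< 1 pN): Lk0-centered via the Gaussian fit, 2-turn
    binning, per-bin mean/STD/SEM.  'high': buckling-point aligned (integer
    shifts to the population-mean buckling point; molecules with no
    detectable buckling are excluded from the mean shift with a warning and
    aligned by their torque-curve zero crossing instead), extension offsets
    equalized at zero turns, per-turn averaging.  When omitted the regime
    is chosen from the curves' force.
    """
    if len(curves) < 2:
        raise InvalidInputError("need >= 2 curves to average")
    forces = np.array([c.force for c in curves], float)
    if forces.max() > 1.5 * forces.min():
        raise InvalidInputError(
            f"mixed forces: {forces.min():.2g}-{forces.max():.2g} pN")
    force = float(forces.mean())
    if force_regime is None:
        force_regime = "low" if force < LOW_FORCE_THRESHOLD else "high"

    curves = [_rezero_torque(c) for c in curves]
    aligned: list[RotationCurve] = []
    if force_regime == "low":
        for c in curves:
            try:
                lk0 = fit_lk0(c)
            except FitError as exc:
                warnings.warn(f"{c.bead_id}: Lk0 fit failed, curve dropped ({exc})")
                continue
            # snap numerically-integer shifts so samples sitting exactly on
            # the half-open bin edges are assigned deterministically
            if abs(lk0 - round(lk0)) < 1e-6:
                lk0 = float(round(lk0))
            aligned.append(c.shifted(-lk0))
        if len(aligned) < 2:
            raise FitError("fewer than 2 curves survived Lk0 alignment")
        return _average_binned(aligned, force, condition)

    # high-force path: buckling alignment
    n_bucks = []
    for c in curves:
        try:
            nb = detect_buckling(c, side="positive", refine=True)
        except (InvalidInputError, FitError):
            nb = None
        n_bucks.append(nb)
    detected = [nb for nb in n_bucks if nb is not None]
    if detected:
        mean_nb = float(np.mean(detected))
        for c, nb in zip(curves, n_bucks):
            if nb is None:
                warnings.warn(f"{c.bead_id}: no buckling detected; aligned by "
                              "torque zero crossing instead")
                shift = -_torque_zero_crossing(c)
            else:
                shift = mean_nb - nb
            aligned.append(c.shifted(float(round(shift))))
    else:
        warnings.warn("no molecule shows buckling; aligning all curves by "
                      "their torque zero crossings")
        aligned = [c.shifted(float(round(-_torque_zero_crossing(c))))
                   for c in curves]

    # equalize extension offsets at zero turns
    z0 = np.array([_extension_at(c, 0.0) for c in aligned])
    z0_mean = float(np.nanmean(z0))
    aligned = [c.shifted(0.0, dz=z0_mean - z) if np.isfinite(z) else c
               for c, z in zip(aligned, z0)]
    return _average_per_turn(aligned, force, condition, min_molecules_per_bin)


def _central_torque_line(curve: RotationCurve) -> tuple[float, float]:
    """(slope, intercept) of the central torque-turns line.

    The reference dwell's torque is zero by construction while every other
    step carries the reference-step measurement error as a common offset;
    the free intercept of the central line estimates that offset.  The
    pinned reference point itself is excluded from the fit.
    """
    keep = ~((curve.torque == 0.0) & (np.abs(curve.N) < 0.5))
    N, tau = curve.N[keep], curve.torque[keep]
    se = curve.torque_se[keep]
    sel = np.argsort(np.abs(N))[:min(12, len(N))]
    b, a, _ = _wline(N[sel], tau[sel], se[sel])
    return b, a


def _rezero_torque(curve: RotationCurve) -> RotationCurve:
    """Shift the torque origin by the central-line intercept."""
    _, a = _central_torque_line(curve)
    out = curve.shifted(0.0)
    out.torque = curve.torque - a
    return out


def _torque_zero_crossing(curve: RotationCurve) -> float:
    b, a = _central_torque_line(curve)
    if b == 0:
        return 0.0
    return -a / b


def _extension_at(curve: RotationCurve, N0: float) -> float:
    i = int(np.argmin(np.abs(curve.N - N0)))
    if abs(curve.N[i] - N0) > 1.0:
        return float("nan")
    return float(curve.extension[i])


def _average_binned(aligned: list[RotationCurve], force: float,
                    condition: str) -> AveragedCurve:
    per_mol: list[dict[float, tuple[float, float]]] = []
    for c in aligned:
        centers = _bin_center(c.N)
        d: dict[float, tuple[float, float]] = {}
        for b in np.unique(centers):
            sel = centers == b
            d[float(b)] = (float(np.mean(c.extension[sel])),
                           float(np.mean(c.torque[sel])))
        per_mol.append(d)
    all_bins = sorted({b for d in per_mol for b in d})
    rows = []
    for b in all_bins:
        ext = np.array([d[b][0] for d in per_mol if b in d])
        tau = np.array([d[b][1] for d in per_mol if b in d])
        if len(ext) < 2:
            continue
        rows.append((b, ext, tau))
    if not rows:
        raise FitError("no bin is populated by >= 2 molecules")
    N = np.array([r[0] for r in rows])
    ext_m = np.array([r[1].mean() for r in rows])
    ext_sd = np.array([r[1].std(ddof=1) for r in rows])
    tau_m = np.array([r[2].mean() for r in rows])
    tau_sd = np.array([r[2].std(ddof=1) for r in rows])
    n = np.array([len(r[1]) for r in rows])
    return AveragedCurve(N=N, extension=ext_m, extension_std=ext_sd,
                         extension_sem=ext_sd / np.sqrt(n),
                         torque=tau_m, torque_std=tau_sd,
                         torque_sem=tau_sd / np.sqrt(n),
                         n_molecules=n, force=force, condition=condition,
                         binned=True)


def _average_per_turn(aligned: list[RotationCurve], force: float,
                      condition: str, min_mol: int) -> AveragedCurve:
    allN = sorted({float(n) for c in aligned for n in np.round(c.N)})
    rows = []
    for Nv in allN:
        ext, tau = [], []
        for c in aligned:
            i = np.where(np.round(c.N) == Nv)[0]
            if len(i):
                ext.append(float(np.mean(c.extension[i])))
                tau.append(float(np.mean(c.torque[i])))
        if len(ext) < max(min_mol, 2):
            continue
        rows.append((Nv, np.array(ext), np.array(tau)))
    if not rows:
        raise FitError("no turn value is shared by enough molecules")
    N = np.array([r[0] for r in rows])
    ext_m = np.array([r[1].mean() for r in rows])
    ext_sd = np.array([r[1].std(ddof=1) for r in rows])
    tau_m = np.array([r[2].mean() for r in rows])
    tau_sd = np.array([r[2].std(ddof=1) for r in rows])
    n = np.array([len(r[1]) for r in rows])
    return AveragedCurve(N=N, extension=ext_m, extension_std=ext_sd,
                         extension_sem=ext_sd / np.sqrt(n),
                         torque=tau_m, torque_std=tau_sd,
                         torque_sem=tau_sd / np.sqrt(n),
                         n_molecules=n, force=force, condition=condition,
                         binned=False)


def post_buckling_slope(avg, n_buck: float, side: str = "positive",
                        margin: float = 1.5, min_points: int = 4,
                        ) -> tuple[float, float]:
    """Weighted line fit to the extension beyond the buckling point.

    Returns (slope, slope_se) in nm/turn; negative by convention on the
    positive side.  Points within ``margin`` turns of n_buck are skipped
    (the kink bin mixes both phases).
    """
    N, z, se = _curve_arrays(avg)
    sgn = 1.0 if side == "positive" else -1.0
    sel = sgn * N >= abs(n_buck) + margin
    if sel.sum() < min_points:
        raise FitError(f"only {int(sel.sum())} points beyond buckling "
                       f"(need >= {min_points})")
    b, _, se_b = _wline(N[sel], z[sel], se[sel] if np.all(se[sel] > 0) else None)
    return b, se_b


def buckling_torque(avg, n_buck: float, side: str = "positive",
                    margin: float = 2.0) -> tuple[float, float]:
    """Mean of the post-buckling torque plateau, with propagated SE."""
    N = np.asarray(avg.N, float)
    tau = np.asarray(avg.torque, float)
    sem = np.asarray(getattr(avg, "torque_sem", getattr(avg, "torque_se", None)), float)
    sgn = 1.0 if side == "positive" else -1.0
    sel = sgn * N >= abs(n_buck) + margin
    if sel.sum() < 3:
        raise FitError(f"plateau has only {int(sel.sum())} points (need >= 3)")
    mean = float(np.mean(tau[sel]))
    k = int(sel.sum())
    se_scatter = float(np.std(tau[sel], ddof=1) / math.sqrt(k))
    se_points = (float(np.sqrt(np.sum(sem[sel] ** 2)) / k)
                 if np.all(np.isfinite(sem[sel])) else 0.0)
    return mean, max(se_scatter, se_points)


def _line_then_plateau(d: np.ndarray, y: np.ndarray,
                       sse_ratio: float = 0.95) -> tuple[float, float]:
    """SSE-optimal partition of a one-sided curve into line-then-constant.

    Mirrors :func:`_two_segment_fit` with the segment roles swapped: the
    inner branch (small distance d from the curve center) is a free line,
    the outer branch a constant.  The partition must beat a single line by
    the ``sse_ratio`` factor, else no plateau is declared.  Returns
    (breakpoint distance, plateau mean).
    """
    order = np.argsort(d)
    dd, yy = d[order], y[order]
    n = len(dd)
    if n < 5:
        raise FitError("too few points for a line-plateau fit")
    best_sse, best = np.inf, None
    for i in range(3, n - 2):
        b, a, _ = _wline(dd[:i], yy[:i])
        sse = float(np.sum((yy[:i] - (a + b * dd[:i])) ** 2))
        m = float(np.mean(yy[i:]))
        sse += float(np.var(yy[i:]) * (n - i))
        if sse < best_sse:
            best_sse, best = sse, (float(dd[i]), m)
    b, a, _ = _wline(dd, yy)
    sse_line = float(np.sum((yy - (a + b * dd)) ** 2))
    if best is None or best_sse > sse_ratio * sse_line:
        raise FitError("no torque plateau detected (curve is linear)")
    return best


def torque_plateau(avg, side: str = "negative", margin: float = 2.0,
                   ) -> tuple[float, float]:
    """Mean torque of the saturated plateau on one side of the curve.

    The side's torque branch is partitioned into a linear rise followed by
    a constant plateau at the SSE-optimal breakpoint; the reported plateau
    is the mean over points ``margin`` turns beyond the breakpoint (with
    propagated SE).  Used for the melting plateau (negative side) and the
    B-to-P plateau (positive side of the no-supercoiling regime).
    """
    N = np.asarray(avg.N, float)
    tau = np.asarray(avg.torque, float)
    sem = np.asarray(getattr(avg, "torque_sem", getattr(avg, "torque_se", None)), float)
    sgn = 1.0 if side == "positive" else -1.0
    onside = sgn * N > 0
    if onside.sum() < 5:
        raise FitError(f"too few points on the {side} side")
    onset, _ = _line_then_plateau(np.abs(N[onside]), tau[onside])
    sel = onside & (np.abs(N) >= onset + margin)
    if sel.sum() < 3:
        raise FitError(f"plateau beyond onset has only {int(sel.sum())} points")
    mean = float(np.mean(tau[sel]))
    k = int(sel.sum())
    se_scatter = float(np.std(tau[sel], ddof=1) / math.sqrt(k))
    se_points = (float(np.sqrt(np.nansum(sem[sel] ** 2)) / k)
                 if np.any(np.isfinite(sem[sel])) else 0.0)
    return mean, max(se_scatter, se_points)


def supercoiling_density(N, params: ModelParams):
    """Supercoiling density sigma = N / Lk0 (Lk0 = bp / helical repeat)."""
    return np.asarray(N, float) / params.lk0_helix


def qc_classify(contour_test: Optional[tuple[float, float]],
                multi_test: Optional[tuple[float, float]],
                coil_test: Optional[tuple[float, float, float]],
                params: ModelParams,
                contour_rel_tol: float = 0.35,
                loss_threshold: Optional[float] = None) -> str:
    """Classify a tether from the three standard selection tests.

    contour_test: (extension at ~5 pN, extension near zero force); the
    difference should be about the contour length, else 'stuck'.
    multi_test: (extension at 5 pN / 0 turns, at 5 pN / -20 turns);
    extension loss under unwinding at high force indicates braiding of
    multiple tethers (single duplexes melt instead of supercoiling there).
    coil_test: (extension at 0.6 pN at 0, +20, -20 turns); symmetric loss
    confirms a coilable (intact) duplex, no loss a nicked one.
    Any missing test yields 'unknown'.
    """
    if contour_test is None or multi_test is None or coil_test is None:
        return "unknown"
    L_C = params.contour_length
    thr = 0.05 * L_C if loss_threshold is None else loss_threshold

    ext_hi, ext_lo = contour_test
    if abs((ext_hi - ext_lo) - L_C) > contour_rel_tol * L_C:
        return "stuck"
    z0_hi, z_m20_hi = multi_test
    if z0_hi - z_m20_hi > thr:
        return "multi_tether"
    z0, z_p20, z_m20 = coil_test
    loss_p, loss_m = z0 - z_p20, z0 - z_m20
    if loss_p > thr and loss_m > thr:
        return "good"
    if loss_p <= thr and loss_m <= thr:
        return "nicked"
    return "unknown"


def fit_power_law(forces, values) -> tuple[float, float, float]:
    """Least-squares power law y = prefactor * F^exponent on log-log axes.

    Returns (prefactor, exponent, exponent_se).
    """
    F = np.asarray(forces, float)
    y = np.asarray(values, float)
    if len(F) < 3:
        raise InvalidInputError("need >= 3 forces")
    if np.any(F <= 0) or np.any(y <= 0):
        raise InvalidInputError("power-law fit requires positive forces and values")
    b, a, se_b = _wline(np.log(F), np.log(y))
    return float(math.exp(a)), float(b), se_b


def extract_features(avg: AveragedCurve, params: ModelParams,
                     condition: str = "") -> CurveFeatures:
    """Extract the buckling observables from one averaged curve.

    Uses the refined (plateau/post-buckling line intersection) buckling
    point; features that do not exist in the curve's force regime are NaN.
    The post-buckling slope magnitude is taken from the extension branch;
    torque plateaus from the torque branch.
    """
    feats = CurveFeatures(force=avg.force, condition=condition,
                          n_molecules=int(np.max(avg.n_molecules)))
    try:
        nb = detect_buckling(avg, side="positive", refine=True)
    except (InvalidInputError, FitError):
        nb = None
    if nb is not None:
        feats.n_buck_pos = nb
        feats.sigma_buck = float(supercoiling_density(nb, params))
        try:
            feats.slope_post = post_buckling_slope(avg, nb)[0]
        except FitError:
            pass
        try:
            feats.tau_buck = buckling_torque(avg, nb)[0]
        except FitError:
            pass
    if avg.force < LOW_FORCE_THRESHOLD:
        try:
            nbn = detect_buckling(avg, side="negative", refine=True)
            if nbn is not None:
                feats.n_buck_neg = float(nbn)
        except (InvalidInputError, FitError):
            pass
    else:
        try:
            feats.tau_melt_obs = torque_plateau(avg, side="negative")[0]
        except FitError:
            pass
    return feats
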