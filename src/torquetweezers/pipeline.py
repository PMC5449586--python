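"""End-to-end analysis chains: traces -> curves -> averages -> features.

Thin orchestration over the tracking, torque and curve modules, shared by
the command-line interface and by recovery tests.  The effective-
torsional-stiffness protocol follows the measurement convention: the fit
window is chosen once per force condition — from the population-averaged
torque curve — and then applied to every molecule relative to its own
torque zero crossing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import AveragedCurve, BeadTrace, CurveFeatures, RotationCurve
from .curves import align_and_average, extract_features, _torque_zero_crossing
from .errors import FitError
from .params import BeadParams, ModelParams, SimConfig
from .synthetic import simulate_population
from .torque import build_torque_curve, fit_ceff, select_linear_region
from .tracking import track_bead

__all__ = ["trace_to_curve", "population_curves", "CeffPopulation",
           "population_ceff", "simulate_condition"]


def trace_to_curve(trace: BeadTrace, force: float, kBT: float = 4.1,
                   discard_s: float = 5.0,
                   strategy: str = "per-step") -> RotationCurve:
    """Track one bead trace and build its torque/extension rotation curve."""
    segments = track_bead(trace, discard_s=discard_s)
    return build_torque_curve(segments, force=force, kBT=kBT,
                              strategy=strategy, bead_id=trace.bead_id)


def population_curves(traces, force: float, kBT: float = 4.1,
                      discard_s: float = 5.0) -> list[RotationCurve]:
    curves = []
    for tr in traces:
        try:
            curves.append(trace_to_curve(tr, force, kBT, discard_s))
        except Exception as exc:   # pragma: no cover - defensive
            warnings.warn(f"{tr.bead_id}: analysis failed ({exc}); dropped")
    return curves


@dataclass
class CeffPopulation:
    """Per-molecule effective torsional stiffnesses and their population mean."""

    values: np.ndarray        # nm, one per molecule
    mean: float
    sem: float
    window_halfwidth: float   # turns, common fit window

    def summary(self) -> str:
        return (f"C_eff over {len(self.values)} molecules "
                f"(window ±{self.window_halfwidth:.1f} turns): "
                f"{self.mean:.1f} ± {self.sem:.1f} nm")


def population_ceff(curves: list[RotationCurve], params: ModelParams,
                    window_halfwidth: float | None = None) -> CeffPopulation:
    """Population C_eff: common fit window, per-molecule slope fits.

    The window half-width is selected on the molecule-averaged torque
    curve when not given, then each molecule is fitted over
    |N - lk0_i| <= halfwidth with lk0_i its own torque zero crossing.
    """
    if window_halfwidth is None:
        avg = _naive_mean_curve(curves)
        lo, hi = select_linear_region(avg, center=0.0)
        window_halfwidth = (hi - lo) / 2.0
    vals = []
    for c in curves:
        lk0 = _torque_zero_crossing(c)
        if not np.isfinite(lk0) or abs(lk0) > 5.0:
            lk0 = 0.0
        try:
            est = fit_ceff(c, params, fit_region=(lk0 - window_halfwidth,
                                                  lk0 + window_halfwidth))
        except FitError as exc:
            warnings.warn(f"{c.bead_id}: C_eff fit failed ({exc}); dropped")
            continue
        vals.append(est.c_eff)
    if not vals:
        raise FitError("no molecule yielded a C_eff estimate")
    vals = np.array(vals)
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return CeffPopulation(values=vals, mean=float(vals.mean()), sem=sem,
                          window_halfwidth=float(window_halfwidth))


def _naive_mean_curve(curves: list[RotationCurve]) -> RotationCurve:
    """Per-turn mean torque curve used only for fit-window selection.

    Each molecule's torque is first de-offset by its own central line
    intercept: the torque of the reference step is pinned to zero by
    construction while every other step carries the reference-step
    measurement error as a common offset, and averaging those offsets
    across molecules would otherwise masquerade as curvature.
    """
    detrended = []
    for c in curves:
        sel = np.argsort(np.abs(c.N))[:min(11, len(c.N))]
        b, a = np.polyfit(c.N[sel], c.torque[sel], 1)
        detrended.append(c.torque - a)
    allN = sorted({float(n) for c in curves for n in np.round(c.N)})
    N, tau, se, ext = [], [], [], []
    for Nv in allN:
        vals, exts = [], []
        for c, taud in zip(curves, detrended):
            i = np.where(np.round(c.N) == Nv)[0]
            if len(i):
                vals.append(float(np.mean(taud[i])))
                exts.append(float(np.mean(c.extension[i])))
        if len(vals) < 2:
            continue
        N.append(Nv)
        tau.append(np.mean(vals))
        se.append(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        ext.append(np.mean(exts))
    return RotationCurve(bead_id="mean", N=np.array(N),
                         extension=np.array(ext),
                         extension_se=np.full(len(N), np.nan),
                         torque=np.array(tau), torque_se=np.array(se),
                         force=curves[0].force)


def simulate_condition(params: ModelParams, bead: BeadParams, cfg: SimConfig,
                       ) -> tuple[list[RotationCurve], AveragedCurve, CurveFeatures]:
    """Simulate a population and run the full analysis chain on it.

    Returns the per-molecule rotation curves, the aligned population
    average and the extracted buckling observables.
    """
    traces, _truth = simulate_population(params, bead, cfg)
    curves = population_curves(traces, force=cfg.force, kBT=params.kBT)
    avg = align_and_average(curves)
    feats = extract_features(avg, params)
    return curves, avg, feats
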