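"""Twistable worm-like-chain models for stretched, supercoiled DNA.

Two closed-form models are implemented:

* the Moroz-Nelson (MN) perturbative result for the force dependence of the
  effective torsional stiffness,

      C_eff(F) = C * [1 - (C / 4A) * sqrt(kBT / (A F))],

  which accounts for the softening of the apparent twist stiffness at low
  force by thermally excited bending fluctuations; and

* the two-phase coexistence model of the buckling transition (Marko's
  mechanical model), in which a stretched, twisted phase coexists with a
  plectonemic phase past a critical torque.  With stretched free energy per
  length g(F) = F - sqrt(kBT F / A) (high-force WLC), stretched twist
  stiffness c_s = kBT * C_eff(F) and plectonemic twist stiffness
  p = kBT * P, the coexistence (buckling) torque is

      tau_buck = sqrt(2 p g / (1 - p / c_s)),

  the phase supercoiling densities are sigma_s = tau/(c_s w0) and
  sigma_p = tau/(p w0) (w0 = 2*pi / helical pitch), and the post-buckling
  extension slope per turn is -2*pi*zhat(F) / (w0 (sigma_p - sigma_s)) with
  relative extension zhat(F) = 1 - 0.5*sqrt(kBT/(A F)).

The model requires P < C_eff(F) and g(F) > 0; violations raise
:class:`~torquetweezers.errors.RegimeError` naming the violated inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, RegimeError
from .params import KBT_DEFAULT, ModelParams

__all__ = [
    "ceff_moroz_nelson",
    "MarkoPrediction",
    "marko_coexistence",
    "free_energy_branches",
    "PlectonemeStiffnessModel",
    "PlectonemeStiffnessResults",
    "fit_plectoneme_stiffness",
    "predict_salt_ratio",
    "model_curve_table",
]


def ceff_moroz_nelson(C: float, A: float, force: float,
                      kBT: float = KBT_DEFAULT) -> float:
    """Effective torsional stiffness C_eff(F) in nm (Moroz-Nelson).

    Raises
    ------
    RegimeError
        If force <= 0 or the perturbative bracket 1 - (C/4A)sqrt(kBT/(A F))
        is not positive (force too low for the expansion).
    """
    if force <= 0:
        raise RegimeError("force must be > 0")
    bracket = 1.0 - (C / (4.0 * A)) * math.sqrt(kBT / (A * force))
    if bracket <= 0.0:
        raise RegimeError(
            "outside perturbative regime: 1 - (C/4A)*sqrt(kBT/(A*F)) <= 0 "
            f"at F = {force} pN")
    return C * bracket


def _stretched_free_energy_density(force: float, A: float, kBT: float) -> float:
    """g(F) = F - sqrt(kBT F / A), free energy per length of the stretched phase (pN)."""
    return force - math.sqrt(kBT * force / A)


def _relative_extension(force: float, A: float, kBT: float) -> float:
    """High-force WLC relative extension zhat(F) = 1 - 0.5 sqrt(kBT/(A F))."""
    return 1.0 - 0.5 * math.sqrt(kBT / (A * force))


@dataclass(frozen=True)
class MarkoPrediction:
    """Coexistence-model observables at one force.

    All torques in pN·nm, lengths in nm, slope in nm per turn, n_buck in
    turns for the parameterized contour length.
    """

    force: float
    g: float                  # stretched free energy per length, pN
    c_eff_stretched: float    # MN effective twist persistence length, nm
    tau_buck: float
    sigma_s: float
    sigma_p: float
    slope: float              # post-buckling extension slope, nm/turn (< 0)
    n_buck: float             # buckling point in turns


def marko_coexistence(params: ModelParams, force: float) -> MarkoPrediction:
    """Evaluate the stretched/plectonemic coexistence model at one force.

    The stretched phase's twist stiffness uses the MN effective stiffness at
    the given force; the plectonemic stiffness is params.P.  Requires
    g(F) > 0 and P < C_eff(F).
    """
    kBT = params.kBT
    g = _stretched_free_energy_density(force, params.A, kBT)
    if g <= 0:
        raise RegimeError(
            f"g(F) = F - sqrt(kBT*F/A) <= 0 at F = {force} pN (force too low)")
    c_eff = ceff_moroz_nelson(params.C, params.A, force, kBT)
    if params.P >= c_eff:
        raise RegimeError(
            f"P = {params.P} nm >= C_eff(F) = {c_eff:.3f} nm: "
            "coexistence model requires P < C_eff")
    c_s = kBT * c_eff        # pN·nm^2
    p = kBT * params.P       # pN·nm^2
    tau = math.sqrt(2.0 * p * g / (1.0 - p / c_s))
    w0 = params.omega0
    sigma_s = tau / (c_s * w0)
    sigma_p = tau / (p * w0)
    zhat = _relative_extension(force, params.A, kBT)
    slope = -2.0 * math.pi * zhat / (w0 * (sigma_p - sigma_s))
    n_buck = sigma_s * params.lk0_helix
    return MarkoPrediction(force=force, g=g, c_eff_stretched=c_eff,
                           tau_buck=tau, sigma_s=sigma_s, sigma_p=sigma_p,
                           slope=slope, n_buck=n_buck)


def free_energy_branches(params: ModelParams, force: float,
                         ) -> tuple[Callable[[np.ndarray], np.ndarray],
                                    Callable[[np.ndarray], np.ndarray]]:
    """Free energy per length (pN) of the two pure phases vs supercoiling density.

    Returns ``(f_stretched, f_plectonemic)`` with

        f_s(sigma) = -g(F) + 0.5 * kBT*C_eff(F) * w0^2 * sigma^2
        f_p(sigma) =          0.5 * kBT*P       * w0^2 * sigma^2

    These quadratic branches are the inputs to the common-tangent (Maxwell)
    construction whose tangency points are sigma_s and sigma_p and whose
    tangent slope is tau_buck * w0.
    """
    kBT = params.kBT
    g = _stretched_free_energy_density(force, params.A, kBT)
    c_s = kBT * ceff_moroz_nelson(params.C, params.A, force, kBT)
    p = kBT * params.P
    w0 = params.omega0

    def f_s(sigma):
        return -g + 0.5 * c_s * (w0 * np.asarray(sigma)) ** 2

    def f_p(sigma):
        return 0.5 * p * (w0 * np.asarray(sigma)) ** 2

    return f_s, f_p


# ---------------------------------------------------------------------------
# Plectonemic-stiffness fit (one free parameter P, A and C held fixed)
# ---------------------------------------------------------------------------

_OBSERVABLES = ("n_buck", "slope", "tau_buck")


class PlectonemeStiffnessModel:
    """Fit the plectonemic twist stiffness P to measured buckling observables.

    The model predicts, at each force, the buckling point n_buck(F), the
    post-buckling extension slope (nm/turn) and the buckling torque
    tau_buck(F) from the coexistence model with A and C held fixed.  P is
    fitted individually to each of the three observables across forces and
    the three estimates are averaged, mirroring the measurement protocol.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per force with columns ``force_pN`` and at least one of
        ``n_buck``, ``slope_post_nm_per_turn``, ``tau_buck_pNnm``.  NaN
        entries are ignored per observable.
    params : ModelParams
        Supplies the fixed A, C, contour length and kBT; its P field is
        only used as the initial guess.
    """

    _COLS = {"n_buck": "n_buck", "slope": "slope_post_nm_per_turn",
             "tau_buck": "tau_buck_pNnm"}

    def __init__(self, features: pd.DataFrame, params: ModelParams):
        if "force_pN" not in features.columns:
            raise FitError("features table needs a force_pN column")
        if len(features) < 3:
            raise FitError("need observables at >= 3 forces to fit P")
        self.features = features.reset_index(drop=True)
        self.params = params

    def _predict(self, P: float, forces: np.ndarray, observable: str) -> np.ndarray:
        prm = self.params.with_(P=float(P))
        out = np.empty(len(forces))
        for i, f in enumerate(forces):
            mk = marko_coexistence(prm, float(f))
            out[i] = getattr(mk, "slope" if observable == "slope" else observable)
        return out

    def _fit_one(self, observable: str) -> tuple[float, int]:
        col = self._COLS[observable]
        sub = self.features.dropna(subset=[col])
        forces = sub["force_pN"].to_numpy(float)
        y = sub[col].to_numpy(float)
        if len(y) < 3:
            raise FitError(f"fewer than 3 finite values for {observable}")
        scale = np.maximum(np.abs(y), 1e-9)

        def resid(theta):
            try:
                return (self._predict(theta[0], forces, observable) - y) / scale
            except RegimeError:
                return np.full_like(y, 1e6)

        res = least_squares(resid, x0=[self.params.P], bounds=(1e-3, 200.0))
        if not res.success:
            raise FitError(f"P fit to {observable} did not converge")
        return float(res.x[0]), len(y)

    def fit(self) -> "PlectonemeStiffnessResults":
        per_fit: dict[str, float] = {}
        for obs in _OBSERVABLES:
            col = self._COLS[obs]
            if col not in self.features.columns:
                continue
            try:
                per_fit[obs], _ = self._fit_one(obs)
            except (FitError, RegimeError) as exc:  # diverging fit: drop, warn
                import warnings
                warnings.warn(f"P fit to {obs} excluded: {exc}")
        if len(per_fit) < 2:
            raise FitError("fewer than 2 surviving individual P fits")
        values = np.array(list(per_fit.values()))
        P = float(values.mean())
        P_se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
        return PlectonemeStiffnessResults(P=P, P_se=P_se, per_fit=per_fit,
                                          model=self)


@dataclass
class PlectonemeStiffnessResults:
    """Result of :class:`PlectonemeStiffnessModel.fit`."""

    P: float
    P_se: float
    per_fit: dict[str, float]
    model: PlectonemeStiffnessModel

    def summary(self) -> str:
        lines = ["Plectonemic twist stiffness fit (A, C fixed)",
                 "-" * 46,
                 f"A = {self.model.params.A:.1f} nm   C = {self.model.params.C:.1f} nm"
                 f"   kBT = {self.model.params.kBT:.2f} pN·nm",
                 f"forces: {', '.join(f'{f:g}' for f in self.model.features['force_pN'])} pN",
                 ""]
        for obs, val in self.per_fit.items():
            lines.append(f"  P from {obs:<9s}: {val:6.2f} nm")
        lines.append("-" * 46)
        lines.append(f"  P (mean of fits): {self.P:6.2f} ± {self.P_se:.2f} nm")
        return "\n".join(lines)


def fit_plectoneme_stiffness(features: pd.DataFrame, params: ModelParams,
                             ) -> PlectonemeStiffnessResults:
    """Convenience wrapper: build and fit a :class:`PlectonemeStiffnessModel`."""
    return PlectonemeStiffnessModel(features, params).fit()


def predict_salt_ratio(A_low: float, A_high: float, C: float,
                       forces: Sequence[float],
                       kBT: float = KBT_DEFAULT) -> np.ndarray:
    """MN-predicted ratio C_eff(A_low)/C_eff(A_high) on a force grid.

    With A_low > A_high (stiffer bending at low salt) the ratio is >= 1 and
    decays toward 1 with increasing force: the torsional softening by
    bending fluctuations is what distinguishes the salt conditions, and it
    vanishes in the high-force limit.
    """
    forces = np.asarray(forces, float)
    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        out[i] = (ceff_moroz_nelson(C, A_low, float(f), kBT)
                  / ceff_moroz_nelson(C, A_high, float(f), kBT))
    return out


def model_curve_table(params: ModelParams, forces: Sequence[float]) -> pd.DataFrame:
    """Model predictions on a force grid (export format).

    Columns: force_pN, ceff_nm, tau_buck_pNnm, sigma_s, slope_nm_per_turn,
    n_buck_turns.  Forces outside the coexistence regime get NaN rows for
    the buckling observables but still report C_eff where defined.
    """
    rows = []
    for f in forces:
        row = {"force_pN": f, "ceff_nm": np.nan, "tau_buck_pNnm": np.nan,
               "sigma_s": np.nan, "slope_nm_per_turn": np.nan,
               "n_buck_turns": np.nan}
        try:
            row["ceff_nm"] = ceff_moroz_nelson(params.C, params.A, f, params.kBT)
            mk = marko_coexistence(params, f)
            row.update(tau_buck_pNnm=mk.tau_buck, sigma_s=mk.sigma_s,
                       slope_nm_per_turn=mk.slope, n_buck_turns=mk.n_buck)
        except RegimeError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
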