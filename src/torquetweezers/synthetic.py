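"""Instrument-realistic synthetic data with known ground truth.

Emulates a multiplexed magnetic-torque-tweezers measurement: a DNA-tethered
magnetic bead in a weak harmonic angular trap orbits the tether axis at
radius ``r_circle``; its angle undergoes Ornstein-Uhlenbeck (OU)
fluctuations with stationary variance kBT/k_rot and relaxation time tau_c.
Turning the magnets by N turns drags the trap equilibrium to
theta0 + 2*pi*N, and the restoring torque of the molecule shifts the dwell
equilibrium by -Gamma_mol(N)/k_rot.  The molecular torque and extension as
functions of N follow the twistable worm-like-chain ground truth of
:func:`model_rotation_response`.

Everything downstream (angle tracking, trap calibration, torque curves,
feature extraction, model fits) is testable by parameter recovery against
the ground-truth table emitted by :func:`simulate_population`.

The OU update is exact in distribution (no Euler discretization error):

    Theta_{t+dt} = theta_eq + (Theta_t - theta_eq) e^{-dt/tau_c} + xi,
    Var(xi) = (kBT/k_rot) (1 - e^{-2 dt/tau_c}),

so equipartition holds exactly at any sampling rate.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import FLAG_DWELL, FLAG_MOVING, AngleTrace, BeadTrace, ScheduleStep
from .errors import InvalidInputError, RegimeError
from .params import BeadParams, ModelParams, SimConfig
from .wlc import ceff_moroz_nelson, marko_coexistence

__all__ = [
    "ou_series",
    "simulate_angle_segment",
    "model_rotation_response",
    "simulate_molecule",
    "simulate_population",
    "simulate_transverse_fluctuations",
    "BRAID_SLOPE_NM_PER_TURN",
]

# Extension loss per turn for a doubly tethered (braiding) bead; braids
# shorten the tether geometrically, independent of stretching force.
BRAID_SLOPE_NM_PER_TURN = 40.0

# Regime thresholds (pN): below FORCE_LOW_REGIME the response is symmetric
# (buckling on both winding directions); between the thresholds unwinding
# melts the duplex instead of buckling; above FORCE_HIGH_REGIME no
# supercoiling occurs and overwinding drives the B-to-P transition.
FORCE_LOW_REGIME = 1.0
FORCE_HIGH_REGIME = 6.0


def ou_series(n: int, mean: float, stat_var: float, phi: float,
              rng: np.random.Generator,
              init: Optional[float] = None) -> np.ndarray:
    """Exact-discretization OU sample path of length n.

    phi = exp(-dt/tau_c); stat_var is the stationary variance.  The first
    sample is drawn from the stationary distribution unless ``init`` gives
    a deterministic starting value (then the first returned sample is the
    first *update* after init).
    """
    if n <= 0:
        return np.empty(0)
    if stat_var == 0.0:
        return np.full(n, mean)
    innov_sd = math.sqrt(stat_var * (1.0 - phi * phi))
    w = rng.normal(0.0, innov_sd, size=n)
    if init is None:
        w[0] = rng.normal(0.0, math.sqrt(stat_var))
        x0 = 0.0
    else:
        x0 = init - mean
    x, _ = lfilter([1.0], [1.0, -phi], w, zi=[phi * x0])
    return mean + x


def simulate_angle_segment(bead: BeadParams, theta_eq: float, duration: float,
                           frame_rate: float, seed=None,
                           kBT: float = 4.1,
                           theta_init: Optional[float] = None) -> AngleTrace:
    """Simulate one dwell of angular fluctuations in the rotational trap.

    Returns an :class:`AngleTrace` whose theta series is a mean-reverting
    OU process around theta_eq with stationary variance kBT/k_rot and
    autocorrelation time bead.tau_c.  Setting kBT = 0 gives the zero-noise
    limit (a constant trace at theta_eq).
    """
    if duration <= 0 or frame_rate <= 0:
        raise InvalidInputError("duration and frame_rate must be > 0")
    if kBT < 0:
        raise InvalidInputError("kBT must be >= 0")
    if duration < 10.0 * bead.tau_c:
        warnings.warn(f"duration {duration} s < 10 * tau_c = {10 * bead.tau_c} s; "
                      "trap calibration from this segment will be poor")
    if frame_rate * bead.tau_c <= 2.0:
        raise InvalidInputError(
            f"frame_rate * tau_c = {frame_rate * bead.tau_c:.2f} <= 2: "
            "angular fluctuations would be aliased")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    phi = math.exp(-dt / bead.tau_c)
    theta = ou_series(n, theta_eq, kBT / bead.k_rot, phi, rng, init=theta_init)
    t = np.arange(n) * dt
    return AngleTrace(t=t, theta=theta, step_index=np.zeros(n, dtype=int),
                      center=(0.0, 0.0), radius=bead.r_circle,
                      flags=np.zeros(n, dtype=bool), turns=None,
                      frame_rate=frame_rate)


def model_rotation_response(params: ModelParams, force: float,
                            turns: Sequence[float],
                            regime_force: Optional[float] = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth extension (nm) and torque (pN·nm) versus applied turns.

    Piecewise twistable-WLC response at fixed force:

    * pre-buckling: torque rises linearly, 2*pi*kBT*C_eff(F)*N/L_C, while
      the extension stays at the WLC plateau L_C*(1 - 0.5*sqrt(kBT/(A F)));
    * past the buckling point the torque is capped at the coexistence
      torque and the extension falls at the coexistence slope per turn;
    * F < 1 pN: buckling on both winding directions (odd-symmetric curve);
      1 <= F <= 6 pN: unwinding melts the duplex instead (torque plateau at
      tau_melt, extension held constant); F > 6 pN: no supercoiling at all,
      overwinding caps at the B-to-P torque tau_BP, extension constant.

    ``regime_force`` selects which regime applies when it should follow
    the nominal experimental condition rather than the per-bead force
    (bead-to-bead magnetization spread perturbs the force magnitude, not
    the qualitative response class of the condition); defaults to
    ``force``.
    """
    if force <= 0:
        raise InvalidInputError("force must be > 0")
    N = np.asarray(turns, dtype=float)
    if not np.all(np.isfinite(N)):
        raise InvalidInputError("turns must be finite")
    regime_force = force if regime_force is None else regime_force
    kBT, L_C = params.kBT, params.contour_length
    c_eff = ceff_moroz_nelson(params.C, params.A, force, kBT)
    dtau_dN = 2.0 * math.pi * kBT * c_eff / L_C        # pN·nm per turn
    z_plat = L_C * (1.0 - 0.5 * math.sqrt(kBT / (params.A * force)))

    buckle_pos = buckle_neg = False
    cap_pos, cap_neg = params.tau_BP, params.tau_melt
    mk = None
    if regime_force <= FORCE_HIGH_REGIME:
        mk = marko_coexistence(params, force)
        if mk.tau_buck < params.tau_BP:
            buckle_pos = True
            cap_pos = mk.tau_buck
        if regime_force < FORCE_LOW_REGIME:
            buckle_neg = True
            cap_neg = -mk.tau_buck

    torque = np.clip(dtau_dN * N, cap_neg, cap_pos)
    extension = np.full_like(N, z_plat)
    if buckle_pos:
        over = np.clip(N - mk.n_buck, 0.0, None)
        extension = extension + mk.slope * over          # slope < 0
    if buckle_neg:
        under = np.clip(-N - mk.n_buck, 0.0, None)
        extension = extension + mk.slope * under
    return extension, torque


def _class_response(params: ModelParams, force: float, N_eff: np.ndarray,
                    tether_class: str,
                    regime_force: Optional[float] = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Extension/torque truth for one tether class at molecule-relative turns."""
    if tether_class == "good":
        return model_rotation_response(params, force, N_eff,
                                       regime_force=regime_force)
    z_plat = params.contour_length * (
        1.0 - 0.5 * math.sqrt(params.kBT / (params.A * force)))
    zero = np.zeros_like(N_eff, dtype=float)
    if tether_class == "nicked":
        # Free swivel: no torque builds up, no supercoiling at any force.
        return np.full_like(N_eff, z_plat, dtype=float), zero
    if tether_class == "multi_tether":
        # Braiding from |N| >= 1 turn shortens the tether symmetrically,
        # independent of force; no net molecular torque is modelled.
        loss = BRAID_SLOPE_NM_PER_TURN * np.clip(np.abs(N_eff) - 1.0, 0.0, None)
        return z_plat - loss, zero
    raise InvalidInputError(f"unknown tether class: {tether_class!r}")


def simulate_molecule(params: ModelParams, bead: BeadParams, cfg: SimConfig,
                      tether_class: str = "good",
                      rng: Optional[np.random.Generator] = None,
                      bead_id: str = "bead0",
                      lk0_offset: float = 0.0,
                      z_offset: float = 0.0,
                      regime_force: Optional[float] = None,
                      ) -> tuple[BeadTrace, dict]:
    """Simulate one molecule's full measurement trace over the turn schedule.

    Returns the BeadTrace (dwell and magnet-ramp samples, flagged) and a
    ground-truth dict with every parameter the trace was generated from.
    """
    if tether_class not in ("good", "nicked", "multi_tether"):
        raise InvalidInputError(f"unknown tether class: {tether_class!r}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    N_sched = np.asarray(cfg.turn_schedule, dtype=float)
    N_eff = N_sched - lk0_offset
    ext_truth, tau_truth = _class_response(params, cfg.force, N_eff, tether_class,
                                           regime_force=regime_force)

    theta0 = rng.uniform(-math.pi, math.pi)
    x0, y0 = rng.normal(0.0, 1000.0, size=2)
    theta_eq = theta0 + 2.0 * math.pi * N_sched - tau_truth / bead.k_rot

    fr = cfg.frame_rate
    dt = 1.0 / fr
    n_dwell = int(round(cfg.dwell * fr))
    phi = math.exp(-dt / bead.tau_c)
    stat_var = params.kBT / bead.k_rot

    t_parts, th_parts, z_parts, flag_parts = [], [], [], []
    schedule: list[ScheduleStep] = []
    t_now = 0.0
    theta_last = None
    for i, N in enumerate(N_sched):
        if i > 0:
            # Magnet ramp between dwells: deterministic equilibrium path,
            # flagged so segmentation logic has something real to discard.
            ramp_dur = abs(N - N_sched[i - 1]) / cfg.rotation_rate
            n_ramp = int(round(ramp_dur * fr))
            if n_ramp > 0:
                frac = (np.arange(n_ramp) + 1) / n_ramp
                th_parts.append(theta_eq[i - 1]
                                + frac * (theta_eq[i] - theta_eq[i - 1]))
                z_parts.append(ext_truth[i - 1]
                               + frac * (ext_truth[i] - ext_truth[i - 1]))
                t_parts.append(t_now + np.arange(n_ramp) * dt)
                flag_parts.append(np.full(n_ramp, FLAG_MOVING, dtype=int))
                t_now += n_ramp * dt
                theta_last = theta_eq[i]
        if cfg.camera_blur:
            oversample = 4
            phi_s = math.exp(-dt / oversample / bead.tau_c)
            th_fine = ou_series(n_dwell * oversample, theta_eq[i], stat_var,
                                phi_s, rng, init=theta_last)
            th = th_fine.reshape(n_dwell, oversample).mean(axis=1)
        else:
            th = ou_series(n_dwell, theta_eq[i], stat_var, phi, rng,
                           init=theta_last)
        theta_last = th[-1] if n_dwell else theta_eq[i]
        t_parts.append(t_now + np.arange(n_dwell) * dt)
        th_parts.append(th)
        z_parts.append(np.full(n_dwell, ext_truth[i]))
        flag_parts.append(np.full(n_dwell, FLAG_DWELL, dtype=int))
        schedule.append(ScheduleStep(index=i, turns=float(N),
                                     t_start=t_now, t_end=t_now + n_dwell * dt))
        t_now += n_dwell * dt

    t = np.concatenate(t_parts)
    theta = np.concatenate(th_parts)
    z = np.concatenate(z_parts) + z_offset
    flags = np.concatenate(flag_parts)
    n = len(t)
    x = x0 + bead.r_circle * np.cos(theta) + rng.normal(0.0, bead.xy_noise, n)
    y = y0 + bead.r_circle * np.sin(theta) + rng.normal(0.0, bead.xy_noise, n)
    z = z + rng.normal(0.0, bead.z_noise, n)

    truth = {"bead_id": bead_id, "tether_class": tether_class,
             "force_pN": cfg.force, "k_rot": bead.k_rot, "tau_c": bead.tau_c,
             "C_nm": params.C, "A_nm": params.A, "P_nm": params.P,
             "lk0_offset_turns": lk0_offset, "z_offset_nm": z_offset,
             "theta0_rad": theta0, "r_circle_nm": bead.r_circle,
             "x0_nm": x0, "y0_nm": y0}
    try:
        truth["ceff_nm"] = ceff_moroz_nelson(params.C, params.A, cfg.force,
                                             params.kBT)
    except RegimeError:
        truth["ceff_nm"] = float("nan")
    try:
        mk = marko_coexistence(params, cfg.force)
        truth.update(tau_buck_pNnm=mk.tau_buck, n_buck_turns=mk.n_buck,
                     slope_nm_per_turn=mk.slope)
    except RegimeError:
        truth.update(tau_buck_pNnm=float("nan"), n_buck_turns=float("nan"),
                     slope_nm_per_turn=float("nan"))

    trace = BeadTrace(t=t, x=x, y=y, z=z, bead_id=bead_id,
                      segment_flag=flags, schedule=schedule)
    return trace, truth


def _class_counts(mix: dict, n: int) -> list[str]:
    """Largest-remainder apportionment of tether classes (deterministic)."""
    classes = ["good", "nicked", "multi_tether"]
    exact = {c: mix.get(c, 0.0) * n for c in classes}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    rem = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    out = []
    for c in classes:
        out.extend([c] * counts[c])
    return out


def simulate_population(params: ModelParams, bead: BeadParams, cfg: SimConfig,
                        ) -> tuple[list[BeadTrace], pd.DataFrame]:
    """Simulate a population of molecules with molecule-to-molecule spread.

    Per molecule, k_rot and force are jittered with relative sd
    bead.magnetization_cv (both scale with the bead's magnetization) and
    the intrinsic torsional stiffness C with relative sd cfg.ceff_cv;
    linking-number and extension offsets are drawn with sd
    cfg.lk0_offset_sd and cfg.z_offset_sd.  Returns the traces and a
    ground-truth table (one row per molecule) recording every jittered
    value for recovery tests.  Output is deterministic for a fixed seed.
    """
    root = np.random.default_rng(cfg.seed)
    classes = _class_counts(cfg.tether_class_mix, cfg.n_molecules)
    classes = [classes[i] for i in root.permutation(cfg.n_molecules)]

    def jitter(cv: float) -> float:
        if cv == 0.0:
            return 1.0
        return 1.0 + cv * float(np.clip(root.normal(), -2.5, 2.5))

    traces, rows = [], []
    for m in range(cfg.n_molecules):
        k_rot_m = bead.k_rot * jitter(bead.magnetization_cv)
        force_m = cfg.force * jitter(bead.magnetization_cv)
        C_m = max(params.C * jitter(cfg.ceff_cv), 1.5 * params.P)
        lk0_m = root.normal(0.0, cfg.lk0_offset_sd) if cfg.lk0_offset_sd else 0.0
        z_off_m = root.normal(0.0, cfg.z_offset_sd) if cfg.z_offset_sd else 0.0
        child = np.random.default_rng(root.integers(2 ** 31))
        trace, truth = simulate_molecule(
            params.with_(C=C_m), bead.with_(k_rot=k_rot_m),
            cfg.with_(force=force_m), tether_class=classes[m], rng=child,
            bead_id=f"bead{m:03d}", lk0_offset=lk0_m, z_offset=z_off_m,
            regime_force=cfg.force)
        traces.append(trace)
        rows.append(truth)
    return traces, pd.DataFrame(rows)


def simulate_transverse_fluctuations(force: float, extension: float,
                                     duration: float, frame_rate: float,
                                     kBT: float = 4.1, tau_c: float = 0.1,
                                     seed=None) -> np.ndarray:
    """Transverse (pendulum-mode) bead fluctuations at known force.

    The tethered bead behaves as an inverted pendulum transverse to the
    field: Var(x) = kBT * extension / F.  Used to exercise and test the
    fluctuation-based force calibration.
    """
    if force <= 0 or extension <= 0:
        raise InvalidInputError("force and extension must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * frame_rate))
    phi = math.exp(-1.0 / (frame_rate * tau_c))
    return ou_series(n, 0.0, kBT * extension / force, phi, rng)
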