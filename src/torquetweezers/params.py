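"""Physical parameters for DNA torsional mechanics and the instrument.

Units follow single-molecule convention throughout the package: lengths in
nm, forces in pN, torques and energies in pN·nm, angles in radians, time in
seconds.  Thermal energy defaults to kBT = 4.1 pN·nm (T ≈ 297 K).

Sign convention (used everywhere): positive applied turns N = overwinding
the right-handed double helix = positive molecular torque.  Unwinding
(negative N, e.g. clockwise magnet rotation as seen from above in the
instrument geometry) gives negative torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["ModelParams", "BeadParams", "SimConfig", "KBT_DEFAULT"]

KBT_DEFAULT = 4.1  # pN·nm


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Elastic constants and geometry of a double-stranded DNA tether.

    Parameters
    ----------
    A : float
        Bending persistence length (nm).  Salt-dependent; ~48 nm at low
        monovalent salt, ~43 nm at high salt.
    C : float
        Intrinsic torsional stiffness / twist persistence length (nm),
        high-force limit.  Consensus value 110 nm, salt-independent.
    P : float
        Twist stiffness of the plectonemic state (nm).
    Lc_bp : float
        Contour length in base pairs (default 7900 bp construct).
    rise : float
        Helix rise per base pair (nm/bp).
    helical_repeat : float
        Base pairs per helical turn of relaxed B-DNA.
    kBT : float
        Thermal energy (pN·nm).
    tau_melt : float
        Torque plateau of torque-induced melting (pN·nm, negative).
    tau_BP : float
        Torque plateau of the B-to-P overwinding transition (pN·nm).
    """

    A: float = 48.0
    C: float = 110.0
    P: float = 20.0
    Lc_bp: float = 7900.0
    rise: float = 0.34
    helical_repeat: float = 10.5
    kBT: float = KBT_DEFAULT
    tau_melt: float = -10.0
    tau_BP: float = 35.0

    def __post_init__(self) -> None:
        for name in ("A", "C", "P", "Lc_bp", "rise", "helical_repeat", "kBT"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.tau_melt < 0 < self.tau_BP,
                 "require tau_melt < 0 < tau_BP")

    # Derived quantities, each defined in exactly one place.

    @property
    def contour_length(self) -> float:
        """Contour length L_C in nm."""
        return self.Lc_bp * self.rise

    @property
    def omega0(self) -> float:
        """Intrinsic twist density of relaxed B-DNA, 2π/(helical pitch) in rad/nm."""
        return 2.0 * math.pi / (self.helical_repeat * self.rise)

    @property
    def lk0_helix(self) -> float:
        """Linking number of the relaxed helix (turns): Lc_bp / helical_repeat."""
        return self.Lc_bp / self.helical_repeat

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def low_salt(cls, **kwargs) -> "ModelParams":
        """Defaults for low-salt buffer (20-100 mM NaCl): A = 48 nm, P = 20 nm."""
        return cls(**{"A": 48.0, "P": 20.0, **kwargs})

    @classmethod
    def high_salt(cls, **kwargs) -> "ModelParams":
        """Defaults for high-salt buffer (500 mM NaCl / 10 mM MgCl2): A = 43 nm, P = 15 nm."""
        return cls(**{"A": 43.0, "P": 15.0, **kwargs})


@dataclass(frozen=True)
class BeadParams:
    """Magnetic bead and angular-trap properties.

    k_rot is the rotational trap stiffness (pN·nm/rad); the instrument's
    usable range is 30-1000 pN·nm/rad.  tau_c is the relaxation time of
    angular fluctuations (~0.5 s for 2.8 um M270 beads, ~0.1 s for 1 um
    MyOne beads).  r_circle is the radius of the bead-center orbit about
    the tether axis; xy_noise and z_noise are Gaussian tracking-noise
    standard deviations.  magnetization_cv is the relative bead-to-bead
    spread of magnetization (affects trap stiffness and force alike).
    """

    k_rot: float = 200.0      # pN·nm/rad
    tau_c: float = 0.5        # s (M270-like)
    r_circle: float = 300.0   # nm
    xy_noise: float = 5.0     # nm
    z_noise: float = 10.0     # nm
    magnetization_cv: float = 0.10

    def __post_init__(self) -> None:
        _require(self.k_rot > 0, "k_rot must be > 0")
        _require(self.tau_c > 0, "tau_c must be > 0")
        _require(self.r_circle > 0, "r_circle must be > 0")
        _require(self.xy_noise >= 0 and self.z_noise >= 0,
                 "tracking noise must be >= 0")
        _require(0.0 <= self.magnetization_cv <= 0.5,
                 "magnetization_cv must be in [0, 0.5]")

    def with_(self, **kwargs) -> "BeadParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated measurement run.

    One run dwells for `dwell` seconds at each entry of `turn_schedule`
    (applied magnet turns N), sampling bead positions at `frame_rate`.
    Between dwells the magnets ramp at `rotation_rate` turns/s and the
    intervening samples are flagged as magnet-moving.  `tether_class_mix`
    gives the population proportions of good, nicked and multiply-tethered
    molecules.  `ceff_cv` is the molecule-to-molecule relative spread of
    torsional stiffness (the instrument-typical 10-20 % variability).
    """

    seed: int = 0
    frame_rate: float = 60.0      # Hz
    dwell: float = 100.0          # s per turn step
    turn_schedule: tuple = tuple(range(-15, 16))
    n_molecules: int = 10
    force: float = 6.5            # pN
    tether_class_mix: dict = field(
        default_factory=lambda: {"good": 1.0, "nicked": 0.0, "multi_tether": 0.0})
    lk0_offset_sd: float = 1.0    # turns
    z_offset_sd: float = 50.0     # nm
    ceff_cv: float = 0.15
    rotation_rate: float = 0.1    # Hz, magnet ramp speed between dwells
    camera_blur: bool = False

    def __post_init__(self) -> None:
        _require(self.frame_rate > 0, "frame_rate must be > 0")
        _require(self.dwell > 0, "dwell must be > 0")
        _require(self.n_molecules >= 1, "n_molecules must be >= 1")
        _require(self.force > 0, "force must be > 0")
        _require(len(self.turn_schedule) >= 1, "turn_schedule must be non-empty")
        total = sum(self.tether_class_mix.values())
        _require(abs(total - 1.0) < 1e-9,
                 f"tether_class_mix proportions must sum to 1, got {total}")
        unknown = set(self.tether_class_mix) - {"good", "nicked", "multi_tether"}
        _require(not unknown, f"unknown tether classes: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)
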