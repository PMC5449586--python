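"""Quick-look plots for rotation curves, averages and field maps."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import AveragedCurve, RotationCurve

__all__ = ["plot_rotation_curve", "plot_averaged_curve", "plot_gradient_profile"]


def plot_rotation_curve(curve: RotationCurve, ax=None):
    """Extension (top) and torque (bottom) versus applied turns."""
    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(5, 6))
    ax[0].errorbar(curve.N, curve.extension, yerr=curve.extension_se,
                   fmt="o", ms=3)
    ax[0].set_ylabel("extension (nm)")
    ax[1].errorbar(curve.N, curve.torque, yerr=curve.torque_se, fmt="o", ms=3)
    ax[1].set_ylabel("torque (pN·nm)")
    ax[1].set_xlabel("applied turns N")
    return ax


def plot_averaged_curve(avg: AveragedCurve, ax=None):
    """Population-averaged curve with SEM bands."""
    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(5, 6))
    for a, y, s, lab in ((ax[0], avg.extension, avg.extension_sem, "extension (nm)"),
                         (ax[1], avg.torque, avg.torque_sem, "torque (pN·nm)")):
        a.plot(avg.N, y, "o-", ms=3)
        a.fill_between(avg.N, y - s, y + s, alpha=0.3)
        a.set_ylabel(lab)
    ax[1].set_xlabel("applied turns N")
    ax[0].set_title(f"{avg.force:g} pN, n = {int(np.max(avg.n_molecules))} molecules")
    return ax


def plot_gradient_profile(lat_mm, grads, ax=None):
    """Axial-field-gradient profile across the field of view."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.asarray(lat_mm) * 1e3, grads, "o-")
    ax.set_xlabel("lateral position (um)")
    ax.set_ylabel("dBz/dz (T/m)")
    return ax
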