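"""Quick-look plots for calibration and matching results.

All functions draw on a provided axes (or create one) and return it, so
they compose with user figures; none of the analysis depends on them.
"""

from __future__ import annotations

import numpy as np


def plot_envelope_fit(x_um, profile, fit, ax=None):
    """Column-average profile with the fitted envelope × harmonic model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(x_um, profile, lw=0.8, color="0.4", label="profile")
    ax.plot(x_um, fit.predict(np.asarray(x_um)), lw=1.2, color="C3", label="fit")
    ax.axvline(fit.b, color="C0", ls="--", lw=1, label=f"b = {fit.b:.1f} um")
    ax.set_xlabel("object-space x (um)")
    ax.set_ylabel("mean intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_depth_model(points, fit, ax=None):
    """(PWM duty, depth) points with the fitted line and its equation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(points, dtype=float)
    ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, color="C0")
    xs = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 50)
    ax.plot(xs, fit.predict(xs), color="C3",
            label=f"y = {fit.slope:.2f}x + {fit.intercept:.2f}, R$^2$ = {fit.r_squared:.3f}")
    ax.set_xlabel("EWL duty cycle (%)")
    ax.set_ylabel("focal depth (um)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_distortion(dist_fit, ax=None):
    """Radial displacement vs ideal radius with the fitted cubic."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r = dist_fit.r_ideal_um
    ax.plot(r, dist_fit.delta_r_um, ".", ms=4, color="0.4")
    xs = np.linspace(0, r.max(), 60)
    ax.plot(xs, dist_fit.k_hat * xs**3, color="C3",
            label=f"k = {dist_fit.k_hat:.2e} um$^{{-2}}$")
    ax.set_xlabel("ideal radius (um)")
    ax.set_ylabel("radial displacement (um)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_match_overlay(result, ax=None):
    """Red/green footprint contours; matched neurons drawn solid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(result.green_stack.time_average(), cmap="gray")
    matched_r = {la for la, _, _ in result.match_table.pairs}
    matched_g = {lb for _, lb, _ in result.match_table.pairs}
    for nmap, matched, color in (
        (result.red_map, matched_r, "red"),
        (result.green_map, matched_g, "deepskyblue"),
    ):
        for fp in nmap.footprints:
            sup = fp.support().astype(float)
            ls = "-" if fp.label in matched else ":"
            ax.contour(sup, levels=[0.5], colors=color, linewidths=1.0, linestyles=ls)
    ax.set_axis_off()
    return ax
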