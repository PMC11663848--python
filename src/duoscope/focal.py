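"""Focal-plane depth estimation from a 45° depth-of-field target.

The focused band of a 15 lp/mm line-pair target imaged at 45° appears as
an oscillation at the 66.67 µm line-pair period whose modulation depth
decays with defocus.  The column-average profile of a trial's
time-average frame is therefore modelled as a first-harmonic Fourier
series under a Gaussian envelope,

    y(x) ≈ d + a·exp(−((x−b)/c)²) · (A0 + A1·cos(2πx/ω) + B1·sin(2πx/ω)),

with ω the line-pair period (66.67 µm for 15 lp/mm).  The envelope
centre *b* is the lateral position of best focus and, with the 45°
geometry, translates one-for-one into focal depth.  A fitted baseline
*d* absorbs the target's background pedestal, which the purely enveloped
model cannot represent; *a* is fixed to 1 (it is not identifiable
jointly with the harmonic coefficients).

Sweeping the electrowetting-lens PWM duty cycle and fitting the envelope
per trial yields (duty, depth) points; :class:`FocalDepthModel` fits the
linear control-signal→depth response by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .frames import FrameStack
from .optics import OpticsParams

#: ω for a 15 lp/mm target: the line-pair period in object-space µm
DEFAULT_OMEGA = 66.67


def pwm_counts_to_percent(counts: float) -> float:
    """Convert a raw 0–1023 EWL control value to percent duty cycle."""
    if not 0 <= counts <= 1023:
        raise ValueError(f"PWM counts must lie in [0, 1023], got {counts}")
    return counts / 1023.0 * 100.0


def column_average_profile(
    stack: FrameStack, optics: OpticsParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-average pixel value of the trial's time-average frame.

    Returns ``(x_um, profile)`` where ``x_um`` is the object-space
    position of each column (pixel pitch / magnification) and
    ``profile[j]`` is the mean over rows of the time-averaged frame at
    column j.
    """
    if len(stack) == 0:
        raise ValueError("cannot profile an empty stack")
    avg = stack.time_average()
    profile = avg.mean(axis=0)
    if optics is not None:
        px = optics.object_pixel_um
    else:
        px = stack.meta.get("object_pixel_um", 1.0)
    x_um = np.arange(profile.size) * px
    return x_um, profile


@dataclass(frozen=True)
class EnvelopeFit:
    """Fitted parameters of the envelope × first-harmonic model."""

    a: float
    b: float
    c: float
    A0: float
    A1: float
    B1: float
    omega: float
    baseline: float
    sse: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        env = self.a * np.exp(-(((x - self.b) / self.c) ** 2))
        arg = 2.0 * np.pi * x / self.omega
        return self.baseline + env * (
            self.A0 + self.A1 * np.cos(arg) + self.B1 * np.sin(arg)
        )

    def summary(self) -> str:
        lines = [
            "Envelope x first-harmonic fit",
            "-" * 37,
            f"envelope center b   {self.b:12.3f} um",
            f"envelope width  c   {self.c:12.3f} um",
            f"A0, A1, B1          {self.A0:8.4f} {self.A1:8.4f} {self.B1:8.4f}",
            f"omega (period)      {self.omega:12.3f} um",
            f"baseline            {self.baseline:12.4f}",
            f"SSE                 {self.sse:12.6g}  (n = {self.n_points})",
        ]
        return "\n".join(lines)


class EnvelopeModel:
    """Least-squares fit of the defocus-envelope line-pair model.

    For fixed (b, c) the coefficients (d, A0, A1, B1) enter linearly and
    are solved in closed form; (b, c) are refined by bounded quasi-Newton
    descent from a deterministic multi-start grid (8 centre starts × 3
    width scales), so the fit has no random state.
    """

    def __init__(self, x_um: np.ndarray, profile: np.ndarray, omega: float = DEFAULT_OMEGA):
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(profile, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x_um and profile must be equal-length 1-D arrays")
        if x.size < 8:
            raise ValueError("profile too short to fit (need >= 8 samples)")
        if omega <= 0:
            raise ValueError("omega must be positive")
        if np.ptp(y) == 0 or np.var(y) == 0:
            raise ValueError("degenerate fit: profile has zero variance")
        self.x = x
        self.y = y
        self.omega = float(omega)
        arg = 2.0 * np.pi * x / omega
        self._cos = np.cos(arg)
        self._sin = np.sin(arg)

    def _solve_linear(self, b: float, c: float) -> tuple[np.ndarray, float]:
        """Best (baseline, A0, A1, B1) and SSE for a given envelope."""
        env = np.exp(-(((self.x - b) / c) ** 2))
        X = np.column_stack([np.ones_like(self.x), env, env * self._cos, env * self._sin])
        coef, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ coef
        return coef, float(resid @ resid)

    def _sse(self, params: np.ndarray) -> float:
        b, log_c = params
        return self._solve_linear(b, float(np.exp(log_c)))[1]

    def fit(self, n_starts_b: int = 8, c_scales: tuple[float, ...] = (0.03, 0.1, 0.3)) -> EnvelopeFit:
        x = self.x
        span = x[-1] - x[0]
        dx = span / (x.size - 1)
        bounds = [(x[0], x[-1]), (np.log(max(2 * dx, 1e-6)), np.log(2 * span))]
        best = None
        b_starts = np.linspace(x[0] + 0.05 * span, x[-1] - 0.05 * span, n_starts_b)
        for b0 in b_starts:
            for cs in c_scales:
                res = minimize(
                    self._sse,
                    x0=np.array([b0, np.log(cs * span)]),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": 1e-12, "gtol": 1e-10},
                )
                if best is None or res.fun < best.fun:
                    best = res
        b, log_c = best.x
        c = float(np.exp(log_c))
        coef, sse = self._solve_linear(b, c)
        return EnvelopeFit(
            a=1.0,
            b=float(b),
            c=c,
            A0=float(coef[1]),
            A1=float(coef[2]),
            B1=float(coef[3]),
            omega=self.omega,
            baseline=float(coef[0]),
            sse=sse,
            n_points=x.size,
        )


def fit_envelope_sinusoid(
    profile: np.ndarray | tuple[np.ndarray, np.ndarray],
    omega: float = DEFAULT_OMEGA,
    x_um: np.ndarray | None = None,
) -> EnvelopeFit:
    """Functional wrapper around :class:`EnvelopeModel`.

    ``profile`` may be a bare intensity vector (x then defaults to the
    sample index, i.e. 1 µm/pixel) or an ``(x_um, profile)`` pair as
    returned by :func:`column_average_profile`.
    """
    if isinstance(profile, tuple):
        x_um, profile = profile
    y = np.asarray(profile, dtype=float)
    if x_um is None:
        x_um = np.arange(y.size, dtype=float)
    return EnvelopeModel(x_um, y, omega=omega).fit()


def trial_focal_depth(
    fit: EnvelopeFit,
    optics: OpticsParams | None = None,
    x_ref: float = 0.0,
    depth_ref: float = 0.0,
) -> float:
    """Focal depth implied by the envelope centre.

    With the 45° target, one object-space µm of lateral envelope
    displacement equals one µm of depth: depth = (b − x_ref) + depth_ref.
    """
    return (fit.b - x_ref) + depth_ref


@dataclass(frozen=True)
class DepthModelFit:
    """OLS fit of focal depth (µm) against PWM duty cycle (%)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, pwm_percent: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(pwm_percent, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            "Control-signal -> depth model (OLS)\n"
            "-----------------------------------\n"
            f"y = {self.slope:.2f}x + {self.intercept:.2f},  "
            f"R^2 = {self.r_squared:.3f}  (n = {self.n_points})"
        )


class FocalDepthModel:
    """Linear model of focal depth vs EWL duty cycle."""

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("need >= 2 (pwm_percent, depth_um) points")
        self.pwm = pts[:, 0]
        self.depth = pts[:, 1]
        if np.ptp(self.pwm) == 0:
            raise ValueError("all PWM values identical: slope undefined")

    def fit(self) -> DepthModelFit:
        slope, intercept = np.polyfit(self.pwm, self.depth, 1)
        pred = slope * self.pwm + intercept
        ss_res = float(np.sum((self.depth - pred) ** 2))
        ss_tot = float(np.sum((self.depth - self.depth.mean()) ** 2))
        if ss_tot == 0.0:
            warnings.warn("zero-variance depths: R^2 reported as 0", stacklevel=2)
            r2 = 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        return DepthModelFit(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(r2),
            n_points=self.pwm.size,
        )


def fit_depth_model(points) -> DepthModelFit:
    """Functional wrapper: OLS depth-vs-duty fit from (pwm, depth) pairs."""
    return FocalDepthModel(points).fit()
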