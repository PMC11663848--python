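"""Per-frame preprocessing: de-interleaving, median filtering, rigid
motion correction by Fourier cross-correlation.

The acquisition alternates the excitation LED and the EWL focal plane
between consecutive sensor frames, so an interleaved stream splits into
two channel videos at half the sensor frame rate.  Each frame is then
3×3 median filtered and registered to a trial reference by the shift
maximizing the Fourier cross-correlation, with optional sub-pixel
refinement via upsampled DFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .frames import FrameStack


def deinterleave(stack: FrameStack, phase: str = "green_first") -> tuple[FrameStack, FrameStack]:
    """Split an alternating-illumination stream into its two channels.

    Frames 0, 2, 4, … go to the channel named first by ``phase``;
    1, 3, 5, … to the other.  Each output runs at half the sensor frame
    rate.  Returns ``(green, red)`` regardless of phase.
    """
    if phase not in ("green_first", "red_first"):
        raise ValueError("phase must be 'green_first' or 'red_first'")
    if len(stack) < 2:
        raise ValueError("need at least 2 frames to de-interleave")
    even = stack.data[0::2]
    odd = stack.data[1::2]
    first, second = ("green", "red") if phase == "green_first" else ("red", "green")
    mk = lambda d, ch: FrameStack(
        data=d, fps=stack.fps / 2.0, channel=ch, meta={**stack.meta, "deinterleaved": True}
    )
    a, b = mk(even, first), mk(odd, second)
    return (a, b) if first == "green" else (b, a)


def reinterleave(green: FrameStack, red: FrameStack, phase: str = "green_first") -> FrameStack:
    """Inverse of :func:`deinterleave` (round-trips exactly)."""
    first, second = (green, red) if phase == "green_first" else (red, green)
    n = len(first) + len(second)
    out = np.empty((n, *first.frame_shape), dtype=first.data.dtype)
    out[0::2] = first.data
    out[1::2] = second.data
    return FrameStack(data=out, fps=first.fps * 2.0, channel="interleaved", meta=dict(first.meta))


def median3x3(image: np.ndarray) -> np.ndarray:
    """3×3 median filter with reflective edge handling.

    Accepts a single frame or a (T, H, W) stack (filtered per frame).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        if min(image.shape) < 3:
            raise ValueError("frame must be at least 3x3")
        return ndimage.median_filter(image, size=3, mode="reflect")
    if image.ndim == 3:
        return ndimage.median_filter(image, size=(1, 3, 3), mode="reflect")
    raise ValueError("expected a 2-D frame or 3-D stack")


@dataclass(frozen=True)
class RigidShift:
    """Rigid x–y displacement of a frame relative to a reference.

    Sign convention: the frame content is displaced by (+dx, +dy)
    relative to the reference, so applying (−dx, −dy) to the frame
    aligns it with the reference.  x = columns, y = rows.
    """

    dx: float
    dy: float
    peak_corr: float = 0.0


def register_translation(
    frame: np.ndarray, reference: np.ndarray, upsample: int = 1,
    max_shift_px: float | None = None,
) -> RigidShift:
    """Shift maximizing the Fourier cross-correlation of frame vs reference.

    Plain (unnormalized) cross-correlation; sub-pixel refinement via
    locally upsampled DFT when ``upsample > 1``.  ``max_shift_px``
    restricts the search to |dx|, |dy| ≤ bound (peak then refined by
    quadratic interpolation) — used when the physical displacement is
    known to be small, e.g. cross-channel chromatic offsets, where
    unrelated image content can otherwise produce a spurious far peak.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have equal shapes")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        raise ValueError("zero-variance input: registration undefined")
    if max_shift_px is not None:
        return _register_bounded(frame, reference, max_shift_px)
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=max(1, int(upsample)), normalization=None
    )
    dy, dx = -shift[0], -shift[1]
    aligned = apply_shift(frame, RigidShift(dx=-dx, dy=-dy))
    corr = float(np.corrcoef(aligned.ravel(), reference.ravel())[0, 1])
    return RigidShift(dx=float(dx), dy=float(dy), peak_corr=corr)


def _register_bounded(
    frame: np.ndarray, reference: np.ndarray, max_shift_px: float
) -> RigidShift:
    """Cross-correlation peak restricted to a small shift window."""
    a = frame - frame.mean()
    b = reference - reference.mean()
    cc = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    H, W = cc.shape
    dys = np.fft.fftfreq(H, 1.0 / H)  # signed shift per row of cc
    dxs = np.fft.fftfreq(W, 1.0 / W)
    mask = (np.abs(dys)[:, None] <= max_shift_px) & (np.abs(dxs)[None, :] <= max_shift_px)
    cc_m = np.where(mask, cc, -np.inf)
    i, j = np.unravel_index(np.argmax(cc_m), cc.shape)
    # quadratic sub-pixel refinement on the circular surface
    def interp(axis, k):
        km, kp = (k - 1) % cc.shape[axis], (k + 1) % cc.shape[axis]
        if axis == 0:
            ym, y0, yp = cc[km, j], cc[k, j], cc[kp, j]
        else:
            ym, y0, yp = cc[i, km], cc[i, k], cc[i, kp]
        denom = 2.0 * (2.0 * y0 - ym - yp)
        if denom <= 0:  # not a proper local max (e.g. mask edge)
            return 0.0
        return float(np.clip((yp - ym) / denom, -0.5, 0.5))

    dy = dys[i] + interp(0, i)
    dx = dxs[j] + interp(1, j)
    aligned = apply_shift(frame, RigidShift(dx=-dx, dy=-dy))
    corr = float(np.corrcoef(aligned.ravel(), reference.ravel())[0, 1])
    return RigidShift(dx=float(dx), dy=float(dy), peak_corr=corr)


def apply_shift(frame: np.ndarray, shift: RigidShift, mode: str = "subpixel") -> np.ndarray:
    """Displace a frame by (+dx, +dy) via spectral (Fourier) shifting.

    ``mode="integer"`` rolls by the nearest integer offset instead.
    """
    if mode == "integer":
        return np.roll(frame, (int(round(shift.dy)), int(round(shift.dx))), axis=(0, 1))
    f = ndimage.fourier_shift(np.fft.fft2(np.asarray(frame, dtype=float)), (shift.dy, shift.dx))
    return np.fft.ifft2(f).real


def motion_correct_trial(
    stack: FrameStack,
    reference_policy: str = "two_pass",
    upsample: int = 10,
    mode: str = "subpixel",
) -> tuple[FrameStack, list[RigidShift]]:
    """Rigid motion correction of all frames in a trial.

    ``reference_policy="two_pass"`` registers to the first frame, forms
    a provisional average, then registers everything to that average
    (the shipped default); ``"first_frame"`` stops after the first pass.
    The corrected stack is anchored at the trial's mean position (the
    mean estimated shift is subtracted), so independently corrected
    streams of the same scene — e.g. the two de-interleaved channels —
    land in a common frame.  Returns the corrected stack and the
    per-frame shifts relative to that mean position.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    data = np.asarray(stack.data, dtype=float)

    def _estimate(ref: np.ndarray) -> list[RigidShift]:
        return [register_translation(f, ref, upsample=upsample) for f in data]

    def _apply(shifts: list[RigidShift]) -> np.ndarray:
        return np.stack(
            [
                apply_shift(f, RigidShift(dx=-s.dx, dy=-s.dy), mode=mode)
                for f, s in zip(data, shifts)
            ]
        )

    shifts = _estimate(data[0])
    if reference_policy == "two_pass":
        shifts = _estimate(_apply(shifts).mean(axis=0))
    elif reference_policy != "first_frame":
        raise ValueError("reference_policy must be 'two_pass' or 'first_frame'")
    mdx = float(np.mean([s.dx for s in shifts]))
    mdy = float(np.mean([s.dy for s in shifts]))
    shifts = [RigidShift(s.dx - mdx, s.dy - mdy, s.peak_corr) for s in shifts]
    corrected = _apply(shifts)
    out = FrameStack(
        data=corrected.astype(np.float32),
        fps=stack.fps,
        channel=stack.channel,
        meta={**stack.meta, "motion_corrected": True},
    )
    return out, shifts
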