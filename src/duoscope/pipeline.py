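"""High-level workflows tying the stages into the two experiment types:

* calibration — focal sweep → PWM→depth model; grid scan → distortion
  and Petzval sphere; bead volumes → chromatic offsets;
* session analysis — de-interleave, filter, motion-correct, segment
  both channels, register and overlap-match them, extract traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import chroma as chroma_mod
from . import dualchan, focal, geom, preproc
from .frames import FrameStack
from .optics import OpticsParams


# ---------------------------------------------------------------------------
# calibration workflows
# ---------------------------------------------------------------------------

def calibrate_focus_sweep(
    trials: list[FrameStack],
    optics: OpticsParams,
    omega: float = focal.DEFAULT_OMEGA,
    depth_origin_um: float | None = None,
) -> dict[str, Any]:
    """Envelope-fit every trial of a PWM sweep and fit the depth model.

    ``depth_origin_um`` maps the envelope centre (lateral µm) to an
    absolute depth; if None it is taken from trial metadata
    (``z_at_x0_um``) when present, else 0 — the slope and R² of the
    depth model are independent of this origin.
    """
    rows = []
    for trial in trials:
        pwm = trial.meta.get("pwm_percent")
        if pwm is None:
            raise ValueError("trial metadata must carry pwm_percent")
        x_um, profile = focal.column_average_profile(trial, optics)
        fit = focal.EnvelopeModel(x_um, profile, omega=omega).fit()
        origin = (
            depth_origin_um
            if depth_origin_um is not None
            else trial.meta.get("z_at_x0_um", 0.0)
        )
        depth = focal.trial_focal_depth(fit, optics, x_ref=0.0, depth_ref=origin)
        rows.append(
            {
                "pwm_percent": float(pwm),
                "b_um": fit.b,
                "c_um": fit.c,
                "sse": fit.sse,
                "depth_um": depth,
                "channel": trial.channel,
            }
        )
    model = focal.FocalDepthModel(
        [(r["pwm_percent"], r["depth_um"]) for r in rows]
    ).fit()
    return {"trials": rows, "depth_model": model}


def calibrate_grid(
    depth_stack: list[tuple[float, np.ndarray]],
    optics: OpticsParams,
    spacing_um: float = 25.0,
) -> dict[str, Any]:
    """Grid-scan calibration: distortion profile and Petzval sphere.

    Intersections are detected on the globally sharpest frame of the
    scan; the per-point optimal depths feed the linearized sphere fit
    (boundary-argmax points excluded).
    """
    energies = [float(np.sum(np.diff(f, axis=0) ** 2) + np.sum(np.diff(f, axis=1) ** 2))
                for _, f in depth_stack]
    sharpest = depth_stack[int(np.argmax(energies))][1]
    detection = geom.detect_grid_intersections(sharpest, spacing_um, optics)
    focus_points = geom.optimal_focus_per_point(
        depth_stack, detection.detected_points, optics, window_um=spacing_um
    )
    # field curvature defocuses off-apex nodes on any single frame:
    # re-localize each node on its own best-focus frame before the
    # distortion fit
    detection = geom.refine_intersections_at_focus(
        depth_stack, detection, focus_points, optics
    )
    distortion = geom.measure_distortion(detection)
    focus_points = geom.optimal_focus_per_point(
        depth_stack, detection.detected_points, optics, window_um=spacing_um
    )
    reliable = [p for p in focus_points if p.reliable]
    # a flat field gives coplanar focus points: no finite sphere exists
    try:
        sphere = geom.fit_petzval_sphere(reliable)
    except ValueError as exc:
        sphere = None
        degenerate_reason = str(exc)
    else:
        degenerate_reason = None
    return {
        "sphere_degenerate_reason": degenerate_reason,
        "detection": detection,
        "distortion": distortion,
        "focus_points": focus_points,
        "sphere": sphere,
        "reference_depth_um": geom.reference_focal_depth(focus_points),
    }


def calibrate_beads(
    green_volume: np.ndarray,
    red_volume: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    min_separation_um: float = 20.0,
    max_match_dist_um: float = 20.0,
    threshold_factor: float = 8.0,
) -> dict[str, Any]:
    """Detect, match and summarize bead peaks across the two channels."""
    green = chroma_mod.detect_beads(
        green_volume, voxel_size_um, min_separation_um, threshold_factor, channel="green"
    )
    red = chroma_mod.detect_beads(
        red_volume, voxel_size_um, min_separation_um, threshold_factor, channel="red"
    )
    pairs = chroma_mod.match_beads(green, red, max_dist_um=max_match_dist_um)
    summary = chroma_mod.chromatic_offsets(pairs)
    return {"green_peaks": green, "red_peaks": red, "pairs": pairs, "summary": summary}


# ---------------------------------------------------------------------------
# dual-channel session workflow
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Outputs of the dual-channel session analysis."""

    green_map: dualchan.NeuralMap
    red_map: dualchan.NeuralMap  # aligned into the green frame
    cross_shift: preproc.RigidShift
    match_table: dualchan.MatchTable
    green_stack: FrameStack
    red_stack: FrameStack
    green_shifts: list[preproc.RigidShift]
    red_shifts: list[preproc.RigidShift]
    traces: list[dualchan.Trace] = field(default_factory=list)

    @property
    def matched_pct_red(self) -> float:
        """Percent of red-channel neurons with a green-channel match."""
        return dualchan.matched_percentage(self.match_table, denominator="channel_A")

    def summary(self) -> str:
        t = self.match_table
        return (
            "Dual-channel session\n"
            "--------------------\n"
            f"green neurons: {len(self.green_map)}   red neurons: {len(self.red_map)}\n"
            f"matched pairs: {len(t.pairs)} (threshold {t.threshold:.2f})\n"
            f"matched % of red channel: {self.matched_pct_red:.1f}\n"
            f"cross-channel shift: dx={self.cross_shift.dx:+.2f} px, "
            f"dy={self.cross_shift.dy:+.2f} px"
        )


def analyze_interleaved_session(
    stack: FrameStack,
    phase: str = "green_first",
    overlap_threshold: float = 0.5,
    *,
    highpass_sigma_px: float = 8.0,
    red_threshold_factor: float = 4.0,
    green_threshold_factor: float = 3.0,
    min_area_px: int = 20,
    max_area_px: int = 800,
    upsample: int = 10,
    extract_traces: bool = False,
) -> SessionResult:
    """Full dual-channel analysis of one interleaved acquisition.

    De-interleaves, 3×3-median-filters and motion-corrects each channel,
    segments the red static channel from its corrected average and the
    green channel from its PNR image (watershed-split for crowded
    fields), registers the red map into the green frame via the channel
    average images, and overlap-matches the two maps.
    """
    green, red = preproc.deinterleave(stack, phase=phase)
    green = FrameStack(preproc.median3x3(green.data), green.fps, "green", dict(green.meta))
    red = FrameStack(preproc.median3x3(red.data), red.fps, "red", dict(red.meta))
    green, g_shifts = preproc.motion_correct_trial(green, upsample=upsample)
    red, r_shifts = preproc.motion_correct_trial(red, upsample=upsample)

    red_avg = red.time_average()
    red_map = dualchan.segment_static_channel(
        red_avg,
        highpass_sigma_px=highpass_sigma_px,
        threshold_factor=red_threshold_factor,
        min_area_px=min_area_px,
        max_area_px=max_area_px,
        split_touching=True,
        channel="red",
    )
    pnr = dualchan.pnr_image(green)
    green_map = dualchan.segment_static_channel(
        pnr,
        highpass_sigma_px=highpass_sigma_px,
        threshold_factor=green_threshold_factor,
        min_area_px=min_area_px,
        max_area_px=max_area_px,
        split_touching=True,
        channel="green",
    )
    # register via the channels' average images (shared anatomy:
    # vasculature and co-labelled somata), high-passed so large-scale
    # illumination differences do not bias the correlation
    from scipy.ndimage import gaussian_filter

    def _hp(im: np.ndarray) -> np.ndarray:
        return im - gaussian_filter(im, highpass_sigma_px)

    green_avg_map = dualchan.NeuralMap(
        green_map.footprints, _hp(green.time_average()), channel="green"
    )
    red_avg_map = dualchan.NeuralMap(red_map.footprints, _hp(red_avg), channel="red")
    shift = dualchan.register_maps(green_avg_map, red_avg_map, upsample=upsample)
    red_aligned = dualchan.shift_map(
        red_map, preproc.RigidShift(dx=-shift.dx, dy=-shift.dy)
    )
    # refine the cross-channel shift from co-labelled somata: loosely
    # match, take the median residual centroid displacement, re-align
    loose = dualchan.match_maps(
        red_aligned, green_map, threshold=max(0.2, overlap_threshold - 0.2)
    )
    if len(loose.pairs) >= 3:
        resid = []
        for la, lb, _ in loose.pairs:
            ca = red_aligned.get(la).centroid
            cb = green_map.get(lb).centroid
            resid.append((cb[0] - ca[0], cb[1] - ca[1]))
        mdy = float(np.median([r[0] for r in resid]))
        mdx = float(np.median([r[1] for r in resid]))
        shift = preproc.RigidShift(
            dx=shift.dx - mdx, dy=shift.dy - mdy, peak_corr=shift.peak_corr
        )
        red_aligned = dualchan.shift_map(
            red_map, preproc.RigidShift(dx=-shift.dx, dy=-shift.dy)
        )
    table = dualchan.match_maps(red_aligned, green_map, threshold=overlap_threshold)

    traces: list[dualchan.Trace] = []
    if extract_traces:
        all_support = np.zeros(green.frame_shape, dtype=bool)
        for fp in green_map.footprints:
            all_support |= fp.support()
        for fp in green_map.footprints:
            traces.append(
                dualchan.roi_trace(green, fp, exclude_mask=all_support)
            )
    return SessionResult(
        green_map=green_map,
        red_map=red_aligned,
        cross_shift=shift,
        match_table=table,
        green_stack=green,
        red_stack=red,
        green_shifts=g_shifts,
        red_shifts=r_shifts,
        traces=traces,
    )
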