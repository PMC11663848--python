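"""Grid-target geometry: intersection detection, distortion, field curvature.

A 25 µm grid slide imaged at stepped focal depths yields, per line
intersection, a sub-pixel lateral position and a depth of best focus.
Radial distortion is quantified against the ideal lattice after a
similarity alignment, and the Petzval field-curvature sphere is fitted
to the (x, y, z_opt) cloud by the standard linearization of the sphere
equation, x² + y² + z² = 2x0·x + 2y0·y + 2z0·z + d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, peak_local_max
from skimage.transform import SimilarityTransform, estimate_transform

from .optics import OpticsParams


# ---------------------------------------------------------------------------
# intersection detection
# ---------------------------------------------------------------------------

@dataclass
class GridDetection:
    """Matched detected/ideal grid intersections, coordinates in µm.

    ``detected_points`` are sub-pixel intersection positions in
    object-space µm, origin at the frame centre.  ``ideal_points`` are
    the corresponding perfect-lattice positions (lattice frame, origin
    at an arbitrary lattice node); ``correspondence`` pairs indices into
    the two arrays one-to-one.
    """

    detected_points: np.ndarray
    ideal_points: np.ndarray
    correspondence: list[tuple[int, int]]
    spacing_um: float = 25.0

    def __post_init__(self) -> None:
        if len(self.detected_points) != len(self.correspondence):
            raise ValueError("correspondence must cover every detected point")


def _cross_template(spacing_px: float, line_halfwidth_px: float) -> np.ndarray:
    half = max(3, int(round(spacing_px * 0.4)))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    w = line_halfwidth_px
    gx = np.exp(-(xx**2) / (2 * w**2))
    gy = np.exp(-(yy**2) / (2 * w**2))
    return -(gx + gy - gx * gy)


def _quadratic_peak_offset(r: np.ndarray, idx: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel offset of a correlation peak by 1-D parabola per axis."""
    i, j = idx
    out = []
    for axis, k in ((0, i), (1, j)):
        if k <= 0 or k >= r.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            ym, y0, yp = r[k - 1, j], r[k, j], r[k + 1, j]
        else:
            ym, y0, yp = r[i, k - 1], r[i, k], r[i, k + 1]
        denom = 2.0 * (2.0 * y0 - ym - yp)
        out.append(0.0 if denom == 0 else float((yp - ym) / denom))
    return out[0], out[1]


def _grid_rotation(points: np.ndarray, spacing: float) -> float:
    """Dominant lattice orientation mod 90°, via 4-fold circular mean."""
    acc = 0.0 + 0.0j
    for p in points:
        d = points - p
        r = np.hypot(d[:, 0], d[:, 1])
        near = (r > 0.3 * spacing) & (r < 1.4 * spacing)
        ang = np.arctan2(d[near, 1], d[near, 0])
        acc += np.exp(4j * ang).sum()
    if acc == 0:
        return 0.0
    return float(np.angle(acc) / 4.0)


def detect_grid_intersections(
    frame: np.ndarray,
    spacing_um: float,
    optics: OpticsParams,
    *,
    min_rel_response: float = 0.4,
    line_halfwidth_um: float = 2.0,
) -> GridDetection:
    """Localize grid line intersections to sub-pixel and index the lattice.

    Intersections are found by normalized cross-correlation with a dark
    cross template, refined by quadratic peak interpolation, and indexed
    to the nearest ideal lattice node after estimating the grid's
    orientation (robust to a few degrees of rotation).
    """
    frame = np.asarray(frame, dtype=float)
    px = optics.object_pixel_um
    spacing_px = spacing_um / px
    tmpl = _cross_template(spacing_px, max(1.0, line_halfwidth_um / px))
    resp = match_template(frame - frame.mean(), tmpl, pad_input=True)
    peaks = peak_local_max(
        resp,
        min_distance=max(2, int(0.55 * spacing_px)),
        threshold_abs=min_rel_response * max(resp.max(), 1e-12),
        exclude_border=max(2, int(0.3 * spacing_px)),
    )
    if len(peaks) < 4:
        raise ValueError(f"found only {len(peaks)} grid intersections (need >= 4)")

    H, W = frame.shape
    pts = []
    for i, j in peaks:
        oy, ox = _quadratic_peak_offset(resp, (i, j))
        pts.append(((j + ox) - (W - 1) / 2.0, (i + oy) - (H - 1) / 2.0))
    detected = np.array(pts) * px  # (x, y) µm, origin at frame centre

    theta = _grid_rotation(detected, spacing_um)
    rot = np.array(
        [[math.cos(-theta), -math.sin(-theta)], [math.sin(-theta), math.cos(-theta)]]
    )
    aligned = detected @ rot.T
    origin = aligned[np.argmin(np.hypot(*(aligned - aligned.mean(axis=0)).T))]
    idx = np.round((aligned - origin) / spacing_um).astype(int)

    # drop lattice-index collisions, keeping the stronger response
    seen: dict[tuple[int, int], int] = {}
    keep = []
    strengths = resp[peaks[:, 0], peaks[:, 1]]
    for n, key in enumerate(map(tuple, idx)):
        if key in seen:
            if strengths[n] > strengths[seen[key]]:
                keep.remove(seen[key])
                keep.append(n)
                seen[key] = n
        else:
            seen[key] = n
            keep.append(n)
    keep = sorted(keep)
    detected = detected[keep]
    ideal = idx[keep].astype(float) * spacing_um
    corr = [(n, n) for n in range(len(keep))]
    return GridDetection(
        detected_points=detected,
        ideal_points=ideal,
        correspondence=corr,
        spacing_um=spacing_um,
    )


# ---------------------------------------------------------------------------
# distortion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionFit:
    """Radial-distortion profile and fitted single-term coefficient."""

    r_ideal_um: np.ndarray
    delta_r_um: np.ndarray
    k_hat: float
    scale: float
    n_points: int

    def summary(self) -> str:
        return (
            "Radial distortion, r_obs = r (1 + k r^2)\n"
            "----------------------------------------\n"
            f"k_hat = {self.k_hat:.4g} um^-2   (similarity scale {self.scale:.5f}, "
            f"n = {self.n_points})\n"
            f"max |delta_r| = {np.max(np.abs(self.delta_r_um)):.3f} um"
        )


class RadialDistortionModel:
    """Single-coefficient radial distortion fitted against an ideal lattice."""

    def __init__(self, detection: GridDetection):
        if len(detection.detected_points) < 6:
            raise ValueError("need >= 6 matched points to measure distortion")
        self.det = np.asarray(detection.detected_points, dtype=float)
        self.ideal = np.asarray(detection.ideal_points, dtype=float)
        centered = self.ideal - self.ideal.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-6 * np.abs(centered).max():
            raise ValueError("degenerate (collinear) points")

    def fit(self) -> DistortionFit:
        tform = estimate_transform("similarity", self.ideal, self.det)
        ideal_aligned = tform(self.ideal)
        center = self.det.mean(axis=0)
        r_id = np.hypot(*(ideal_aligned - center).T)
        r_dt = np.hypot(*(self.det - center).T)
        # r_det = alpha r + beta r^3.  With r = s * r_true (the similarity
        # scale s absorbs part of the distortion), alpha = 1/s and
        # beta = k/s^3, so k on the true undistorted radius scale is
        # beta/alpha^3; a pure scale perturbation still yields beta = 0.
        X = np.column_stack([r_id, r_id**3])
        coef, _, _, _ = np.linalg.lstsq(X, r_dt, rcond=None)
        alpha, beta = coef
        k_hat = float(beta / alpha**3) if alpha != 0 else 0.0
        return DistortionFit(
            r_ideal_um=r_id,
            delta_r_um=r_dt - r_id,
            k_hat=k_hat,
            scale=float(np.hypot(tform.params[0, 0], tform.params[1, 0])),
            n_points=len(r_id),
        )


def measure_distortion(detection: GridDetection) -> DistortionFit:
    """Functional wrapper around :class:`RadialDistortionModel`."""
    return RadialDistortionModel(detection).fit()


def refine_intersections_at_focus(
    depth_stack: list[tuple[float, np.ndarray]],
    detection: GridDetection,
    focus_points: "list[FocusPoint]",
    optics: OpticsParams,
    *,
    line_halfwidth_um: float = 2.0,
    search_px: int = 4,
) -> GridDetection:
    """Re-localize each intersection on the frame where it is sharpest.

    On a field-curved optic a single frame cannot hold the whole grid in
    focus, so positions from one frame are biased off-centre.  For each
    point this repeats the template correlation in a small window of its
    own best-focus frame and updates the sub-pixel position; the lattice
    correspondence is preserved.
    """
    px = optics.object_pixel_um
    spacing_px = detection.spacing_um / px
    tmpl = _cross_template(spacing_px, max(1.0, line_halfwidth_um / px))
    th = tmpl.shape[0] // 2
    H, W = depth_stack[0][1].shape
    depths = np.array([z for z, _ in depth_stack])

    refined = detection.detected_points.copy()
    for n, (pt, fp) in enumerate(zip(detection.detected_points, focus_points)):
        fi = int(np.argmin(np.abs(depths - fp.z_opt)))
        frame = depth_stack[fi][1]
        j = pt[0] / px + (W - 1) / 2.0
        i = pt[1] / px + (H - 1) / 2.0
        i0, j0 = int(round(i)), int(round(j))
        r = th + search_px
        if not (r <= i0 < H - r and r <= j0 < W - r):
            continue
        win = frame[i0 - r : i0 + r + 1, j0 - r : j0 + r + 1]
        resp = match_template(win - win.mean(), tmpl, pad_input=True)
        # restrict to the central search region to stay on this node
        c = resp.shape[0] // 2
        sub = resp[c - search_px : c + search_px + 1, c - search_px : c + search_px + 1]
        pi, pj = np.unravel_index(np.argmax(sub), sub.shape)
        pi += c - search_px
        pj += c - search_px
        oy, ox = _quadratic_peak_offset(resp, (pi, pj))
        refined[n] = (
            ((j0 + (pj - c) + ox) - (W - 1) / 2.0) * px,
            ((i0 + (pi - c) + oy) - (H - 1) / 2.0) * px,
        )
    return GridDetection(
        detected_points=refined,
        ideal_points=detection.ideal_points.copy(),
        correspondence=list(detection.correspondence),
        spacing_um=detection.spacing_um,
    )


# ---------------------------------------------------------------------------
# per-point optimal focus
# ---------------------------------------------------------------------------

@dataclass
class FocusPoint:
    """One intersection's lateral position and depth of best focus (µm)."""

    x: float
    y: float
    z_opt: float
    focus_scores: np.ndarray
    depths: np.ndarray
    reliable: bool = True


def _gradient_energy(window: np.ndarray) -> float:
    gx = np.diff(window, axis=1)
    gy = np.diff(window, axis=0)
    return float((gx**2).sum() + (gy**2).sum())


def optimal_focus_per_point(
    depth_stack: list[tuple[float, np.ndarray]],
    points_um: np.ndarray,
    optics: OpticsParams,
    window_um: float = 25.0,
) -> list[FocusPoint]:
    """Depth of best focus per lateral point from a focal scan.

    Sharpness is local gradient energy in a window of side ≈ the grid
    spacing; the optimum depth is refined by parabolic interpolation
    around the argmax.  Points whose score curve peaks at a scan
    boundary are flagged unreliable (their true optimum may lie outside
    the scanned range) and should be excluded from the sphere fit.
    """
    if len(depth_stack) < 3:
        raise ValueError("need >= 3 depths")
    depths = np.array([z for z, _ in depth_stack])
    frames = [f for _, f in depth_stack]
    H, W = frames[0].shape
    px = optics.object_pixel_um
    half = max(2, int(round(window_um / px / 2)))

    out = []
    for x, y in np.asarray(points_um, dtype=float):
        col = x / px + (W - 1) / 2.0
        row = y / px + (H - 1) / 2.0
        i, j = int(round(row)), int(round(col))
        if not (half <= i < H - half and half <= j < W - half):
            continue
        scores = np.array(
            [_gradient_energy(f[i - half : i + half + 1, j - half : j + half + 1]) for f in frames]
        )
        a = int(np.argmax(scores))
        if a == 0 or a == len(scores) - 1:
            out.append(FocusPoint(x, y, float(depths[a]), scores, depths, reliable=False))
            continue
        ym, y0, yp = scores[a - 1], scores[a], scores[a + 1]
        denom = 2.0 * (2.0 * y0 - ym - yp)
        off = 0.0 if denom == 0 else (yp - ym) / denom
        step = depths[a + 1] - depths[a]
        out.append(FocusPoint(x, y, float(depths[a] + off * step), scores, depths))
    return out


def reference_focal_depth(points: list[FocusPoint], rel: float = 0.95) -> float:
    """Scan depth where the largest number of intersections are in focus.

    A point counts as in focus at a depth if its score there is at least
    ``rel`` of its own curve maximum.
    """
    if not points:
        raise ValueError("no focus points")
    depths = points[0].depths
    counts = np.zeros(len(depths), dtype=int)
    for p in points:
        counts += p.focus_scores >= rel * p.focus_scores.max()
    return float(depths[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Petzval sphere
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereFit:
    """Sphere centre/radius from the linearized least-squares fit."""

    center: tuple[float, float, float]
    radius: float
    rms_residual: float
    n_points: int

    def summary(self) -> str:
        x0, y0, z0 = self.center
        return (
            "Petzval field-curvature sphere (linear regression)\n"
            "--------------------------------------------------\n"
            f"radius  {self.radius:10.2f} um\n"
            f"center  ({x0:.2f}, {y0:.2f}, {z0:.2f}) um\n"
            f"rms residual {self.rms_residual:.3f} um  (n = {self.n_points})"
        )


class PetzvalSphereModel:
    """Linearized sphere fit to per-intersection best-focus points.

    Substituting the sphere equation gives the linear system
    x² + y² + z² = 2x0·x + 2y0·y + 2z0·z + d, solved by least squares;
    radius = sqrt(d + x0² + y0² + z0²).
    """

    #: condition-number threshold flagging (near-)coplanar input
    COND_LIMIT = 1e8

    def __init__(self, points):
        if isinstance(points, (list, tuple)) and points and isinstance(points[0], FocusPoint):
            pts = np.array([[p.x, p.y, p.z_opt] for p in points if p.reliable])
        else:
            pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError("need >= 4 (x, y, z) points")
        self.pts = pts

    def fit(self) -> SphereFit:
        p = self.pts
        A = np.column_stack([2 * p, np.ones(len(p))])
        sv = np.linalg.svd(A, compute_uv=False)
        if sv[-1] == 0 or sv[0] / sv[-1] > self.COND_LIMIT:
            raise ValueError("degenerate sphere fit: points are (near-)coplanar")
        b = (p**2).sum(axis=1)
        sol, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
        x0, y0, z0, d = sol
        r2 = d + x0**2 + y0**2 + z0**2
        if r2 <= 0:
            raise ValueError("degenerate sphere fit: non-positive squared radius")
        radius = math.sqrt(r2)
        dist = np.linalg.norm(p - np.array([x0, y0, z0]), axis=1)
        rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
        return SphereFit(
            center=(float(x0), float(y0), float(z0)),
            radius=float(radius),
            rms_residual=rms,
            n_points=len(p),
        )


def fit_petzval_sphere(points) -> SphereFit:
    """Functional wrapper around :class:`PetzvalSphereModel`."""
    return PetzvalSphereModel(points).fit()
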