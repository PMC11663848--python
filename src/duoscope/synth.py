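"""Synthetic scenes with known ground truth for every calibration stage.

Each generator emulates one of the bench acquisitions used to
characterise the dual-color miniscope:

* a 45° depth-of-field target carrying 15 lp/mm vertical line pairs
  (66.67 µm object-space period), imaged at a commanded EWL focal depth;
* a 25 µm grid calibration slide imaged through a radially distorting,
  field-curved optic at stepped focal depths;
* two-channel 3-D fluorescent-bead volumes with an injected red−green
  chromatic offset;
* an interleaved two-channel calcium-imaging session with static
  red-labelled somata, dynamic green transients, rigid jitter and noise.

All generators are deterministic given their parameters and a seed, and
return the ground truth needed to score the downstream estimators.

Defocus is modelled as a Gaussian blur whose σ grows linearly with the
axial distance from best focus (``OpticsParams.defocus_blur_gain``,
pixels per µm, clamped below at 0.3 px).  The real EWL+GRIN point-spread
function is not characterised; this is the simplest monotone proxy.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np

from .frames import FrameStack
from .optics import OpticsParams, SceneSpec

#: object-space period of a 15 lp/mm line-pair target, µm
LINE_PAIR_PERIOD_UM = 1000.0 / 15.0

#: measured optical resolution of the miniscope (USAF group 7/6), µm FWHM.
#: The defocus blur never falls below this in-focus floor.
RESOLUTION_FWHM_UM = 4.4

_MIN_BLUR_UM = RESOLUTION_FWHM_UM / 2.355  # Gaussian sigma at best focus


# ---------------------------------------------------------------------------
# 45° depth-of-field target
# ---------------------------------------------------------------------------

def generate_dof_target_trial(
    optics: OpticsParams,
    pwm_percent: float,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    width: int = 768,
    height: int = 128,
    z_at_x0_um: float = -130.0,
    bar_low: float = 0.3,
    bar_high: float = 1.0,
    profile: str = "sine",
) -> FrameStack:
    """Simulate one trial of the 45° depth-of-field target.

    The target surface depth increases at 1 µm per object-space µm along
    x (45° geometry), so the lateral position of the focused band of
    66.67 µm line pairs encodes the commanded focal depth.  Column x = 0
    sits at target depth ``z_at_x0_um``; the focused column in µm is
    ``optics.focal_depth_um(pwm) − z_at_x0_um`` and is recorded in
    ``meta["focus_column_x_um"]`` together with the commanded depth.

    ``profile`` selects the line-pair waveform: ``"sine"`` (default), a
    sinusoidal grating that matches the first-harmonic measurement
    model, or ``"square"``, bright/dark bars like the physical target —
    whose odd harmonics perturb the envelope fit by up to ~2 µm at this
    blur gain.
    """
    if not 0.0 <= pwm_percent <= 100.0:
        raise ValueError(f"pwm_percent must lie in [0, 100], got {pwm_percent}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    rng = np.random.default_rng(seed)
    px = optics.object_pixel_um
    x_um = np.arange(width) * px
    focal = optics.focal_depth_um(pwm_percent)
    focus_x = focal - z_at_x0_um

    mid = (bar_high + bar_low) / 2.0
    amp = (bar_high - bar_low) / 2.0
    if profile == "sine":
        pattern = mid + amp * np.cos(2 * np.pi * x_um / LINE_PAIR_PERIOD_UM)
    elif profile == "square":
        phase = np.mod(x_um, LINE_PAIR_PERIOD_UM)
        pattern = np.where(phase < LINE_PAIR_PERIOD_UM / 2.0, bar_high, bar_low)
    else:
        raise ValueError("profile must be 'sine' or 'square'")

    # per-column Gaussian blur, radius grows with defocus of that column
    sigma_px = np.maximum(
        _MIN_BLUR_UM / px, optics.defocus_blur_gain * np.abs(x_um - focus_x)
    )
    cols = np.arange(width, dtype=float)
    d2 = (cols[:, None] - cols[None, :]) ** 2  # (target col, source col)
    w = np.exp(-d2 / (2.0 * sigma_px[:, None] ** 2))
    w /= w.sum(axis=1, keepdims=True)
    profile = w @ pattern

    base = np.broadcast_to(profile, (height, width))
    stack = np.empty((n_frames, height, width), dtype=np.float32)
    for t in range(n_frames):
        frame = base
        if noise_sd > 0:
            frame = base + rng.normal(0.0, noise_sd, size=base.shape)
        stack[t] = frame

    return FrameStack(
        data=stack,
        fps=10.0,
        channel="green",
        meta={
            "pwm_percent": float(pwm_percent),
            "true_focus_um": float(focal),
            "focus_column_x_um": float(focus_x),
            "z_at_x0_um": float(z_at_x0_um),
            "object_pixel_um": px,
            "line_period_um": LINE_PAIR_PERIOD_UM,
        },
    )


def generate_dof_sweep(
    optics: OpticsParams,
    n_trials: int = 24,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs: Any,
) -> list[FrameStack]:
    """A full PWM sweep, 0→100 % duty in ``n_trials`` equispaced trials."""
    pwms = np.linspace(0.0, 100.0, n_trials)
    return [
        generate_dof_target_trial(
            optics, p, n_frames, noise_sd, seed=seed + i, **kwargs
        )
        for i, p in enumerate(pwms)
    ]


def generate_dual_dof_trial(
    optics: OpticsParams,
    pwm_green: float,
    pwm_red: float,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs: Any,
) -> FrameStack:
    """Alternating-channel acquisition of the 45° target.

    Even sensor frames image the target with the green channel's EWL
    setting, odd frames with the red channel's — the interleaved mode
    in which the lens steps between two focal depths on every frame.
    ``n_frames`` counts sensor frames (must be even; each channel gets
    half).  Ground truth for both channels is kept in ``meta``.
    """
    if n_frames % 2 != 0:
        raise ValueError("n_frames must be even for interleaved acquisition")
    g = generate_dof_target_trial(
        optics, pwm_green, n_frames // 2, noise_sd, seed=seed, **kwargs
    )
    r = generate_dof_target_trial(
        optics, pwm_red, n_frames // 2, noise_sd, seed=seed + 1, **kwargs
    )
    data = np.empty((n_frames, *g.frame_shape), dtype=g.data.dtype)
    data[0::2] = g.data
    data[1::2] = r.data
    return FrameStack(
        data=data,
        fps=10.0,
        channel="interleaved",
        meta={
            "phase": "green_first",
            "pwm_percent_green": float(pwm_green),
            "pwm_percent_red": float(pwm_red),
            "true_focus_green_um": g.meta["true_focus_um"],
            "true_focus_red_um": r.meta["true_focus_um"],
            "z_at_x0_um": g.meta["z_at_x0_um"],
            "object_pixel_um": g.meta["object_pixel_um"],
        },
    )


# ---------------------------------------------------------------------------
# grid calibration slide
# ---------------------------------------------------------------------------

def petzval_surface_z(
    optics: OpticsParams, x_um: np.ndarray, y_um: np.ndarray
) -> np.ndarray:
    """Depth of best focus at lateral position (x, y), near cap of the sphere.

    Computed as (z0 − R) + sag with sag = ρ²/(R + sqrt(R² − ρ²)), which is
    numerically stable for the quasi-flat field (R → ∞) as well.
    """
    x0, y0, z0 = optics.petzval_center_um
    R = optics.petzval_radius_um
    rho2 = (np.asarray(x_um) - x0) ** 2 + (np.asarray(y_um) - y0) ** 2
    rho2 = np.minimum(rho2, R**2)
    sag = rho2 / (R + np.sqrt(R**2 - rho2))
    return (z0 - R) + sag


def _invert_radial(x_obs: np.ndarray, y_obs: np.ndarray, k: float, n_iter: int = 25):
    """Solve r_obs = r(1 + k r²) for the undistorted coordinates."""
    if k == 0.0:
        return x_obs, y_obs
    r_obs = np.hypot(x_obs, y_obs)
    r = r_obs.copy()
    for _ in range(n_iter):
        r = r_obs / (1.0 + k * r**2)
    scale = np.where(r_obs > 0, r / np.maximum(r_obs, 1e-12), 1.0)
    return x_obs * scale, y_obs * scale


def _distort_radial(x: np.ndarray, y: np.ndarray, k: float):
    r2 = x**2 + y**2
    f = 1.0 + k * r2
    return x * f, y * f


def generate_grid_stack(
    optics: OpticsParams,
    spacing_um: float = 25.0,
    depth_step_um: float = 9.6,
    n_depths: int = 36,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    z_start_um: float = 0.0,
    line_halfwidth_um: float = 2.0,
    noise_sd: float = 0.0,
) -> tuple[list[tuple[float, np.ndarray]], dict[str, Any]]:
    """Simulate a focal scan of a square grid target.

    Returns ``(stack, truth)`` where ``stack`` is a list of
    ``(depth_um, frame)`` pairs and ``truth`` carries the ideal lattice
    positions, the distorted (observed) positions, and each
    intersection's depth of best focus on the Petzval surface.
    Coordinates are object-space µm with origin at the frame centre.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    if n_depths < 3:
        raise ValueError("n_depths must be >= 3")

    rng = np.random.default_rng(seed)
    H, W = shape
    px = optics.object_pixel_um
    k = optics.radial_distortion_k

    yy, xx = np.mgrid[0:H, 0:W]
    x_obs = (xx - (W - 1) / 2.0) * px
    y_obs = (yy - (H - 1) / 2.0) * px
    # forward model: observed = distort(ideal); render via inverse mapping
    x_id, y_id = _invert_radial(x_obs, y_obs, k)

    sigma_floor_um = _MIN_BLUR_UM
    z_focus = petzval_surface_z(optics, x_obs, y_obs)

    dx = x_id - spacing_um * np.round(x_id / spacing_um)
    dy = y_id - spacing_um * np.round(y_id / spacing_um)

    stack = []
    depths = z_start_um + depth_step_um * np.arange(n_depths)
    w0 = line_halfwidth_um
    for z in depths:
        sig = np.maximum(
            sigma_floor_um, optics.defocus_blur_gain * px * np.abs(z - z_focus)
        )
        weff2 = w0**2 + sig**2
        amp = w0 / np.sqrt(weff2)
        gx = amp * np.exp(-(dx**2) / (2.0 * weff2))
        gy = amp * np.exp(-(dy**2) / (2.0 * weff2))
        frame = 1.0 - (gx + gy - gx * gy)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        stack.append((float(z), frame.astype(np.float32)))

    # ground-truth intersections: lattice points inside the field with margin
    half_x = (W - 1) / 2.0 * px
    half_y = (H - 1) / 2.0 * px
    m = spacing_um * 0.75
    nx = int((half_x - m) // spacing_um)
    ny = int((half_y - m) // spacing_um)
    gi, gj = np.meshgrid(
        np.arange(-nx, nx + 1), np.arange(-ny, ny + 1), indexing="ij"
    )
    ideal = np.column_stack([gi.ravel() * spacing_um, gj.ravel() * spacing_um])
    obs_x, obs_y = _distort_radial(ideal[:, 0], ideal[:, 1], k)
    observed = np.column_stack([obs_x, obs_y])
    z_opt = petzval_surface_z(optics, observed[:, 0], observed[:, 1])

    truth = {
        "ideal_points_um": ideal,
        "observed_points_um": observed,
        "z_opt_um": z_opt,
        "spacing_um": spacing_um,
        "object_pixel_um": px,
        "depths_um": depths,
        "radial_distortion_k": k,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# fluorescent-bead volumes
# ---------------------------------------------------------------------------

def default_bead_voxel_size(
    optics: OpticsParams, axial_step_um: float = 6.0
) -> tuple[float, float, float]:
    """(z, y, x) voxel size in µm for the bead-volume generator."""
    px = optics.object_pixel_um
    return (axial_step_um, px, px)


def generate_bead_volumes(
    optics: OpticsParams,
    n_beads: int = 8,
    bead_diameter_um: float = 15.0,
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = (64, 160, 160),
    axial_step_um: float = 6.0,
    noise_sd: float = 0.01,
    z_band_um: float = 20.0,
    max_tries: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel 3-D bead volumes with an injected chromatic offset.

    Beads lie quasi-planar, as on a physical bead slide: lateral (x, y)
    positions are drawn uniformly with pairwise separation of at least
    three bead diameters, and axial positions scatter within a
    ``z_band_um`` band around the feasible mid-depth.  Red centres equal
    green centres plus ``optics.chroma_shift_um``.  Returns
    ``(green, red, positions)`` with ``positions`` the (n, 3) green
    centres in (x, y, z) µm.  Volumes are (z, y, x) arrays; voxel size
    from :func:`default_bead_voxel_size`.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vz, vy, vx = default_bead_voxel_size(optics, axial_step_um)
    ext = np.array([nx * vx, ny * vy, nz * vz])  # (x, y, z) extent µm
    shift = np.asarray(optics.chroma_shift_um, dtype=float)

    margin = max(bead_diameter_um, 10.0)
    lo = np.array([margin, margin, margin])
    hi = ext - margin
    # both green and shifted red centres must stay inside the volume
    lo = np.maximum(lo, lo - shift)
    hi = np.minimum(hi, hi - shift)
    if np.any(hi <= lo):
        raise ValueError("volume too small to place beads with this chroma shift")
    z_mid = 0.5 * (lo[2] + hi[2])
    z_lo = max(lo[2], z_mid - z_band_um / 2.0)
    z_hi = min(hi[2], z_mid + z_band_um / 2.0)

    min_sep = 3.0 * bead_diameter_um
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_beads:
        tries += 1
        if tries > max_tries:
            raise ValueError("volume too small to place beads at the required separation")
        p = np.array(
            [
                lo[0] + rng.random() * (hi[0] - lo[0]),
                lo[1] + rng.random() * (hi[1] - lo[1]),
                z_lo + rng.random() * (z_hi - z_lo),
            ]
        )
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in centers):
            centers.append(p)
    positions = np.array(centers)
    amps = rng.uniform(0.8, 1.2, size=n_beads)

    voxel = np.array([vx, vy, vz])
    sigma_um = bead_diameter_um / 2.355

    def render(pos_um: np.ndarray) -> np.ndarray:
        vol = np.zeros(shape, dtype=np.float32)
        zs = np.arange(nz) * vz
        ys = np.arange(ny) * vy
        xs = np.arange(nx) * vx
        for amp, p in zip(amps, pos_um):
            wz = np.exp(-((zs - p[2]) ** 2) / (2 * sigma_um**2))
            wy = np.exp(-((ys - p[1]) ** 2) / (2 * sigma_um**2))
            wx = np.exp(-((xs - p[0]) ** 2) / (2 * sigma_um**2))
            vol += amp * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
        return vol

    green = render(positions)
    red = render(positions + shift)
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
        red = red + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
    return green, red, positions


# ---------------------------------------------------------------------------
# interleaved two-channel calcium session
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    existing: list[np.ndarray] | None = None,
    max_tries: int = 100000,
) -> list[np.ndarray]:
    pts: list[np.ndarray] = []
    others = list(existing) if existing else []
    H, W = shape
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("field too crowded to place somata at the requested separation")
        p = np.array(
            [margin + rng.random() * (H - 2 * margin), margin + rng.random() * (W - 2 * margin)]
        )
        if all(np.linalg.norm(p - q) >= min_sep for q in pts + others):
            pts.append(p)
    return pts


def _soma_blob(shape, center_yx, radius_px, amp=1.0):
    """Gaussian soma with half-max at radius; returns a full-frame image."""
    sigma = radius_px / math.sqrt(2.0 * math.log(2.0))
    H, W = shape
    cy, cx = center_yx
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    img = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = amp * np.exp(
        -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    )
    return img


def _fourier_shift_frame(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    from scipy.ndimage import fourier_shift

    return np.fft.ifft2(fourier_shift(np.fft.fft2(frame), (dy, dx))).real


def generate_interleaved_session(
    scene: SceneSpec,
    optics: OpticsParams,
    n_frames: int = 400,
    fps: float = 10.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (300, 300),
    background: float = 0.1,
    green_static_level: float = 0.35,
    vessel_contrast: float = 0.5,
) -> tuple[FrameStack, dict[str, Any]]:
    """Simulate an alternating-illumination dual-channel session.

    Even sensor frames (0, 2, …) carry the green channel: static GECI
    baseline fluorescence plus calcium transients with instantaneous
    rise and exponential decay (τ = ``scene.decay_tau_s``).  Odd frames
    carry the static red channel, laterally displaced by the chromatic
    offset in ``optics.chroma_shift_um``.  A per-sensor-frame rigid
    shift (σ = ``scene.jitter_sd_px``) emulates miniscope motion shared
    by both channels.  A static vascular shadow field (dark strands of
    relative depth ``vessel_contrast``) multiplies both channels, as
    blood vessels do in real one-photon data — it is the shared
    anatomical content that anchors cross-channel registration.

    Returns the interleaved :class:`FrameStack` and a ground-truth dict
    with per-neuron footprints, centres, channel membership, co-labelled
    (red, green) index pairs, per-frame shifts and transient times.
    """
    if n_frames % 2 != 0:
        raise ValueError("n_frames must be even for interleaved acquisition")
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    H, W = shape
    r = scene.soma_radius_px
    margin = 3.0 * r + 6.0
    min_sep = 2.8 * r

    green_pts = _place_points(rng, scene.n_neurons_green, shape, min_sep, margin)
    n_co = int(round(scene.overlap_fraction * scene.n_neurons_red))
    n_co = min(n_co, scene.n_neurons_green, scene.n_neurons_red)
    co_green_idx = rng.permutation(scene.n_neurons_green)[:n_co] if n_co else np.array([], int)
    red_pts = [green_pts[i].copy() for i in co_green_idx]
    red_pts += _place_points(
        rng, scene.n_neurons_red - n_co, shape, min_sep, margin, existing=green_pts + red_pts
    )
    colabel_pairs = [(ri, int(gi)) for ri, gi in enumerate(co_green_idx)]

    amps_g = rng.lognormal(0.0, 0.15, size=scene.n_neurons_green)
    amps_r = rng.lognormal(0.0, 0.15, size=scene.n_neurons_red)

    green_fps = [
        _soma_blob(shape, p, r) for p in green_pts
    ]  # unit-amplitude footprints
    px = optics.object_pixel_um
    chroma_dx_px = optics.chroma_shift_um[0] / px
    chroma_dy_px = optics.chroma_shift_um[1] / px
    red_fps = [
        _soma_blob(shape, (p[0] + chroma_dy_px, p[1] + chroma_dx_px), r)
        for p in red_pts
    ]

    static_green = background + green_static_level * sum(
        a * f for a, f in zip(amps_g, green_fps)
    )
    static_red = background + sum(a * f for a, f in zip(amps_r, red_fps))

    # shared vascular shadows: smooth random field, darkest strands dim
    # both channels multiplicatively
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=shape), 6.0)
    depth = np.clip((np.quantile(field, 0.12) - field) / field.std(), 0.0, 1.5)
    shadow = 1.0 - vessel_contrast * np.minimum(depth, 1.0)
    static_red = static_red * shadow

    # transient event times over the whole session (green frames sample them)
    duration_s = n_frames / fps
    events: list[np.ndarray] = []
    for _ in range(scene.n_neurons_green):
        n_ev = rng.poisson(scene.transient_rate_hz * duration_s)
        events.append(np.sort(rng.random(n_ev) * duration_s))

    shifts = rng.normal(0.0, scene.jitter_sd_px, size=(n_frames, 2))  # (dy, dx)
    if scene.jitter_sd_px > 0:
        shifts -= shifts.mean(axis=0)

    stack = np.empty((n_frames, H, W), dtype=np.float32)
    for t in range(n_frames):
        ts = t / fps
        if t % 2 == 0:  # green
            frame = static_green.copy()
            for i, (a, fp, ev) in enumerate(zip(amps_g, green_fps, events)):
                past = ev[ev <= ts]
                if past.size:
                    c = np.exp(-(ts - past) / scene.decay_tau_s).sum()
                    if c > 1e-3:
                        frame = frame + a * c * fp
            frame = frame * shadow
        else:  # red
            frame = static_red
        dy, dx = shifts[t]
        if scene.jitter_sd_px > 0:
            frame = _fourier_shift_frame(frame, dy, dx)
        if scene.noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.noise_sd, size=shape)
        stack[t] = frame

    truth = {
        "green_centers_yx": np.array(green_pts),
        "red_centers_yx": np.array(
            [[p[0] + chroma_dy_px, p[1] + chroma_dx_px] for p in red_pts]
        ),
        "green_footprints": green_fps,
        "red_footprints": red_fps,
        "colabel_pairs": colabel_pairs,
        "shifts_yx": shifts,
        "event_times_s": events,
        "amps_green": amps_g,
        "amps_red": amps_r,
        "chroma_shift_px": (chroma_dy_px, chroma_dx_px),
        "soma_radius_px": r,
    }
    meta = {"phase": "green_first", "seed": seed}
    return FrameStack(data=stack, fps=fps, channel="interleaved", meta=meta), truth


# ---------------------------------------------------------------------------
# longitudinal series of static (red-channel style) sessions
# ---------------------------------------------------------------------------

def generate_longitudinal_sessions(
    n_neurons: int = 60,
    n_sessions: int = 5,
    dropout: float = 0.1,
    drift_px: float = 6.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    soma_radius_px: float = 5.0,
    noise_sd: float = 0.01,
) -> tuple[list[np.ndarray], dict[str, Any]]:
    """Average images of one field of view revisited over sessions.

    Each neuron present in session s survives to s+1 with probability
    1 − ``dropout``; the field drifts rigidly by ``drift_px`` between
    consecutive sessions (alternating direction components so the field
    stays in frame).  Returns per-session average images and the truth
    (per-session alive mask, centres, cumulative shifts).
    """
    rng = np.random.default_rng(seed)
    margin = 3.0 * soma_radius_px + 6.0 + drift_px * n_sessions
    pts = _place_points(rng, n_neurons, shape, 2.8 * soma_radius_px, margin)
    amps = rng.lognormal(0.0, 0.15, size=n_neurons)

    alive = np.ones((n_sessions, n_neurons), dtype=bool)
    for s in range(1, n_sessions):
        survive = rng.random(n_neurons) >= dropout
        alive[s] = alive[s - 1] & survive

    angle0 = rng.random() * 2 * np.pi
    images = []
    cum_shifts = []
    for s in range(n_sessions):
        ang = angle0 + s * 2.4  # varied direction, deterministic
        shift = np.array([np.sin(ang), np.cos(ang)]) * drift_px * s
        cum_shifts.append(shift)
        img = np.full(shape, 0.1, dtype=np.float32)
        for i in range(n_neurons):
            if alive[s, i]:
                cy, cx = pts[i] + shift
                img += amps[i] * _soma_blob(shape, (cy, cx), soma_radius_px)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
        images.append(img)

    truth = {
        "alive": alive,
        "centers_yx": np.array(pts),
        "cum_shifts_yx": np.array(cum_shifts),
        "amps": amps,
    }
    return images, truth
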