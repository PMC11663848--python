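"""Grid geometry: intersection detection, distortion, Petzval sphere."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from duoscope import geom, synth
from duoscope.optics import OpticsParams
from duoscope.pipeline import calibrate_grid
from duoscope.validation import sphere_fit_nonlinear


@pytest.fixture(scope="module")
def clean_grid(flat_optics):
    stack, truth = synth.generate_grid_stack(
        flat_optics, n_depths=3, depth_step_um=9.6, seed=0, z_start_um=-9.6
    )
    return stack, truth


def test_detection_matches_truth_quarter_pixel(flat_optics, clean_grid):
    stack, truth = clean_grid
    det = geom.detect_grid_intersections(stack[1][1], 25.0, flat_optics)
    d, _ = cKDTree(truth["observed_points_um"]).query(det.detected_points)
    assert len(det.detected_points) == len(truth["observed_points_um"])
    assert d.max() <= 0.25 * flat_optics.object_pixel_um


def test_detection_blank_frame_errors(flat_optics):
    with pytest.raises(ValueError):
        geom.detect_grid_intersections(np.ones((128, 128)), 25.0, flat_optics)


def test_detection_absorbs_small_rotation(flat_optics, clean_grid):
    from scipy.ndimage import rotate

    stack, _ = clean_grid
    rot = rotate(stack[1][1], 2.0, reshape=False, mode="nearest", order=1)
    det = geom.detect_grid_intersections(rot, 25.0, flat_optics)
    fit = geom.measure_distortion(det)
    assert np.abs(fit.delta_r_um).max() < 0.5  # residuals unchanged by rotation


def test_distortion_identity_and_pure_scale():
    g = np.arange(-5, 6) * 25.0
    gx, gy = np.meshgrid(g, g)
    ideal = np.column_stack([gx.ravel(), gy.ravel()])
    det = geom.GridDetection(ideal.copy(), ideal.copy(), [(i, i) for i in range(len(ideal))])
    fit = geom.measure_distortion(det)
    assert np.allclose(fit.delta_r_um, 0.0, atol=1e-9)
    assert abs(fit.k_hat) < 1e-12
    scaled = geom.GridDetection(ideal * 1.07, ideal.copy(), [(i, i) for i in range(len(ideal))])
    assert abs(geom.measure_distortion(scaled).k_hat) < 1e-12


def test_distortion_recovers_injected_k(optics):
    assert optics.radial_distortion_k == pytest.approx(1e-6)
    stack, _ = synth.generate_grid_stack(optics, n_depths=36, depth_step_um=9.6, seed=3)
    res = calibrate_grid(stack, optics)
    assert res["distortion"].k_hat == pytest.approx(1e-6, rel=0.10)


def test_distortion_collinear_points_error():
    pts = np.column_stack([np.arange(8.0), np.zeros(8)])
    det = geom.GridDetection(pts, pts.copy(), [(i, i) for i in range(8)])
    with pytest.raises(ValueError):
        geom.measure_distortion(det)


def test_focus_flat_field_all_equal(flat_optics):
    stack, truth = synth.generate_grid_stack(
        flat_optics, n_depths=7, depth_step_um=9.6, seed=1, z_start_um=-28.8
    )
    pts = geom.optimal_focus_per_point(stack, truth["observed_points_um"], flat_optics)
    zs = np.array([p.z_opt for p in pts if p.reliable])
    assert len(zs) > 0
    assert np.abs(zs - 0.0).max() <= 4.8  # half a depth step


def test_focus_curved_field_within_one_step(optics):
    stack, truth = synth.generate_grid_stack(optics, n_depths=36, depth_step_um=9.6, seed=2)
    pts = geom.optimal_focus_per_point(stack, truth["observed_points_um"], optics)
    kd = cKDTree(truth["observed_points_um"])
    errs = []
    for p in pts:
        if not p.reliable:
            continue
        _, i = kd.query([p.x, p.y])
        errs.append(abs(p.z_opt - truth["z_opt_um"][i]))
    assert np.max(errs) <= 9.6


def test_focus_boundary_argmax_flagged(optics):
    # scan that stops short of the apex depth: every optimum is at an edge
    stack, truth = synth.generate_grid_stack(
        optics, n_depths=4, depth_step_um=9.6, seed=2, z_start_um=-60.0
    )
    pts = geom.optimal_focus_per_point(stack, truth["observed_points_um"][:5], optics)
    assert all(not p.reliable for p in pts)


def test_sphere_exact_recovery():
    rng = np.random.default_rng(0)
    center = np.array([10.0, -5.0, 343.1])
    R = 343.1
    th = rng.uniform(0, 0.5, 8)
    ph = rng.uniform(0, 2 * np.pi, 8)
    pts = center + R * np.column_stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), -np.cos(th)]
    )
    fit = geom.fit_petzval_sphere(pts)
    assert fit.radius == pytest.approx(R, rel=1e-9)
    assert np.allclose(fit.center, center, atol=1e-6)


def test_sphere_noisy_recovery_and_nonlinear_oracle(rng):
    center = np.array([10.0, -5.0, 343.1])
    R = 343.1
    g = np.linspace(-170, 170, 16)
    gx, gy = np.meshgrid(g, g)
    x = gx.ravel() + center[0]
    y = gy.ravel() + center[1]
    z = center[2] - np.sqrt(R**2 - (x - center[0]) ** 2 - (y - center[1]) ** 2)
    pts = np.column_stack([x, y, z]) + rng.normal(0, 2.0, (x.size, 3))
    fit = geom.fit_petzval_sphere(pts)
    assert fit.radius == pytest.approx(R, rel=0.05)
    _, r_nl = sphere_fit_nonlinear(pts)
    assert fit.radius == pytest.approx(r_nl, rel=0.01)


def test_sphere_coplanar_errors():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]])
    with pytest.raises(ValueError):
        geom.fit_petzval_sphere(pts)


def test_sphere_translation_equivariance(rng):
    pts = rng.normal(0, 1, (20, 3))
    pts = 100 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
    t = np.array([55.0, -12.0, 300.0])
    f0 = geom.fit_petzval_sphere(pts)
    f1 = geom.fit_petzval_sphere(pts + t)
    assert f1.radius == pytest.approx(f0.radius, abs=1e-8)
    assert np.allclose(np.array(f1.center) - np.array(f0.center), t, atol=1e-8)


def test_end_to_end_radius_within_ten_percent(optics):
    stack, _ = synth.generate_grid_stack(optics, n_depths=36, depth_step_um=9.6, seed=11)
    res = calibrate_grid(stack, optics)
    assert res["sphere"].radius == pytest.approx(optics.petzval_radius_um, rel=0.10)
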