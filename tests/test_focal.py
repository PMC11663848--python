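"""Focal calibration: column profiles, envelope fits, depth model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoscope import focal, synth
from duoscope.frames import FrameStack
from duoscope.validation import column_mean_loop, envelope_grid_search


# ---------------------------------------------------------------------------
# PWM conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected", [(0, 0.0), (1023, 100.0), (512, 512 / 1023 * 100)]
)
def test_pwm_counts_to_percent(counts, expected):
    assert focal.pwm_counts_to_percent(counts) == pytest.approx(expected)


@pytest.mark.parametrize("counts", [-1, 1024, 5000])
def test_pwm_counts_out_of_range(counts):
    with pytest.raises(ValueError):
        focal.pwm_counts_to_percent(counts)


# ---------------------------------------------------------------------------
# column-average profile
# ---------------------------------------------------------------------------

def test_profile_constant_stack():
    stack = FrameStack(np.full((4, 10, 20), 7.0), meta={"object_pixel_um": 2.0})
    x, prof = focal.column_average_profile(stack)
    assert np.allclose(prof, 7.0)
    assert x[1] - x[0] == pytest.approx(2.0)


def test_profile_single_frame_equals_column_means(rng):
    frame = rng.random((12, 30))
    stack = FrameStack(frame[None])
    _, prof = focal.column_average_profile(stack)
    assert np.allclose(prof, frame.mean(axis=0))


def test_profile_matches_loop_oracle(optics):
    trial = synth.generate_dof_target_trial(optics, 40.0, n_frames=5, noise_sd=0.01, seed=0)
    _, prof = focal.column_average_profile(trial, optics)
    assert np.allclose(prof, column_mean_loop(trial.data), atol=1e-10)


def test_profile_empty_stack_errors():
    with pytest.raises(ValueError):
        focal.column_average_profile(FrameStack(np.empty((0, 4, 4))))


# ---------------------------------------------------------------------------
# envelope fit
# ---------------------------------------------------------------------------

def test_pure_envelope_center_recovered():
    x = np.arange(0, 500, 1.0)
    y = np.exp(-(((x - 200.0) / 40.0) ** 2))
    fit = focal.fit_envelope_sinusoid(y, x_um=x)
    assert abs(fit.b - 200.0) <= 0.5


def test_envelope_fit_recovers_center_and_beats_grid_oracle(optics):
    trial = synth.generate_dof_target_trial(optics, 35.0, n_frames=50, noise_sd=0.007, seed=2)
    x, prof = focal.column_average_profile(trial, optics)
    fit = focal.EnvelopeModel(x, prof).fit()
    assert abs(fit.b - trial.meta["focus_column_x_um"]) <= 2.0
    b_o, _, sse_o = envelope_grid_search(x, prof, fit.omega)
    assert abs(fit.b - b_o) <= 0.5
    assert fit.sse <= sse_o * (1 + 1e-6)


def test_envelope_translation_equivariance(optics):
    trial = synth.generate_dof_target_trial(optics, 50.0, n_frames=20, noise_sd=0.005, seed=3)
    x, prof = focal.column_average_profile(trial, optics)
    fit0 = focal.EnvelopeModel(x, prof).fit()
    dx = 37.5
    fit1 = focal.EnvelopeModel(x + dx, prof, omega=fit0.omega).fit()
    assert fit1.b - fit0.b == pytest.approx(dx, abs=0.05)


def test_envelope_sse_not_worse_than_pure_envelope(optics):
    """Nested models: the harmonic-bearing fit is at least as good."""
    trial = synth.generate_dof_target_trial(optics, 60.0, n_frames=20, noise_sd=0.01, seed=4)
    x, prof = focal.column_average_profile(trial, optics)
    fit = focal.EnvelopeModel(x, prof).fit()
    # dense pure-envelope (A1 = B1 = 0) reference fit
    best = np.inf
    span = x[-1] - x[0]
    for b in np.linspace(x[0], x[-1], 200):
        for c in np.exp(np.linspace(np.log(span / 50), np.log(span), 25)):
            env = np.exp(-(((x - b) / c) ** 2))
            X = np.column_stack([np.ones_like(x), env])
            coef, _, _, _ = np.linalg.lstsq(X, prof, rcond=None)
            r = prof - X @ coef
            best = min(best, float(r @ r))
    assert fit.sse <= best * (1 + 1e-9)


def test_envelope_flat_profile_errors():
    with pytest.raises(ValueError):
        focal.fit_envelope_sinusoid(np.full(64, 3.0))


def test_trial_focal_depth_shifts_one_to_one():
    fit = focal.EnvelopeFit(1, 150.0, 40.0, 0, 1, 0, 66.67, 0.5, 0.0, 100)
    assert focal.trial_focal_depth(fit, x_ref=150.0, depth_ref=200.0) == 200.0
    fit10 = focal.EnvelopeFit(1, 160.0, 40.0, 0, 1, 0, 66.67, 0.5, 0.0, 100)
    assert focal.trial_focal_depth(fit10, x_ref=150.0, depth_ref=200.0) == 210.0


# ---------------------------------------------------------------------------
# depth model
# ---------------------------------------------------------------------------

def test_depth_model_exact_line():
    pwm = np.arange(0, 101, 10.0)
    fit = focal.fit_depth_model(np.column_stack([pwm, 2 * pwm + 5]))
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(5.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert "y = 2.00x + 5.00" in fit.summary()


def test_depth_model_constant_depths_r2_zero():
    pts = [(0.0, 5.0), (50.0, 5.0), (100.0, 5.0)]
    with pytest.warns(UserWarning):
        fit = focal.fit_depth_model(pts)
    assert fit.slope == pytest.approx(0.0)
    assert fit.r_squared == 0.0


def test_depth_model_identical_pwm_errors():
    with pytest.raises(ValueError):
        focal.fit_depth_model([(10.0, 1.0), (10.0, 2.0)])


@settings(deadline=None, max_examples=25)
@given(
    slope=st.floats(-10, 10, allow_nan=False),
    intercept=st.floats(-100, 100, allow_nan=False),
)
def test_depth_model_recovers_any_exact_line(slope, intercept):
    pwm = np.linspace(0, 100, 12)
    fit = focal.fit_depth_model(np.column_stack([pwm, slope * pwm + intercept]))
    assert fit.slope == pytest.approx(slope, abs=1e-8)
    assert fit.intercept == pytest.approx(intercept, abs=1e-6)
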