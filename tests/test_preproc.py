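"""De-interleaving, median filtering, rigid registration."""

import numpy as np
import pytest
from scipy import ndimage

from duoscope import preproc, synth
from duoscope.frames import FrameStack
from duoscope.optics import SceneSpec
from duoscope.validation import integer_shift_bruteforce, median3x3_bruteforce


# ---------------------------------------------------------------------------
# de-interleaving
# ---------------------------------------------------------------------------

def test_deinterleave_splits_and_halves_fps(rng):
    stack = FrameStack(rng.random((10, 8, 8)), fps=10.0)
    g, r = preproc.deinterleave(stack, "green_first")
    assert len(g) == len(r) == 5
    assert g.fps == r.fps == 5.0
    assert g.channel == "green" and r.channel == "red"
    assert np.array_equal(g.data, stack.data[0::2])


def test_deinterleave_roundtrip(rng):
    stack = FrameStack(rng.random((12, 6, 6)), fps=10.0)
    for phase in ("green_first", "red_first"):
        g, r = preproc.deinterleave(stack, phase)
        back = preproc.reinterleave(g, r, phase)
        assert np.array_equal(back.data, stack.data)
        assert back.fps == 10.0


def test_deinterleave_phase_swaps_channels(rng):
    stack = FrameStack(rng.random((6, 4, 4)))
    g1, r1 = preproc.deinterleave(stack, "green_first")
    g2, r2 = preproc.deinterleave(stack, "red_first")
    assert np.array_equal(g1.data, r2.data)
    assert np.array_equal(r1.data, g2.data)


# ---------------------------------------------------------------------------
# median filter
# ---------------------------------------------------------------------------

def test_median_constant_unchanged():
    f = np.full((5, 7), 3.3)
    assert np.array_equal(preproc.median3x3(f), f)


def test_median_removes_impulse():
    f = np.zeros((9, 9))
    f[4, 4] = 100.0
    assert preproc.median3x3(f).max() == 0.0


@pytest.mark.parametrize("n", [8, 64])
def test_median_equals_bruteforce(rng, n):
    f = rng.random((n, n))
    assert np.array_equal(preproc.median3x3(f), median3x3_bruteforce(f))


def test_median_idempotent_on_constant_patches():
    f = np.zeros((12, 12))
    f[3:9, 3:9] = 1.0
    once = preproc.median3x3(f)
    assert np.array_equal(preproc.median3x3(once), once)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

@pytest.fixture()
def textured(rng):
    return ndimage.gaussian_filter(rng.random((64, 64)), 2.0)


def test_register_identity(textured):
    s = preproc.register_translation(textured, textured)
    assert (s.dx, s.dy) == (0.0, 0.0)
    assert s.peak_corr == pytest.approx(1.0)


def test_register_integer_circular_shift_exact(textured):
    frame = np.roll(textured, (-2, 3), axis=(0, 1))  # displaced by dx=3, dy=-2
    s = preproc.register_translation(frame, textured)
    assert (s.dx, s.dy) == (3.0, -2.0)


def test_register_subpixel_within_tenth(textured):
    frame = preproc.apply_shift(textured, preproc.RigidShift(dx=1.5, dy=-0.7))
    s = preproc.register_translation(frame, textured, upsample=10)
    assert s.dx == pytest.approx(1.5, abs=0.1)
    assert s.dy == pytest.approx(-0.7, abs=0.1)


def test_register_antisymmetry(textured):
    frame = preproc.apply_shift(textured, preproc.RigidShift(dx=2.3, dy=-1.1))
    ab = preproc.register_translation(frame, textured, upsample=10)
    ba = preproc.register_translation(textured, frame, upsample=10)
    assert abs(ab.dx + ba.dx) <= 0.1
    assert abs(ab.dy + ba.dy) <= 0.1


def test_register_matches_spatial_oracle(rng):
    ref = ndimage.gaussian_filter(rng.random((32, 32)), 1.5)
    frame = np.roll(ref, (5, -4), axis=(0, 1))
    s = preproc.register_translation(frame, ref)
    dx, dy = integer_shift_bruteforce(frame, ref, max_shift=8)
    assert (s.dx, s.dy) == (dx, dy)


def test_register_zero_variance_errors(textured):
    with pytest.raises(ValueError):
        preproc.register_translation(np.zeros_like(textured), textured)


def test_register_bounded_restricts_search(textured):
    frame = np.roll(textured, (20, 0), axis=(0, 1))
    s = preproc.register_translation(frame, textured, max_shift_px=5)
    assert abs(s.dy) <= 5.5 and abs(s.dx) <= 5.5


# ---------------------------------------------------------------------------
# motion correction
# ---------------------------------------------------------------------------

def test_motion_correct_jitter_free_noop(textured):
    stack = FrameStack(np.stack([textured] * 5), fps=5.0)
    corrected, shifts = preproc.motion_correct_trial(stack)
    assert all(abs(s.dx) < 0.05 and abs(s.dy) < 0.05 for s in shifts)
    assert np.allclose(corrected.data, stack.data, atol=1e-6)


@pytest.fixture(scope="module")
def jittered_session(flat_optics):
    scene = SceneSpec(
        n_neurons_green=30, n_neurons_red=12, jitter_sd_px=2.0, noise_sd=0.02
    )
    return synth.generate_interleaved_session(
        scene, flat_optics, n_frames=60, seed=5, shape=(200, 200)
    )


def test_motion_correct_recovers_known_jitter(jittered_session):
    stack, truth = jittered_session
    g, _ = preproc.deinterleave(stack)
    corrected, shifts = preproc.motion_correct_trial(g)
    true = truth["shifts_yx"][0::2]
    est = np.array([[s.dy, s.dx] for s in shifts])
    resid = (est - est.mean(0)) - (true - true.mean(0))
    assert np.sqrt((resid**2).mean()) <= 0.2


def test_motion_correct_sharpens_average(jittered_session):
    stack, _ = jittered_session
    g, _ = preproc.deinterleave(stack)
    corrected, _ = preproc.motion_correct_trial(g)

    def grad_energy(im):
        return float(np.sum(np.diff(im, axis=0) ** 2) + np.sum(np.diff(im, axis=1) ** 2))

    assert grad_energy(corrected.time_average()) > grad_energy(g.time_average())


def test_channels_coregistered_after_correction_and_registration(jittered_session):
    """Shared rigid motion: after per-channel correction and one
    cross-channel average-image registration, the two channels sit in a
    common frame (residual below 0.3 px)."""
    stack, _ = jittered_session
    g, r = preproc.deinterleave(stack)
    gc, _ = preproc.motion_correct_trial(g)
    rc, _ = preproc.motion_correct_trial(r)
    s = preproc.register_translation(
        rc.time_average(), gc.time_average(), upsample=20
    )
    # channel-mean anchoring alone leaves the sampling error of the two
    # channels' mean jitter; the average-image registration removes it
    aligned = np.stack(
        [preproc.apply_shift(f, preproc.RigidShift(dx=-s.dx, dy=-s.dy)) for f in rc.data]
    )
    resid = preproc.register_translation(
        aligned.mean(axis=0), gc.time_average(), upsample=20
    )
    assert np.hypot(resid.dx, resid.dy) <= 0.3
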