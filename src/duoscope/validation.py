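"""Independent reference implementations used to validate the estimators.

Everything here is deliberately brute-force and shares no code with the
production path: dense grid search for the envelope fit, spatial-domain
cross-correlation for registration, per-pixel sorting for the median
filter, direct nonlinear minimization for the sphere, and optimal
assignment for footprint matching.  These routines back the test suite
and the acceptance checks; they are not meant for production use.
"""

from __future__ import annotations

import numpy as np


def column_mean_loop(stack_data: np.ndarray) -> np.ndarray:
    """Column means of the time-average frame, by explicit loops."""
    T, H, W = stack_data.shape
    avg = np.zeros((H, W))
    for t in range(T):
        avg += stack_data[t]
    avg /= T
    out = np.zeros(W)
    for j in range(W):
        s = 0.0
        for i in range(H):
            s += avg[i, j]
        out[j] = s / H
    return out


def envelope_grid_search(
    x: np.ndarray,
    y: np.ndarray,
    omega: float,
    b_step_coarse: float = 1.0,
    b_step_fine: float = 0.02,
    n_c: int = 25,
) -> tuple[float, float, float]:
    """Dense (b, c) grid search with exact linear subproblem.

    For every candidate envelope (b, c) the baseline and harmonic
    coefficients are solved in closed form via batched normal equations;
    a fine pass refines b around the coarse optimum.  Returns
    ``(b, c, sse)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arg = 2 * np.pi * x / omega
    cosw, sinw = np.cos(arg), np.sin(arg)
    span = x[-1] - x[0]
    dx = span / (x.size - 1)
    c_grid = np.exp(np.linspace(np.log(2 * dx), np.log(span), n_c))

    def scan(b_grid: np.ndarray) -> tuple[float, float, float]:
        best = (np.inf, 0.0, 0.0)
        yy = float(y @ y)
        for c in c_grid:
            E = np.exp(-(((x[None, :] - b_grid[:, None]) / c) ** 2))  # (nb, n)
            ones = np.ones_like(x)
            basis = np.stack(
                [np.broadcast_to(ones, E.shape), E, E * cosw, E * sinw], axis=1
            )  # (nb, 4, n)
            M = np.einsum("bin,bjn->bij", basis, basis)
            rhs = np.einsum("bin,n->bi", basis, y)
            M += 1e-12 * np.eye(4)
            sol = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
            sse = yy - np.einsum("bi,bi->b", rhs, sol)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (float(sse[i]), float(b_grid[i]), float(c))
        return best

    b_coarse = np.arange(x[0], x[-1] + b_step_coarse, b_step_coarse)
    sse0, b0, c0 = scan(b_coarse)
    b_fine = np.arange(b0 - 2 * b_step_coarse, b0 + 2 * b_step_coarse, b_step_fine)
    b_fine = b_fine[(b_fine >= x[0]) & (b_fine <= x[-1])]
    sse1, b1, c1 = scan(b_fine)
    if sse1 < sse0:
        return b1, c1, sse1
    return b0, c0, sse0


def median3x3_bruteforce(frame: np.ndarray) -> np.ndarray:
    """3×3 median with reflect padding by per-pixel sort-and-middle.

    Reflection duplicates the border sample (half-sample symmetry),
    i.e. the padded row reads (a | a b c ...).
    """
    frame = np.asarray(frame)
    pad = np.pad(frame, 1, mode="symmetric")
    out = np.empty_like(frame)
    H, W = frame.shape
    for i in range(H):
        for j in range(W):
            vals = sorted(pad[i : i + 3, j : j + 3].ravel().tolist())
            out[i, j] = vals[4]
    return out


def integer_shift_bruteforce(
    frame: np.ndarray, reference: np.ndarray, max_shift: int | None = None
) -> tuple[int, int]:
    """(dx, dy) maximizing the circular spatial cross-correlation.

    Evaluated exhaustively by rolling the frame; same sign convention as
    ``register_translation`` (frame displaced by (+dx, +dy) vs
    reference).
    """
    H, W = frame.shape
    if max_shift is None:
        max_shift = min(H, W) // 2 - 1
    best = (-np.inf, 0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            rolled = np.roll(frame, (-dy, -dx), axis=(0, 1))
            score = float((rolled * reference).sum())
            if score > best[0]:
                best = (score, dx, dy)
    return best[1], best[2]


def sphere_fit_nonlinear(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Direct minimization of Σ(‖p − c‖ − r)² by Levenberg–Marquardt."""
    from scipy.optimize import least_squares

    p = np.asarray(points, dtype=float)
    c0 = p.mean(axis=0)
    r0 = np.linalg.norm(p - c0, axis=1).mean()
    # crude center init along +z to avoid the local flat-sphere solution
    x0 = np.array([c0[0], c0[1], c0[2] + 2 * r0, 2 * r0])

    def resid(q):
        c, r = q[:3], q[3]
        return np.linalg.norm(p - c, axis=1) - r

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    return sol.x[:3], float(sol.x[3])


def optimal_assignment_pairs(
    overlap: np.ndarray, threshold: float
) -> list[tuple[int, int]]:
    """Globally optimal one-to-one matching maximizing total overlap.

    Uses the Hungarian algorithm on the thresholded overlap matrix;
    pairs below threshold are disallowed.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.where(overlap >= threshold, -overlap, 1.0)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if overlap[i, j] >= threshold]
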