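"""Readers/writers, manifests and run configuration.

Interchange formats: multi-page TIFF for video stacks and volumes
(8/16-bit integer or 32-bit float grayscale), CSV for manifests and
tables, JSON for fitted results, YAML for run configuration.

Coordinate convention, used in every output: 0-based pixel indices,
x = column, y = row, origin top-left; z increases away from the
objective.  No operation mutates its inputs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import FrameStack


class StackFormatError(ValueError):
    """A video stack on disk is malformed (truncated, mixed bit depth...)."""


def write_stack(stack: FrameStack | np.ndarray, path: str | Path) -> None:
    """Write frames as a multi-page grayscale TIFF, dtype preserved.

    Accepted dtypes: uint8, uint16, float32.  Other dtypes raise — cast
    explicitly so the on-disk representation is a deliberate choice.
    """
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("expected (T, H, W) data")
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        raise ValueError(f"unsupported dtype {data.dtype}: cast to uint8/uint16/float32 first")
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack(
    path: str | Path,
    fps: float = 10.0,
    channel: str = "interleaved",
    meta: dict[str, Any] | None = None,
) -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    Frames come back in acquisition (page) order; a truncated or
    mixed-bit-depth file raises :class:`StackFormatError` naming the
    last good page.
    """
    import json as _json

    frames: list[np.ndarray] = []
    dtype = None
    expected = None
    try:
        with tifffile.TiffFile(str(path)) as tf:
            try:  # shaped-series descriptor written by tifffile
                desc = tf.pages[0].description
                if desc and desc.strip().startswith("{"):
                    shape = _json.loads(desc).get("shape")
                    if shape and len(shape) == 3:
                        expected = int(shape[0])
            except Exception:
                expected = None
            for i, page in enumerate(tf.pages):
                try:
                    arr = page.asarray()
                except Exception as exc:
                    raise StackFormatError(
                        f"{path}: truncated or unreadable at page {i} "
                        f"(last good page {i - 1})"
                    ) from exc
                if dtype is None:
                    dtype = arr.dtype
                elif arr.dtype != dtype:
                    raise StackFormatError(
                        f"{path}: mixed bit depth at page {i} ({arr.dtype} vs {dtype})"
                    )
                frames.append(arr)
    except StackFormatError:
        raise
    except Exception as exc:
        raise StackFormatError(f"{path}: cannot read TIFF ({exc})") from exc
    if not frames:
        raise StackFormatError(f"{path}: no pages")
    if expected is not None and len(frames) < expected:
        raise StackFormatError(
            f"{path}: truncated — {expected} pages declared, last good page "
            f"{len(frames) - 1}"
        )
    return FrameStack(
        data=np.stack(frames), fps=fps, channel=channel, meta=dict(meta or {})
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["trial_id", "path", "channel", "fps"]
_CHANNELS = {"green", "red", "interleaved"}


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a trial manifest CSV.

    Required columns: trial_id, path, channel, fps and one of
    pwm_counts / pwm_percent (may be empty for session rows); optional:
    session_id, depth_label.  Relative paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = set(df["channel"]) - _CHANNELS
    if bad:
        raise ValueError(f"invalid channel values: {sorted(bad)}")
    if "pwm_percent" not in df.columns and "pwm_counts" in df.columns:
        from .focal import pwm_counts_to_percent

        df["pwm_percent"] = [pwm_counts_to_percent(c) for c in df["pwm_counts"]]
    if "pwm_percent" in df.columns:
        vals = df["pwm_percent"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("pwm_percent outside [0, 100]")
    df["path"] = [str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
                  for p in df["path"]]
    if check_paths:
        for p in df["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters with defaults; round-trips through YAML."""

    workflow: str = "session"  # "calibration" or "session"
    seed: int = 0
    out_dir: str = "duoscope_out"
    omega: float = 66.67
    overlap_threshold: float = 0.5
    median_kernel: int = 3
    registration_upsample: int = 10
    phase: str = "green_first"
    fps: float = 10.0
    spacing_um: float = 25.0
    pixel_size_um: float = 4.5
    magnification: float = 3.3
    # input locations (paths are resolved by the caller)
    focus_manifest: str | None = None
    grid_stack: str | None = None
    grid_depths: str | None = None
    bead_green: str | None = None
    bead_red: str | None = None
    bead_voxel_z_um: float = 6.0
    session_stack: str | None = None
    extract_traces: bool = True

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def dump_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, fixed layout)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured workflow and write all stage outputs.

    Deterministic given (config, seed): result files are byte-identical
    across reruns.  Wall-clock stage timings go to ``provenance.json``,
    which is the only output excluded from that contract.
    """
    import time

    from .optics import OpticsParams
    from . import pipeline as pl

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    optics = OpticsParams(
        pixel_size_um=config.pixel_size_um, magnification=config.magnification
    )
    results: dict[str, Any] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0

        return deco

    if config.workflow == "calibration":
        if config.focus_manifest:
            @stage("calibrate-focus")
            def _focus():
                man = read_manifest(config.focus_manifest)
                trials = []
                for _, row in man.iterrows():
                    st = read_stack(row["path"], fps=row["fps"], channel=row["channel"])
                    st.meta["pwm_percent"] = float(row["pwm_percent"])
                    if "z_at_x0_um" in man.columns:
                        st.meta["z_at_x0_um"] = float(row["z_at_x0_um"])
                    trials.append(st)
                res = pl.calibrate_focus_sweep(trials, optics, omega=config.omega)
                m = res["depth_model"]
                dump_json(
                    {
                        "slope_um_per_pct": m.slope,
                        "intercept_um": m.intercept,
                        "r_squared": m.r_squared,
                        "n_points": m.n_points,
                        "trials": res["trials"],
                    },
                    out / "depthmodel.json",
                )
                results["focus"] = res

        if config.grid_stack and config.grid_depths:
            @stage("calibrate-grid")
            def _grid():
                depths = pd.read_csv(config.grid_depths)["depth_um"].to_numpy()
                st = read_stack(config.grid_stack, channel="green")
                depth_stack = [(float(z), f.astype(float)) for z, f in zip(depths, st.data)]
                res = pl.calibrate_grid(depth_stack, optics, spacing_um=config.spacing_um)
                sph, dist = res["sphere"], res["distortion"]
                dump_json(
                    {
                        "center_um": list(sph.center) if sph else None,
                        "radius_um": sph.radius if sph else None,
                        "rms_residual_um": sph.rms_residual if sph else None,
                        "degenerate_reason": res["sphere_degenerate_reason"],
                        "k_hat_per_um2": dist.k_hat,
                        "reference_depth_um": res["reference_depth_um"],
                    },
                    out / "petzval.json",
                )
                pts = pd.DataFrame(
                    [
                        {"x_um": p.x, "y_um": p.y, "z_opt_um": p.z_opt, "reliable": p.reliable}
                        for p in res["focus_points"]
                    ]
                )
                pts.to_csv(out / "focus_points.csv", index=False)
                results["grid"] = res

        if config.bead_green and config.bead_red:
            @stage("calibrate-beads")
            def _beads():
                g = read_stack(config.bead_green, channel="green").data.astype(float)
                r = read_stack(config.bead_red, channel="red").data.astype(float)
                vx = optics.object_pixel_um
                res = pl.calibrate_beads(g, r, (config.bead_voxel_z_um, vx, vx))
                s = res["summary"]
                dump_json(
                    {
                        "mean_offset_um": list(s.mean_offset),
                        "sd_offset_um": list(s.sd_offset),
                        "n_pairs": s.n_pairs,
                    },
                    out / "chroma.json",
                )
                pd.DataFrame(
                    s.per_bead_offsets, columns=["dx_um", "dy_um", "dz_um"]
                ).to_csv(out / "bead_offsets.csv", index=False)
                results["beads"] = res

    elif config.workflow == "session":
        if not config.session_stack:
            raise ValueError("session workflow requires session_stack")

        @stage("session")
        def _session():
            st = read_stack(config.session_stack, fps=config.fps, channel="interleaved")
            res = pl.analyze_interleaved_session(
                FrameStack(st.data.astype(np.float32), st.fps, st.channel, st.meta),
                phase=config.phase,
                overlap_threshold=config.overlap_threshold,
                upsample=config.registration_upsample,
                extract_traces=config.extract_traces,
            )
            res.match_table.to_frame().to_csv(out / "matches.csv", index=False)
            dump_json(
                {
                    "n_green": len(res.green_map),
                    "n_red": len(res.red_map),
                    "n_matched": len(res.match_table.pairs),
                    "matched_pct_red": res.matched_pct_red,
                    "cross_shift_px": [res.cross_shift.dx, res.cross_shift.dy],
                },
                out / "session_summary.json",
            )
            if res.traces:
                rows = []
                for tr in res.traces:
                    for t, v in enumerate(tr.values):
                        rows.append(
                            {
                                "frame": t,
                                "label": tr.label,
                                "raw": float(v),
                                "dff": float(tr.dff[t]) if tr.dff is not None else np.nan,
                            }
                        )
                pd.DataFrame(rows).to_csv(out / "traces.csv", index=False)
            results["session"] = res
    else:
        raise ValueError(f"unknown workflow: {config.workflow}")

    import duoscope

    dump_json(
        {
            "config_hash": config.config_hash(),
            "duoscope_version": duoscope.__version__,
            "numpy_version": np.__version__,
            "stage_timings_s": timings,
        },
        out / "provenance.json",
    )
    results["timings"] = timings
    return results
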