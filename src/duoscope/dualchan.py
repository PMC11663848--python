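"""Two-channel neuron segmentation, traces, and cross-channel matching.

The red channel carries static fluorescence of anatomically labelled
somata: its per-plane average image is high-pass filtered and segmented
into footprints.  The green channel carries dynamic GECI signal: active
somata are found on the peak-to-noise-ratio (PNR) image with the same
segmenter (external footprints from a source-extraction tool can be
supplied instead).  After registering the two channels' reference
images, neurons are matched one-to-one when their footprints overlap by
at least 50 % (intersection over the smaller support by default), and
the matched percentage summarizes the co-labelled fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .frames import FrameStack
from .preproc import RigidShift, register_translation

#: fraction of a footprint's max weight defining its binary support
SUPPORT_LEVEL = 0.5


@dataclass
class Footprint:
    """A single neuron's spatial weight image (full-frame, sparse support)."""

    label: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D image")
        if self.weights.max() <= 0:
            raise ValueError("footprint has empty support")

    def support(self, level: float = SUPPORT_LEVEL) -> np.ndarray:
        """Binary mask: pixels with weight ≥ level × max weight."""
        return self.weights >= level * self.weights.max()

    @property
    def area_px(self) -> int:
        return int(self.support().sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Weight centroid as (y, x) in pixels."""
        cy, cx = ndimage.center_of_mass(self.weights)
        return float(cy), float(cx)


@dataclass
class NeuralMap:
    """Footprints of one trial/session plus its reference image."""

    footprints: list[Footprint]
    reference_image: np.ndarray
    session_id: str = ""
    channel: str = ""
    depth_label: str = ""

    def __post_init__(self) -> None:
        labels = [fp.label for fp in self.footprints]
        if len(labels) != len(set(labels)):
            raise ValueError("footprint labels must be unique within a map")

    def __len__(self) -> int:
        return len(self.footprints)

    def labels(self) -> list[int]:
        return [fp.label for fp in self.footprints]

    def get(self, label: int) -> Footprint:
        for fp in self.footprints:
            if fp.label == label:
                return fp
        raise KeyError(label)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_static_channel(
    avg_image: np.ndarray,
    highpass_sigma_px: float = 10.0,
    threshold_factor: float = 4.0,
    min_area_px: int = 20,
    max_area_px: int = 800,
    *,
    split_touching: bool = False,
    peak_min_distance_px: int = 5,
    channel: str = "red",
    session_id: str = "",
    depth_label: str = "",
) -> NeuralMap:
    """Segment somata from a (high-passed) average or PNR image.

    High-pass = image − Gaussian blur(σ = ``highpass_sigma_px``); the
    result is binarized at ``median + threshold_factor × robust sd``
    (1.4826 × MAD), connected components are extracted and filtered by
    area, and footprint weights are the high-pass intensities on the
    component support.  ``split_touching`` additionally runs a
    local-maxima-seeded watershed inside the binary mask, separating
    somata that merge into one component in crowded fields.
    """
    img = np.asarray(avg_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("avg_image must be 2-D")
    hp = img - ndimage.gaussian_filter(img, highpass_sigma_px)
    med = np.median(hp)
    noise = 1.4826 * np.median(np.abs(hp - med))
    mask = hp > med + threshold_factor * max(noise, 1e-12)

    if split_touching:
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        sm = ndimage.gaussian_filter(hp, 1.5)
        seeds = peak_local_max(
            sm, min_distance=peak_min_distance_px, labels=mask, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=int)
        for n, (i, j) in enumerate(seeds, start=1):
            markers[i, j] = n
        labels = watershed(-sm, markers=markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)

    footprints = []
    next_label = 1
    for lab in range(1, labels.max() + 1):
        sup = labels == lab
        area = int(sup.sum())
        if not (min_area_px <= area <= max_area_px):
            continue
        w = np.where(sup, np.maximum(hp - med, 0.0), 0.0)
        if w.max() <= 0:
            continue
        footprints.append(Footprint(label=next_label, weights=w))
        next_label += 1
    return NeuralMap(
        footprints=footprints,
        reference_image=img,
        session_id=session_id,
        channel=channel,
        depth_label=depth_label,
    )


def pnr_image(stack: FrameStack) -> np.ndarray:
    """Per-pixel peak-to-noise ratio of the temporal trace.

    (temporal max − temporal median) / robust sd of the trace, with a
    PNR of 0 for constant pixels.
    """
    if len(stack) < 10:
        raise ValueError("need >= 10 frames for a PNR image")
    data = np.asarray(stack.data, dtype=float)
    med = np.median(data, axis=0)
    mad = np.median(np.abs(data - med), axis=0)
    sd = 1.4826 * mad
    peak = data.max(axis=0) - med
    out = np.zeros_like(med)
    np.divide(peak, sd, out=out, where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# session maps and traces
# ---------------------------------------------------------------------------

def shift_footprint(fp: Footprint, shift: RigidShift) -> Footprint:
    """Footprint displaced by (+dx, +dy) (linear interpolation)."""
    w = ndimage.shift(fp.weights, (shift.dy, shift.dx), order=1, mode="constant")
    w = np.maximum(w, 0.0)
    return Footprint(label=fp.label, weights=w)


def shift_map(nmap: NeuralMap, shift: RigidShift) -> NeuralMap:
    """All footprints and the reference image displaced by (+dx, +dy).

    Footprints shifted entirely out of the frame are dropped.
    """
    ref = ndimage.shift(nmap.reference_image, (shift.dy, shift.dx), order=1, mode="nearest")
    kept = []
    for fp in nmap.footprints:
        w = ndimage.shift(fp.weights, (shift.dy, shift.dx), order=1, mode="constant")
        if w.max() > 0:
            kept.append(Footprint(label=fp.label, weights=np.maximum(w, 0.0)))
    return NeuralMap(
        footprints=kept,
        reference_image=ref,
        session_id=nmap.session_id,
        channel=nmap.channel,
        depth_label=nmap.depth_label,
    )


def build_session_map(
    trial_maps: list[NeuralMap],
    trial_shifts: list[RigidShift] | None = None,
    threshold: float = 0.5,
) -> NeuralMap:
    """Average per-trial footprints of each neuron into a session map.

    Trial maps are aligned by the inter-trial shifts (from average-image
    registration; identity if None), corresponded across trials by
    overlap matching, and each session footprint is the mean of its
    aligned per-trial weight images over the trials where the neuron was
    detected.
    """
    if not trial_maps:
        raise ValueError("need >= 1 trial map")
    if trial_shifts is None:
        trial_shifts = [RigidShift(0.0, 0.0)] * len(trial_maps)
    aligned = [
        shift_map(m, RigidShift(dx=-s.dx, dy=-s.dy)) if (s.dx or s.dy) else m
        for m, s in zip(trial_maps, trial_shifts)
    ]

    # accumulate: list of per-neuron weight-image lists
    acc: list[list[np.ndarray]] = [[fp.weights] for fp in aligned[0].footprints]
    anchors = list(aligned[0].footprints)
    for m in aligned[1:]:
        table = match_maps(
            NeuralMap(anchors, aligned[0].reference_image), m, threshold=threshold
        )
        matched_b = {lb: la for la, lb, _ in table.pairs}
        anchor_idx = {fp.label: i for i, fp in enumerate(anchors)}
        for fp in m.footprints:
            if fp.label in matched_b:
                acc[anchor_idx[matched_b[fp.label]]].append(fp.weights)
            else:
                new = Footprint(label=max(a.label for a in anchors) + 1, weights=fp.weights)
                anchors.append(new)
                acc.append([fp.weights])

    session_fps = [
        Footprint(label=a.label, weights=np.mean(ws, axis=0))
        for a, ws in zip(anchors, acc)
    ]
    ref = np.mean([m.reference_image for m in aligned], axis=0)
    first = trial_maps[0]
    return NeuralMap(
        footprints=session_fps,
        reference_image=ref,
        session_id=first.session_id,
        channel=first.channel,
        depth_label=first.depth_label,
    )


@dataclass
class Trace:
    """Per-frame fluorescence of one footprint."""

    values: np.ndarray
    dff: np.ndarray | None
    frame_rate: float
    label: int


def roi_trace(
    stack: FrameStack,
    footprint: Footprint,
    neuropil_annulus: tuple[int, int] = (2, 6),
    neuropil_factor: float = 0.7,
    exclude_mask: np.ndarray | None = None,
    f0_percentile: float = 20.0,
) -> Trace:
    """ROI-based activity estimate for one footprint.

    raw[t] is the weight-normalized mean over the footprint support;
    the neuropil signal is the plain mean over an annulus
    (``inner..outer`` px dilations of the support), excluding pixels
    belonging to any footprint (``exclude_mask``); the corrected trace
    is raw − neuropil_factor × neuropil and ΔF/F uses
    F0 = ``f0_percentile`` of the corrected trace.
    """
    sup = footprint.support()
    if not sup.any():
        raise ValueError("footprint support is empty")
    data = np.asarray(stack.data, dtype=float)
    w = np.where(sup, footprint.weights, 0.0)
    w = w / w.sum()
    raw = np.tensordot(data, w, axes=([1, 2], [0, 1]))

    inner, outer = neuropil_annulus
    ring = ndimage.binary_dilation(sup, iterations=outer) & ~ndimage.binary_dilation(
        sup, iterations=max(1, inner)
    )
    if exclude_mask is not None:
        ring &= ~exclude_mask
    if neuropil_factor != 0.0 and not ring.any():
        warnings.warn("empty neuropil annulus: neuropil correction skipped", stacklevel=2)
        corrected = raw
    elif neuropil_factor != 0.0:
        neuropil = data[:, ring].mean(axis=1)
        corrected = raw - neuropil_factor * neuropil
    else:
        corrected = raw

    f0 = np.percentile(corrected, f0_percentile)
    dff = (corrected - f0) / f0 if f0 != 0 else None
    return Trace(values=corrected, dff=dff, frame_rate=stack.fps, label=footprint.label)


# ---------------------------------------------------------------------------
# overlap matching
# ---------------------------------------------------------------------------

def overlap_fraction(
    fp_a: Footprint,
    fp_b: Footprint,
    denominator: str = "min",
    support_level: float = SUPPORT_LEVEL,
) -> float:
    """Fraction of footprint supports that overlap, in [0, 1].

    ``denominator="min"`` (default) divides the intersection by the
    smaller support — the natural soma-in-soma criterion; ``"union"``
    gives intersection-over-union.
    """
    sa = fp_a.support(support_level)
    sb = fp_b.support(support_level)
    na, nb = int(sa.sum()), int(sb.sum())
    if na == 0 or nb == 0:
        raise ValueError("empty footprint support")
    inter = int((sa & sb).sum())
    if denominator == "min":
        return inter / min(na, nb)
    if denominator == "union":
        return inter / (na + nb - inter)
    raise ValueError("denominator must be 'min' or 'union'")


@dataclass
class MatchTable:
    """One-to-one cross-map correspondences with overlap fractions."""

    pairs: list[tuple[int, int, float]]  # (label_A, label_B, overlap)
    unmatched_a: list[int]
    unmatched_b: list[int]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["label_A", "label_B", "overlap"])


def register_maps(
    map_a: NeuralMap,
    map_b: NeuralMap,
    upsample: int = 10,
    max_shift_px: float | None = 15.0,
) -> RigidShift:
    """Translation of map B's reference image relative to map A's.

    The search is bounded (default ±15 px): cross-channel and
    inter-trial displacements are small, and the two reference images
    share only part of their content, so an unbounded correlation can
    lock onto a spurious far peak.
    """
    if map_a.reference_image.shape != map_b.reference_image.shape:
        raise ValueError("reference images must have equal shapes")
    return register_translation(
        map_b.reference_image,
        map_a.reference_image,
        upsample=upsample,
        max_shift_px=max_shift_px,
    )


def match_maps(
    map_a: NeuralMap,
    map_b: NeuralMap,
    threshold: float = 0.5,
    denominator: str = "min",
    max_centroid_dist_px: float = 30.0,
) -> MatchTable:
    """Greedy one-to-one matching of footprints by descending overlap.

    Pairs with overlap ≥ ``threshold`` are assigned greedily in
    descending overlap order; ties break by smaller centroid distance,
    then by (label_A, label_B) order, so the result is deterministic.
    Maps must already be co-registered (see :func:`register_maps` and
    :func:`shift_map`).
    """
    cents_a = [fp.centroid for fp in map_a.footprints]
    cents_b = [fp.centroid for fp in map_b.footprints]
    candidates = []
    for i, fa in enumerate(map_a.footprints):
        for j, fb in enumerate(map_b.footprints):
            d = np.hypot(
                cents_a[i][0] - cents_b[j][0], cents_a[i][1] - cents_b[j][1]
            )
            if d > max_centroid_dist_px:
                continue
            ov = overlap_fraction(fa, fb, denominator=denominator)
            if ov >= threshold:
                candidates.append((ov, d, fa.label, fb.label))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ov, _, la, lb in candidates:
        if la in used_a or lb in used_b:
            continue
        pairs.append((la, lb, float(ov)))
        used_a.add(la)
        used_b.add(lb)
    return MatchTable(
        pairs=pairs,
        unmatched_a=[l for l in map_a.labels() if l not in used_a],
        unmatched_b=[l for l in map_b.labels() if l not in used_b],
        threshold=threshold,
    )


def matched_percentage(table: MatchTable, denominator: str = "channel_A") -> float:
    """Percent of one channel's neurons matched in the other channel."""
    unmatched = table.unmatched_a if denominator == "channel_A" else table.unmatched_b
    total = len(table.pairs) + len(unmatched)
    if total == 0:
        raise ValueError("empty denominator map")
    return 100.0 * len(table.pairs) / total


def track_longitudinal(
    session_maps: list[NeuralMap],
    threshold: float = 0.5,
    upsample: int = 10,
    max_shift_px: float | None = None,
) -> pd.DataFrame:
    """Track neurons of the first session across later sessions.

    Each later session's map is registered (translation of reference
    images) and overlap-matched against the first session.  The result
    is a chain table: one row per session-1 neuron, one column per
    session, holding that neuron's label in the session or <NA>.  The
    registration search is unbounded by default: revisited fields share
    most of their content, and inter-session drift can exceed the
    few-pixel cross-channel scale.
    """
    if len(session_maps) < 2:
        raise ValueError("need >= 2 sessions")
    base = session_maps[0]
    chains = {fp.label: [fp.label] for fp in base.footprints}
    for m in session_maps[1:]:
        shift = register_maps(base, m, upsample=upsample, max_shift_px=max_shift_px)
        aligned = shift_map(m, RigidShift(dx=-shift.dx, dy=-shift.dy))
        table = match_maps(base, aligned, threshold=threshold)
        found = {la: lb for la, lb, _ in table.pairs}
        for la in chains:
            chains[la].append(found.get(la))
    cols = [f"session_{i}" for i in range(len(session_maps))]
    df = pd.DataFrame.from_dict(chains, orient="index", columns=cols)
    df.index.name = "neuron"
    return df.astype("Int64")
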