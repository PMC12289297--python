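"""Fuse a burst of fundus frames into one composite image.

Three stages, composable individually or through :func:`burst_reduce`:

1. :func:`estimate_gaze_shifts` — translation-only registration of every
   frame against a reference frame by frequency-domain normalized
   cross-correlation restricted to the field of view.  Gaze drift within a
   sub-200 ms burst is small, so translations suffice.
2. :func:`compute_score_layer` — per-frame, per-pixel fidelity weights in
   [0, 1] that separate retinal signal from scatter, occlusion and local
   blur, by smooth downweighting of deviations from the robust temporal
   median of the aligned stack and of locally depressed gradient energy.
3. :func:`merge_burst` — weight-normalized convex combination of the aligned
   frames.  No spatial filtering of any kind is applied to the output: the
   composite is pointwise convex in the aligned frame values, so spatially
   constant inputs produce spatially constant output.

Registration and scoring run on the green channel for 3-channel input; the
merge is applied per channel with shared weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import BurstStack
from .utils import integer_shift, luma, smoothstep

__all__ = [
    "ShiftSet",
    "ScoreLayer",
    "CompositeImage",
    "ScoreParams",
    "estimate_gaze_shifts",
    "compute_score_layer",
    "merge_burst",
    "burst_reduce",
    "default_reference_index",
]


@dataclass
class ShiftSet:
    """Estimated per-frame (dy, dx) shifts relative to a reference frame,
    with a registration confidence in [0, 1] per frame (the peak normalized
    correlation).  The reference frame's shift is (0, 0), confidence 1."""

    shifts: list[tuple[int, int]]
    confidences: np.ndarray
    reference_index: int

    def __post_init__(self) -> None:
        if self.shifts[self.reference_index] != (0, 0):
            raise ValueError("reference frame must have shift (0, 0)")


@dataclass
class ScoreLayer:
    """Per-frame, per-pixel fusion weights in [0, 1] on the aligned grid."""

    weights: np.ndarray  # (n_frames, H, W)
    method: str = "temporal-median-deviation"

    @property
    def n_frames(self) -> int:
        return self.weights.shape[0]


@dataclass
class CompositeImage:
    """Merged burst: the image, per-pixel total weight, the number of frames
    that materially contributed, and the mask of pixels no frame could
    recover (filled from the temporal median)."""

    image: np.ndarray
    weight_sum_map: np.ndarray
    n_frames_used: int
    unrecoverable_mask: np.ndarray


def default_reference_index(n_frames: int) -> int:
    """Middle frame of the burst, ties broken toward the earlier index."""
    return (n_frames - 1) // 2


# ---------------------------------------------------------------------------
# registration


def _wrap_displacement(idx: int, size: int) -> int:
    return idx - size if idx > size // 2 else idx


def estimate_gaze_shifts(
    stack: BurstStack,
    reference_index: int | None = None,
    max_shift: int = 16,
) -> ShiftSet:
    """Estimate integer translation of each frame relative to the reference.

    The normalized cross-correlation surface is computed via FFT on
    mean-subtracted, FOV-masked frames; the argmax within ``max_shift`` gives
    the shift and the peak correlation value (clipped to [0, 1]) is the
    confidence.  Uncorrelated noise frames peak near 0; well-registered
    structured frames near 1.
    """
    n = stack.n_frames
    if reference_index is None:
        reference_index = default_reference_index(n)
    if not (0 <= reference_index < n):
        raise ValueError(f"reference_index {reference_index} out of range for {n} frames")
    fov = stack.fov_mask
    h, w = luma(stack.frames[0]).shape

    def prep(frame: np.ndarray) -> np.ndarray:
        g = luma(frame).astype(float) * fov
        g = g - g[fov].mean()
        g[~fov] = 0.0
        return g

    ref = prep(stack.frames[reference_index])
    f_ref = np.fft.rfft2(ref)
    norm_ref = np.linalg.norm(ref)

    # wrap-aware window of allowed displacements
    dy_grid = np.minimum(np.arange(h), h - np.arange(h))
    dx_grid = np.minimum(np.arange(w), w - np.arange(w))
    allowed = (dy_grid[:, None] <= max_shift) & (dx_grid[None, :] <= max_shift)

    shifts: list[tuple[int, int]] = []
    conf = np.empty(n)
    for i, frame in enumerate(stack.frames):
        if luma(frame).shape != (h, w):
            raise ValueError("all frames must share one shape")
        if i == reference_index:
            shifts.append((0, 0))
            conf[i] = 1.0
            continue
        g = prep(frame)
        # corr[d] = sum_x ref(x) g(x + d): peak at d = s when g = ref shifted by s
        corr = np.fft.irfft2(np.conj(f_ref) * np.fft.rfft2(g), s=(h, w))
        corr = np.where(allowed, corr, -np.inf)
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        dy = _wrap_displacement(int(peak[0]), h)
        dx = _wrap_displacement(int(peak[1]), w)
        denom = norm_ref * np.linalg.norm(g)
        conf[i] = float(np.clip(corr[peak] / denom if denom > 0 else 0.0, 0.0, 1.0))
        shifts.append((dy, dx))
    return ShiftSet(shifts=shifts, confidences=conf, reference_index=reference_index)


# ---------------------------------------------------------------------------
# score layer


@dataclass(frozen=True)
class ScoreParams:
    """Tuning of the fidelity weights; defaults documented in the methods
    note.  ``deviation_scale_mult`` multiplies the robust per-stack noise
    estimate to set both the deviation tolerance and the falloff width."""

    deviation_scale_mult: float = 3.0
    min_deviation_scale: float = 0.02
    gradient_window_px: int = 15
    gradient_ratio_lo: float = 0.2
    gradient_ratio_hi: float = 0.8
    unrecoverable_eps: float = 1e-3
    frame_use_floor: float = 0.1


def _aligned_stack(stack: BurstStack, shifts: list[tuple[int, int]]):
    """Align luma frames to the reference grid; returns (frames, validity)."""
    fov = stack.fov_mask
    aligned, valid = [], []
    ones = np.ones(luma(stack.frames[0]).shape)
    for frame, (dy, dx) in zip(stack.frames, shifts):
        aligned.append(integer_shift(luma(frame).astype(float), -dy, -dx))
        valid.append(integer_shift(ones, -dy, -dx) > 0.5)
    return np.stack(aligned), np.stack(valid) & fov


def _gradient_energy(img: np.ndarray, window: int) -> np.ndarray:
    gy = ndimage.sobel(img, axis=0) / 8.0
    gx = ndimage.sobel(img, axis=1) / 8.0
    return ndimage.uniform_filter(gy * gy + gx * gx, size=window)


def compute_score_layer(
    stack: BurstStack,
    shifts: ShiftSet,
    params: ScoreParams = ScoreParams(),
) -> ScoreLayer:
    """Per-pixel fusion weights from deviation against the temporal median.

    After alignment, the robust temporal reference is the per-pixel median of
    the valid frames.  A frame's weight at a pixel decreases smoothly when its
    value deviates above the median beyond a tolerance (specular scatter /
    saturation), below it (occlusion / darkness), or when its local gradient
    energy is depressed relative to the median frame's (local blur).  Pixels a
    shifted frame never observed get weight 0.  A single-frame stack gets all
    weights 1 (degenerate but valid).
    """
    if len(shifts.shifts) != stack.n_frames:
        raise ValueError("shift count must match the stack's frame count")
    aligned, valid = _aligned_stack(stack, shifts.shifts)
    n = stack.n_frames
    if n == 1:
        return ScoreLayer(weights=valid.astype(float))

    import warnings

    data = np.where(valid, aligned, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(data, axis=0)
    median = np.where(np.isnan(median), 0.0, median)

    dev = aligned - median
    abs_dev = np.abs(dev)[valid]
    sigma = 1.4826 * np.median(abs_dev) if abs_dev.size else 0.0
    scale = max(params.deviation_scale_mult * sigma, params.min_deviation_scale)
    tol = scale
    # exactly 1 for |dev| <= tol, smooth falloff to 0 at tol + scale
    w_dev = 1.0 - smoothstep((np.abs(dev) - tol) / scale)

    e_med = _gradient_energy(median, params.gradient_window_px)
    eps = 1e-8
    lo, hi = params.gradient_ratio_lo, params.gradient_ratio_hi
    w = np.empty_like(aligned)
    for i in range(n):
        ratio = (_gradient_energy(aligned[i], params.gradient_window_px) + eps) / (e_med + eps)
        w_blur = smoothstep((ratio - lo) / (hi - lo))
        w[i] = w_dev[i] * w_blur
    w = np.clip(w, 0.0, 1.0) * valid
    return ScoreLayer(weights=w)


# ---------------------------------------------------------------------------
# merge


def merge_burst(
    stack: BurstStack,
    shifts: ShiftSet,
    scores: ScoreLayer,
    params: ScoreParams = ScoreParams(),
) -> CompositeImage:
    """Weight-normalized convex combination of the aligned frames.

    Composite pixel = sum_f w_f * aligned_f / sum_f w_f.  Pixels whose total
    weight falls below ``unrecoverable_eps`` times the frame count are filled
    from the temporal median and flagged.  No spatial filtering is applied.
    """
    if scores.weights.shape[0] != stack.n_frames:
        raise ValueError("score layer frame count must match the stack")
    fov = stack.fov_mask
    w = scores.weights
    wsum = w.sum(axis=0)
    floor = params.unrecoverable_eps * stack.n_frames
    unrecoverable = (wsum < floor) & fov

    multichannel = stack.frames[0].ndim == 3
    channels = stack.frames[0].shape[-1] if multichannel else 1
    out = np.zeros(stack.frames[0].shape, dtype=float)
    for c in range(channels):
        planes = [f[..., c] if multichannel else f for f in stack.frames]
        aligned = np.stack([
            integer_shift(p.astype(float), -dy, -dx)
            for p, (dy, dx) in zip(planes, shifts.shifts)
        ])
        num = (w * aligned).sum(axis=0)
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            merged = np.where(wsum >= floor, num / np.where(wsum > 0, wsum, 1.0), 0.0)
            tmed = np.nanmedian(np.where(w > 0, aligned, np.nan), axis=0)
            fallback = np.nanmedian(aligned, axis=0)
        tmed = np.where(np.isnan(tmed), fallback, tmed)
        merged = np.where(unrecoverable, tmed, merged)
        if multichannel:
            out[..., c] = merged
        else:
            out = merged
    out[~fov] = 0.0

    mean_w = np.array([w[i][fov].mean() for i in range(stack.n_frames)])
    n_used = int((mean_w >= params.frame_use_floor).sum())
    return CompositeImage(image=out, weight_sum_map=wsum,
                          n_frames_used=n_used, unrecoverable_mask=unrecoverable)


def burst_reduce(
    stack: BurstStack,
    reference_index: int | None = None,
    params: ScoreParams = ScoreParams(),
    max_shift: int = 16,
) -> CompositeImage:
    """Full fusion pipeline: register, score, merge with default parameters."""
    shifts = estimate_gaze_shifts(stack, reference_index=reference_index, max_shift=max_shift)
    scores = compute_score_layer(stack, shifts, params=params)
    return merge_burst(stack, shifts, scores, params=params)
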