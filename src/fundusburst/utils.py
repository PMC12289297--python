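"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np


def smoothstep(x: np.ndarray | float) -> np.ndarray:
    """Cubic smoothstep: 0 for x<=0, 1 for x>=1, smooth in between.

    Unlike a logistic, it saturates exactly at 0 and 1, so fully degraded
    regions map to impairment exactly 1 and pristine regions exactly 0.
    """
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def ramp_up(x: np.ndarray | float, width: float) -> np.ndarray:
    """Smooth ramp from 0 to 1 as x goes from 0 to ``width``."""
    return smoothstep(np.asarray(x, dtype=float) / float(width))


def integer_shift(img: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Shift a 2-D (or 2-D + channel) array by whole pixels, filling exposed
    borders with ``fill``.  Positive dy/dx move content down/right."""
    out = np.full_like(img, fill)
    h, w = img.shape[:2]
    dy, dx = int(dy), int(dx)
    if abs(dy) >= h or abs(dx) >= w:
        return out
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out


def luma(img: np.ndarray) -> np.ndarray:
    """Working channel for registration/scoring: the image itself when 2-D,
    the green channel when 3-channel (highest retinal vessel contrast)."""
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return img[..., 1]
    raise ValueError(f"expected 2-D or 3-channel image, got shape {img.shape}")


def inscribed_circle_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the inscribed circle of a (square) frame."""
    h, w = shape[:2]
    c_y, c_x = (h - 1) / 2.0, (w - 1) / 2.0
    r = min(h, w) / 2.0 - 1.0
    yy, xx = np.ogrid[0:h, 0:w]
    return (yy - c_y) ** 2 + (xx - c_x) ** 2 <= r * r


def masked_psnr(img: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> float:
    """PSNR (dB, data range 1) computed only over ``mask``."""
    a = luma(np.asarray(img, dtype=float))[mask]
    b = luma(np.asarray(ref, dtype=float))[mask]
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))
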