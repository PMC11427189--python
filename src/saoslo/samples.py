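"""Synthetic fluorescence sample textures.

Stand-ins for the two sample classes imaged on a confocal SLO bench:
lens-tissue preparations (sparse fibrous strands of mixed width, dyed with
fluorescent ink) and retinal ganglion-cell mosaics (quasi-regular fields of
bright somata).  Both are generated procedurally and seeded, so every test
and benchmark can rebuild its sample bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["generate_sample_image"]


def _fibers(size: int, rng: np.random.Generator) -> np.ndarray:
    """Sparse smooth random curves with two stroke widths."""
    img = np.zeros((size, size))
    n_fibers = max(4, size // 16)
    n_steps = size * 2
    for i in range(n_fibers):
        pos = rng.uniform(0, size, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.6, 1.0)
        pts = np.empty((n_steps, 2))
        for t in range(n_steps):
            ang += rng.normal(0.0, 0.15)
            pos = (pos + [np.cos(ang), np.sin(ang)]) % size
            pts[t] = pos
        ij = np.floor(pts).astype(int) % size
        img[ij[:, 0], ij[:, 1]] = np.maximum(img[ij[:, 0], ij[:, 1]], amp)
        if i % 2 == 0:  # every other strand is a wide fibre
            wide = np.zeros_like(img)
            wide[ij[:, 0], ij[:, 1]] = amp
            img = np.maximum(img, ndimage.grey_dilation(wide, size=(3, 3)))
    img = ndimage.gaussian_filter(img, sigma=0.8)
    return img


def _cells(size: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal mosaic of bright disks (soma-like blobs)."""
    img = np.zeros((size, size))
    pitch = max(8, size // 14)
    radius = pitch / 3.5
    yy, xx = np.mgrid[0:size, 0:size]
    rows = np.arange(-pitch, size + pitch, int(pitch * 0.87))
    for r_i, y in enumerate(rows):
        offset = (pitch / 2) if r_i % 2 else 0.0
        for x in np.arange(-pitch + offset, size + pitch, pitch):
            cy = y + rng.normal(0, pitch * 0.12)
            cx = x + rng.normal(0, pitch * 0.12)
            amp = rng.uniform(0.5, 1.0)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img = np.maximum(img, amp * np.exp(-d2 / (2 * radius ** 2)))
    return img


def generate_sample_image(kind: str, size: int, rng) -> np.ndarray:
    """Generate a nonnegative seeded sample texture normalised to [0, 1].

    Parameters
    ----------
    kind
        ``"fibers"`` (lens-tissue-like strands), ``"cells"`` (ganglion-cell
        mosaic) or ``"mixed"`` (mean of the two).
    size
        Image side in pixels, >= 64.
    rng
        :class:`numpy.random.Generator` or integer seed.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(rng)
    if kind == "fibers":
        img = _fibers(size, rng)
    elif kind == "cells":
        img = _cells(size, rng)
    elif kind == "mixed":
        img = 0.5 * _fibers(size, rng) + 0.5 * _cells(size, rng)
    else:
        raise ValueError(f"unknown sample kind {kind!r}")
    peak = img.max()
    if peak <= 0:
        raise RuntimeError("degenerate all-zero texture")
    return img / peak
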