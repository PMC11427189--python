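"""Noll-indexed Zernike polynomials on a discrete circular pupil.

Zernike modes form an orthonormal basis for wavefront phase maps over the
unit disk.  We use Noll's single-index ordering (index 1 = piston,
2-3 = tip/tilt, 4 = defocus, 5-6 = astigmatism, ...) and Noll's
normalisation, under which the mean of ``Z_i**2`` over the pupil equals 1,
so a coefficient of ``c`` micrometres on any single mode contributes
exactly ``c`` micrometres of RMS wavefront error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

__all__ = ["noll_to_nm", "zernike_map", "ZernikeBasis", "make_zernike_basis"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll index ``j >= 1`` to radial degree ``n`` and azimuthal
    frequency ``m`` (signed; m < 0 denotes the sine harmonic)."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n, j1 = 0, j - 1
    while j1 > n:
        j1 -= n + 1
        n += 1
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^|m|(rho)."""
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coef = ((-1) ** k * factorial(n - k)
                / (factorial(k) * factorial((n + m) // 2 - k)
                   * factorial((n - m) // 2 - k)))
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_map(j: int, grid_size: int, pupil_radius: float) -> np.ndarray:
    """Evaluate Noll mode ``j`` on a ``grid_size``-square grid.

    The pupil is centred on the pixel ``(grid_size//2, grid_size//2)`` (the
    FFT centre after ``fftshift``) and the map is zero outside the pupil.
    """
    n, m = noll_to_nm(j)
    yy, xx = np.meshgrid(*(np.arange(grid_size, dtype=float) - grid_size // 2,) * 2,
                         indexing="ij")
    rho = np.hypot(xx, yy) / pupil_radius
    theta = np.arctan2(yy, xx)
    mask = rho <= 1.0
    r = _radial_poly(n, m, np.where(mask, rho, 0.0))
    if m == 0:
        z = np.sqrt(n + 1.0) * r
    elif m > 0:
        z = np.sqrt(2.0 * (n + 1)) * r * np.cos(m * theta)
    else:
        z = np.sqrt(2.0 * (n + 1)) * r * np.sin(-m * theta)
    return np.where(mask, z, 0.0)


@dataclass(frozen=True)
class ZernikeBasis:
    """A stack of Noll-normalised mode maps over a shared discrete pupil.

    Attributes
    ----------
    noll_indices
        Noll indices of the modes, ascending; piston/tip/tilt (1-3) excluded.
    mode_maps
        Array of shape ``(n_modes, grid_size, grid_size)``; each map is zero
        outside ``pupil_mask``.
    pupil_mask
        Boolean pupil support.
    """

    noll_indices: tuple[int, ...]
    mode_maps: np.ndarray
    pupil_mask: np.ndarray
    grid_size: int
    pupil_radius: float
    _index_pos: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "_index_pos", {j: p for p, j in enumerate(self.noll_indices)}
        )

    @property
    def n_modes(self) -> int:
        return len(self.noll_indices)

    def compose(self, coeffs) -> np.ndarray:
        """Wavefront OPD map (same units as the coefficients) from a mapping
        ``{noll_index: coeff}`` or an array aligned with ``noll_indices``."""
        if isinstance(coeffs, dict):
            vec = np.zeros(self.n_modes)
            for j, c in coeffs.items():
                if j not in self._index_pos:
                    raise KeyError(f"Noll index {j} not in basis {self.noll_indices}")
                vec[self._index_pos[j]] = c
        else:
            vec = np.asarray(coeffs, dtype=float)
            if vec.shape != (self.n_modes,):
                raise ValueError(
                    f"expected {self.n_modes} coefficients, got shape {vec.shape}")
        return np.tensordot(vec, self.mode_maps, axes=1)

    def pupil_mean(self, field2d: np.ndarray) -> float:
        return float(field2d[self.pupil_mask].mean())

    def pupil_rms(self, field2d: np.ndarray) -> float:
        return float(np.sqrt(np.mean(field2d[self.pupil_mask] ** 2)))


def make_zernike_basis(noll_indices, grid_size: int, pupil_radius: float) -> ZernikeBasis:
    """Build a :class:`ZernikeBasis` for target/noise wavefront modes.

    Parameters
    ----------
    noll_indices
        Iterable of Noll indices, all >= 4 (piston, tip and tilt carry no
        image-sharpness information in this geometry and are excluded).
    grid_size
        Side of the square complex-pupil array, pixels.
    pupil_radius
        Pupil radius in pixels; the pupil must fit inside the grid.
    """
    indices = tuple(int(j) for j in noll_indices)
    if any(j < 4 for j in indices):
        raise ValueError("Noll indices below 4 (piston/tip/tilt) are not supported")
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate Noll indices")
    if 2 * pupil_radius > grid_size:
        raise ValueError(
            f"pupil (diameter {2 * pupil_radius}) does not fit grid {grid_size}")
    maps = np.stack([zernike_map(j, grid_size, pupil_radius) for j in indices])
    yy, xx = np.meshgrid(*(np.arange(grid_size, dtype=float) - grid_size // 2,) * 2,
                         indexing="ij")
    mask = np.hypot(xx, yy) <= pupil_radius
    return ZernikeBasis(indices, maps, mask, grid_size, float(pupil_radius))
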