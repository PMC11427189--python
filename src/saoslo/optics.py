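"""Fourier-optics image formation for a confocal scanning-laser ophthalmoscope.

The model chain is:

1. wavefront OPD ``W(x,y)`` (micrometres) from Zernike coefficients,
2. generalised pupil ``P = A * exp(-i * 2*pi/lambda * W)``,
3. intensity PSF ``h = |FFT{P}|**2`` (illumination and detection passes share
   the same aberration: the beam traverses the same mirror/eye path twice),
4. confocal effective PSF ``hs = h1 * (f (*) h2)`` where ``f`` is the
   multimode collection fiber modelled as a uniform disk a few Airy-disk
   diameters wide (``hs = h1*h2`` in the point-detector limit),
5. image ``I = hs (*) rf`` by circular convolution with the sample's
   fluorescence reflectance ``rf``,
6. sharpness metric ``m = sum(I**2)``.

All convolutions are circular (FFT-based).  The phase convention converts
micrometres of OPD to radians with ``2*pi/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sfft
from scipy.signal import fftconvolve

from .zernike import ZernikeBasis, make_zernike_basis

__all__ = [
    "PSF", "SystemModel", "compose_wavefront", "compute_psf", "effective_psf",
    "render_image", "sharpness_metric", "airy_disk_diameter_px",
]


def airy_disk_diameter_px(padded_size: int, pupil_diameter_px: float) -> float:
    """Airy-disk diameter (twice the first dark ring) in PSF-plane pixels."""
    return 2 * 1.22 * padded_size / pupil_diameter_px


@dataclass
class PSF:
    """Intensity point-spread function on the padded FFT grid, centred."""
    intensity: np.ndarray
    kind: str = "illumination"  # one of {illumination, detection, effective}

    def __post_init__(self):
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("PSF contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("PSF contains negative values")


def _disk_kernel(size: int, diameter_px: float) -> np.ndarray:
    """Uniform unit-height disk of the given diameter, centred at size//2."""
    c = size // 2
    yy, xx = np.meshgrid(*(np.arange(size, dtype=float) - c,) * 2, indexing="ij")
    return (np.hypot(xx, yy) <= diameter_px / 2.0).astype(float)


@dataclass
class SystemModel:
    """Optical and sampling parameters of the simulated confocal SLO.

    Parameters
    ----------
    wavelength
        Laser wavelength, micrometres.
    grid_size
        Side of the complex pupil array, pixels (pupil diameter fills it by
        default); zero-padded by ``pad_factor`` before the FFT so the Airy
        core spans several PSF pixels.
    fiber_diameter
        Collection-fiber diameter in Airy-disk-diameter units; 0 selects the
        ideal point-detector (pinhole) limit.
    sample_image
        Nonnegative 2-D fluorescence sample; images are formed on its grid.
    kernel_size
        Side of the central crop of the effective PSF used as the imaging
        kernel (odd).
    mode_scaling
        How coefficient vectors map onto wavefront OPD.  ``"peak"``
        (default) treats a coefficient as the peak surface amplitude of its
        mode, the convention of deformable-mirror command units: the Noll
        map of mode i is divided by its maximum over the pupil.  ``"noll"``
        treats a coefficient directly as the pupil-RMS OPD of its mode.
    """

    wavelength: float = 0.488
    grid_size: int = 256
    pupil_radius: Optional[float] = None
    pad_factor: int = 2
    fiber_diameter: float = 3.0
    sample_image: Optional[np.ndarray] = None
    kernel_size: int = 33
    mode_scaling: str = "peak"
    render_count: int = field(default=0, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.fiber_diameter < 0:
            raise ValueError("fiber_diameter must be >= 0")
        if self.pupil_radius is None:
            self.pupil_radius = self.grid_size / 2
        if 2 * self.pupil_radius > self.grid_size:
            raise ValueError("pupil does not fit the grid")
        if self.sample_image is not None:
            self.sample_image = np.asarray(self.sample_image, dtype=float)
            if self.sample_image.ndim != 2 or not np.any(self.sample_image > 0):
                raise ValueError("sample_image must be 2-D with a positive pixel")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.mode_scaling not in ("peak", "noll"):
            raise ValueError("mode_scaling must be 'peak' or 'noll'")

    # -- derived geometry ---------------------------------------------------
    @property
    def padded_size(self) -> int:
        return self.grid_size * self.pad_factor

    @property
    def airy_diameter_px(self) -> float:
        return airy_disk_diameter_px(self.padded_size, 2 * self.pupil_radius)

    @property
    def fiber_diameter_px(self) -> float:
        return self.fiber_diameter * self.airy_diameter_px

    # -- cached spectra -----------------------------------------------------
    def _fiber_fft(self) -> np.ndarray:
        key = ("fiber_fft", self.padded_size, round(self.fiber_diameter_px, 9))
        if key not in self._cache:
            disk = _disk_kernel(self.padded_size, self.fiber_diameter_px)
            self._cache[key] = sfft.fft2(sfft.ifftshift(disk))
        return self._cache[key]

    def _sample_fft(self) -> np.ndarray:
        key = ("sample_fft", id(self.sample_image))
        if key not in self._cache:
            self._cache[key] = sfft.fft2(self.sample_image)
        return self._cache[key]

    def make_basis(self, noll_indices) -> ZernikeBasis:
        return make_zernike_basis(noll_indices, self.grid_size, self.pupil_radius)

    # -- full pipeline ------------------------------------------------------
    def _psf_window(self, opd: np.ndarray, pupil_mask: np.ndarray,
                    q: int) -> np.ndarray:
        """Central ``(2q+1)``-square window of the (centred) intensity PSF.

        Identical to cropping :func:`compute_psf`, but the squared modulus
        is evaluated only on the window actually needed downstream.
        """
        g, m = self.grid_size, self.padded_size
        key = ("pupil_buf", m)
        if key not in self._cache:
            self._cache[key] = np.zeros((m, m), dtype=complex)
        buf = self._cache[key]
        phase = (2 * np.pi / self.wavelength) * opd
        buf[:g, :g] = pupil_mask * np.exp(-1j * phase)
        F = sfft.fft2(buf)
        idx = np.arange(-q, q + 1) % m
        w = F[np.ix_(idx, idx)]
        return w.real ** 2 + w.imag ** 2

    def _effective_crop(self, h: np.ndarray) -> np.ndarray:
        """Central ``kernel_size`` crop of the effective PSF ``h*(f (*) h)``.

        Equivalent to cropping :func:`effective_psf` but blurs only the
        window the imaging kernel needs, since the fiber disk is compact.
        """
        m = h.shape[0]
        c, half = m // 2, self.kernel_size // 2
        if self.fiber_diameter == 0:
            crop = h[c - half:c + half + 1, c - half:c + half + 1]
            return crop * crop
        pad = int(np.ceil(self.fiber_diameter_px / 2.0))
        key = ("fiber_small", 2 * pad + 1, round(self.fiber_diameter_px, 9))
        if key not in self._cache:
            self._cache[key] = _disk_kernel(2 * pad + 1, self.fiber_diameter_px)
        disk = self._cache[key]
        big = h[c - half - pad:c + half + pad + 1, c - half - pad:c + half + pad + 1]
        blurred = fftconvolve(big, disk, mode="valid")
        np.clip(blurred, 0.0, None, out=blurred)
        crop = h[c - half:c + half + 1, c - half:c + half + 1]
        return crop * blurred

    def image_for_opd(self, opd: np.ndarray, basis: ZernikeBasis) -> np.ndarray:
        half = self.kernel_size // 2
        pad = (0 if self.fiber_diameter == 0
               else int(np.ceil(self.fiber_diameter_px / 2.0)))
        h = self._psf_window(opd, basis.pupil_mask, half + pad)
        hs = PSF(self._effective_crop(h), kind="effective")
        return render_image(hs, self.sample_image, self)

    def coeff_scale(self, basis: ZernikeBasis) -> np.ndarray:
        """Per-mode factors converting command coefficients to Noll-basis
        weights (all ones under ``"noll"``; 1/peak under ``"peak"``)."""
        key = ("scale", self.mode_scaling, basis.noll_indices,
               basis.grid_size, basis.pupil_radius)
        if key not in self._cache:
            if self.mode_scaling == "noll":
                self._cache[key] = np.ones(basis.n_modes)
            else:
                peaks = np.abs(basis.mode_maps).max(axis=(1, 2))
                self._cache[key] = 1.0 / peaks
        return self._cache[key]

    def compose_command(self, coeffs, basis: ZernikeBasis) -> np.ndarray:
        """Wavefront OPD produced by a coefficient command vector."""
        coeffs = np.asarray(coeffs, dtype=float)
        return basis.compose(coeffs * self.coeff_scale(basis))

    def metric_for_coeffs(self, coeffs, basis: ZernikeBasis) -> float:
        """Sharpness metric of the image formed under the given aberration."""
        return sharpness_metric(
            self.image_for_opd(self.compose_command(coeffs, basis), basis))


def compose_wavefront(coeffs, basis: ZernikeBasis) -> np.ndarray:
    """Wavefront OPD map (micrometres) as the linear superposition of basis
    modes weighted by ``coeffs`` (dict keyed by Noll index, or aligned array)."""
    return basis.compose(coeffs)


def compute_psf(opd: np.ndarray, system: SystemModel,
                pupil_mask: Optional[np.ndarray] = None,
                kind: str = "illumination") -> PSF:
    """Intensity PSF of the generalised pupil carrying ``opd`` micrometres.

    The pupil amplitude is the binary aperture; the phase is
    ``-(2*pi/lambda) * opd``.  The result lives on the padded grid and is
    ``fftshift``-centred so the unaberrated peak sits at ``(M//2, M//2)``.
    """
    g = system.grid_size
    if opd.shape != (g, g):
        raise ValueError(f"opd shape {opd.shape} does not match pupil grid {g}")
    if pupil_mask is None:
        yy, xx = np.meshgrid(*(np.arange(g, dtype=float) - g // 2,) * 2, indexing="ij")
        pupil_mask = np.hypot(xx, yy) <= system.pupil_radius
    phase = (2 * np.pi / system.wavelength) * opd
    pupil = np.zeros((system.padded_size,) * 2, dtype=complex)
    pupil[:g, :g] = pupil_mask * np.exp(-1j * phase)
    h = np.abs(sfft.fft2(pupil)) ** 2
    return PSF(sfft.fftshift(h), kind=kind)


def effective_psf(h1: PSF, h2: PSF, system: SystemModel) -> PSF:
    """Confocal effective PSF.

    Point detector (``fiber_diameter == 0``): ``hs = h1 * h2``.  Finite
    fiber: ``hs = h1 * (f (*) h2)`` with ``f`` a uniform unit-height disk of
    the configured diameter and ``(*)`` circular convolution.
    """
    a, b = h1.intensity, h2.intensity
    if a.shape != b.shape:
        raise ValueError(f"PSF shapes differ: {a.shape} vs {b.shape}")
    if system.fiber_diameter == 0:
        return PSF(a * b, kind="effective")
    blurred = sfft.ifft2(sfft.fft2(b) * system._fiber_fft()).real
    np.clip(blurred, 0.0, None, out=blurred)
    return PSF(a * blurred, kind="effective")


def render_image(hs: PSF, sample_image: np.ndarray,
                 system: Optional[SystemModel] = None) -> np.ndarray:
    """Form the detected image: circular convolution of the sample with the
    central ``kernel_size`` crop of the effective PSF.

    The kernel is rolled so its centre sits at the origin; a single-pixel
    kernel therefore reproduces the sample exactly.
    """
    if sample_image is None:
        raise ValueError("system has no sample_image")
    sample_image = np.asarray(sample_image, dtype=float)
    s = sample_image.shape[0]
    k = system.kernel_size if system is not None else min(33, s)
    k = min(k, s)
    m = hs.intensity.shape[0]
    c, half = m // 2, k // 2
    crop = hs.intensity[c - half:c + half + 1, c - half:c + half + 1]
    kern = np.zeros_like(sample_image)
    kern[:k, :k] = crop
    kern = np.roll(kern, (-half, -half), axis=(0, 1))
    if system is not None and sample_image is system.sample_image:
        spec = system._sample_fft()
    else:
        spec = sfft.fft2(sample_image)
    img = sfft.ifft2(sfft.fft2(kern) * spec).real
    np.clip(img, 0.0, None, out=img)
    if system is not None:
        system.render_count += 1
    return img


def sharpness_metric(image: np.ndarray) -> float:
    """Image-sharpness metric: the sum of squared pixel intensities.

    Quadratic in image scale, maximised (for a fixed-energy kernel) when the
    effective PSF is most compact, i.e. at zero aberration.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    return float(np.sum(image * image))
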