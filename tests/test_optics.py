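"""Fourier-optics pipeline: PSFs, confocal effective PSF, image formation,
sharpness metric."""

import numpy as np
import pytest

import saoslo as s
from saoslo.optics import PSF, SystemModel, compute_psf, effective_psf, render_image, sharpness_metric


@pytest.fixture(scope="module")
def system():
    return s.default_system()


@pytest.fixture(scope="module")
def basis(system):
    return system.make_basis(range(4, 16))


def test_unaberrated_psf_peaks_at_center(system, basis):
    h = compute_psf(np.zeros((256, 256)), system, basis.pupil_mask)
    m = h.intensity.shape[0]
    assert np.unravel_index(h.intensity.argmax(), h.intensity.shape) == (m // 2, m // 2)


def test_parseval_energy_conservation(system, basis):
    """A phase-only pupil change cannot alter total PSF energy."""
    h0 = compute_psf(np.zeros((256, 256)), system, basis.pupil_mask)
    rng = np.random.default_rng(1)
    for _ in range(3):
        w = basis.compose(rng.normal(0, 0.1, basis.n_modes))
        h = compute_psf(w, system, basis.pupil_mask)
        assert h.intensity.sum() == pytest.approx(h0.intensity.sum(), rel=1e-6)


def test_tip_ramp_translates_psf(system, basis):
    """A linear phase ramp translates the PSF without changing its energy
    (Fourier shift theorem oracle)."""
    g, m = system.grid_size, system.padded_size
    shift = 5
    x = np.arange(g, dtype=float)
    # ramp worth `shift` PSF pixels on the padded grid
    opd = system.wavelength * shift * x[None, :] / m * np.ones((g, 1))
    h0 = compute_psf(np.zeros((g, g)), system, basis.pupil_mask).intensity
    h1 = compute_psf(opd, system, basis.pupil_mask).intensity
    rolled = np.roll(h0, -shift, axis=1)
    assert h1.sum() == pytest.approx(h0.sum(), rel=1e-6)
    np.testing.assert_allclose(h1, rolled, rtol=1e-6, atol=h0.max() * 1e-9)


def test_point_detector_limit(system, basis):
    """With a zero-diameter fiber the effective PSF is the plain product."""
    w = basis.compose({4: 0.05})
    h = compute_psf(w, system, basis.pupil_mask)
    sys0 = SystemModel(sample_image=system.sample_image, fiber_diameter=0.0)
    hs = effective_psf(h, h, sys0)
    np.testing.assert_array_equal(hs.intensity, h.intensity * h.intensity)


def test_one_pixel_fiber_equals_point_detector(system, basis):
    """A single-pixel fiber disk is a delta kernel: the effective PSF
    collapses to the point-detector product."""
    w = basis.compose({5: 0.04})
    h = compute_psf(w, system, basis.pupil_mask)
    # diameter of 1 px in ADD units
    tiny = SystemModel(sample_image=system.sample_image,
                       fiber_diameter=1.0 / system.airy_diameter_px)
    hs = effective_psf(h, h, tiny)
    np.testing.assert_allclose(hs.intensity, h.intensity ** 2,
                               rtol=1e-12, atol=h.intensity.max() ** 2 * 1e-15)


def test_metric_curvature_flattens_with_fiber(small_basis):
    """The normalised metric's curvature at zero defocus shrinks in
    magnitude as the collection fiber grows (finite-difference oracle)."""
    sample = s.generate_sample_image("fibers", 64, 7)
    d = 0.02
    curvatures = []
    for fiber in (0.0, 1.0, 2.0, 3.0):
        sys_ = SystemModel(sample_image=sample, grid_size=64, pupil_radius=32,
                           kernel_size=17, fiber_diameter=fiber)
        m0 = sys_.metric_for_coeffs(np.zeros(25), small_basis)
        mp = sys_.metric_for_coeffs(np.r_[d, np.zeros(24)], small_basis)
        mm = sys_.metric_for_coeffs(np.r_[-d, np.zeros(24)], small_basis)
        curvatures.append((mp + mm - 2 * m0) / (m0 * d * d))
    assert all(c < 0 for c in curvatures)
    mags = [abs(c) for c in curvatures]
    assert mags == sorted(mags, reverse=True)


def test_render_identity_kernels(system):
    sample = system.sample_image
    delta = np.zeros((system.padded_size,) * 2)
    delta[system.padded_size // 2, system.padded_size // 2] = 1.0
    img = render_image(PSF(delta), sample, system)
    np.testing.assert_allclose(img, sample, atol=1e-12)


def test_render_delta_sample_returns_kernel(system, basis):
    """Imaging a point source reproduces the kernel, up to the circular
    shift that places the kernel centre at the source."""
    point = np.zeros((128, 128))
    point[0, 0] = 1.0
    w = basis.compose({4: 0.03})
    h = compute_psf(w, system, basis.pupil_mask)
    hs = effective_psf(h, h, system)
    img = render_image(hs, point, system)
    k, m = system.kernel_size, system.padded_size
    c, half = m // 2, k // 2
    crop = hs.intensity[c - half:c + half + 1, c - half:c + half + 1]
    expected = np.zeros((128, 128))
    expected[:k, :k] = crop
    expected = np.roll(expected, (-half, -half), axis=(0, 1))
    np.testing.assert_allclose(img, expected, rtol=1e-10, atol=crop.max() * 1e-12)


def test_render_mass_conservation(system, basis):
    """Circular convolution preserves total mass: sum(I) = sum(hs)*sum(rf)."""
    w = basis.compose({7: 0.06})
    h = compute_psf(w, system, basis.pupil_mask)
    hs = effective_psf(h, h, system)
    img = render_image(hs, system.sample_image, system)
    k, m = system.kernel_size, system.padded_size
    c, half = m // 2, k // 2
    kern_sum = hs.intensity[c - half:c + half + 1, c - half:c + half + 1].sum()
    assert img.sum() == pytest.approx(kern_sum * system.sample_image.sum(),
                                      rel=1e-6)


def test_metric_basics():
    assert sharpness_metric(np.zeros((8, 8))) == 0.0
    img = np.random.default_rng(0).random((16, 16))
    assert sharpness_metric(3.0 * img) == pytest.approx(9.0 * sharpness_metric(img), rel=1e-12)
    with pytest.raises(ValueError):
        sharpness_metric(img - 1.0)


def test_metric_maximal_at_zero_aberration(system, basis):
    """The flat wavefront beats every single-mode offset of +-0.05 um."""
    full = system.make_basis(range(4, 16))
    m0 = system.metric_for_coeffs(np.zeros(12), full)
    for p in range(12):
        for sign in (-1, 1):
            c = np.zeros(12)
            c[p] = sign * 0.05
            assert system.metric_for_coeffs(c, full) < m0


def test_metric_reflection_symmetry(system, basis):
    """For a flat underlying wavefront, +b and -b probes of the same mode
    give equal metrics (pupil-conjugation / Fourier reflection symmetry)."""
    full = system.make_basis(range(4, 16))
    for p in (0, 1, 4):
        cp, cn = np.zeros(12), np.zeros(12)
        cp[p], cn[p] = 0.5, -0.5
        a = system.metric_for_coeffs(cp, full)
        b = system.metric_for_coeffs(cn, full)
        assert abs(a - b) / a <= 1e-9


def test_metric_determinism(system, basis):
    c = np.linspace(-0.05, 0.05, basis.n_modes)
    assert (system.metric_for_coeffs(c, basis)
            == system.metric_for_coeffs(c.copy(), basis))


def test_mode_scaling_conventions(system):
    """Peak scaling weakens every mode's optical effect relative to Noll
    scaling (peak amplitude of a Noll map exceeds its RMS of 1)."""
    b = system.make_basis(range(4, 16))
    scale = system.coeff_scale(b)
    assert np.all(scale < 1.0)
    noll = SystemModel(sample_image=system.sample_image, mode_scaling="noll")
    assert np.all(noll.coeff_scale(b) == 1.0)
    c = np.r_[0.1, np.zeros(11)]
    m_peak = system.metric_for_coeffs(c, b) / system.metric_for_coeffs(np.zeros(12), b)
    m_noll = noll.metric_for_coeffs(c, b) / noll.metric_for_coeffs(np.zeros(12), b)
    assert m_peak > m_noll


def test_system_validation():
    good = np.ones((64, 64))
    with pytest.raises(ValueError):
        SystemModel(wavelength=0.0, sample_image=good)
    with pytest.raises(ValueError):
        SystemModel(fiber_diameter=-1.0, sample_image=good)
    with pytest.raises(ValueError):
        SystemModel(sample_image=np.zeros((64, 64)))
    with pytest.raises(ValueError):
        SystemModel(sample_image=good, kernel_size=32)
    with pytest.raises(ValueError):
        SystemModel(sample_image=good, pupil_radius=200, grid_size=256)
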