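"""Dose convolution, detector volume averaging and profile metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.signal import convolve2d
from scipy.special import erf

from planedose import (DetectorResponse, FluenceGrid, KernelParams, Profile,
                       apply_detector_response, convolve_dose,
                       convolve_dose_separable, extract_profile,
                       penumbra_width, symmetric_axis)
from planedose.dose import sampled_kernel


def narrow_kernel(sigma=0.2241):
    """Effectively single-Gaussian kernel (two negligible companions)."""
    return KernelParams(((1.0, sigma), (1e-12, sigma * 2), (1e-12, sigma * 3)))


def test_impulse_reproduces_sampled_kernel(m6fff):
    n = 121
    v = np.zeros((n, n))
    v[n // 2, n // 2] = 1.0
    flu = FluenceGrid(v, spacing=0.1)
    dz = convolve_dose(flu, m6fff.kernel)
    k = sampled_kernel(m6fff.kernel, 0.1)
    m = k.shape[0] // 2
    assert np.argmax(dz.values) == np.ravel_multi_index((n // 2, n // 2), (n, n))
    np.testing.assert_allclose(
        dz.values[n // 2 - 5:n // 2 + 6, n // 2 - 5:n // 2 + 6],
        k[m - 5:m + 6, m - 5:m + 6] * 0.1**2, rtol=1e-12)


def test_uniform_fluence_scales_by_kernel_weight(m6fff):
    n = 601   # interior far from edges relative to 3*sigma_max
    flu = FluenceGrid(np.full((n, n), 2.0), spacing=0.1)
    dz = convolve_dose(flu, m6fff.kernel)
    assert dz.values[n // 2, n // 2] == pytest.approx(
        2.0 * m6fff.kernel.total_weight, rel=1e-4)


def test_gaussian_through_gaussian_kernel_widens_in_quadrature():
    ax = symmetric_axis(6, 0.1)
    sf, s0 = 0.8, 0.2241
    xx, yy = np.meshgrid(ax, ax)
    flu = FluenceGrid(np.exp(-(xx**2 + yy**2) / (2 * sf**2)), spacing=0.1)
    dz = convolve_dose(flu, narrow_kernel(s0))
    prof = extract_profile(dz, "x", normalize=False)
    s_out = np.sqrt(np.sum(prof.values * prof.positions**2)
                    / np.sum(prof.values))
    assert s_out == pytest.approx(np.sqrt(sf**2 + s0**2), abs=1e-4)


def test_fft_convolution_matches_direct_summation(m6fff):
    rng = np.random.default_rng(7)
    v = rng.random((64, 64))
    flu = FluenceGrid(v, spacing=0.1)
    dz = convolve_dose(flu, m6fff.kernel)
    k = sampled_kernel(m6fff.kernel, 0.1)
    direct = convolve2d(v, k, mode="same") * 0.1**2
    np.testing.assert_allclose(dz.values, direct, atol=1e-10)


def test_convolution_translation_equivariance(m6fff):
    n = 101
    a = np.zeros((n, n)); a[40, 30] = 1.0
    b = np.zeros((n, n)); b[50, 45] = 1.0
    da = convolve_dose(FluenceGrid(a, spacing=0.1), m6fff.kernel).values
    db = convolve_dose(FluenceGrid(b, spacing=0.1), m6fff.kernel).values
    np.testing.assert_allclose(da[30:50, 20:40], db[40:60, 35:55], atol=1e-12)


def test_mirrored_fluence_gives_mirrored_dose(m6fff):
    rng = np.random.default_rng(3)
    v = rng.random((41, 41))
    da = convolve_dose(FluenceGrid(v, spacing=0.1), m6fff.kernel).values
    db = convolve_dose(FluenceGrid(v[:, ::-1], spacing=0.1), m6fff.kernel).values
    np.testing.assert_allclose(db, da[:, ::-1], atol=1e-14)


def test_padding_diagnostics(m6fff):
    flu = FluenceGrid(np.ones((51, 51)), spacing=0.1)
    with pytest.raises(ValueError, match="padding"):
        convolve_dose(flu, m6fff.kernel, check_padding=True)
    with pytest.raises(ValueError, match="radius_factor"):
        convolve_dose(flu, m6fff.kernel, radius_factor=2.0)
    with pytest.raises(ValueError, match="spacing"):
        convolve_dose(FluenceGrid(np.ones((5, 5)), spacing=0.2), m6fff.kernel)


def test_separable_path_matches_fft_path(m6fff):
    rng = np.random.default_rng(11)
    flu = FluenceGrid(rng.random((81, 81)), spacing=0.1)
    a = convolve_dose(flu, m6fff.kernel, radius_factor=5.0).values
    b = convolve_dose_separable(flu, m6fff.kernel, truncate=5.0).values
    np.testing.assert_allclose(a, b, atol=2e-4)


# ---------------------------------------------------------------------------
# detector response


def step_profile(n=401, spacing=0.05, edge=0.0):
    pos = symmetric_axis((n - 1) / 2 * spacing, spacing)
    return Profile(pos, (pos < edge).astype(float) + 0.0, "x")


def test_zero_sigma_is_identity():
    p = step_profile()
    q = apply_detector_response(p, DetectorResponse(0.0))
    np.testing.assert_array_equal(q.values, p.values)


def test_step_edge_becomes_erf_with_known_penumbra():
    sigma = 0.2
    pos = symmetric_axis(5, 0.02)
    vals = (pos < 2.0).astype(float)
    q = apply_detector_response(Profile(pos, vals, "x"), DetectorResponse(sigma))
    # closed form: 20-80% distance of an erf edge = 2 * 0.8416 * sigma
    w = penumbra_width(q, "right")
    assert w == pytest.approx(2 * 0.841621 * sigma, abs=1e-3)
    # discrete edge midpoint sits half a sample before 2.0; compare in the
    # interior (zero padding distorts the first/last few sigma of the array)
    expected = 0.5 * (1 - erf((pos - 1.99) / (np.sqrt(2) * sigma)))
    interior = np.abs(pos) < 3.5
    np.testing.assert_allclose(q.values[interior], expected[interior], atol=2e-3)


def test_detector_convolution_conserves_area():
    pos = symmetric_axis(8, 0.05)
    vals = np.exp(-pos**2 / 2.0) * (np.abs(pos) < 5)
    q = apply_detector_response(Profile(pos, vals, "x"), DetectorResponse(0.3))
    assert np.trapezoid(q.values, pos) == pytest.approx(
        np.trapezoid(vals, pos), rel=1e-6)


def test_non_uniform_sampling_rejected():
    p = Profile(np.array([0.0, 1.0, 2.5]), np.array([1.0, 1.0, 1.0]), "x")
    with pytest.raises(ValueError, match="uniform"):
        apply_detector_response(p, DetectorResponse(0.2))


# ---------------------------------------------------------------------------
# profiles and penumbra


@pytest.fixture(scope="module")
def square_dose(m6fff):
    from planedose import rect_field_segment, segment_fluence
    seg = rect_field_segment(10, 10)
    ax = symmetric_axis(9, 0.1)
    flu = segment_fluence(m6fff, seg, ax, ax)
    return convolve_dose(flu, m6fff.kernel)


def test_symmetric_field_has_equal_penumbras(square_dose):
    prof = extract_profile(square_dose, "x")
    assert penumbra_width(prof, "left") == pytest.approx(
        penumbra_width(prof, "right"), abs=1e-6)


def test_volume_averaging_broadens_penumbra(square_dose, det):
    prof = extract_profile(square_dose, "x")
    vae = apply_detector_response(prof, det)
    for edge in ("left", "right"):
        assert penumbra_width(vae, edge) > penumbra_width(prof, edge)


def test_missing_edge_diagnostic():
    pos = symmetric_axis(2, 0.1)
    flat = Profile(pos, np.ones_like(pos), "x")
    with pytest.raises(ValueError, match="crossing"):
        penumbra_width(flat, "left")


def test_step_fluence_penumbra_matches_closed_form_oracle(m6fff):
    # edge response of an isotropic Gaussian mixture to a half-plane step is
    # a sum of erf terms; its 20-80% width is the penumbra the discrete
    # convolution must reproduce
    ax = symmetric_axis(12, 0.1)
    xx, _ = np.meshgrid(ax, ax)
    # edge at +3 cm so the central axis sits on the plateau
    flu = FluenceGrid((xx < 3.0).astype(float), spacing=0.1)
    dz = convolve_dose(flu, m6fff.kernel)
    prof = extract_profile(dz, "x", normalize=False)
    plateau = float(prof.value_at(0.0))
    p = Profile(prof.positions, prof.values / plateau, "x")
    total = m6fff.kernel.total_weight

    def edge(x):
        return sum(a / 2 * (1 - erf(x / (np.sqrt(2) * s)))
                   for a, s in m6fff.kernel.components) / total

    ref = edge(-3.0)   # plateau level of the analytic edge response at the CAX
    x20 = brentq(lambda x: edge(x) / ref - 0.2, -5, 5)
    x80 = brentq(lambda x: edge(x) / ref - 0.8, -5, 5)
    assert penumbra_width(p, "right") == pytest.approx(abs(x20 - x80), abs=0.01)
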