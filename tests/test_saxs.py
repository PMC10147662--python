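import math

import numpy as np
import pytest

from astatools import synthetic
from astatools.saxs import (SAXSCurve, SAXSError, chi2_fit, debye_intensity,
                            dimensionless_kratky, guinier_fit,
                            mw_from_porod_volume, mw_from_vc, porod_volume,
                            read_dat, sphere_form_factor,
                            volume_of_correlation)


def sphere_curve(radius=2.0, s_max=15.0, n=3000, i0=1.0):
    _, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="sphere", radius=radius, i0=i0, noise_fraction=0.0,
        s_min=0.02, s_max=s_max, n_points=n))
    return clean


# --- reading --------------------------------------------------------------

def test_read_three_column_text():
    text = ("# header comment\nSample: whatever\n"
            + "\n".join(f"{0.1 * k:.2f} {math.exp(-k):.5f} 0.01"
                        for k in range(1, 6)))
    curve = read_dat(text, unit="nm^-1")
    assert len(curve) == 5
    assert curve.sigma is not None


def test_two_column_theoretical_curve():
    curve = read_dat("0.1 1.0\n0.2 0.9\n0.3 0.7\n", unit="nm^-1")
    assert curve.sigma is None


def test_non_monotonic_s_rejected():
    with pytest.raises(SAXSError, match="strictly increasing"):
        read_dat("0.2 1.0 0.1\n0.1 0.9 0.1\n0.3 0.8 0.1\n", unit="nm^-1")


# --- Guinier --------------------------------------------------------------

def test_gaussian_curve_recovers_rg_exactly():
    _, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.0, s_max=2.0))
    result = guinier_fit(clean)
    assert result.rg == pytest.approx(2.0, rel=1e-6)
    assert result.i0 == pytest.approx(1.0, rel=1e-6)
    assert result.srg_limits[1] <= 1.3 + 1e-9


def test_sphere_rg_matches_closed_form():
    result = guinier_fit(sphere_curve(radius=2.58, s_max=1.0), srg_max=0.5)
    assert result.rg == pytest.approx(math.sqrt(3.0 / 5.0) * 2.58,
                                      rel=5e-3)


def test_noisy_guinier_recovery_within_two_percent():
    noisy, _ = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.01, s_max=2.0, seed=7))
    assert guinier_fit(noisy).rg == pytest.approx(2.0, rel=0.02)


def test_rising_curve_has_no_guinier_decay():
    s = np.linspace(0.05, 1.0, 50)
    with pytest.raises(SAXSError, match="decay"):
        guinier_fit(SAXSCurve(s, np.exp(s ** 2), None, "nm^-1"))


# --- Kratky ---------------------------------------------------------------

def test_kratky_gaussian_peaks_at_reference_point():
    _, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.0, s_min=0.01,
        s_max=2.5, n_points=2000))
    g = guinier_fit(clean)
    x, y = dimensionless_kratky(clean, g)
    peak = np.argmax(y)
    assert x[peak] == pytest.approx(math.sqrt(3.0), abs=0.01)
    assert y[peak] == pytest.approx(3.0 / math.e, abs=0.01)


def test_kratky_sphere_bell_near_reference():
    clean = sphere_curve(radius=2.0, s_max=3.0)
    g = guinier_fit(clean, srg_max=0.5)
    x, y = dimensionless_kratky(clean, g)
    first = y[x < 3.0]
    peak = np.argmax(first)
    # compact globule: bell shape with its maximum near the rigid-sphere
    # reference marker (exact sphere peak sits at sRg ≈ 1.61)
    assert x[peak] == pytest.approx(math.sqrt(3.0), abs=0.15)
    assert first[peak] > first[0] and first[peak] > first[-1]


def test_kratky_flexible_chain_rises_without_bell():
    # Debye polymer scattering: I/I0 = 2(e^-x - 1 + x)/x², x = (sRg)²
    s = np.linspace(0.01, 4.0, 800)
    rg = 2.0
    x2 = (s * rg) ** 2
    i = 2.0 * (np.exp(-x2) - 1.0 + x2) / x2 ** 2
    curve = SAXSCurve(s, i, None, "nm^-1")
    g = guinier_fit(curve, srg_max=0.5)
    xs, ys = dimensionless_kratky(curve, g)
    # monotonic rise onto a plateau, no interior maximum
    assert np.all(np.diff(ys) > -1e-9)


# --- Porod / Mw -----------------------------------------------------------

def test_porod_volume_of_sphere_within_five_percent():
    clean = sphere_curve(radius=2.0)
    g = guinier_fit(clean, srg_max=0.6)
    report = porod_volume(clean, g)
    true_volume = 4.0 / 3.0 * math.pi * 2.0 ** 3
    assert report.porod_volume == pytest.approx(true_volume, rel=0.05)


def test_porod_volume_invariant_to_intensity_scale():
    one = sphere_curve(radius=2.0, i0=1.0)
    two = sphere_curve(radius=2.0, i0=13.7)
    v1 = porod_volume(one, guinier_fit(one, srg_max=0.6)).porod_volume
    v2 = porod_volume(two, guinier_fit(two, srg_max=0.6)).porod_volume
    assert v1 == pytest.approx(v2, rel=1e-6)


@pytest.mark.parametrize("vp,expected", [(38.1, 23.8), (40.8, 25.5),
                                         (1.6, 1.0)])
def test_porod_mass_estimator(vp, expected):
    assert round(mw_from_porod_volume(vp), 1) == expected


def test_vc_mass_estimator_consistency():
    clean = sphere_curve(radius=2.58, s_max=3.0)
    g = guinier_fit(clean, srg_max=0.6)
    vc = volume_of_correlation(clean, g)
    # formula identity: Mw[kDa] = (Vc²/Rg)[nm³]/0.1231
    assert mw_from_vc(vc, g.rg) == pytest.approx(vc ** 2 / g.rg / 0.1231)
    assert vc > 0


# --- Debye ----------------------------------------------------------------

def test_single_scatterer_is_flat():
    s = np.linspace(0.1, 5.0, 20)
    curve = debye_intensity((np.zeros((1, 3)), np.array([3.0])), s)
    np.testing.assert_allclose(curve.intensity, 9.0)


def test_two_point_closed_form_exact():
    s = np.linspace(0.1, 5.0, 100)
    d_nm = 0.2  # atoms 2 Å apart
    curve = debye_intensity(
        (np.array([[0.0, 0, 0], [0, 0, 2.0]]), np.ones(2)), s)
    expected = 2.0 * (1.0 + np.sin(s * d_nm) / (s * d_nm))
    np.testing.assert_allclose(curve.intensity, expected, atol=1e-12)


def test_intensity_at_zero_angle_is_total_electrons_squared():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(40, 3)) * 5.0
    f = rng.uniform(1.0, 8.0, 40)
    curve = debye_intensity((coords, f), np.array([1e-8, 0.1]))
    assert curve.intensity[0] == pytest.approx(f.sum() ** 2, rel=1e-9)


def test_symmetric_under_atom_reordering():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(30, 3)) * 5.0
    f = rng.uniform(1.0, 8.0, 30)
    s = np.linspace(0.1, 3.0, 40)
    perm = rng.permutation(30)
    a = debye_intensity((coords, f), s)
    b = debye_intensity((coords[perm], f[perm]), s)
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)


def test_sphere_point_cloud_matches_analytic_form_factor():
    rng = np.random.default_rng(5)
    n = 4000
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= 20.0 * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)  # R = 2 nm
    s = np.linspace(0.05, 2.5, 60)  # sR up to 5
    curve = debye_intensity((pts, np.ones(n)), s)
    analytic = sphere_form_factor(s, 2.0, curve.intensity[0])
    assert np.max(np.abs(curve.intensity - analytic)
                  / curve.intensity[0]) < 0.02


def test_binned_histogram_path_agrees_with_exact_sum():
    rng = np.random.default_rng(6)
    coords = rng.normal(size=(300, 3)) * 10.0
    f = rng.uniform(1.0, 8.0, 300)
    s = np.linspace(0.05, 3.0, 50)
    exact = debye_intensity((coords, f), s)
    # independent histogram evaluation of the same double sum
    d_max = float(np.linalg.norm(coords.max(0) - coords.min(0))) + 1e-9
    from scipy.spatial.distance import pdist
    d = pdist(coords * 0.1)
    w = (f[:, None] * f[None, :])[np.triu_indices(300, k=1)]
    edges = np.linspace(0.0, d_max * 0.1, 20000)
    hist, _ = np.histogram(d, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = hist > 0
    approx = (f ** 2).sum() + 2.0 * (
        np.sinc(np.outer(s, centers[keep]) / np.pi) @ hist[keep])
    np.testing.assert_allclose(exact.intensity, approx, rtol=2e-3)


def test_empty_model_rejected():
    with pytest.raises(ValueError, match="empty"):
        debye_intensity((np.empty((0, 3)), np.empty(0)),
                        np.array([0.1, 0.2]))


# --- chi² fitting ---------------------------------------------------------

def test_scaled_noiseless_data_fit_perfectly():
    _, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.0))
    exp = SAXSCurve(clean.s, 2.0 * clean.intensity,
                    np.ones(len(clean)), "nm^-1")
    fit = chi2_fit(clean, exp)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
    assert fit.scale == pytest.approx(2.0)


def test_chi2_of_self_noise_is_near_one():
    noisy, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.0, noise_floor=1e-3,
        n_points=500, seed=11))
    assert chi2_fit(clean, noisy).chi2 == pytest.approx(1.0, abs=0.15)


def test_chi2_invariant_when_sigma_and_residuals_scale_together():
    noisy, clean = synthetic.make_curve(synthetic.CurveSpec(
        body="gaussian", rg=2.0, noise_fraction=0.0, noise_floor=1e-3,
        n_points=200, seed=3))
    base = chi2_fit(clean, noisy).chi2
    resid = noisy.intensity - clean.intensity
    scaled = SAXSCurve(noisy.s, clean.intensity + 5.0 * resid,
                       5.0 * noisy.sigma, "nm^-1")
    assert chi2_fit(clean, scaled).chi2 == pytest.approx(base, rel=1e-9)


def test_non_overlapping_grids_rejected():
    a = SAXSCurve(np.linspace(0.1, 1.0, 10), np.ones(10), None, "nm^-1")
    b = SAXSCurve(np.linspace(2.0, 3.0, 10), np.ones(10),
                  np.ones(10), "nm^-1")
    with pytest.raises(SAXSError, match="cover"):
        chi2_fit(a, b)


def test_true_model_beats_decoy_with_larger_rg():
    """Model discrimination: data simulated from a compact globule must
    prefer it over an inflated decoy (ΔRg > 0.2 nm)."""
    rng = np.random.default_rng(2)
    n = 300
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= 25.8 * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)  # Rg ≈ 2 nm
    decoy = pts * (29.0 / 25.8)  # Rg ≈ +0.25 nm
    s = np.linspace(0.05, 3.0, 200)
    truth = debye_intensity((pts, np.ones(n)), s)
    i = truth.intensity / truth.intensity[0]
    sigma = 0.02 * i + 1e-4
    experiment = SAXSCurve(s, i + rng.normal(size=len(s)) * sigma, sigma,
                           "nm^-1")
    chi_true = chi2_fit(truth, experiment).chi2
    chi_decoy = chi2_fit(debye_intensity((decoy, np.ones(n)), s),
                         experiment).chi2
    assert chi_true < 2.0
    assert chi_decoy > 5.0 * chi_true


def test_unit_conversion_angstrom_to_nm():
    curve = SAXSCurve(np.array([0.01, 0.02, 0.03]), np.ones(3), None,
                      "A^-1")
    nm = curve.in_nm()
    np.testing.assert_allclose(nm.s, [0.1, 0.2, 0.3])
    with pytest.raises(SAXSError, match="unknown unit"):
        SAXSCurve(np.array([0.1, 0.2]), np.ones(2), None, "furlong").in_nm()
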