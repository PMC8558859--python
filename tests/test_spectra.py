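"""Unit conversions, broadened spectra, lambda_max, shifts, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sitekit as sk
from sitekit.spectra import VibronicProfile, default_grid


# -------------------------------------------------------------- conversions


def test_ev_nm_tabulated_transition():
    # 2.541 eV corresponds to the 487.9 nm transition wavelength
    assert sk.ev_nm_convert(2.541) == pytest.approx(487.9, abs=0.05)


def test_ev_nm_definition_point():
    assert sk.ev_nm_convert(1239.84193) == pytest.approx(1.0, rel=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=2000.0, allow_nan=False))
def test_ev_nm_involution(x):
    assert sk.ev_nm_convert(sk.ev_nm_convert(x)) == pytest.approx(x, rel=1e-12)


def test_ev_nm_rejects_nonpositive():
    with pytest.raises(ValueError):
        sk.ev_nm_convert(0.0)


# --------------------------------------------------------- Gaussian spectra


def test_single_snapshot_peak_position():
    spec = sk.gaussian_spectrum([2.567], sigma=0.15)
    peak_ev = spec.grid_ev[np.argmax(spec.intensity)]
    assert peak_ev == pytest.approx(2.567, abs=0.001)
    assert spec.lambda_max_nm == pytest.approx(sk.ev_nm_convert(2.567), abs=0.3)


def test_identical_snapshots_match_single():
    one = sk.gaussian_spectrum([2.5], sigma=0.1)
    many = sk.gaussian_spectrum([2.5] * 50, sigma=0.1)
    np.testing.assert_allclose(one.intensity, many.intensity, atol=1e-12)


def test_gaussian_area_is_unity():
    e = sk.generate_snapshot_energies(2.6, 0.1, 200, seed=1)
    assert sk.gaussian_spectrum(e, sigma=0.15).area() == pytest.approx(1.0, abs=1e-6)


def test_gaussian_convolution_width():
    """Normal snapshot scatter s convolved with width sigma gives a
    spectrum of variance s^2 + sigma^2 (1 % check at large N)."""
    e = sk.generate_snapshot_energies(2.6, 0.2, 100_000, seed=2)
    spec = sk.gaussian_spectrum(e, sigma=0.15)
    w = spec.intensity / np.trapezoid(spec.intensity, spec.grid_ev)
    mu = np.trapezoid(w * spec.grid_ev, spec.grid_ev)
    var = np.trapezoid(w * (spec.grid_ev - mu) ** 2, spec.grid_ev)
    assert np.sqrt(var) == pytest.approx(np.sqrt(0.2**2 + 0.15**2), rel=0.01)


def test_gaussian_rejects_empty_or_bad_sigma():
    with pytest.raises(ValueError):
        sk.gaussian_spectrum([], sigma=0.15)
    with pytest.raises(ValueError):
        sk.gaussian_spectrum([2.5], sigma=0.0)


# --------------------------------------------------------- vibronic spectra


def test_vibronic_single_line_reduces_to_gaussian():
    e = sk.generate_snapshot_energies(2.55, 0.12, 300, seed=3)
    g = sk.gaussian_spectrum(e, sigma=0.15)
    v = sk.vibronic_spectrum(e, VibronicProfile.single_line(0.15))
    np.testing.assert_array_equal(g.intensity, v.intensity)


def test_vibronic_two_line_profile_peak_structure():
    """A 0.7/0.3 two-line profile on one snapshot gives two narrow peaks
    0.18 eV apart with 7:3 heights."""
    prof = VibronicProfile(np.array([0.0, 0.18]), np.array([0.7, 0.3]), width=0.005)
    spec = sk.vibronic_spectrum([2.5], prof)
    i0 = np.argmin(np.abs(spec.grid_ev - 2.5))
    i1 = np.argmin(np.abs(spec.grid_ev - 2.68))
    assert spec.intensity[i0] == pytest.approx(spec.intensity.max(), rel=1e-6)
    assert spec.intensity[i1] / spec.intensity[i0] == pytest.approx(3 / 7, rel=0.01)


def test_vibronic_area_is_unity():
    e = sk.generate_snapshot_energies(2.55, 0.1, 100, seed=4)
    v = sk.vibronic_spectrum(e, VibronicProfile.default())
    assert v.area() == pytest.approx(1.0, abs=1e-6)


def test_vibronic_matches_gaussian_under_strong_smearing():
    """When the snapshot scatter dwarfs the progression spacing, the
    vibronic spectrum agrees with a mean/variance-matched Gaussian one
    within 2 % sup-norm."""
    prof = VibronicProfile.default()
    mean_off = float((prof.intensities * prof.offsets).sum())
    var_off = float((prof.intensities * (prof.offsets - mean_off) ** 2).sum())
    e = sk.generate_snapshot_energies(2.567, 0.4, 50_000, seed=5)
    v = sk.vibronic_spectrum(e, prof)
    g = sk.gaussian_spectrum(e + mean_off, sigma=np.sqrt(prof.width**2 + var_off))
    rel = np.abs(v.intensity - g.intensity).max() / v.intensity.max()
    assert rel < 0.02


def test_profile_validation():
    with pytest.raises(ValueError):
        VibronicProfile(np.array([0.1, 0.2]), np.array([0.5, 0.5]))  # no 0-0 line
    with pytest.raises(ValueError):
        VibronicProfile(np.array([0.0]), np.array([1.0]), width=0.0)


def test_profile_file_roundtrip(tmp_path):
    prof = VibronicProfile.default()
    path = tmp_path / "profile.txt"
    prof.to_file(path)
    back = VibronicProfile.from_file(path)
    np.testing.assert_allclose(back.offsets, prof.offsets, atol=1e-9)
    np.testing.assert_allclose(back.intensities, prof.intensities, atol=1e-9)


def test_snapshot_count_convergence_rate():
    """Sup-norm distance to the limiting spectrum shrinks like N^{-1/2}."""
    rng = np.random.default_rng(6)
    grid = default_grid(2.0, 3.2, 0.002)

    def dist(n, seed):
        e1 = 2.6 + 0.15 * np.random.default_rng(seed).standard_normal(n)
        e2 = 2.6 + 0.15 * np.random.default_rng(seed + 1000).standard_normal(n)
        a = sk.gaussian_spectrum(e1, 0.1, grid).intensity
        b = sk.gaussian_spectrum(e2, 0.1, grid).intensity
        return np.abs(a - b).max()

    d_small = np.mean([dist(500, s) for s in range(8)])
    d_large = np.mean([dist(8000, s) for s in range(8)])
    ratio = d_small / d_large
    assert 2.0 < ratio < 8.0  # ideal sqrt(16) = 4


# ---------------------------------------------------------------- lambda_max


def test_lambda_max_anchor_value():
    spec = sk.gaussian_spectrum([sk.ev_nm_convert(502.0)], sigma=0.1)
    assert sk.lambda_max(spec) == pytest.approx(502.0, abs=0.3)


def test_lambda_max_tie_breaks_to_longer_wavelength():
    grid = np.linspace(2.0, 3.0, 101)
    flat = sk.SpectrumResult(grid, np.ones_like(grid), "gaussian", 1)
    assert flat.tie_broken
    assert flat.lambda_max_nm == pytest.approx(sk.ev_nm_convert(2.0))


def test_lambda_max_symmetric_two_peak():
    grid = np.linspace(2.0, 3.0, 1001)
    inten = np.exp(-0.5 * ((grid - 2.2) / 0.02) ** 2) + np.exp(
        -0.5 * ((grid - 2.8) / 0.02) ** 2
    )
    spec = sk.SpectrumResult(grid, inten, "gaussian", 1)
    assert spec.lambda_max_nm == pytest.approx(sk.ev_nm_convert(2.2), abs=0.5)


def test_lambda_max_invariant_under_rescaling():
    e = sk.generate_snapshot_energies(2.5, 0.1, 50, seed=7)
    spec = sk.gaussian_spectrum(e, 0.15)
    scaled = sk.SpectrumResult(spec.grid_ev, 10.0 * spec.intensity, "gaussian", 50)
    assert scaled.lambda_max_nm == spec.lambda_max_nm


# ------------------------------------------------------------ shift analysis


def test_shift_water_discrepancy():
    # simulated 483 nm vs measured 470 nm -> 0.07 eV
    _, de = sk.shift_analysis(483.0, 470.0)
    assert de == pytest.approx(0.07, abs=0.005)


def test_shift_protein_discrepancy():
    # simulated 502 nm, 33 nm blue shift -> 0.15 eV
    dl, de = sk.shift_analysis(502.0, 502.0 + 33.0)
    assert dl == pytest.approx(33.0)
    assert de == pytest.approx(0.15, abs=0.005)


def test_shift_identity_and_antisymmetry():
    assert sk.shift_analysis(480.0, 480.0) == (0.0, 0.0)
    d1, e1 = sk.shift_analysis(480.0, 500.0)
    d2, e2 = sk.shift_analysis(500.0, 480.0)
    assert d1 == -d2 and e1 == e2


def test_shift_rejects_nonpositive():
    with pytest.raises(ValueError):
        sk.shift_analysis(-1.0, 480.0)


# --------------------------------------------------------- conformer average


def test_conformer_average_degenerate_weights():
    e = sk.generate_snapshot_energies(2.5, 0.1, 40, seed=8)
    a = sk.gaussian_spectrum(e, 0.15)
    b = sk.gaussian_spectrum(e + 0.1, 0.15)
    avg = sk.conformer_average([a, b], [1.0, 0.0])
    np.testing.assert_array_equal(avg.intensity, a.intensity)


def test_conformer_average_identical_spectra_unchanged():
    e = sk.generate_snapshot_energies(2.5, 0.1, 40, seed=9)
    a = sk.gaussian_spectrum(e, 0.15)
    avg = sk.conformer_average([a, a], [0.3, 0.7])
    np.testing.assert_allclose(avg.intensity, a.intensity, atol=1e-12)


def test_conformer_average_mixture_bounds_lambda_max():
    """Equal-weight mixture of conformer bands at 485/480 nm peaks
    between the two (the combined solution band sits at ~483 nm)."""
    cis = sk.gaussian_spectrum([sk.ev_nm_convert(485.0)], sigma=0.15)
    trans = sk.gaussian_spectrum([sk.ev_nm_convert(480.0)], sigma=0.15)
    avg = sk.conformer_average([cis, trans], [0.5, 0.5])
    assert 480.0 <= avg.lambda_max_nm <= 485.0


def test_conformer_average_rejects_mismatched_grids():
    a = sk.gaussian_spectrum([2.5], 0.15, grid=np.linspace(2, 3, 100))
    b = sk.gaussian_spectrum([2.5], 0.15, grid=np.linspace(2, 3, 101))
    with pytest.raises(ValueError):
        sk.conformer_average([a, b], [0.5, 0.5])
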