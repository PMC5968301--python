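"""Spectrum I/O, preprocessing, QC and peak picking."""

import numpy as np
import pytest

from spectyper import spectra as sp
from spectyper import synthetic as syn


# ---------------------------------------------------------------------------
# I/O


def test_read_csv_direct_parse(tmp_path):
    f = tmp_path / "s.csv"
    f.write_text("1000,0\n2000,5\n3000,1\n")
    s = sp.read_spectrum(f, format="csv")
    assert len(s) == 3
    assert s.mz.tolist() == [1000.0, 2000.0, 3000.0]
    assert s.intensity.tolist() == [0.0, 5.0, 1.0]


def test_read_csv_sort_invariance(tmp_path):
    a = tmp_path / "sorted.csv"
    a.write_text("mz,intensity\n1000,1\n2000,5\n3000,2\n")
    b = tmp_path / "shuffled.tsv"
    b.write_text("3000\t2\n1000\t1\n2000\t5\n")
    sa = sp.read_spectrum(a)
    sb = sp.read_spectrum(b)
    np.testing.assert_array_equal(sa.mz, sb.mz)
    np.testing.assert_array_equal(sa.intensity, sb.intensity)


def test_read_csv_errors(tmp_path):
    with pytest.raises(IOError):
        sp.read_spectrum(tmp_path / "absent.csv")
    bad = tmp_path / "bad.csv"
    bad.write_text("1000,1\n2000,oops\n")
    with pytest.raises(sp.SpectrumFormatError, match="row 1"):
        sp.read_spectrum(bad)
    neg = tmp_path / "neg.csv"
    neg.write_text("1000,1\n2000,-4\n")
    with pytest.raises(sp.SpectrumFormatError, match="negative"):
        sp.read_spectrum(neg)


def test_mzml_round_trip(tmp_path, fingerprint, default_noise):
    rng = np.random.default_rng(3)
    spectra = [
        syn.simulate_spectrum(fingerprint, default_noise, rng,
                              isolate_id="iso1", replicate_id=f"rep{i}",
                              acquisition_index=i + 1)
        for i in range(3)
    ]
    path = tmp_path / "iso1.mzML"
    sp.write_mzml(spectra, path)
    back = sp.read_mzml(path)
    assert len(back) == 3
    for orig, rt in zip(spectra, back):
        np.testing.assert_array_equal(orig.mz, rt.mz)
        np.testing.assert_array_equal(orig.intensity, rt.intensity)
        assert rt.isolate_id == "iso1"
        assert rt.acquisition_index == orig.acquisition_index


def test_rawspectrum_invariants():
    with pytest.raises(ValueError):
        sp.RawSpectrum(np.array([1.0, 1.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        sp.RawSpectrum(np.array([1.0, 2.0]), np.array([0.0, -1.0]))


# ---------------------------------------------------------------------------
# Baseline subtraction


def test_baseline_removes_constant():
    grid = np.arange(0.0, 500.0)
    s = sp.RawSpectrum(grid, np.full_like(grid, 7.5))
    out = sp.subtract_baseline(s, half_window=20)
    np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)
    np.testing.assert_array_equal(out.mz, s.mz)


def test_baseline_zero_idempotent():
    grid = np.arange(0.0, 200.0)
    s = sp.RawSpectrum(grid, np.zeros_like(grid))
    out = sp.subtract_baseline(s, half_window=10)
    np.testing.assert_array_equal(out.intensity, 0.0)


def test_baseline_preserves_peak_area_on_ramp():
    grid = np.arange(0.0, 2000.0)
    sigma, amp, center = 4.0, 10.0, 1000.0
    peak = amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    true_area = peak.sum()  # oracle: integrate before baseline addition
    ramp = 0.002 * grid + 1.0
    s = sp.RawSpectrum(grid, peak + ramp)
    out = sp.subtract_baseline(s, half_window=40)
    window = (grid > center - 6 * sigma) & (grid < center + 6 * sigma)
    recovered = out.intensity[window].sum()
    assert abs(recovered - true_area) / true_area < 0.05


def test_baseline_parameter_errors():
    s = sp.RawSpectrum(np.arange(10.0), np.ones(10))
    with pytest.raises(ValueError):
        sp.subtract_baseline(s, half_window=0)
    with pytest.raises(ValueError):
        sp.subtract_baseline(s, half_window=20)  # spectrum too short


# ---------------------------------------------------------------------------
# Smoothing


def test_smooth_reproduces_polynomials():
    grid = np.arange(0.0, 300.0)
    const = sp.smooth(sp.RawSpectrum(grid, np.full_like(grid, 3.3)))
    np.testing.assert_allclose(const.intensity, 3.3, atol=1e-9)
    line = sp.smooth(sp.RawSpectrum(grid, 0.5 * grid + 2), window=11, polyorder=1)
    np.testing.assert_allclose(line.intensity, 0.5 * grid + 2, rtol=1e-9)


def test_smooth_reduces_noise_variance():
    rng = np.random.default_rng(99)
    grid = np.arange(0.0, 400.0)
    ratios = []
    for _ in range(1000):
        noise = rng.normal(0, 1.0, size=grid.shape) + 10.0
        out = sp.smooth(sp.RawSpectrum(grid, np.maximum(noise, 0)))
        ratios.append(out.intensity.var() / noise.var())
    assert np.mean(ratios) < 1.0


def test_smooth_rejects_even_window():
    s = sp.RawSpectrum(np.arange(50.0), np.ones(50))
    with pytest.raises(ValueError):
        sp.smooth(s, window=10)


# ---------------------------------------------------------------------------
# QC


def _render(fp, noise, rng):
    return syn.simulate_spectrum(fp, noise, rng)


def test_qc_flat_line_on_zero_spectrum(fingerprint, default_noise):
    grid = np.arange(2000.0, 4000.0)
    zero = sp.RawSpectrum(grid, np.zeros_like(grid))
    rep = sp.qc_spectrum(zero, [zero])
    assert rep.flat_line
    assert rep.reason


def test_qc_accepts_consistent_replicates(fingerprint, default_noise):
    rng = np.random.default_rng(5)
    cohort = [_render(fingerprint, default_noise, rng) for _ in range(10)]
    rep = sp.qc_spectrum(cohort[0], cohort)
    assert not rep.flat_line
    assert not rep.outlier


def test_qc_flags_unrelated_species_as_outlier(fingerprint, default_noise):
    rng = np.random.default_rng(6)
    other_fp = syn.make_fingerprint(30, np.random.default_rng(777))
    cohort = [_render(fingerprint, default_noise, rng) for _ in range(9)]
    intruder = _render(other_fp, default_noise, rng)
    rep = sp.qc_spectrum(intruder, cohort + [intruder])
    assert rep.outlier
    # permutation invariance of the cohort
    rep2 = sp.qc_spectrum(intruder, [intruder] + cohort[::-1])
    assert rep2.outlier == rep.outlier and rep2.flat_line == rep.flat_line


def test_qc_empty_cohort_error(fingerprint, default_noise):
    s = _render(fingerprint, default_noise, np.random.default_rng(1))
    with pytest.raises(ValueError):
        sp.qc_spectrum(s, [])


# ---------------------------------------------------------------------------
# Peak picking


def test_detect_peaks_empty_on_zero_spectrum():
    grid = np.arange(2000.0, 3000.0)
    s = sp.RawSpectrum(grid, np.zeros_like(grid))
    assert len(sp.detect_peaks(s)) == 0


def test_detect_peaks_noise_free_exact(quiet_noise, rng):
    fp = syn.make_fingerprint(5, rng, occurrence_range=(1.0, 1.0))
    s = syn.simulate_spectrum(fp, quiet_noise)
    pl = sp.detect_peaks(s)
    assert len(pl) == 5
    # positions within one grid spacing of the generator's ground truth
    assert np.max(np.abs(pl.mz - fp.mz)) <= 1.0


def test_detect_peaks_snr_threshold(rng):
    grid = np.arange(2000.0, 6000.0)
    sigma = 3.0
    centers = [2500.0, 3200.0, 3900.0, 4600.0, 5300.0]
    amps = [1.0, 0.8, 0.6, 0.4, 0.004]  # last peak below snr x noise
    trace = np.zeros_like(grid)
    for c, a in zip(centers, amps):
        trace += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    noise_sd = 0.004
    trace += rng.normal(0, noise_sd, size=grid.shape)
    s = sp.smooth(sp.RawSpectrum(grid, np.maximum(trace, 0)))
    pl = sp.detect_peaks(s, snr=3.0, min_mz=2000, max_mz=6000)
    assert len(pl) == 4
    matched = [c for c in centers[:4] if np.min(np.abs(pl.mz - c)) <= 2.0]
    assert len(matched) == 4
    assert np.min(np.abs(pl.mz - centers[4])) > 2.0  # sub-threshold peak dropped


def test_detect_peaks_scale_invariant(fingerprint, default_noise):
    s = syn.simulate_spectrum(fingerprint, default_noise, np.random.default_rng(8))
    pl1 = sp.detect_peaks(s)
    scaled = sp.RawSpectrum(s.mz, s.intensity * 37.5)
    pl2 = sp.detect_peaks(scaled)
    np.testing.assert_array_equal(pl1.mz, pl2.mz)
    np.testing.assert_allclose(pl1.intensity, pl2.intensity, rtol=1e-12)


def test_preprocess_keeps_mz_axis(fingerprint, default_noise):
    s = syn.simulate_spectrum(fingerprint, default_noise, np.random.default_rng(9))
    cleaned = sp.subtract_baseline(sp.smooth(s))
    np.testing.assert_array_equal(cleaned.mz, s.mz)
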