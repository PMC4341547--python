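"""Spectra and burst detection on constructed fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstfield import analysis as A
from burstfield.integrator import (Grid, Protocol, Recording, Segment,
                                   constant_protocol)
from burstfield.params import default_parameters

FS = 250.0


def _recording_from_traces(traces, fs=FS, c=0.0):
    """Wrap (nt, ny, nx) data as a Recording for the analysis chain."""
    traces = np.asarray(traces, dtype=np.float32)
    nt = traces.shape[0]
    t = np.arange(nt) / fs
    prot = constant_protocol(c, nt / fs)
    return Recording(t=t, c=np.full(nt, c), fields={"h_e": traces,
                                                    "C_e": traces},
                     fs_hz=fs, grid=Grid(traces.shape[2], traces.shape[1]),
                     params=default_parameters(), protocol=prot, seed=0,
                     dt_ms=1000.0 / fs)


class TestWelch:
    def test_sine_peak_and_integrated_power(self):
        t = np.arange(0, 20.0, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = A.welch_psd(x, FS)
        assert psd.f[np.argmax(psd.density)] == pytest.approx(10.0, abs=psd.df)
        assert psd.total_power == pytest.approx(0.5, rel=0.02)

    def test_white_noise_flat_at_variance_over_nyquist(self, rng):
        x = 2.0 * rng.standard_normal(int(FS * 120))
        psd = A.welch_psd(x, FS)
        assert np.median(psd.density) == pytest.approx(4.0 / (FS / 2), rel=0.05)

    def test_constant_series_zero_after_detrend(self):
        psd = A.welch_psd(np.full(2000, 3.0), FS)
        assert psd.total_power == pytest.approx(0.0, abs=1e-20)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            A.welch_psd(np.zeros(100), FS)


class TestGridAverage:
    def test_normalised_variant_integrates_to_one(self, rng):
        data = rng.standard_normal((1500, 8, 8))
        rec = _recording_from_traces(data)
        psd = A.grid_average_psd(rec, (0.0, 6.0))
        assert np.sum(psd.density_normed) * psd.df == pytest.approx(1.0, abs=1e-6)

    def test_averaging_is_linear(self, rng):
        tr = rng.standard_normal(1500)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        rec = _recording_from_traces(data)
        avg = A.grid_average_psd(rec, (0.0, 6.0))
        single = A.welch_psd(tr, FS)
        assert np.allclose(avg.density, single.density, rtol=1e-5)

    def test_parseval_consistency(self, rng):
        """Integrated raw PSD ≈ variance of the detrended trace (±2 %)."""
        t = np.arange(0, 60.0, 1 / FS)
        tr = (np.sin(2 * np.pi * 9.0 * t) + 0.5 * rng.standard_normal(len(t)))
        data = np.tile(tr[:, None, None], (1, 8, 8))
        rec = _recording_from_traces(data)
        psd = A.grid_average_psd(rec, (0.0, 60.0))
        assert psd.total_power == pytest.approx(np.var(tr), rel=0.02)

    def test_power_ratio_scales_quadratically(self, rng):
        tr = rng.standard_normal(2600)
        data = np.concatenate([np.tile(tr[:1250, None, None], (1, 8, 8)),
                               np.tile(2.0 * tr[:1250, None, None], (1, 8, 8))])
        rec = _recording_from_traces(data)
        r = (A.grid_average_psd(rec, (5.0, 10.0)).total_power
             / A.grid_average_psd(rec, (0.0, 5.0)).total_power)
        assert r == pytest.approx(4.0, rel=1e-6)

    def test_identical_plateaus_ratio_one(self, rng):
        tr = rng.standard_normal(1250)
        data = np.tile(np.concatenate([tr, tr])[:, None, None], (1, 8, 8))
        rec = _recording_from_traces(data)
        assert (A.grid_average_psd(rec, (5.0, 10.0)).total_power
                / A.grid_average_psd(rec, (0.0, 5.0)).total_power
                ) == pytest.approx(1.0, rel=1e-6)


def _dips(dip_times, width_s=0.2, depth=0.29, fs=FS, dur=8.0):
    """Baseline 0.3 with Gaussian dips to 0.3 - depth (no saturation, so
    each dip has a unique deepest sample at its nominal time)."""
    t = np.arange(0, dur, 1 / fs)
    x = np.full_like(t, 0.3)
    if np.isscalar(depth):
        depth = [depth] * len(dip_times)
    for td, dp in zip(dip_times, depth):
        x -= dp * np.exp(-0.5 * ((t - td) / (width_s / 4)) ** 2)
    return t, x


class TestBurstDetection:
    def test_three_clean_dips(self):
        t, x = _dips([1.0, 3.2, 5.4])
        peaks = A.detect_burst_peaks(t, x)
        assert np.allclose(peaks, [1.0, 3.2, 5.4], atol=1 / FS)
        assert np.allclose(np.diff(peaks), [2.2, 2.2], atol=2 / FS)

    def test_double_dip_censored_to_single_peak(self):
        # two dips 0.5 s apart, the second shallower: the deeper one wins
        t, x = _dips([2.0, 2.5], depth=[0.29, 0.28])
        peaks = A.detect_burst_peaks(t, x)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(2.0, abs=1 / FS)

    def test_never_below_threshold_yields_no_peaks(self):
        t = np.arange(0, 5, 1 / FS)
        assert len(A.detect_burst_peaks(t, np.full_like(t, 0.2))) == 0

    def test_detection_idempotent_on_reconstruction(self):
        t, x = _dips([1.0, 2.1, 4.0, 6.5])
        peaks = A.detect_burst_peaks(t, x)
        # rebuild a signal dipping only at the retained peaks
        _, xr = _dips(peaks)
        again = A.detect_burst_peaks(t, xr)
        assert np.allclose(again, peaks, atol=1 / FS)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.02, 0.3))
    def test_threshold_regions_grow_monotonically(self, seed, thr):
        """Raising the threshold only extends or merges below-threshold
        regions: the covered sample set grows, and every region at the
        lower threshold lies inside a region at the higher one."""
        rng = np.random.default_rng(seed)
        x = np.cumsum(0.02 * rng.standard_normal(400)) + 0.15
        lo = x <= thr
        hi = x <= thr + 0.05
        assert np.all(hi[lo])                  # coverage is nested
        assert hi.sum() >= lo.sum()
        # detected peaks at the lower threshold remain below the higher
        t = np.arange(len(x)) / FS
        for pk in A.detect_burst_peaks(t, x, threshold=thr, min_ibi_s=0.0):
            assert x[int(round(pk * FS))] <= thr + 0.05


class TestIbiStatistics:
    def test_periodic_grid_of_identical_traces(self):
        t, x = _dips([1.0, 3.0, 5.0, 7.0])
        data = np.tile(x[:, None, None], (1, 8, 8))
        rec = _recording_from_traces(data)
        bs = A.ibi_statistics(rec, (0.0, 8.0), source="h_e")
        assert bs.mean_ibi == pytest.approx(2.0, abs=2 / FS)
        assert bs.sd_ibi == pytest.approx(0.0, abs=1e-9)
        assert bs.fraction_bursting == 1.0
        assert np.all(bs.ibis >= A.MIN_IBI_S)

    def test_gamma_ee_source_uses_hill_scaling(self):
        # C_e dipping to 0.2 at c = 0: Γ_ee = 0.18424·C_e crosses 0.05
        t = np.arange(0, 8, 1 / FS)
        ce = np.full_like(t, 1.0)
        for td in (2.0, 5.0):
            ce -= 0.9 * np.exp(-0.5 * ((t - td) / 0.05) ** 2)
        data = np.tile(ce[:, None, None], (1, 8, 8)).astype(np.float32)
        rec = _recording_from_traces(data)
        rec.fields["C_e"] = data
        bs = A.ibi_statistics(rec, (0.0, 8.0))
        assert bs.fraction_bursting == 1.0
        assert bs.mean_ibi == pytest.approx(3.0, abs=2 / FS)
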