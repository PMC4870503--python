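"""Signal chain: FIR design, windowed spectra, band power, artifact flags,
theta-window individualisation and epoch aggregation."""

import numpy as np
import pytest
from scipy import signal as sps

from biocyberloop import (EEGRecording, FilterSpec, THETA_OFFLINE, UPPER_ALPHA,
                          apply_bandpass, band_power, band_power_series,
                          design_bandpass, epoch_band_power, exclude_artifacts,
                          select_theta_window, short_time_spectra)
from biocyberloop.spectral import BandDef, SpectralFrame


def _sine_recording(freq, amplitude, fs=256.0, duration=10.0):
    t = np.arange(int(duration * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return EEGRecording(fs, ["Fz", "P4"], np.vstack([x, x]))


class TestFilterDesign:
    def test_passband_sine_preserved(self):
        """10-Hz unit sine through the 2–30 Hz default keeps its RMS (±2%)."""
        fs = 512.0
        taps = design_bandpass(FilterSpec(), fs)
        rec = _sine_recording(10.0, 1.0, fs=fs, duration=20.0)
        out = apply_bandpass(rec, FilterSpec())
        edge = len(taps)
        kept = out.channel("Fz")[edge:-edge]
        ref = rec.channel("Fz")[edge:-edge]
        assert np.sqrt(np.mean(kept**2)) == pytest.approx(
            np.sqrt(np.mean(ref**2)), rel=0.02)

    @pytest.mark.parametrize("freq,min_atten_db", [(0.3, 40.0), (45.0, 40.0)])
    def test_stopband_attenuation(self, freq, min_atten_db):
        taps = design_bandpass(FilterSpec(), 512.0)
        w, h = sps.freqz(taps, worN=[2 * np.pi * freq / 512.0])
        assert 20 * np.log10(np.abs(h[0])) < -min_atten_db

    def test_passband_response_flat(self):
        spec = FilterSpec()
        taps = design_bandpass(spec, 512.0)
        freqs = np.linspace(spec.low_cut + spec.transition_width,
                            spec.high_cut - spec.transition_width, 40)
        _, h = sps.freqz(taps, worN=2 * np.pi * freqs / 512.0)
        db = 20 * np.log10(np.abs(h))
        assert np.all(np.abs(db) < 0.5)

    def test_linear_phase_symmetry(self):
        taps = design_bandpass(FilterSpec(), 512.0)
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)

    def test_transition_wider_than_passband_rejected(self):
        with pytest.raises(ValueError, match="transition"):
            FilterSpec(2.0, 4.0, 60.0, 3.0).validate(512.0)


class TestShortTimeSpectra:
    def test_frame_count_180s_256hz(self):
        """180 s at 256 Hz, 2-s windows, 50% overlap → 179 frames of 512 points."""
        rec = EEGRecording(256.0, ["Fz"], np.zeros((1, 180 * 256)))
        frames = short_time_spectra(rec, "Fz", 2.0, 0.5)
        assert len(frames) == 179
        assert len(frames[0].freq_bins) == 512 // 2 + 1  # 512-point windows
        assert frames[0].freq_bins[1] == pytest.approx(0.5)

    def test_zero_signal_zero_power(self):
        rec = EEGRecording(256.0, ["Fz"], np.zeros((1, 256 * 8)))
        frames = short_time_spectra(rec, "Fz")
        assert all(np.all(f.power == 0) for f in frames)

    @pytest.mark.parametrize("taper", ["hanning", "none"])
    def test_parseval_white_noise(self, taper):
        """Summed full-spectrum power matches time-domain variance (3 SE)."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal(180 * 256)
        rec = EEGRecording(256.0, ["Fz"], x[None, :])
        frames = short_time_spectra(rec, "Fz", taper=taper)
        totals = np.array([f.power.sum() for f in frames])
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - x.var()) < 3 * se

    def test_too_short_recording_rejected(self):
        rec = EEGRecording(256.0, ["Fz"], np.zeros((1, 100)))
        with pytest.raises(ValueError, match="shorter"):
            short_time_spectra(rec, "Fz")


class TestBandPower:
    def test_brute_force_dft_oracle(self):
        """band_power equals an explicit DFT summation to 1e-9 relative."""
        rng = np.random.default_rng(7)
        for n, fs in ((512, 256.0), (1024, 512.0)):
            x = rng.standard_normal(n)
            rec = EEGRecording(fs, ["Fz"], x[None, :])
            frame = short_time_spectra(rec, "Fz", n / fs, 0.5)[0]
            w = np.hanning(n)
            k = np.arange(n // 2 + 1)
            dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n) @ (w * x)
            coef = np.full(len(k), 2.0)
            coef[0] = 1.0
            coef[-1] = 1.0
            oracle_bins = coef * np.abs(dft) ** 2 / (n * np.sum(w * w))
            freqs = k * fs / n
            for band in (THETA_OFFLINE, UPPER_ALPHA):
                mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
                assert band_power(frame, band) == pytest.approx(
                    float(oracle_bins[mask].sum()), rel=1e-9)

    def test_narrowband_sinusoid_recovers_variance(self):
        """11.5-Hz, 10-µV-amplitude sine → ~50 µV² in the upper-alpha band."""
        rec = _sine_recording(11.5, 10.0)
        frame = short_time_spectra(rec, "P4")[0]
        assert band_power(frame, UPPER_ALPHA) == pytest.approx(50.0, rel=0.05)
        assert band_power(frame, THETA_OFFLINE) < 0.01 * 50.0

    def test_empty_band_rejected(self):
        frame = SpectralFrame(0.0, np.array([0.0, 0.5, 1.0]),
                              np.zeros(3), "Fz")
        with pytest.raises(ValueError, match="no bins"):
            band_power(frame, BandDef("narrow", 0.6, 0.9))


class TestArtifactExclusion:
    def _clean_recording(self, peak=60.0):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 30 * 256) * peak
        return EEGRecording(256.0, ["Fz"], x[None, :])

    def test_clean_recording_unflagged(self):
        assert not exclude_artifacts(self._clean_recording()).any()

    def test_lower_threshold_flags_more(self):
        """Flag count is non-increasing in the threshold."""
        rec = self._clean_recording()
        counts = [exclude_artifacts(rec, threshold=t).sum()
                  for t in (50.0, 59.99, 100.0)]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[1] > 0
        assert counts[2] == 0

    def test_burst_flags_overlapping_frames(self):
        x = np.zeros(30 * 256)
        x[10 * 256:11 * 256] = 150.0
        rec = EEGRecording(256.0, ["Fz"], x[None, :])
        flags = exclude_artifacts(rec)
        frames = short_time_spectra(rec, "Fz")
        times = np.array([f.frame_start for f in frames])
        overlapping = (times + 2.0 > 10.0) & (times < 11.0)
        assert flags[overlapping].all()
        assert not flags[~overlapping].any()


class TestThetaWindowSelection:
    def _frames(self, perturb=None):
        freqs = np.fft.rfftfreq(512, 1 / 256)
        base = np.ones(len(freqs))
        other = base.copy()
        if perturb is not None:
            f0, gain = perturb
            other[np.isclose(freqs, f0)] = gain
        return {"low": SpectralFrame(0, freqs, base, "Fz"),
                "high": SpectralFrame(0, freqs, other, "Fz")}

    def test_peak_modulation_at_6hz(self):
        tw = select_theta_window(self._frames((6.0, 5.0)))
        assert tw.center == 6.0
        assert (tw.band.f_lo, tw.band.f_hi) == (5.5, 6.5)

    def test_tie_returns_lowest_bin_clipped(self):
        tw = select_theta_window(self._frames(None))
        assert (tw.band.f_lo, tw.band.f_hi) == (4.0, 5.0)

    def test_boundary_peak_clipped_into_range(self):
        tw = select_theta_window(self._frames((4.0, 5.0)))
        assert (tw.band.f_lo, tw.band.f_hi) == (4.0, 5.0)

    def test_single_condition_rejected(self):
        frames = self._frames(None)
        with pytest.raises(ValueError, match="two conditions"):
            select_theta_window({"only": frames["low"]})


class TestEpochAggregation:
    def _series(self, powers, flags=None):
        freqs = np.fft.rfftfreq(512, 1 / 256)
        frames = []
        for i, p in enumerate(powers):
            bins = np.zeros(len(freqs))
            bins[np.isclose(freqs, 5.0)] = p
            frames.append(SpectralFrame(float(i), freqs, bins, "Fz"))
        return band_power_series(frames, THETA_OFFLINE, flags)

    def test_constant_power_mean(self):
        ep = epoch_band_power(self._series([4.0] * 10), 5.0)
        assert ep.power[0] == pytest.approx(4.0)

    def test_mean_of_mixed_frames(self):
        ep = epoch_band_power(self._series([2.0, 4.0, 6.0, 4.0]), 5.0)
        assert ep.power[0] == pytest.approx(4.0)

    def test_fully_flagged_epoch_invalid(self):
        flags = np.ones(4, dtype=bool)
        ep = epoch_band_power(self._series([4.0] * 4, flags), 5.0)
        assert not ep.valid[0]
        assert np.isnan(ep.power[0])

    def test_full_containment_gives_four_frames_per_epoch(self):
        """At 2-s/50% framing a 5-s epoch holds 4 fully-contained frames."""
        powers = np.arange(9, dtype=float)  # frames start at 0..8 s
        ep = epoch_band_power(self._series(list(powers)), 5.0)
        assert len(ep.starts) == 2
        assert ep.power[0] == pytest.approx(np.mean(powers[:4]))
        assert ep.power[1] == pytest.approx(np.mean(powers[5:9]))

    def test_start_containment_option(self):
        powers = np.arange(9, dtype=float)
        ep = epoch_band_power(self._series(list(powers)), 5.0,
                              containment="start")
        assert ep.power[0] == pytest.approx(np.mean(powers[:5]))
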