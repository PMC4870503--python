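"""Signal chain: FIR bandpass, windowed FFT power spectra, band power,
artifact exclusion, theta-window individualisation and epoch aggregation.

Two framing conventions are supported by the same code path:

* offline analysis — 50 %-overlapped 2-s windows over a whole recording
  (512 points at the 256-Hz offline rate);
* real-time loop — a Kaiser FIR of 2–30 Hz, then 2-s Hanning windows at 50 %
  overlap, aggregated into 5-s assessment epochs.

Per-bin powers are taper-power-corrected (divided by the window's mean-square
gain) so that summing bins over the full spectrum is an unbiased estimate of
the signal's time-domain variance, with or without the taper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import EEGRecording

__all__ = [
    "FilterSpec",
    "BandDef",
    "SpectralFrame",
    "BandPowerSeries",
    "ThetaWindow",
    "THETA_OFFLINE",
    "THETA_LOOP",
    "LOWER_ALPHA",
    "UPPER_ALPHA",
    "DEFAULT_FILTER",
    "design_bandpass",
    "apply_bandpass",
    "short_time_spectra",
    "band_power",
    "exclude_artifacts",
    "select_theta_window",
    "band_power_series",
    "EpochPowers",
    "epoch_band_power",
]

_EDGE_EPS = 1e-9  # float tolerance when testing bin centres against band edges


@dataclass(frozen=True)
class FilterSpec:
    low_cut: float = 2.0
    high_cut: float = 30.0
    stopband_attenuation: float = 60.0
    transition_width: float = 1.0

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.low_cut < self.high_cut < nyq):
            raise ValueError(f"need 0 < low_cut < high_cut < Nyquist ({nyq} Hz)")
        if self.stopband_attenuation <= 0:
            raise ValueError("stopband_attenuation must be > 0")
        if self.transition_width >= (self.high_cut - self.low_cut):
            raise ValueError("transition band wider than passband")


@dataclass(frozen=True)
class BandDef:
    """Frequency band, closed at both ends over FFT bin centres."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be < f_hi")


THETA_OFFLINE = BandDef("theta", 4.0, 7.0)   # offline analysis convention
THETA_LOOP = BandDef("theta", 4.0, 8.0)      # real-time loop convention
LOWER_ALPHA = BandDef("lower_alpha", 7.5, 10.0)
UPPER_ALPHA = BandDef("upper_alpha", 10.5, 13.0)
DEFAULT_FILTER = FilterSpec()


@dataclass
class SpectralFrame:
    frame_start: float
    freq_bins: np.ndarray
    power: np.ndarray  # µV² per bin, taper-power-corrected
    channel: str


@dataclass
class BandPowerSeries:
    channel: str
    band: BandDef
    times: np.ndarray
    power: np.ndarray
    artifact_flags: np.ndarray
    frame_length: float  # seconds
    frame_hop: float     # seconds

    @property
    def log_power(self) -> np.ndarray:
        out = np.full_like(self.power, np.nan)
        pos = self.power > 0
        out[pos] = np.log(self.power[pos])
        return out


@dataclass(frozen=True)
class ThetaWindow:
    center: float
    width: float = 1.0

    @property
    def band(self) -> BandDef:
        return BandDef("theta_individual", self.center - self.width / 2.0,
                       self.center + self.width / 2.0)


def design_bandpass(spec: FilterSpec = DEFAULT_FILTER,
                    sampling_rate: float = 512.0) -> np.ndarray:
    """Linear-phase Kaiser-window FIR bandpass coefficients."""
    spec.validate(sampling_rate)
    numtaps, beta = sps.kaiserord(spec.stopband_attenuation,
                                  spec.transition_width / (sampling_rate / 2.0))
    numtaps |= 1  # odd length keeps a type-I (symmetric) design
    return sps.firwin(numtaps, [spec.low_cut, spec.high_cut],
                      window=("kaiser", beta), pass_zero=False, fs=sampling_rate)


def apply_bandpass(recording: EEGRecording,
                   spec: FilterSpec = DEFAULT_FILTER) -> EEGRecording:
    """Zero-phase application of the FIR (symmetric taps, centred convolution)."""
    taps = design_bandpass(spec, recording.sampling_rate)
    out = recording.copy()
    for i in range(out.samples.shape[0]):
        out.samples[i] = sps.fftconvolve(out.samples[i], taps, mode="same")
    return out


def _frame_geometry(n_samples: int, fs: float, window_length: float,
                    overlap_fraction: float) -> tuple[int, int, np.ndarray]:
    length = window_length * fs
    if abs(length - round(length)) > 1e-9:
        raise ValueError("window_length × sampling_rate must be an integer")
    length = int(round(length))
    if length > n_samples:
        raise ValueError(
            f"recording ({n_samples} samples) shorter than one "
            f"{length}-sample window"
        )
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    hop = int(round(length * (1.0 - overlap_fraction)))
    starts = np.arange(0, n_samples - length + 1, hop)
    return length, hop, starts


def short_time_spectra(
    recording: EEGRecording,
    channel: str,
    window_length: float = 2.0,
    overlap_fraction: float = 0.5,
    taper: str = "hanning",
) -> list[SpectralFrame]:
    """Windowed FFT power spectra of one channel.

    Frame count is ``floor((N − L) / (L·(1 − overlap))) + 1``.  Per-bin power
    is ``|X_k|²`` scaled by ``2/(N·Σw²)`` (factor 1 at DC/Nyquist), so the sum
    over all bins estimates the window's variance (Parseval-consistent).
    """
    if taper not in ("hanning", "none"):
        raise ValueError("taper must be 'hanning' or 'none'")
    x = recording.channel(channel)
    fs = recording.sampling_rate
    length, _, starts = _frame_geometry(recording.n_samples, fs,
                                        window_length, overlap_fraction)
    w = np.hanning(length) if taper == "hanning" else np.ones(length)
    scale = 1.0 / (length * np.sum(w * w))
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    coef = np.full(len(freqs), 2.0)
    coef[0] = 1.0
    if length % 2 == 0:
        coef[-1] = 1.0
    frames = []
    for s in starts:
        spec = np.fft.rfft(w * x[s:s + length])
        power = coef * np.abs(spec) ** 2 * scale
        frames.append(SpectralFrame(recording.start_time + s / fs, freqs, power, channel))
    return frames


def band_power(frame: SpectralFrame, band: BandDef) -> float:
    """Total power (µV²): sum of bins whose centre lies in [f_lo, f_hi]."""
    mask = (frame.freq_bins >= band.f_lo - _EDGE_EPS) & \
           (frame.freq_bins <= band.f_hi + _EDGE_EPS)
    if not np.any(mask):
        spacing = frame.freq_bins[1] - frame.freq_bins[0] if len(frame.freq_bins) > 1 else float("nan")
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz contains no bins "
            f"(bin spacing {spacing:g} Hz)"
        )
    return float(np.sum(frame.power[mask]))


def exclude_artifacts(
    recording: EEGRecording,
    window_length: float = 2.0,
    overlap_fraction: float = 0.5,
    threshold: float = 100.0,
) -> np.ndarray:
    """Flag frames whose source window has any sample over ``threshold`` µV.

    A frame is flagged when |x| > threshold on any channel anywhere inside its
    window; flagged frames are excluded from every downstream aggregate.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if recording.n_samples == 0:
        return np.zeros(0, dtype=bool)
    length, _, starts = _frame_geometry(recording.n_samples, recording.sampling_rate,
                                        window_length, overlap_fraction)
    hot = np.any(np.abs(recording.samples) > threshold, axis=0)
    return np.array([bool(np.any(hot[s:s + length])) for s in starts])


def select_theta_window(per_condition_spectra: dict[str, SpectralFrame],
                        f_lo: float = 4.0, f_hi: float = 7.0) -> ThetaWindow:
    """Individualised 1-Hz theta window at the frequency of peak modulation.

    The centre is the bin in [f_lo, f_hi] maximising the across-condition range
    of log power (ties → lowest frequency), clipped so the window stays inside
    [f_lo, f_hi].
    """
    if len(per_condition_spectra) < 2:
        raise ValueError("need spectra for at least two conditions")
    frames = list(per_condition_spectra.values())
    bins = frames[0].freq_bins
    for fr in frames[1:]:
        if not np.array_equal(fr.freq_bins, bins):
            raise ValueError("condition spectra must share a bin grid")
    mask = (bins >= f_lo - _EDGE_EPS) & (bins <= f_hi + _EDGE_EPS)
    if not np.any(mask):
        raise ValueError(f"no FFT bins inside [{f_lo}, {f_hi}] Hz")
    logs = np.vstack([np.log(np.maximum(fr.power[mask], 1e-300)) for fr in frames])
    modulation = logs.max(axis=0) - logs.min(axis=0)
    center = float(bins[mask][int(np.argmax(modulation))])  # argmax → lowest tied bin
    center = min(max(center, f_lo + 0.5), f_hi - 0.5)
    return ThetaWindow(center=center)


def band_power_series(
    frames: list[SpectralFrame],
    band: BandDef,
    artifact_flags: np.ndarray | None = None,
) -> BandPowerSeries:
    """Collapse per-frame spectra into a band-power time series."""
    if not frames:
        raise ValueError("no frames")
    times = np.array([f.frame_start for f in frames])
    power = np.array([band_power(f, band) for f in frames])
    if artifact_flags is None:
        artifact_flags = np.zeros(len(frames), dtype=bool)
    artifact_flags = np.asarray(artifact_flags, dtype=bool)
    if len(artifact_flags) != len(frames):
        raise ValueError("artifact_flags length must match frame count")
    hop = float(times[1] - times[0]) if len(times) > 1 else float("nan")
    length = float(1.0 / (frames[0].freq_bins[1] - frames[0].freq_bins[0]))
    return BandPowerSeries(frames[0].channel, band, times, power,
                           artifact_flags, length, hop)


@dataclass
class EpochPowers:
    """Per-epoch mean linear band power; ``valid`` is False where every frame
    in the epoch was artifact-flagged."""

    starts: np.ndarray
    power: np.ndarray  # NaN where invalid
    valid: np.ndarray
    epoch_length: float


def epoch_band_power(series: BandPowerSeries, epoch_length: float = 5.0,
                     containment: str = "full") -> EpochPowers:
    """Aggregate frames into fixed-length epochs (mean of unflagged powers).

    ``containment='full'`` (default) assigns a frame to an epoch only when its
    whole window lies inside the epoch — four 2-s frames per 5-s epoch at 50 %
    overlap, and no analysis window straddles an epoch boundary.
    ``containment='start'`` assigns by frame start time alone.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be > 0")
    if containment not in ("full", "start"):
        raise ValueError("containment must be 'full' or 'start'")
    t0 = series.times[0]
    span = series.times[-1] + series.frame_length - t0
    n_epochs = int(np.floor(span / epoch_length + 1e-9))
    if n_epochs < 1:
        raise ValueError("series shorter than one epoch")
    starts = t0 + epoch_length * np.arange(n_epochs)
    power = np.full(n_epochs, np.nan)
    valid = np.zeros(n_epochs, dtype=bool)
    for i, e in enumerate(starts):
        lo = series.times >= e - 1e-9
        if containment == "start":
            in_epoch = lo & (series.times < e + epoch_length - 1e-9)
        else:
            in_epoch = lo & (series.times + series.frame_length <= e + epoch_length + 1e-9)
        use = in_epoch & ~series.artifact_flags
        if np.any(use):
            power[i] = float(np.mean(series.power[use]))
            valid[i] = True
    return EpochPowers(starts, power, valid, epoch_length)
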