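"""Synthetic two-channel (Fz, P4) EEG with scripted band-power dynamics.

The generator emulates the input side of an EEG-driven difficulty-adaptation
loop: a frontal-midline theta rhythm on Fz and an upper-alpha rhythm on P4,
each riding on a 1/f background, with the band RMS of each rhythm following a
scripted timeline of player states.  Oscillators are narrowband filtered-noise
processes (white noise brick-wall bandpassed to the oscillator band), not pure
sinusoids, so spectral estimates downstream carry realistic estimator
variance.  Segment transitions use a 100-ms linear crossfade of the RMS
envelope to avoid step discontinuities leaking broadband power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OscillatorSpec",
    "NoiseSpec",
    "Segment",
    "StateScript",
    "EEGRecording",
    "STATE_LABELS",
    "generate_recording",
    "script_from_states",
    "inject_artifact",
    "DEFAULT_THETA_OSC",
    "DEFAULT_ALPHA_OSC",
    "DEFAULT_NOISE",
]

#: Length of the linear RMS crossfade centred on each interior segment boundary.
CROSSFADE_S = 0.1

STATE_LABELS = ("baseline", "boredom", "engagement", "zone", "overload", "custom")


@dataclass(frozen=True)
class OscillatorSpec:
    """A narrowband rhythm: centre frequency, bandwidth and baseline RMS (µV)."""

    center_freq: float
    bandwidth: float
    rms_amplitude: float

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError("center_freq must be > 0")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be >= 0")

    @property
    def f_lo(self) -> float:
        return self.center_freq - self.bandwidth / 2.0

    @property
    def f_hi(self) -> float:
        return self.center_freq + self.bandwidth / 2.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background activity with power ∝ 1/f**spectral_exponent and given RMS (µV)."""

    spectral_exponent: float = 1.0
    rms_amplitude: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spectral_exponent <= 2.0):
            raise ValueError("spectral_exponent must lie in [0, 2]")
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be >= 0")


@dataclass(frozen=True)
class Segment:
    duration: float
    state: str
    theta_multiplier: float
    alpha_multiplier: float


@dataclass(frozen=True)
class StateScript:
    """Ordered ground-truth timeline of player states and band-RMS multipliers."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        for i, seg in enumerate(self.segments):
            if seg.duration <= 0:
                raise ValueError(f"segment {i} ({seg.state!r}) has non-positive duration")
            if seg.theta_multiplier <= 0 or seg.alpha_multiplier <= 0:
                raise ValueError(f"segment {i} ({seg.state!r}) has non-positive multiplier")
            if seg.state not in STATE_LABELS:
                raise ValueError(f"segment {i} has unknown state label {seg.state!r}")

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    def boundaries(self) -> np.ndarray:
        """Segment start/end times: length ``len(segments)+1``, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def state_at(self, t: float) -> Segment:
        """Segment active at time ``t`` (end-exclusive; last segment owns the end)."""
        edges = self.boundaries()
        idx = int(np.searchsorted(edges[1:-1], t, side="right"))
        return self.segments[idx]


@dataclass
class EEGRecording:
    """Uniformly sampled multichannel signal in microvolts."""

    sampling_rate: float
    channel_labels: list[str]
    samples: np.ndarray  # shape (n_channels, n_samples)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.sampling_rate,
            list(self.channel_labels),
            self.samples.copy(),
            self.start_time,
        )


# Defaults: theta centred on the 6-Hz grand-average peak, upper alpha filling
# the 10.5–13 Hz band.  Amplitudes are synthetic conventions (see
# docs/methods.md): each rhythm dominates the 1/f floor within its band while
# scripted deviations stay inside the physiological microvolt range.
DEFAULT_THETA_OSC = OscillatorSpec(center_freq=6.0, bandwidth=2.0, rms_amplitude=7.0)
DEFAULT_ALPHA_OSC = OscillatorSpec(center_freq=11.75, bandwidth=2.5, rms_amplitude=5.0)
DEFAULT_NOISE = NoiseSpec(spectral_exponent=1.0, rms_amplitude=10.0)


def _bandlimited_unit_noise(rng: np.random.Generator, n: int, fs: float,
                            f_lo: float, f_hi: float) -> np.ndarray:
    """Zero-mean unit-RMS Gaussian noise brick-wall bandpassed to [f_lo, f_hi]."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < f_lo) | (f > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x * x))
    if rms == 0:
        raise ValueError(f"oscillator band [{f_lo}, {f_hi}] Hz contains no FFT bins")
    return x / rms


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent background, normalised to the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)  # DC removed
    x = np.fft.irfft(spec * gain, n)
    return x * (rms / np.sqrt(np.mean(x * x)))


def _rms_envelope(script: StateScript, which: str, n: int, fs: float) -> np.ndarray:
    """Per-sample RMS multiplier with linear crossfades at interior boundaries."""
    edges = script.boundaries()
    mults = np.array(
        [s.theta_multiplier if which == "theta" else s.alpha_multiplier
         for s in script.segments]
    )
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(edges[1:-1], t, side="right"), 0, len(mults) - 1)
    env = mults[idx]
    half = CROSSFADE_S / 2.0
    for b, m_prev, m_next in zip(edges[1:-1], mults[:-1], mults[1:]):
        in_fade = (t >= b - half) & (t < b + half)
        if np.any(in_fade):
            frac = (t[in_fade] - (b - half)) / CROSSFADE_S
            env[in_fade] = m_prev + (m_next - m_prev) * frac
    return env


def generate_recording(
    script: StateScript,
    osc_theta: OscillatorSpec = DEFAULT_THETA_OSC,
    osc_alpha: OscillatorSpec = DEFAULT_ALPHA_OSC,
    noise: NoiseSpec = DEFAULT_NOISE,
    sampling_rate: float = 512.0,
    seed: int = 0,
) -> EEGRecording:
    """Generate a two-channel (Fz, P4) recording following ``script``.

    Within each segment the expected theta-band RMS on Fz is
    ``osc_theta.rms_amplitude * theta_multiplier`` and the expected upper-alpha
    RMS on P4 is ``osc_alpha.rms_amplitude * alpha_multiplier``.  Identical
    arguments and seed give bit-identical samples.
    """
    if sampling_rate < 2.0 * (osc_alpha.center_freq + osc_alpha.bandwidth):
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz violates Nyquist for the alpha "
            f"oscillator at {osc_alpha.center_freq} Hz"
        )
    n = int(round(script.total_duration * sampling_rate))
    rng = np.random.default_rng(seed)

    def channel(osc: OscillatorSpec, which: str) -> np.ndarray:
        # Draw order is fixed (oscillator, then noise) for determinism.
        if osc.rms_amplitude > 0:
            carrier = _bandlimited_unit_noise(rng, n, sampling_rate, osc.f_lo, osc.f_hi)
            env = osc.rms_amplitude * _rms_envelope(script, which, n, sampling_rate)
            sig = carrier * env
        else:
            rng.standard_normal(n)  # keep the stream position fixed
            sig = np.zeros(n)
        sig = sig + _one_over_f_noise(
            rng, n, sampling_rate, noise.spectral_exponent, noise.rms_amplitude
        )
        return sig

    fz = channel(osc_theta, "theta")
    p4 = channel(osc_alpha, "alpha")
    return EEGRecording(sampling_rate, ["Fz", "P4"], np.vstack([fz, p4]))


def script_from_states(
    state_sequence: list[tuple[float, str]],
    deviation_strength: float = 3.0,
) -> StateScript:
    """Map named player states to band multipliers at a given deviation strength.

    boredom → (theta 1/s, alpha s); overload → (1/s, 1/s); engagement → (s, s);
    zone → (s, 1/s); baseline → (1, 1), where s = ``deviation_strength``.
    """
    if deviation_strength < 1:
        raise ValueError("deviation_strength must be >= 1")
    s = deviation_strength
    table = {
        "baseline": (1.0, 1.0),
        "boredom": (1.0 / s, s),
        "overload": (1.0 / s, 1.0 / s),
        "engagement": (s, s),
        "zone": (s, 1.0 / s),
    }
    segments = []
    for duration, label in state_sequence:
        if label not in table:
            raise ValueError(f"unknown state label {label!r}")
        th, al = table[label]
        segments.append(Segment(duration, label, th, al))
    return StateScript(tuple(segments))


def inject_artifact(
    recording: EEGRecording,
    at: float,
    duration: float,
    amplitude: float,
) -> EEGRecording:
    """Return a copy with a high-amplitude burst added to all channels.

    The burst is a raised-cosine bump whose peak is lifted above the local
    signal extremum, guaranteeing at least one sample with absolute value
    >= ``amplitude`` inside the window.  ``amplitude == 0`` is the identity.
    """
    if at < 0 or duration <= 0 or at + duration > recording.duration + 1e-9:
        raise ValueError(
            f"artifact window [{at}, {at + duration}] s outside the "
            f"{recording.duration:.3f}-s recording"
        )
    out = recording.copy()
    if amplitude == 0:
        return out
    fs = recording.sampling_rate
    i0 = int(round(at * fs))
    i1 = min(int(round((at + duration) * fs)), recording.n_samples)
    m = i1 - i0
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(m) / max(m - 1, 1)))
    local_max = np.max(np.abs(out.samples[:, i0:i1])) if m else 0.0
    out.samples[:, i0:i1] += (amplitude + local_max) * bump
    return out
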