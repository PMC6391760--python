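"""Waveform synthesis of vole-like distress calls.

A call is a harmonic stack with a concave (arch-shaped) fundamental-frequency
trajectory plus spectrally shaped broadband noise, mixed by energy fraction
and amplitude-enveloped.  A low-level broadband background (as on any real
recording) is always present so that spectral entropy is well defined and
graded rather than collapsing to zero for purely tonal calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import CallSpec

DEFAULT_SAMPLING_RATE_HZ = 22_050

#: 1-sigma width (Hz) of the Gaussian spectral envelope of the noise part.
NOISE_SPECTRAL_WIDTH_HZ = 2_500.0
#: Amplitude floor of the noise spectral envelope across the band, relative
#: to the envelope peak; keeps the whole spectrum weakly excited so the
#: spectral median stays near the centre without entropy collapsing.
NOISE_FLOOR_REL = 0.5
#: RMS of the ever-present broadband background, relative to call RMS
#: (~ -28 dB; emulates recording-chain background).
BACKGROUND_RMS_REL = 0.04
#: 1-sigma width, in harmonic index, of the amplitude rolloff around the
#: dominant partial.
PARTIAL_WIDTH = 1.0


@dataclass(frozen=True)
class Waveform:
    """Mono audio snippet: normalised samples plus the sampling rate."""

    samples: np.ndarray
    sampling_rate_hz: int

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


def _shaped_noise(rng: np.random.Generator, n: int, rate: int,
                  centre_hz: float) -> np.ndarray:
    """White noise re-shaped to a broad Gaussian bump centred on *centre_hz*.

    A relative floor keeps the whole band up to 0.97*Nyquist weakly excited,
    so noise calls have a spectral median near the centre without a hard
    band edge.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    nyq = rate / 2.0
    mask = np.exp(-0.5 * ((freqs - centre_hz) / NOISE_SPECTRAL_WIDTH_HZ) ** 2)
    mask = np.where(freqs <= 0.97 * nyq, np.maximum(mask, NOISE_FLOOR_REL), 0.0)
    return np.fft.irfft(spec * mask, n)


def _envelope(n: int, attack_fraction: float, decay_fraction: float) -> np.ndarray:
    env = np.ones(n)
    na = int(round(attack_fraction * n))
    nd = int(round(decay_fraction * n))
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na, endpoint=False)
    if nd > 0:
        env[n - nd:] = np.linspace(1.0, 0.0, nd)
    return env


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize(spec: CallSpec,
               sampling_rate_hz: int = DEFAULT_SAMPLING_RATE_HZ,
               seed: int | np.random.Generator = 0) -> Waveform:
    """Render a :class:`CallSpec` to a normalised mono waveform.

    The fundamental follows a half-sine arch from ``f0max - modulation_range``
    up to ``f0max`` at mid-call and back; partial k sits at ``k * f0(t)`` with
    a Gaussian amplitude rolloff around the partial nearest the call's target
    spectral centre.  Partials whose peak frequency would exceed Nyquist are
    dropped.  Harmonic and noise parts are mixed so that ``noise_fraction``
    is the noise share of total energy.  Bit-identical output for identical
    ``(spec, sampling_rate_hz, seed)``.
    """
    if spec.f0max_hz <= spec.modulation_range_hz:
        raise ValueError("f0max_hz must exceed modulation_range_hz")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    rate = int(sampling_rate_hz)
    nyq = rate / 2.0
    n = int(round(spec.duration_s * rate))
    if n < 2:
        raise ValueError("call too short for this sampling rate")
    t = np.arange(n) / rate

    f0 = (spec.f0max_hz - spec.modulation_range_hz
          + spec.modulation_range_hz * np.sin(np.pi * t / spec.duration_s))
    phase = 2.0 * np.pi * np.cumsum(f0) / rate

    harmonic = np.zeros(n)
    if spec.noise_fraction < 1.0:
        k_centre = float(np.clip(spec.q50_target_hz / spec.f0max_hz,
                                 1.0, spec.n_harmonics))
        for k in range(1, spec.n_harmonics + 1):
            if k * spec.f0max_hz >= 0.98 * nyq:
                break
            amp = np.exp(-0.5 * ((k - k_centre) / PARTIAL_WIDTH) ** 2)
            harmonic += amp * np.sin(k * phase + rng.uniform(0.0, 2.0 * np.pi))

    noise_fraction = spec.noise_fraction
    if noise_fraction < 1.0 and not np.any(harmonic):
        # all partials above Nyquist: nothing tonal can be rendered
        noise_fraction = 1.0
    noise = _shaped_noise(rng, n, rate, spec.q50_target_hz)

    x = np.zeros(n)
    if noise_fraction < 1.0:
        x += np.sqrt(1.0 - noise_fraction) * _unit_rms(harmonic)
    if noise_fraction > 0.0:
        x += np.sqrt(noise_fraction) * _unit_rms(noise)
    x += BACKGROUND_RMS_REL * _unit_rms(rng.standard_normal(n))

    x *= _envelope(n, spec.attack_fraction, spec.decay_fraction)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return Waveform(samples=x, sampling_rate_hz=rate)
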