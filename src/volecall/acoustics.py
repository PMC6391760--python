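"""Spectrogram computation and call-parameter extraction.

Re-implements the classic desktop-bioacoustics measurement set on a short
mono call: duration from the amplitude envelope, and — from the call-average
power spectrum of a Hamming/512-point/87.5%-overlap spectrogram — peak
frequency, the 25/50/75% energy quartiles and spectral entropy (geometric
over arithmetic mean of the spectrum).  Harmonic calls additionally get a
fundamental-frequency track (harmonic-comb search), its maximum and its
modulation range, and every call is typed as harmonic, noise or mixed from
the fraction of energy explained by the best harmonic comb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .synth import Waveform

#: Frames with energy below this fraction of the loudest frame are treated
#: as silence for the call-average spectrum and the f0 track.
SILENCE_ENERGY_FRACTION = 0.01
#: Relative floor applied to zero-power bins before the geometric mean.
ENTROPY_FLOOR_REL = 1e-12
#: f0 search band (Hz) — covers the species' 1.5-3.8 kHz fundamentals with
#: margin while excluding implausible subharmonics.
F0_SEARCH_HZ = (800.0, 6000.0)
F0_GRID_HZ = 10.0
#: Number of partials scored by the comb search.
F0_COMB_PARTIALS = 5
#: A frame counts as voiced when the best comb explains at least this
#: fraction of its energy (white-noise frames stay below ~0.23 even with
#: best-comb selection bias).
VOICED_HARMONICITY = 0.25
#: Harmonicity thresholds for typing a call harmonic / noise / mixed.
HARMONIC_THRESHOLD = 0.8
NOISE_THRESHOLD = 0.2


class SilentSignalError(ValueError):
    """Raised when an operation needs a non-silent input."""


class NoVoicedFramesError(ValueError):
    """Raised by the f0 tracker when no frame shows a harmonic comb
    (a noise call: the fundamental is undefined)."""


@dataclass(frozen=True)
class Spectrogram:
    magnitude: np.ndarray          # [frames x bins]
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    window: str
    fft_size: int
    overlap_fraction: float
    sampling_rate_hz: int


@dataclass(frozen=True)
class PowerSpectrum:
    power: np.ndarray
    bin_freqs_hz: np.ndarray


@dataclass(frozen=True)
class CallMeasurement:
    """The measured parameter set of one call.

    ``f0max_hz`` and ``modulation_range_hz`` are ``None`` for noise calls
    (no harmonic relation between components, fundamental undefined).
    """

    duration_s: float
    peak_frequency_hz: float
    q25_hz: float
    q50_hz: float
    q75_hz: float
    entropy: float
    structure: str
    f0max_hz: float | None = None
    modulation_range_hz: float | None = None


def compute_spectrogram(w: Waveform, fft_size: int = 512,
                        overlap: float = 0.875,
                        window: str = "hamming") -> Spectrogram:
    """Magnitude STFT with the stated framing (hop = fft_size*(1-overlap)).

    Inputs shorter than one window are zero-padded to a single frame.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = int(round(fft_size * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large for this fft_size")
    if x.size < fft_size:
        x = np.pad(x, (0, fft_size - x.size))
    frames = sliding_window_view(x, fft_size)[::hop]
    win = get_window(window, fft_size)
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    rate = w.sampling_rate_hz
    return Spectrogram(
        magnitude=mag,
        frame_times_s=(np.arange(frames.shape[0]) * hop + fft_size / 2) / rate,
        bin_freqs_hz=np.fft.rfftfreq(fft_size, 1.0 / rate),
        window=window,
        fft_size=fft_size,
        overlap_fraction=overlap,
        sampling_rate_hz=rate,
    )


def _frame_power(s: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    power = s.magnitude ** 2
    return power, power.sum(axis=1)


def call_power_spectrum(s: Spectrogram) -> PowerSpectrum:
    """Per-bin power averaged over the non-silent frames of the call."""
    power, energy = _frame_power(s)
    emax = energy.max() if energy.size else 0.0
    if emax <= 0.0:
        raise SilentSignalError("all-silent spectrogram")
    keep = energy >= SILENCE_ENERGY_FRACTION * emax
    return PowerSpectrum(power=power[keep].mean(axis=0),
                         bin_freqs_hz=s.bin_freqs_hz)


def measure_duration(w: Waveform, threshold_db: float = -20.0,
                     smooth_s: float = 0.001) -> float:
    """Call duration from the smoothed amplitude envelope.

    The duration is the span between the first and last sample whose envelope
    exceeds ``threshold_db`` relative to the envelope maximum; it is invariant
    to leading/trailing silence (an automated stand-in for on-screen cursor
    measurement).
    """
    x = np.abs(np.asarray(w.samples, dtype=float))
    if x.size == 0 or x.max() <= 0.0:
        raise SilentSignalError("silent waveform")
    k = max(1, int(round(smooth_s * w.sampling_rate_hz)))
    env = np.convolve(x, np.ones(k) / k, mode="same")
    thr = env.max() * 10.0 ** (threshold_db / 20.0)
    idx = np.flatnonzero(env >= thr)
    return (idx[-1] - idx[0] + 1) / w.sampling_rate_hz


def peak_frequency(ps: PowerSpectrum) -> float:
    """Frequency of the strongest bin; ties resolve to the lowest frequency."""
    if ps.power.sum() <= 0.0:
        raise SilentSignalError("zero spectrum")
    return float(ps.bin_freqs_hz[int(np.argmax(ps.power))])


def energy_quartiles(ps: PowerSpectrum) -> tuple[float, float, float]:
    """Frequencies below which 25/50/75% of total spectral energy lies.

    Each quartile is the smallest bin frequency at which the cumulative power
    reaches the stated fraction of the total.
    """
    total = ps.power.sum()
    if total <= 0.0:
        raise SilentSignalError("zero spectrum")
    cum = np.cumsum(ps.power)
    idx = [int(np.searchsorted(cum, f * total, side="left"))
           for f in (0.25, 0.50, 0.75)]
    idx = [min(i, len(cum) - 1) for i in idx]
    f = ps.bin_freqs_hz
    return float(f[idx[0]]), float(f[idx[1]]), float(f[idx[2]])


def spectral_entropy(ps: PowerSpectrum) -> float:
    """Geometric over arithmetic mean of the power spectrum, in [0, 1].

    1 for a flat (white) spectrum, toward 0 for a pure tone.  Zero-power bins
    are floored at ``ENTROPY_FLOOR_REL`` times the maximum so the geometric
    mean is defined; the ratio is scale invariant.
    """
    m = ps.power.max() if ps.power.size else 0.0
    if m <= 0.0:
        raise SilentSignalError("zero spectrum")
    q = np.maximum(ps.power, ENTROPY_FLOOR_REL * m) / m
    return float(np.exp(np.mean(np.log(q))) / np.mean(q))


def _comb_analysis(spec_power: np.ndarray, bin_freqs: np.ndarray,
                   f0_search: tuple[float, float]) -> tuple[float, float]:
    """Best-comb f0 (Hz) and the fraction of frame energy it explains.

    Scores a grid of f0 candidates by the mean log power interpolated at the
    first ``F0_COMB_PARTIALS`` partials; a partial above Nyquist contributes
    the spectrum's median log power (a typical background bin), so sparse
    high-frequency combs riding on a single true harmonic are penalised on
    the same footing as subharmonic combs hitting background between true
    partials.  The best candidate is refined by parabolic interpolation on
    the score.  Harmonicity sums power within +-1 bin of each partial of the
    winner.
    """
    nyq = bin_freqs[-1]
    floor = ENTROPY_FLOOR_REL * spec_power.max()
    logspec = np.log(np.maximum(spec_power, floor))
    log_floor = float(np.median(logspec))
    cand = np.arange(f0_search[0], f0_search[1] + F0_GRID_HZ, F0_GRID_HZ)
    scores = np.zeros(cand.size)
    for k in range(1, F0_COMB_PARTIALS + 1):
        fk = cand * k
        ok = fk <= nyq
        scores[ok] += np.interp(fk[ok], bin_freqs, logspec)
        scores[~ok] += log_floor
    scores /= F0_COMB_PARTIALS
    j = int(np.argmax(scores))
    f0 = cand[j]
    if 0 < j < cand.size - 1 and np.isfinite(scores[j - 1]) \
            and np.isfinite(scores[j + 1]):
        denom = scores[j - 1] - 2.0 * scores[j] + scores[j + 1]
        if denom < 0:
            f0 += 0.5 * F0_GRID_HZ * (scores[j - 1] - scores[j + 1]) / denom

    df = bin_freqs[1] - bin_freqs[0]
    comb_bins: set[int] = set()
    k = 1
    while k * f0 <= nyq and k <= 10:
        b = int(round(k * f0 / df))
        comb_bins.update(i for i in (b - 1, b, b + 1)
                         if 0 <= i < spec_power.size)
        k += 1
    harmonicity = spec_power[list(comb_bins)].sum() / spec_power.sum()
    return float(f0), float(harmonicity)


def _frame_combs(s: Spectrogram,
                 f0_search: tuple[float, float]) -> tuple[np.ndarray, ...]:
    """Per active frame: (f0 estimate, harmonicity, frame energy)."""
    power, energy = _frame_power(s)
    emax = energy.max() if energy.size else 0.0
    if emax <= 0.0:
        raise SilentSignalError("silent spectrogram")
    active = np.flatnonzero(energy >= SILENCE_ENERGY_FRACTION * emax)
    f0s, harms = [], []
    for i in active:
        f0, h = _comb_analysis(power[i], s.bin_freqs_hz, f0_search)
        f0s.append(f0)
        harms.append(h)
    return np.array(f0s), np.array(harms), energy[active]


def track_fundamental(s: Spectrogram,
                      f0_search_hz: tuple[float, float] = F0_SEARCH_HZ,
                      ) -> tuple[float, float, np.ndarray]:
    """(f0max, modulation range, per-frame f0 track) over the voiced frames.

    Voiced frames are the non-silent frames whose best harmonic comb explains
    at least ``VOICED_HARMONICITY`` of the frame energy; raises
    :class:`NoVoicedFramesError` when there are none (a noise call).
    """
    f0s, harms, _ = _frame_combs(s, f0_search_hz)
    voiced = harms >= VOICED_HARMONICITY
    if not np.any(voiced):
        raise NoVoicedFramesError("no voiced frames: noise call, f0 undefined")
    track = f0s[voiced]
    return float(track.max()), float(track.max() - track.min()), track


def classify_structure(s: Spectrogram,
                       harmonic_threshold: float = HARMONIC_THRESHOLD,
                       noise_threshold: float = NOISE_THRESHOLD) -> str:
    """Type a call as harmonic / noise / mixed from its overall harmonicity.

    Harmonicity is the energy-weighted mean, over non-silent frames, of the
    fraction of frame energy explained by the frame's best harmonic comb.
    """
    f0s, harms, energies = _frame_combs(s, F0_SEARCH_HZ)
    h = float(np.sum(harms * energies) / np.sum(energies))
    if h >= harmonic_threshold:
        return "harmonic"
    if h <= noise_threshold:
        return "noise"
    return "mixed"


def measure(w: Waveform, fft_size: int = 512, overlap: float = 0.875,
            window: str = "hamming") -> CallMeasurement:
    """Full measurement of one call (the per-call Table-1-style record).

    Composes duration, the call-average spectrum parameters, structure typing
    and — for harmonic/mixed calls — the fundamental-frequency statistics.
    A call typed harmonic/mixed but without any voiced frame is demoted to
    noise so that f0 fields are absent exactly for noise calls.
    """
    duration = measure_duration(w)
    s = compute_spectrogram(w, fft_size=fft_size, overlap=overlap, window=window)
    ps = call_power_spectrum(s)
    q25, q50, q75 = energy_quartiles(ps)
    structure = classify_structure(s)
    f0max = mod_range = None
    if structure != "noise":
        try:
            f0max, mod_range, _ = track_fundamental(s)
        except NoVoicedFramesError:
            structure = "noise"
    return CallMeasurement(
        duration_s=duration,
        peak_frequency_hz=peak_frequency(ps),
        q25_hz=q25, q50_hz=q50, q75_hz=q75,
        entropy=spectral_entropy(ps),
        structure=structure,
        f0max_hz=f0max,
        modulation_range_hz=mod_range,
    )
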