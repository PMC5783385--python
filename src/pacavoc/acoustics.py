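"""Element-level acoustic measurement.

Mirrors a manual spectrogram workflow: short-time Fourier analysis with a
Hann window (defaults: 1460-sample window, 90% overlap, 4096-point FFT at
48 kHz), element selections given as time/frequency boxes, and five
parameters per element -- duration, minimum, maximum and dominant
frequency, and the number of harmonics under 1 kHz.

The reference workflow drew the min/max frequency bounds by hand in a GUI;
here they are defined algorithmically as the outermost frequency bins whose
in-selection power exceeds a floor relative to the selection peak (-20 dB
by default), a reproducible surrogate for the hand-drawn box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Waveform",
    "Spectrogram",
    "ElementSelection",
    "ElementMeasurements",
    "compute_spectrogram",
    "measure_element",
    "emission_rate",
    "read_wav",
    "write_wav",
]

DEFAULT_WINDOW = 1460
DEFAULT_OVERLAP = 0.9
DEFAULT_FFT = 4096


@dataclass
class Waveform:
    """Mono audio: float samples and a sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("waveform must be non-empty and mono")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def read_wav(path) -> Waveform:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(samples=np.asarray(data, dtype=float), rate=int(rate))


def write_wav(path, w: Waveform) -> None:
    """Write 16-bit PCM mono (the field-recorder setting)."""
    from scipy.io import wavfile

    peak = np.max(np.abs(w.samples))
    scaled = w.samples / peak if peak > 0 else w.samples
    wavfile.write(path, w.rate, np.round(scaled * 32767).astype(np.int16))


@dataclass
class Spectrogram:
    """Power by (frequency bin x time frame).

    Frequency bin centers sit at ``k * rate / fft_size``; time coordinates
    are frame centers; the hop is ``floor(window * (1 - overlap))``.
    """

    matrix: np.ndarray  # (n_freqs, n_frames) power
    freqs: np.ndarray
    times: np.ndarray
    window: int
    overlap: float
    fft_size: int
    rate: int


def compute_spectrogram(
    w: Waveform,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    fft_size: int = DEFAULT_FFT,
) -> Spectrogram:
    """Hann-tapered short-time power spectra of a waveform."""
    from scipy.signal import spectrogram as _spectrogram

    if window > w.samples.size:
        raise ValueError("analysis window longer than the signal")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if fft_size < window:
        raise ValueError("fft_size must be >= window")
    # floor, with an epsilon so 1460 * (1 - 0.9) floors to 146 not 145
    hop = int(window * (1 - overlap) + 1e-9)
    freqs, times, sxx = _spectrogram(
        w.samples,
        fs=w.rate,
        window="hann",
        nperseg=window,
        noverlap=window - hop,
        nfft=fft_size,
        mode="psd",
        detrend=False,
    )
    return Spectrogram(
        matrix=sxx, freqs=freqs, times=times,
        window=window, overlap=overlap, fft_size=fft_size, rate=w.rate,
    )


@dataclass(frozen=True)
class ElementSelection:
    """A time/frequency box around one element (a continuous sound)."""

    t_start: float
    t_end: float
    f_low: float = 0.0
    f_high: float = math.inf

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.f_high <= self.f_low:
            raise ValueError("f_high must exceed f_low")


@dataclass(frozen=True)
class ElementMeasurements:
    duration: float
    min_freq: float
    max_freq: float
    dominant_freq: float
    n_harmonics_under_1kHz: int


def measure_element(
    s: Spectrogram,
    sel: ElementSelection,
    floor_db: float = -20.0,
    harmonic_limit: float = 1000.0,
) -> ElementMeasurements:
    """Measure one element inside a selection.

    Duration is the selection length. The dominant frequency is the bin of
    maximum power within the selection. Min/max frequencies are the
    outermost bins whose in-selection power (summed over frames) exceeds
    ``floor_db`` relative to the peak bin. The harmonic count takes the
    lowest spectral peak above the floor as the fundamental and counts its
    integer multiples below ``harmonic_limit`` that also exceed the floor.
    Measurements are invariant to uniform amplitude scaling.
    """
    ti = np.flatnonzero((s.times >= sel.t_start) & (s.times <= sel.t_end))
    fi = np.flatnonzero((s.freqs >= sel.f_low) & (s.freqs <= sel.f_high))
    if ti.size == 0 or fi.size == 0:
        raise ValueError("selection contains no spectrogram frames/bins")
    block = s.matrix[np.ix_(fi, ti)]
    if not block.any():
        raise ValueError("selection contains only silence")
    peak_f, peak_t = np.unravel_index(np.argmax(block), block.shape)
    dominant = float(s.freqs[fi[peak_f]])

    power = block.sum(axis=1)
    floor = power.max() * 10 ** (floor_db / 10)
    above = np.flatnonzero(power >= floor)
    fmin = float(s.freqs[fi[above[0]]])
    fmax = float(s.freqs[fi[above[-1]]])

    # fundamental = lowest spectral peak above the floor
    above_mask = power >= floor
    peaks = [
        k
        for k in range(1, power.size - 1)
        if above_mask[k] and power[k] >= power[k - 1] and power[k] >= power[k + 1]
    ]
    if above_mask[0] and (power.size < 2 or power[0] >= power[1]):
        peaks.insert(0, 0)
    n_harm = 0
    if peaks:
        f0 = float(s.freqs[fi[peaks[0]]])
        if f0 > 0:
            df = s.freqs[1] - s.freqs[0]
            k = 1
            while k * f0 < harmonic_limit:
                idx = np.argmin(np.abs(s.freqs[fi] - k * f0))
                lo, hi = max(idx - 1, 0), min(idx + 2, power.size)
                if power[lo:hi].max() >= floor:
                    n_harm += 1
                k += 1
    duration = sel.t_end - sel.t_start
    lo, hi = min(fmin, dominant), max(fmax, dominant)
    return ElementMeasurements(
        duration=duration,
        min_freq=lo,
        max_freq=hi,
        dominant_freq=dominant,
        n_harmonics_under_1kHz=n_harm,
    )


def emission_rate(n_calls: int, total_hours: float) -> float:
    """Calls per hour of observation.

    Note: the reference text labels these hourly rates "calls/s" in places;
    they are per hour (counts divided by total observation hours).
    """
    if total_hours <= 0:
        raise ValueError("total observation time must be positive")
    if n_calls < 0:
        raise ValueError("n_calls must be non-negative")
    return n_calls / total_hours
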