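"""Periodogram analysis of active-state dR/R segments.

Active-state segments are mean-subtracted and Fourier transformed with
zero-padding to the next power of two at least 4x the segment length (about
1-2 mHz frequency spacing for a two-minute segment at 20 frames/s); the
dominant rhythm is the largest power peak between 0 and 250 mHz, excluding the
zero-frequency bin.  A Lomb-Scargle periodogram (for uneven sampling or event
trains) and an autocorrelation estimate are provided as cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

__all__ = [
    "Periodogram",
    "periodogram_fft",
    "periodogram_lomb_scargle",
    "periodogram_autocorrelation",
    "dominant_peak",
    "active_segments",
]

DEFAULT_BAND = (0.0, 250.0)  # mHz


@dataclass
class Periodogram:
    frequency_mhz: np.ndarray
    power: np.ndarray
    method: str
    segment: tuple = (np.nan, np.nan)
    low_resolution: bool = False

    @property
    def grid_spacing_mhz(self) -> float:
        return float(self.frequency_mhz[1] - self.frequency_mhz[0]) \
            if self.frequency_mhz.size > 1 else np.nan

    def dominant_peak(self, band=DEFAULT_BAND):
        return dominant_peak(self, band)


def _next_pow2(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(n, 1))))


def periodogram_fft(segment: np.ndarray, frame_rate: float,
                    span=(np.nan, np.nan), taper: str | None = None) -> Periodogram:
    """Squared-magnitude FFT spectrum of a mean-subtracted, zero-padded segment.

    No taper is applied by default (segments are short); ``taper='hann'`` is
    available.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("segment too short for a periodogram")
    low_res = n / frame_rate < 30.0
    if low_res:
        warnings.warn("segment shorter than 30 s; periodogram flagged low-resolution")
    xm = x - x.mean()
    if taper == "hann":
        xm = xm * np.hanning(n)
    nfft = _next_pow2(4 * n)
    coeffs = np.fft.rfft(xm, nfft)
    power = np.abs(coeffs) ** 2
    freq = np.fft.rfftfreq(nfft, d=1.0 / frame_rate) * 1000.0
    return Periodogram(frequency_mhz=freq, power=power, method="fft",
                       segment=tuple(span), low_resolution=low_res)


def periodogram_lomb_scargle(times, values=None, frame_rate: float = 20.0,
                             max_freq_mhz: float = 300.0,
                             span=(np.nan, np.nan)) -> Periodogram:
    """Normalized Lomb-Scargle periodogram for unevenly sampled segments.

    With ``values=None`` the input is treated as an event train and converted
    to a binarized series on a regular grid at ``frame_rate`` before analysis.
    """
    t = np.asarray(times, dtype=float)
    if values is None:
        if t.size < 4:
            raise ValueError("need at least 4 events")
        t0, t1 = t.min(), t.max()
        grid = np.arange(t0, t1 + 1.0 / frame_rate, 1.0 / frame_rate)
        x = np.zeros(grid.size)
        x[np.clip(np.round((t - t0) * frame_rate).astype(int), 0, grid.size - 1)] = 1.0
        t = grid
    else:
        x = np.asarray(values, dtype=float)
        if t.size != x.size:
            raise ValueError("times and values must have the same length")
        if t.size < 4:
            raise ValueError("need at least 4 samples")
    duration = t[-1] - t[0]
    nfft = _next_pow2(int(4 * duration * frame_rate))
    df_mhz = frame_rate / nfft * 1000.0
    freq = np.arange(df_mhz, max_freq_mhz + df_mhz, df_mhz)
    omega = 2.0 * np.pi * freq / 1000.0
    power = lombscargle(t, x - x.mean(), omega, normalize=True)
    return Periodogram(frequency_mhz=freq, power=power, method="lomb_scargle",
                       segment=tuple(span))


def periodogram_autocorrelation(segment: np.ndarray, frame_rate: float,
                                span=(np.nan, np.nan)) -> Periodogram:
    """Rhythm estimate from the first significant positive autocorrelation peak.

    The reported "power" is the autocorrelation as a function of 1/lag so the
    dominant-peak machinery applies; significance bound is 2/sqrt(n).
    """
    from scipy.signal import find_peaks

    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("segment too short")
    xm = x - x.mean()
    acf = np.correlate(xm, xm, mode="full")[n - 1:]
    denom = acf[0]
    if denom <= 0:
        raise ValueError("zero-variance segment")
    acf = acf / denom
    idx, _ = find_peaks(acf)
    bound = 2.0 / np.sqrt(n)
    lags = idx / frame_rate
    freq = np.where(lags > 0, 1000.0 / lags, np.inf)
    keep = acf[idx] > bound
    return Periodogram(frequency_mhz=freq[keep][::-1], power=acf[idx][keep][::-1],
                       method="autocorrelation", segment=tuple(span))


def dominant_peak(p: Periodogram, band=DEFAULT_BAND):
    """(frequency mHz, power) of the largest peak in the open band, excluding
    the zero-frequency bin; ties break toward the lower frequency."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty frequency band")
    mask = (p.frequency_mhz > lo) & (p.frequency_mhz <= hi) & (p.frequency_mhz > 0)
    if not mask.any():
        raise ValueError("no frequencies inside the band")
    freqs = p.frequency_mhz[mask]
    powers = p.power[mask]
    # argmax returns the first occurrence; frequencies increase, so ties
    # resolve toward the lower frequency
    i = int(np.argmax(powers))
    return float(freqs[i]), float(powers[i])


def active_segments(trace, states, min_duration: float = 30.0):
    """Yield (start, end, dR/R slice) for each active interval of at least
    ``min_duration`` seconds."""
    if trace.droverr is None:
        raise ValueError("trace has no dR/R; run compute_baseline first")
    for s, e in states.active():
        if e - s < min_duration:
            continue
        i0 = int(np.ceil(s * trace.frame_rate))
        i1 = int(np.floor(e * trace.frame_rate))
        i0 = max(i0, 0)
        i1 = min(i1, trace.droverr.size)
        if i1 - i0 >= 2:
            yield s, e, trace.droverr[i0:i1]
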