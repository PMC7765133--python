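"""Multitaper spectral estimation and relative band-limited power (BLP).

Band power is estimated with discrete prolate spheroidal (Slepian) tapers
averaged across eigenspectra, then normalised by the summed power of the
four sleep bands so that subjects with different skull conductivity remain
comparable. The windowed version supplies the BLP time series that later
becomes a BOLD regressor.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.signal import windows as _windows

from .core import (
    BAND_NAMES,
    BandPowerSeries,
    ConfigurationError,
    DataError,
    EEGRecording,
    PreconditionError,
)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


#: Contiguous, non-overlapping sleep bands in Hz. Bins are assigned to the
#: half-open interval [lo, hi) except beta which closes at 30.0, so a bin on
#: a shared edge is never counted twice.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.5),
    BandDefinition("theta", 4.5, 8.5),
    BandDefinition("alpha", 8.5, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

DEFAULT_NW = 2.0
DEFAULT_K = 3


def dpss_tapers(n_samples: int, nw: float = DEFAULT_NW, k: int = DEFAULT_K) -> np.ndarray:
    """Return k orthonormal Slepian tapers as a k x n_samples matrix.

    The tapers maximise energy concentration in the band
    [-nw/n, nw/n] cycles/sample; k must satisfy 1 <= k <= 2*nw - 1.
    """
    if n_samples < 8:
        raise PreconditionError("need at least 8 samples for taper design")
    if not (1 <= k <= 2 * nw - 1):
        raise ConfigurationError(
            f"taper count k={k} outside [1, 2*nw-1] = [1, {2 * nw - 1:g}]"
        )
    tapers = _windows.dpss(n_samples, nw, Kmax=k, norm=2)
    return np.atleast_2d(tapers)


def multitaper_spectrum(
    segment: np.ndarray, rate: float, nw: float = DEFAULT_NW, k: int = DEFAULT_K
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenspectrum average for channels x samples data.

    Returns ``(freqs, psd)`` with ``psd`` channels x bins scaled so the sum
    over all bins equals the taper-weighted mean square of the signal
    (a discrete Parseval convention; relative band shares are unaffected).
    """
    segment = np.atleast_2d(np.asarray(segment, float))
    n = segment.shape[1]
    if n == 0:
        raise PreconditionError("empty segment")
    tapers = dpss_tapers(n, nw, k)  # k x n
    # channels x k x bins
    spectra = np.fft.rfft(segment[:, None, :] * tapers[None, :, :], axis=-1)
    power = (spectra.real**2 + spectra.imag**2) / n
    # one-sided: double everything except DC (and Nyquist when n even)
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    psd = power.mean(axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, psd


def _band_slices(freqs: np.ndarray, bands) -> list[np.ndarray]:
    out = []
    last = bands[-1]
    for b in bands:
        if b is last:
            sel = (freqs >= b.lo) & (freqs <= b.hi)
        else:
            sel = (freqs >= b.lo) & (freqs < b.hi)
        out.append(sel)
    return out


def band_power(
    segment: np.ndarray,
    rate: float,
    bands=DEFAULT_BANDS,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> np.ndarray:
    """Absolute multitaper band powers, channels x n_bands.

    Segments shorter than 2 s resolve the 0.5 Hz delta edge poorly and
    trigger a warning; shorter than 1 s is rejected.
    """
    segment = np.atleast_2d(np.asarray(segment, float))
    if segment.shape[1] == 0:
        raise PreconditionError("empty segment")
    dur = segment.shape[1] / rate
    if dur < 1.0:
        raise PreconditionError(f"segment of {dur:.3f} s is below the 1 s minimum")
    if dur < 2.0:
        warnings.warn("segment shorter than 2 s: delta band poorly resolved")
    freqs, psd = multitaper_spectrum(segment, rate, nw, k)
    sels = _band_slices(freqs, bands)
    return np.stack([psd[:, sel].sum(axis=1) for sel in sels], axis=1)


def relative_power(absolute: np.ndarray) -> np.ndarray:
    """Normalise each channel's band powers by the four-band total.

    All-zero rows (flat signal) are mapped to the uninformative uniform
    share 1/n_bands rather than NaN.
    """
    absolute = np.atleast_2d(np.asarray(absolute, float))
    if np.any(absolute < 0):
        raise DataError("negative band power")
    total = absolute.sum(axis=1, keepdims=True)
    out = np.full_like(absolute, 1.0 / absolute.shape[1])
    ok = total[:, 0] > 0
    out[ok] = absolute[ok] / total[ok]
    return out


def blp_time_series(
    eeg: EEGRecording,
    window: float = 2.0,
    step: float = 1.0,
    bands=DEFAULT_BANDS,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
    t_start: float = 0.0,
) -> BandPowerSeries:
    """Sliding-window relative band power for a whole recording.

    ``t_start`` maps sample 0 of the recording onto the session clock
    (negative when the EEG starts before the first fMRI volume). Window
    centers are reported on that clock. All windows are tapered and
    Fourier-transformed in one batched pass, so full sessions stay cheap.
    """
    if window < 1.0:
        raise ConfigurationError("window must be at least 1 s")
    if step <= 0:
        raise ConfigurationError("step must be positive")
    if window > eeg.duration:
        raise PreconditionError("window longer than the recording")
    wlen = int(round(window * eeg.rate))
    hop = step * eeg.rate
    n_windows = int(np.floor((eeg.n_samples - wlen) / hop)) + 1
    starts = np.round(np.arange(n_windows) * hop).astype(int)
    tapers = dpss_tapers(wlen, nw, k)
    idx = starts[:, None] + np.arange(wlen)[None, :]
    seg = eeg.signal[:, idx]  # channels x windows x wlen
    spec = np.fft.rfft(seg[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    power = (spec.real**2 + spec.imag**2) / wlen
    power[..., 1:] *= 2.0
    if wlen % 2 == 0:
        power[..., -1] /= 2.0
    psd = power.mean(axis=2)  # channels x windows x bins
    freqs = np.fft.rfftfreq(wlen, d=1.0 / eeg.rate)
    sels = _band_slices(freqs, bands)
    absolute = np.stack([psd[:, :, sel].sum(axis=2) for sel in sels], axis=2)
    total = absolute.sum(axis=2, keepdims=True)
    rel = np.full_like(absolute, 1.0 / absolute.shape[2])
    ok = total[..., 0] > 0
    rel[ok] = absolute[ok] / total[ok]
    centers = t_start + (starts + wlen / 2.0) / eeg.rate
    return BandPowerSeries(
        values=rel,
        window_centers=centers,
        window_length=window,
        step=step,
        taper_params=(nw, k),
        bands=tuple(b.name for b in bands),
    )


def band_names(bands=DEFAULT_BANDS) -> tuple[str, ...]:
    names = tuple(b.name for b in bands)
    assert names == BAND_NAMES or len(names) == len(set(names))
    return names
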