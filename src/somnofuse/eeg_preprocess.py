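"""MR-environment and physiological artifact removal for in-scanner EEG.

The chain mirrors standard simultaneous-EEG-fMRI practice: sliding-window
average-artifact subtraction (AAS) with a PCA residual basis for the
TR-periodic gradient artifact, an optimal-basis-set (OBS) approach with
per-beat least-squares refit for the cardiac (ballistocardiographic)
artifact, ICA-based eye-artifact rejection against a blink reference, and
finally zero-phase band-pass + notch filtering with mastoid referencing.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal as _sig
from sklearn.decomposition import FastICA

from .core import (
    ConfigurationError,
    DataError,
    EEGRecording,
    NumericalError,
    PreconditionError,
    VOLUME_TRIGGER,
)


@dataclass
class BeatTrain:
    """Detected heartbeat onsets in seconds with per-beat confidence."""

    onsets: np.ndarray
    confidence: np.ndarray
    flags: list[str]

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, float)
        self.confidence = np.asarray(self.confidence, float)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise DataError("beat onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


def _sliding_window_indices(n_epochs: int, window: int) -> list[np.ndarray]:
    """For each epoch, the indices of the ``window`` nearest other epochs."""
    out = []
    for i in range(n_epochs):
        order = np.argsort(np.abs(np.arange(n_epochs) - i), kind="stable")
        picks = [j for j in order if j != i][:window]
        out.append(np.sort(np.array(picks, dtype=int)))
    return out


def remove_gradient_artifact(
    eeg: EEGRecording,
    window_epochs: int = 30,
    n_residual_basis: int = 4,
) -> EEGRecording:
    """Sliding-template AAS with an optional PCA residual (OBS) step.

    Per channel and per volume epoch, the mean of the ``window_epochs``
    nearest *other* epochs is subtracted; excluding the current epoch
    keeps the brain signal of the epoch itself untouched. Residual epochs
    are then projected onto their first ``n_residual_basis`` principal
    components, which are fitted and subtracted per epoch. Samples before
    the first and after the last trigger epoch pass through unchanged and
    are flagged in ``meta['ga_untouched_samples']``.
    """
    triggers = eeg.event_samples(VOLUME_TRIGGER)
    if triggers.size == 0:
        raise PreconditionError("no volume triggers in the recording")
    if triggers.size < window_epochs:
        raise PreconditionError(
            f"only {triggers.size} trigger epochs, need >= window_epochs={window_epochs}")
    spacing = np.diff(triggers)
    if spacing.size and (spacing.max() - spacing.min()) > 1:
        bad = int(np.argmax(np.abs(spacing - np.median(spacing))))
        raise DataError(
            f"irregular volume-trigger spacing at interval {bad}: "
            f"{spacing[bad]} samples vs median {int(np.median(spacing))}")
    L = int(np.median(spacing)) if spacing.size else eeg.n_samples - triggers[0]
    n_ep = triggers.size
    out = eeg.copy()
    # channels x epochs x L view of the artifact-bearing span
    idx = triggers[:, None] + np.arange(L)[None, :]
    valid = idx[:, -1] < eeg.n_samples
    idx = idx[valid]
    n_ep = idx.shape[0]
    epochs = eeg.signal[:, idx]  # ch x n_ep x L
    csum = np.concatenate(
        [np.zeros((eeg.n_channels, 1, L)), np.cumsum(epochs, axis=1)], axis=1)
    windows = _sliding_window_indices(n_ep, min(window_epochs, n_ep - 1))
    templates = np.empty_like(epochs)
    for i, w in enumerate(windows):
        # nearest-neighbour windows are contiguous runs around i (minus i
        # itself), so two cumsum spans give the mean cheaply
        lo, hi = w[0], w[-1]
        if lo <= i <= hi:
            s = (csum[:, hi + 1] - csum[:, lo]) - epochs[:, i]
            templates[:, i] = s / (hi - lo)
        else:
            templates[:, i] = (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)
    residual = epochs - templates
    if n_residual_basis > 0 and n_ep > n_residual_basis + 2:
        for c in range(eeg.n_channels):
            mat = residual[c]  # n_ep x L
            mu = mat.mean(axis=0)
            centered = mat - mu
            # principal directions of the residual epochs
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            basis = vt[:n_residual_basis]  # n_basis x L
            coefs = centered @ basis.T
            residual[c] = centered - coefs @ basis + mu
    cleaned = eeg.signal.copy()
    cleaned[:, idx] = residual
    out.signal = cleaned
    untouched = int(triggers[0]) + int(eeg.n_samples - (triggers[n_ep - 1] + L))
    out.meta["ga_untouched_samples"] = untouched
    out.meta["ga_window_epochs"] = window_epochs
    out.reference = eeg.reference + "+aas"
    return out


def detect_heartbeats(
    reference_channel: np.ndarray, rate: float, refractory: float = 0.35
) -> BeatTrain:
    """Peak-pick a band-passed energy envelope to find cardiac beats.

    The channel is band-passed 0.5-20 Hz, squared, smoothed to an energy
    envelope, and local maxima separated by at least ``refractory``
    seconds are taken as beats; confidence is the normalised peak
    prominence. A flat channel yields an empty low-confidence train.
    """
    x = np.asarray(reference_channel, float).ravel()
    if x.size < 10 * rate:
        raise PreconditionError("need at least 10 s of signal")
    if np.ptp(x) == 0:
        return BeatTrain(np.array([]), np.array([]), ["flat_signal"])
    sos = _sig.butter(4, [0.5, 20.0], btype="bandpass", fs=rate, output="sos")
    bp = _sig.sosfiltfilt(sos, x)
    env = bp**2
    smooth_n = max(int(0.08 * rate), 3)
    env = np.convolve(env, np.ones(smooth_n) / smooth_n, mode="same")
    peaks, props = _sig.find_peaks(
        env, distance=max(int(refractory * rate), 1), prominence=0.0)
    if peaks.size == 0:
        return BeatTrain(np.array([]), np.array([]), ["no_peaks"])
    prom = props["prominences"]
    # beat period from the envelope autocorrelation in the plausible
    # cardiac range, then interval-consistent tracking: a multi-lobed
    # cardiac waveform makes raw peak-picking alternate between lobes,
    # which per-beat template fitting cannot tolerate
    env_c = env - env.mean()
    ac = _sig.fftconvolve(env_c, env_c[::-1])[env_c.size - 1 :]
    lo, hi = int(0.5 * rate), min(int(1.5 * rate), ac.size - 1)
    flags = []
    if hi > lo:
        period = (lo + int(np.argmax(ac[lo:hi]))) / rate
        peaks, prom = _track_beats(env, rate, period, refractory)
    else:
        flags.append("short_record_no_period")
    if peaks.size == 0:
        return BeatTrain(np.array([]), np.array([]), flags + ["no_peaks"])
    conf = prom / prom.max()
    peaks = _matched_filter_refine(bp, rate, peaks)
    order = np.argsort(peaks)
    peaks, conf = peaks[order], conf[order]
    dedup = np.concatenate([[True], np.diff(peaks) > refractory * rate / 2])
    peaks, conf = peaks[dedup], conf[dedup]
    ibi = np.diff(peaks) / rate
    if ibi.size and not (0.25 <= np.median(ibi) <= 2.5):
        flags.append("implausible_rate")
    return BeatTrain(peaks / rate, conf, flags)


def _track_beats(
    env: np.ndarray, rate: float, period: float, refractory: float, penalty: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pick one envelope peak per cardiac cycle by dynamic programming.

    Candidate peaks score by normalised prominence; transitions between
    consecutive beats are penalised by the squared deviation of the
    interval from the autocorrelation period, so the tracker stays on the
    same waveform lobe instead of hopping between lobes of similar energy.
    """
    cand, props = _sig.find_peaks(env, distance=max(int(0.1 * rate), 1), prominence=0.0)
    if cand.size == 0:
        return np.array([], int), np.array([])
    prom = props["prominences"]
    score = prom / (np.median(prom) + 1e-30)
    score = np.log1p(score)
    p_samp = period * rate
    lo_i, hi_i = 0.55 * p_samp, 1.6 * p_samp
    n = cand.size
    dp = score.copy()
    prev = np.full(n, -1)
    start = 0
    for i in range(n):
        while cand[i] - cand[start] > hi_i:
            start += 1
        best, arg = 0.0, -1
        for j in range(start, i):
            gap = cand[i] - cand[j]
            if gap < max(lo_i, refractory * rate):
                continue
            val = dp[j] - penalty * ((gap - p_samp) / p_samp) ** 2
            if val > best:
                best, arg = val, j
        dp[i] += max(best, 0.0)
        prev[i] = arg
    i = int(np.argmax(dp))
    path = []
    while i >= 0:
        path.append(i)
        i = prev[i]
    path = path[::-1]
    return cand[path], prom[path]


def _matched_filter_refine(
    bp: np.ndarray, rate: float, peaks: np.ndarray, half_window: float = 0.45,
    search: float = 0.25, n_iter: int = 2,
) -> np.ndarray:
    """Tighten beat onsets by cross-correlating with the beat-triggered
    average waveform; the cardiac artifact repeats (up to scale) every
    beat, so the matched filter pins the phase that envelope peak-picking
    leaves ambiguous."""
    h = int(half_window * rate)
    s = int(search * rate)
    onsets = peaks.astype(int)
    for _ in range(n_iter):
        segs = [bp[p - h : p + h] for p in onsets if h <= p < bp.size - h]
        if len(segs) < 5:
            return onsets
        template = np.mean(segs, axis=0)
        template -= template.mean()
        score = _sig.fftconvolve(bp, template[::-1], mode="same")
        refined = []
        for p in onsets:
            lo, hi = max(p - s, 0), min(p + s, bp.size)
            refined.append(lo + int(np.argmax(score[lo:hi])))
        onsets = np.array(refined, dtype=int)
    return onsets


def remove_pulse_artifact(
    eeg: EEGRecording,
    beats: BeatTrain,
    n_basis: int = 3,
    window: tuple[float, float] = (-0.1, 0.7),
    pooled_scale: bool = True,
) -> EEGRecording:
    """OBS removal of the cardiac artifact with per-beat refit.

    Beat-locked epochs (``window`` seconds around each onset, truncated at
    the next beat) are collected per channel; the first ``n_basis``
    principal components of the uncentered epoch matrix form the basis
    (the leading one is the artifact template itself), and per-epoch
    coefficients are refitted by least squares and subtracted (the
    "adaptive" step). Samples outside epochs are unchanged.

    With ``pooled_scale`` the leading coefficient — the per-beat artifact
    scale, which is common to all channels because the cardiac artifact
    is spatially coherent — is solved jointly across channels (energy
    weighted least squares). Pooling divides the brain-signal leakage
    into the fit by roughly the channel count; per-channel fits remain
    for the higher basis components.
    """
    if len(beats) == 0:
        warnings.warn("empty beat train: pulse-artifact removal skipped")
        out = eeg.copy()
        out.meta["pa_skipped"] = True
        return out
    if n_basis < 1:
        raise ConfigurationError("n_basis must be >= 1")
    if len(beats) < max(20, n_basis + 5):
        raise PreconditionError(
            f"{len(beats)} beats is too few (need >= {max(20, n_basis + 5)})")
    rate = eeg.rate
    o0 = int(round(window[0] * rate))
    L = int(round((window[1] - window[0]) * rate))
    starts = np.round(beats.onsets * rate).astype(int) + o0
    next_start = np.append(starts[1:], eeg.n_samples)
    lengths = np.minimum(L, next_start - starts)
    lengths = np.minimum(lengths, eeg.n_samples - starts)
    ok = (starts >= 0) & (lengths > n_basis)
    starts, lengths = starts[ok], lengths[ok]
    full = lengths == L
    if full.sum() < n_basis + 2:
        raise PreconditionError("too few full-length beat epochs for the OBS basis")
    out = eeg.copy()
    n_ch = eeg.n_channels

    def build_basis(starts_now):
        idx = starts_now[full][:, None] + np.arange(L)[None, :]
        tpl = np.empty((n_ch, L))
        ext = []
        for c in range(n_ch):
            mat = eeg.signal[c][idx]  # n_full x L
            _, _, vt = np.linalg.svd(mat, full_matrices=False)
            tpl[c] = vt[0]
            ext.append(vt[1:n_basis])
        return tpl, ext

    templates, extras = build_basis(starts)
    if pooled_scale:
        # per-beat onset realignment: the detected onsets carry jitter
        # that is identical across channels, so a pooled matched filter
        # (sum of squared per-channel template correlations) pins each
        # beat to sample precision before any coefficient is fitted
        search = int(round(0.12 * rate))
        for _round in range(2):
            if search <= 0:
                break
            score = np.zeros(eeg.n_samples)
            for c in range(n_ch):
                mf = _sig.fftconvolve(eeg.signal[c], templates[c][::-1], mode="full")
                # mf[j] correlates the segment starting at j - L + 1
                aligned = mf[L - 1 :]
                score[: aligned.size] += aligned**2
            refined = []
            for s in starts:
                lo = max(s - search, 0)
                hi = min(s + search + 1, score.size)
                refined.append(lo + int(np.argmax(score[lo:hi])))
            starts = np.array(refined, dtype=int)
            order = np.argsort(starts)
            starts = starts[order]
            keep = np.concatenate([[True], np.diff(starts) > L // 4])
            starts = starts[keep]
            next_start = np.append(starts[1:], eeg.n_samples)
            lengths = np.minimum(L, next_start - starts)
            lengths = np.minimum(lengths, eeg.n_samples - starts)
            inb = (starts >= 0) & (lengths > n_basis)
            starts, lengths = starts[inb], lengths[inb]
            full = lengths == L
            templates, extras = build_basis(starts)
            search = max(search // 3, 2)
    n_ep = starts.size
    if pooled_scale:
        # leading coefficient per (channel, epoch), then the common
        # per-beat scale as the energy-weighted average of normalised
        # coefficients across channels
        alpha = np.zeros((n_ch, n_ep))
        for c in range(n_ch):
            t = templates[c]
            for i, (s, ln) in enumerate(zip(starts, lengths)):
                b = t[:ln]
                alpha[c, i] = b @ eeg.signal[c, s : s + ln] / (b @ b)
        mean_alpha = np.median(alpha, axis=1)
        w = mean_alpha**2
        if w.sum() == 0:
            w = np.ones(n_ch)
        safe = np.where(mean_alpha == 0, 1.0, mean_alpha)
        ratios = alpha / safe[:, None]
        scale = (w[:, None] * ratios).sum(axis=0) / w.sum()
        for c in range(n_ch):
            t = templates[c]
            for i, (s, ln) in enumerate(zip(starts, lengths)):
                out.signal[c, s : s + ln] -= scale[i] * mean_alpha[c] * t[:ln]
    for c in range(n_ch):
        if pooled_scale:
            basis = extras[c]
        else:
            basis = np.vstack([templates[c][None, :], extras[c]])
        if basis.shape[0] == 0:
            continue
        for s, ln in zip(starts, lengths):
            seg = out.signal[c, s : s + ln]
            b = basis[:, :ln]
            coef, *_ = np.linalg.lstsq(b.T, seg, rcond=None)
            out.signal[c, s : s + ln] = seg - coef @ b
    out.meta["pa_n_beats"] = int(len(beats))
    out.reference = eeg.reference + "+obs"
    return out


def remove_eye_artifact(
    eeg: EEGRecording,
    blink_reference: str | np.ndarray | None = None,
    corr_threshold: float = 0.7,
    max_components: int | None = None,
    random_state: int = 97,
) -> EEGRecording:
    """Zero ICA components correlated with a blink reference.

    ``blink_reference`` may be a channel label, an explicit time series,
    or ``None`` to use the average of the most frontal quarter of the
    sensors (largest y coordinate). Components whose absolute Pearson
    correlation with the reference reaches ``corr_threshold`` are zeroed
    and the mixing inverted; if none reach it the output equals the input.
    """
    if corr_threshold <= 0:
        raise ConfigurationError("corr_threshold must be positive (0 would remove everything)")
    if isinstance(blink_reference, str):
        if blink_reference not in eeg.labels:
            raise DataError(f"blink reference channel {blink_reference!r} not found")
        ref = eeg.signal[eeg.labels.index(blink_reference)]
    elif blink_reference is None:
        if eeg.positions is None:
            raise DataError("positions required to derive a frontal blink reference")
        n_front = max(2, eeg.n_channels // 4)
        front = np.argsort(eeg.positions[:, 1])[-n_front:]
        ref = eeg.signal[front].mean(axis=0)
    else:
        ref = np.asarray(blink_reference, float).ravel()
        if ref.size != eeg.n_samples:
            raise DataError("blink reference length != sample count")
    rank = np.linalg.matrix_rank(eeg.signal @ eeg.signal.T / eeg.n_samples)
    if rank < eeg.n_channels:
        raise NumericalError(
            f"rank-deficient data: rank {rank} < {eeg.n_channels} channels")
    n_comp = max_components or eeg.n_channels
    ica = FastICA(n_components=n_comp, random_state=random_state, max_iter=500, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on long records
        sources = ica.fit_transform(eeg.signal.T)  # samples x comps
    ref_c = ref - ref.mean()
    src_c = sources - sources.mean(axis=0)
    denom = np.linalg.norm(src_c, axis=0) * np.linalg.norm(ref_c)
    denom[denom == 0] = np.inf
    corr = np.abs(src_c.T @ ref_c) / denom
    bad = corr >= corr_threshold
    out = eeg.copy()
    if bad.any():
        sources[:, bad] = 0.0
        recon = ica.inverse_transform(sources).T
        out.signal = recon
    out.meta["eye_components_removed"] = int(bad.sum())
    out.meta["eye_component_corrs"] = corr[bad].tolist()
    out.reference = eeg.reference + "+ica-eye"
    return out


def filter_and_reference(
    eeg: EEGRecording,
    band: tuple[float, float] = (0.5, 30.0),
    notch: float | None = 50.0,
    mastoid_labels: tuple[str, str] = ("M1", "M2"),
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase band-pass + notch, then average-mastoid referencing."""
    lo, hi = band
    if not (0 < lo < hi < eeg.rate / 2):
        raise ConfigurationError(f"band {band} outside (0, rate/2)")
    for m in mastoid_labels:
        if m not in eeg.labels:
            raise DataError(f"mastoid channel {m!r} not found")
    sos = _sig.butter(order, [lo, hi], btype="bandpass", fs=eeg.rate, output="sos")
    x = _sig.sosfiltfilt(sos, eeg.signal, axis=1)
    if notch is not None and notch < eeg.rate / 2:
        b, a = _sig.iirnotch(notch, notch_q, fs=eeg.rate)
        x = _sig.filtfilt(b, a, x, axis=1)
    m_idx = [eeg.labels.index(m) for m in mastoid_labels]
    ref = x[m_idx].mean(axis=0)
    x = x - ref[None, :]
    out = eeg.copy()
    out.signal = x
    out.reference = f"mastoid-average({mastoid_labels[0]},{mastoid_labels[1]})"
    out.meta["filter_band"] = band
    out.meta["notch"] = notch
    return out


def preprocess_chain(
    eeg: EEGRecording,
    window_epochs: int | None = None,
    n_residual_basis: int = 4,
    n_pulse_basis: int = 1,
    eye_corr_threshold: float = 0.7,
    band: tuple[float, float] = (0.5, 30.0),
    notch: float | None = 50.0,
    mastoid_labels: tuple[str, str] = ("M1", "M2"),
    beat_channel: int | None = None,
    passes: int = 2,
) -> EEGRecording:
    """Full artifact-removal chain: AAS -> beat detection -> OBS -> eye ICA
    -> filter + mastoid reference.

    ``window_epochs=None`` uses every available epoch for the gradient
    template. A narrow sliding window entangles the template with the
    cardiac artifact whenever the heart period is near-commensurate with
    the TR (the neighbour-mean of the pulse is then locally beat-phase
    locked, so the OBS step absorbs it into its estimate and leaves a
    large leak); with a temporally stable gradient waveform the widest
    window minimises that leakage. Use ~30 for drifting gradients, and
    ``passes=2`` to re-estimate the template on pulse-subtracted data.
    """
    n_triggers = len(eeg.event_samples(VOLUME_TRIGGER))
    if window_epochs is None:
        window_epochs = max(n_triggers - 1, 1)
    # pass 1: pure AAS (no PCA residual step) so the beat-locked pulse
    # survives intact for detection and template estimation — the PCA
    # step would latch onto the pulse, the dominant residual, and smear
    # it across TR epochs
    aas_out = remove_gradient_artifact(eeg, window_epochs, 0)
    if beat_channel is None:
        # channel with the largest post-AAS low-frequency energy carries
        # the clearest cardiac signature
        sos = _sig.butter(4, [0.5, 20.0], btype="bandpass", fs=eeg.rate, output="sos")
        energy = (_sig.sosfiltfilt(sos, aas_out.signal, axis=1) ** 2).mean(axis=1)
        beat_channel = int(np.argmax(energy))
    beats = detect_heartbeats(aas_out.signal[beat_channel], eeg.rate)
    step = remove_pulse_artifact(aas_out, beats, n_pulse_basis)
    if passes > 1:
        # the gradient template of pass 1 inherits the neighbour-mean of
        # the cardiac artifact (a spatially coherent, TR-periodic comb),
        # which in turn contaminates the OBS scale estimates. Re-estimate
        # the template on pulse-subtracted data, add the pulse back, and
        # re-run the OBS fit on the now comb-free record.
        pulse_estimate = aas_out.signal - step.signal
        work = eeg.copy()
        work.signal = eeg.signal - pulse_estimate
        aas2 = remove_gradient_artifact(work, window_epochs, 0)
        full = aas2.copy()
        full.signal = aas2.signal + pulse_estimate
        step = remove_pulse_artifact(full, beats, n_pulse_basis)
    step.meta["pa_n_beats"] = int(len(beats))
    step = remove_eye_artifact(step, corr_threshold=eye_corr_threshold)
    return filter_and_reference(step, band, notch, mastoid_labels)


def harmonic_band_energy_db(
    eeg: EEGRecording, tr: float, n_harmonics: int = 12, half_width: float = 0.05
) -> float:
    """Total energy (dB) in narrow bands around harmonics of 1/TR.

    A before/after difference of this number measures gradient-artifact
    attenuation.
    """
    freqs = np.fft.rfftfreq(eeg.n_samples, 1 / eeg.rate)
    psd = np.abs(np.fft.rfft(eeg.signal, axis=1)) ** 2
    total = 0.0
    f0 = 1.0 / tr
    for h in range(1, n_harmonics + 1):
        sel = np.abs(freqs - h * f0) <= half_width
        total += psd[:, sel].sum()
    return 10 * np.log10(max(total, 1e-300))
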