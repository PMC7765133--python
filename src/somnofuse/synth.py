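"""Synthetic EEG-fMRI sleep cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure of a simultaneous
EEG-fMRI study of NREM parasomnia: two groups (8 controls, 9 patients by
default), sessions with an initial-wake interval followed by scattered
awakening (``A``) and transition-to-sleep (``T``) epochs, EEG built from
four band-limited oscillatory processes plus 1/f noise, MR gradient and
cardiac pulse artifacts, and BOLD volumes generated by the forward model
``y = X beta + eps`` with band-limited-power (BLP) regressors coupled to
labelled regions with configurable signs per group.

Every planted quantity (clean EEG, artifact templates, band-power tables,
true betas, event tables) is kept in :class:`GroundTruth` so each
downstream stage has an exact recovery oracle.

Defaults are desk-scale (32 channels, 250 Hz, 300 s, 12 x 14 x 12 grid);
the full-scale acquisition (256 channels, 1 kHz, ~83 min, TR = 1 s, 3 mm
voxels) is reachable through :class:`CohortSpec` fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig
from scipy.ndimage import gaussian_filter

from .core import (
    BAND_NAMES,
    ConfigurationError,
    DataError,
    DimensionError,
    EEGRecording,
    EventTable,
    MotionTrace,
    VolumeSeries,
    VOLUME_TRIGGER,
)
from .design import DesignMatrix, HRFSpec, hrf_kernel, occurrence_regressor

GROUPS = ("control", "patient")

#: Region labels standing in for atlas areas. ``frontal`` hosts the planted
#: condition (A/T) responses; the three posterior/medial labels host the
#: planted BLP couplings.
LABEL_IDS = {
    "background": 0,
    "precuneus": 1,
    "secondary_visual_cortex": 2,
    "dorsal_posterior_cingulate_cortex": 3,
    "frontal": 4,
}

_REGION_BOXES = {
    # fractional (lo, hi) extents along x, y (posterior -> anterior), z
    "secondary_visual_cortex": ((0.25, 0.75), (0.00, 0.29), (0.25, 0.58)),
    "precuneus": ((0.33, 0.67), (0.29, 0.57), (0.58, 0.92)),
    "dorsal_posterior_cingulate_cortex": ((0.33, 0.67), (0.29, 0.57), (0.25, 0.50)),
    "frontal": ((0.25, 0.75), (0.71, 1.00), (0.33, 0.67)),
}


@dataclass(frozen=True)
class PlantedEffect:
    """One cell of the planted region x band x group coupling pattern."""

    region_mask_id: str
    band: str
    group: str
    coupling_sign: int
    coupling_amplitude: float = 3.0

    def __post_init__(self):
        if self.coupling_sign not in (-1, 0, 1):
            raise ConfigurationError("coupling_sign must be -1, 0 or +1")
        if self.coupling_sign == 0 and self.coupling_amplitude != 0:
            raise ConfigurationError("sign 0 requires amplitude 0")
        if self.region_mask_id not in LABEL_IDS or self.region_mask_id == "background":
            raise ConfigurationError(f"unknown region label {self.region_mask_id!r}")
        if self.band not in BAND_NAMES:
            raise ConfigurationError(f"unknown band {self.band!r}")
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")


def default_effect_table(amplitude: float = 3.0) -> list[PlantedEffect]:
    """The default coupling-sign pattern over three regions and three bands.

    Secondary visual cortex couples positively in controls and negatively
    in patients for all three bands; the precuneus likewise except that
    its delta coupling is absent in controls; the dorsal posterior
    cingulate couples positively in both groups for alpha/theta but flips
    sign between groups for delta.
    """
    signs = {
        "secondary_visual_cortex": {
            "alpha": (1, -1), "theta": (1, -1), "delta": (1, -1)},
        "precuneus": {
            "alpha": (1, -1), "theta": (1, -1), "delta": (0, -1)},
        "dorsal_posterior_cingulate_cortex": {
            "alpha": (1, 1), "theta": (1, 1), "delta": (1, -1)},
    }
    table = []
    for region, per_band in signs.items():
        for band, (c_sign, p_sign) in per_band.items():
            for group, s in zip(GROUPS, (c_sign, p_sign)):
                table.append(
                    PlantedEffect(
                        region_mask_id=region,
                        band=band,
                        group=group,
                        coupling_sign=s,
                        coupling_amplitude=abs(s) * amplitude,
                    )
                )
    return table


def validation_effect_table(amplitude: float = 3.0) -> list[PlantedEffect]:
    """Effect table for the data-quality validation analyses.

    Plants only the well-established coupling those analyses are meant to
    recover: occipital (secondary visual cortex) alpha-power coupling,
    negative and common to both groups. The full sign table flips the
    occipital alpha sign between groups, which cancels in an
    across-subject one-sample t-test by construction — the validation map
    therefore gets its own cohort.
    """
    return [
        PlantedEffect("secondary_visual_cortex", "alpha", g, -1, amplitude)
        for g in GROUPS
    ]


@dataclass(frozen=True)
class EventModel:
    """Per-group occurrence statistics of A and T epochs.

    Counts are Poisson with per-minute rates matching the study inventory
    scaled by session length (minimum one occurrence of each condition is
    enforced so every subject contributes to the epoch statistics).
    Per-occurrence durations are log-normal with the listed mean/variance
    magnitudes, clipped to [2, 15] s; epochs never overlap.
    """

    a_rate_per_min: dict = field(
        default_factory=lambda: {"control": 0.455, "patient": 0.280})
    t_rate_per_min: dict = field(
        default_factory=lambda: {"control": 0.292, "patient": 0.110})
    a_duration_mean: dict = field(
        default_factory=lambda: {"control": 3.5, "patient": 3.9})
    a_duration_var: dict = field(
        default_factory=lambda: {"control": 29.4, "patient": 20.2})
    t_duration_mean: dict = field(
        default_factory=lambda: {"control": 5.7, "patient": 6.2})
    t_duration_var: dict = field(
        default_factory=lambda: {"control": 1.3, "patient": 2.1})
    duration_bounds: tuple[float, float] = (2.0, 15.0)
    wake_bounds: tuple[float, float] = (15.0, 35.0)


@dataclass(frozen=True)
class ArtifactModel:
    """Amplitudes (relative to brain-signal RMS) and timing of MR artifacts."""

    gradient_rms_ratio: float = 25.0
    pulse_rms_ratio: float = 3.0
    blink_rms_ratio: float = 2.0
    heart_rate_bpm: float = 62.0
    heart_jitter_sd: float = 0.04  # s, beat-to-beat
    pulse_scale_sd: float = 0.2
    blink_rate_hz: float = 0.12


@dataclass(frozen=True)
class SpectralEffect:
    """Planted group difference in A-epoch relative band power.

    Patients' relative share of each band in ``bands`` is raised during A
    epochs, on a contiguous posterior patch of ``n_electrodes`` channels,
    by ``effect_size_d`` times the per-channel between-subject share SD,
    the increase being compensated from the beta band so shares still sum
    to one.

    Between-subject variability has a subject-global part (``subject_sd``,
    shared by all channels — overall physiological state) and a dominant
    channel-local part (``channel_sd``); the effect size is defined
    against their quadrature sum. Keeping the global part small keeps the
    channel-wise t-fields weakly correlated, which is what makes a
    focal electrode cluster detectable against the permutation null.
    """

    bands: tuple[str, ...] = ("delta", "theta", "alpha")
    effect_size_d: float = 1.5
    n_electrodes: int = 10
    subject_sd: float = 0.008
    channel_sd: float = 0.0183

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.subject_sd, self.channel_sd))


@dataclass(frozen=True)
class CohortSpec:
    n_controls: int = 8
    n_patients: int = 9
    session_duration: float = 300.0  # s
    tr: float = 1.0  # s
    eeg_rate: float = 250.0  # Hz
    n_channels: int = 32
    grid_shape: tuple[int, int, int] = (12, 14, 12)
    voxel_size: float = 3.0  # mm
    seed: int = 0
    effect_table: tuple[PlantedEffect, ...] = tuple(default_effect_table())
    event_model: EventModel = EventModel()
    artifacts: ArtifactModel = ArtifactModel()
    spectral_effect: SpectralEffect = SpectralEffect()
    bold_noise_sd: float = 1.0
    bold_baseline: float = 100.0
    condition_amplitude: float = 2.0  # frontal A response, BOLD units
    network_amplitude: float = 1.5
    brain_rms_uv: float = 10.0
    pink_ratio: float = 0.3
    pre_roll: float = 2.0  # s of EEG before the first volume trigger

    def validate(self) -> None:
        for name in ("n_controls", "n_patients", "n_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.eeg_rate < 60.0:
            raise ConfigurationError("eeg_rate must be at least 60 Hz (2 x 30 Hz)")
        if self.session_duration < 10 * self.tr:
            raise ConfigurationError("session_duration must cover >= 10 volumes")
        if int(np.prod(self.grid_shape)) < 64:
            raise ConfigurationError("grid_shape volume must be >= 64 voxels")
        if abs(self.tr * self.eeg_rate - round(self.tr * self.eeg_rate)) > 1e-9:
            raise ConfigurationError("tr x eeg_rate must be an integer sample count")
        if self.n_channels < self.spectral_effect.n_electrodes + 2:
            raise ConfigurationError(
                "n_channels too small for spectral_effect.n_electrodes plus mastoids")

    @property
    def n_scans(self) -> int:
        return int(round(self.session_duration / self.tr))


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream oracles."""

    clean_eeg: EEGRecording | None
    gradient_template: np.ndarray | None  # channels x samples-per-TR
    gradient_onsets: np.ndarray | None  # sample indices
    pulse_template: np.ndarray | None  # channels x template length
    pulse_onsets: np.ndarray | None  # sample indices
    pulse_scales: np.ndarray | None  # per beat
    blink_mixing: np.ndarray | None  # per channel
    blink_course: np.ndarray | None  # 1 x samples
    true_motion: MotionTrace | None
    true_betas: np.ndarray | None  # voxels x design columns
    true_design: DesignMatrix | None
    planted_electrodes: np.ndarray  # channel indices of the spectral effect
    event_table: EventTable
    band_shares: dict  # state -> channels x 4 planted relative shares
    rel_power_truth: np.ndarray | None  # channels x n_scans x 4 on the TR grid

    def gradient_component(self, n_samples: int) -> np.ndarray:
        out = np.zeros((self.gradient_template.shape[0], n_samples))
        L = self.gradient_template.shape[1]
        for s in self.gradient_onsets:
            out[:, s : s + L] += self.gradient_template[:, : n_samples - s]
        return out

    def pulse_component(self, n_samples: int) -> np.ndarray:
        out = np.zeros((self.pulse_template.shape[0], n_samples))
        L = self.pulse_template.shape[1]
        for s, a in zip(self.pulse_onsets, self.pulse_scales):
            seg = self.pulse_template[:, : n_samples - s]
            out[:, s : s + seg.shape[1]] += a * seg
        return out

    def blink_component(self) -> np.ndarray:
        return np.outer(self.blink_mixing, self.blink_course)


@dataclass
class SubjectBundle:
    subject_id: str
    group: str
    eeg: EEGRecording | None
    bold: VolumeSeries | None
    events: EventTable
    truth: GroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectBundle]
    label_volume: np.ndarray
    label_names: dict

    def group(self, name: str) -> list[SubjectBundle]:
        return [s for s in self.subjects if s.group == name]


# ---------------------------------------------------------------------------
# geometry helpers


def make_label_volume(grid_shape) -> np.ndarray:
    """Integer label volume with the four named regions on a common grid."""
    vol = np.zeros(grid_shape, dtype=int)
    for name, box in _REGION_BOXES.items():
        sl = tuple(
            slice(int(round(lo * n)), int(round(hi * n)))
            for (lo, hi), n in zip(box, grid_shape)
        )
        vol[sl] = LABEL_IDS[name]
    return vol


def region_mask(label_volume: np.ndarray, name: str) -> np.ndarray:
    return label_volume == LABEL_IDS[name]


def sensor_positions(n_channels: int) -> tuple[np.ndarray, list[str]]:
    """Sensor layout on the upper unit hemisphere (Fibonacci spiral).

    The last two channels are mastoid-analog references placed low and
    lateral; labels are E1..E{n-2}, M1, M2. The y axis points anterior,
    so occipital sensors have the most negative y.
    """
    if n_channels < 4:
        raise ConfigurationError("need at least 4 channels")
    n_scalp = n_channels - 2
    i = np.arange(n_scalp)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 0.15 + 0.85 * (i + 0.5) / n_scalp  # upper hemisphere only
    r = np.sqrt(1 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    mastoids = np.array([[0.95, -0.25, -0.2], [-0.95, -0.25, -0.2]])
    positions = np.vstack([pos, mastoids])
    labels = [f"E{j + 1}" for j in range(n_scalp)] + ["M1", "M2"]
    return positions, labels


def _planted_electrodes(positions: np.ndarray, n: int) -> np.ndarray:
    """Contiguous posterior patch: the occipital-most scalp sensor plus its
    nearest neighbours (mastoids excluded)."""
    scalp = np.arange(positions.shape[0] - 2)
    seed = scalp[np.argmin(positions[scalp, 1])]
    d = np.linalg.norm(positions[scalp] - positions[seed], axis=1)
    return scalp[np.argsort(d)[:n]]


# ---------------------------------------------------------------------------
# noise primitives


def _bandpass_noise(rng, n_ch: int, n: int, lo: float, hi: float, rate: float) -> np.ndarray:
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _pink_noise(rng, n_ch: int, n: int) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _slow_process(rng, n: int, fs: float, cutoff_hz: float = 0.03, sd: float = 1.0) -> np.ndarray:
    """Lowpass-filtered Gaussian noise, standardised to the requested SD."""
    wn = min(cutoff_hz / (fs / 2), 0.9)
    b, a = _sig.butter(2, wn)
    x = _sig.filtfilt(b, a, rng.standard_normal(n))
    s = x.std()
    if s > 0:
        x = x / s * sd
    return x


# ---------------------------------------------------------------------------
# events


def _lognormal_params(mean: float, var: float) -> tuple[float, float]:
    sigma2 = np.log(1 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def simulate_events(spec: CohortSpec, group: str, rng) -> EventTable:
    """Draw the initial-wake interval and non-overlapping A/T epochs."""
    em = spec.event_model
    wake_dur = rng.uniform(*em.wake_bounds)
    wake_dur = min(wake_dur, spec.session_duration * 0.3)
    records = [(0.0, float(wake_dur), "wake")]
    minutes = spec.session_duration / 60.0
    occupied = [(0.0, wake_dur + 2.0)]

    def place(condition, rate, dmean, dvar):
        count = max(1, int(rng.poisson(rate * minutes)))
        mu, sig = _lognormal_params(dmean, dvar)
        for _ in range(count):
            dur = float(np.clip(rng.lognormal(mu, sig), *em.duration_bounds))
            for _try in range(200):
                onset = rng.uniform(wake_dur + 2.0, spec.session_duration - dur - 1.0)
                if all(onset + dur + 1.0 <= lo or onset >= hi + 1.0 for lo, hi in occupied):
                    occupied.append((onset, onset + dur))
                    records.append((float(onset), dur, condition))
                    break

    place("A", em.a_rate_per_min[group], em.a_duration_mean[group], em.a_duration_var[group])
    place("T", em.t_rate_per_min[group], em.t_duration_mean[group], em.t_duration_var[group])
    frame_records = sorted(records, key=lambda r: r[0])
    return EventTable.from_records(frame_records)


# ---------------------------------------------------------------------------
# band shares (the planted spectral structure)

_BASE_SHARES = np.array([0.38, 0.24, 0.20, 0.18])  # delta, theta, alpha, beta
# physiological state modulations, identical for both groups
_A_STATE = {"alpha": +0.03, "delta": -0.03}
_T_STATE = {"delta": +0.02, "alpha": -0.02}


def _apply_shift(shares: np.ndarray, deltas: dict) -> np.ndarray:
    out = shares.copy()
    for band, d in deltas.items():
        out[..., BAND_NAMES.index(band)] += d
    return out


def subject_band_shares(spec: CohortSpec, group: str, rng) -> dict:
    """Planted relative band shares per channel for each behavioural state.

    Returns ``{"baseline"|"A"|"T": channels x 4}``; rows sum to one. The
    patient-only A-epoch shift on the planted electrode patch realises the
    configured Cohen's d against the between-subject share SD.
    """
    se = spec.spectral_effect
    base = _BASE_SHARES + se.subject_sd * rng.standard_normal(4)
    per_ch = base[None, :] + se.channel_sd * rng.standard_normal((spec.n_channels, 4))
    per_ch = np.clip(per_ch, 0.02, None)
    per_ch /= per_ch.sum(axis=1, keepdims=True)

    positions, _ = sensor_positions(spec.n_channels)
    planted = _planted_electrodes(positions, se.n_electrodes)

    a_shares = _apply_shift(per_ch, _A_STATE)
    if group == "patient":
        delta = se.effect_size_d * se.total_sd
        shift = {b: +delta for b in se.bands}
        shift["beta"] = shift.get("beta", 0.0) - delta * len(se.bands)
        a_shares[planted] = _apply_shift(a_shares[planted], shift)
    t_shares = _apply_shift(per_ch, _T_STATE)
    out = {"baseline": per_ch, "A": a_shares, "T": t_shares}
    floor = 0.003
    for v in out.values():
        low = v < floor
        if low.any():
            # rare tail draws: borrow the shortfall from the largest band
            # of the affected channel so the unit-sum invariant holds
            for ci, bi in zip(*np.nonzero(low)):
                shortfall = floor - v[ci, bi]
                donor = int(np.argmax(v[ci]))
                v[ci, donor] -= shortfall
                v[ci, bi] = floor
        if np.any(v < 0):
            raise DataError("band shares driven negative; reduce planted shifts")
        np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-9)
    return out


def simulate_band_share_tables(spec: CohortSpec, state: str = "A") -> dict:
    """Light-weight cohort draw of the planted per-subject share tables.

    Returns ``{"control": n_c x channels x 4, "patient": n_p x channels x 4,
    "planted_electrodes": indices}`` without synthesising any signals; this
    is the generator-side oracle for the electrode-space group statistics.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_controls + spec.n_patients)
    out = {}
    k = 0
    for group, n in zip(GROUPS, (spec.n_controls, spec.n_patients)):
        tables = []
        for _ in range(n):
            rng = np.random.default_rng(children[k])
            k += 1
            tables.append(subject_band_shares(spec, group, rng)[state])
        out[group] = np.stack(tables)
    positions, _ = sensor_positions(spec.n_channels)
    out["planted_electrodes"] = _planted_electrodes(
        positions, spec.spectral_effect.n_electrodes)
    return out


# ---------------------------------------------------------------------------
# EEG synthesis


def _state_occupancy(events: EventTable, n_scans: int, tr: float) -> np.ndarray:
    """Per-scan state index: 0 baseline, 1 A, 2 T (wake counts as baseline)."""
    state = np.zeros(n_scans, dtype=int)
    t = (np.arange(n_scans) + 0.5) * tr
    for _, row in events.frame.iterrows():
        if row["condition"] in ("A", "T"):
            code = 1 if row["condition"] == "A" else 2
            sel = (t >= row["onset"]) & (t < row["onset"] + row["duration"])
            state[sel] = code
    return state


def _band_power_trajectory(
    shares: dict, state: np.ndarray, drivers: np.ndarray
) -> np.ndarray:
    """channels x n_scans x 4 absolute band-power trajectory on the TR grid.

    ``drivers`` (4 x n_scans) are the slow multiplicative band
    fluctuations shared across channels; they both shape the EEG envelopes
    and, through the resulting relative power, drive the planted BOLD
    couplings.
    """
    state_shares = np.stack(
        [shares["baseline"], shares["A"], shares["T"]], axis=0
    )  # 3 x ch x 4
    per_scan = state_shares[state]  # n_scans x ch x 4
    power = per_scan.transpose(1, 0, 2) * drivers.T[None, :, :]
    return power


def synthesize_clean_eeg(
    spec: CohortSpec, power_traj: np.ndarray, rng
) -> EEGRecording:
    """Clean brain EEG realising a planted band-power trajectory.

    Four band-passed Gaussian-noise carriers are amplitude-modulated by
    the square root of the planted power trajectory (interpolated from the
    TR grid to the sample grid) and summed with 1/f noise.
    """
    from .spectral import DEFAULT_BANDS

    n = int(round((spec.pre_roll + spec.session_duration) * spec.eeg_rate))
    positions, labels = sensor_positions(spec.n_channels)
    t_scan = (np.arange(spec.n_scans) + 0.5) * spec.tr
    t_samp = np.arange(n) / spec.eeg_rate - spec.pre_roll
    signal = np.zeros((spec.n_channels, n))
    for bi, band in enumerate(DEFAULT_BANDS):
        carrier = _bandpass_noise(rng, spec.n_channels, n, band.lo, band.hi, spec.eeg_rate)
        env = np.empty((spec.n_channels, n))
        for c in range(spec.n_channels):
            env[c] = np.interp(t_samp, t_scan, power_traj[c, :, bi])
        signal += np.sqrt(np.clip(env, 0, None)) * carrier
    pink = _pink_noise(rng, spec.n_channels, n)
    signal = signal + spec.pink_ratio * pink
    signal *= spec.brain_rms_uv / signal.std()
    return EEGRecording(
        signal=signal,
        rate=spec.eeg_rate,
        labels=labels,
        positions=positions,
        events=[],
        reference="synthetic-clean",
    )


def gradient_template(spec: CohortSpec, rng, brain_rms: float) -> np.ndarray:
    """Deterministic multi-harmonic gradient waveform, channels x TR samples.

    Harmonics of 1/TR with 1/h amplitude decay and per-channel gains,
    scaled so the template RMS is ``gradient_rms_ratio`` times brain RMS.
    """
    L = int(round(spec.tr * spec.eeg_rate))
    t = np.arange(L) / spec.eeg_rate
    n_harm = min(40, L // 2 - 1)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    wave = np.zeros(L)
    for h in range(1, n_harm + 1):
        wave += np.sin(2 * np.pi * h * t / spec.tr + phases[h - 1]) / h
    gains = rng.uniform(0.5, 1.5, spec.n_channels)
    tmpl = np.outer(gains, wave)
    tmpl *= spec.artifacts.gradient_rms_ratio * brain_rms / np.sqrt((tmpl**2).mean())
    return tmpl


def pulse_template(spec: CohortSpec, rng, brain_rms: float) -> np.ndarray:
    """Cardiac-locked waveform (damped oscillation), channels x samples."""
    L = int(round(0.7 * spec.eeg_rate))
    t = np.arange(L) / spec.eeg_rate
    wave = np.exp(-t / 0.18) * np.sin(2 * np.pi * 7.0 * t) + 0.4 * np.exp(
        -((t - 0.35) ** 2) / (2 * 0.05**2)
    )
    wave *= _sig.windows.tukey(L, 0.2)
    gains = rng.uniform(0.6, 1.4, spec.n_channels) * rng.choice([-1, 1], spec.n_channels)
    tmpl = np.outer(gains, wave)
    tmpl *= spec.artifacts.pulse_rms_ratio * brain_rms / np.sqrt((tmpl**2).mean())
    return tmpl


def embed_gradient_artifact(
    eeg: EEGRecording, volume_onsets: np.ndarray, template: np.ndarray, amplitude: float = 1.0
) -> EEGRecording:
    """Add an identical per-channel template at every volume onset.

    Records ``volume_trigger`` events at the onsets; with amplitude 0 the
    signal is returned unchanged (triggers still added).
    """
    volume_onsets = np.asarray(volume_onsets, dtype=int)
    if np.any(np.diff(volume_onsets) <= 0):
        raise DataError("volume onsets must be strictly increasing")
    L = template.shape[1]
    if volume_onsets[-1] + L > eeg.n_samples:
        raise DataError(
            f"last volume onset {volume_onsets[-1]} + template length {L} "
            f"exceeds record length {eeg.n_samples}")
    out = eeg.copy()
    if amplitude != 0.0:
        for s in volume_onsets:
            out.signal[:, s : s + L] += amplitude * template
    out.events = sorted(
        out.events + [(int(s), VOLUME_TRIGGER) for s in volume_onsets])
    return out


def embed_pulse_artifact(
    eeg: EEGRecording,
    beat_onsets_s: np.ndarray,
    base_template: np.ndarray,
    per_beat_scale_sd: float = 0.2,
    rng=None,
) -> tuple[EEGRecording, np.ndarray]:
    """Add per-beat scaled copies of a template; returns (eeg, scales)."""
    beat_onsets_s = np.asarray(beat_onsets_s, float)
    if np.any(np.diff(beat_onsets_s) <= 0):
        raise DataError("beat onsets must be strictly increasing")
    intervals = np.diff(beat_onsets_s)
    if intervals.size and not (0.5 <= intervals.mean() <= 1.5):
        raise DataError("mean beat interval outside [0.5, 1.5] s")
    L = base_template.shape[1]
    if intervals.size and L > intervals.min() * eeg.rate:
        raise ConfigurationError("pulse template longer than the minimum beat interval")
    rng = np.random.default_rng(0) if rng is None else rng
    scales = 1.0 + per_beat_scale_sd * rng.standard_normal(beat_onsets_s.size)
    out = eeg.copy()
    onsets = np.round(beat_onsets_s * eeg.rate).astype(int)
    for s, a in zip(onsets, scales):
        if s >= eeg.n_samples:
            continue
        seg = base_template[:, : eeg.n_samples - s]
        out.signal[:, s : s + seg.shape[1]] += a * seg
    return out, scales


# ---------------------------------------------------------------------------
# BOLD forward model


def generate_bold(
    design: DesignMatrix,
    true_betas: np.ndarray,
    noise_sd: float,
    grid_shape,
    tr: float,
    rng=None,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> VolumeSeries:
    """Forward model ``y = X beta + eps`` with i.i.d. Gaussian noise."""
    true_betas = np.asarray(true_betas, float)
    n_vox = int(np.prod(grid_shape))
    if true_betas.shape != (n_vox, design.n_columns):
        raise DimensionError(
            f"true_betas shape {true_betas.shape} != (n_voxels={n_vox}, "
            f"n_columns={design.n_columns})")
    y = true_betas @ design.matrix.T  # voxels x scans
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        y = y + noise_sd * rng.standard_normal(y.shape)
    data = y.reshape(*grid_shape, design.n_scans)
    return VolumeSeries(data=data, tr=tr, voxel_size=voxel_size)


def _hrf_convolve_zscore(series: np.ndarray, tr: float, hrf: HRFSpec) -> np.ndarray:
    """HRF-convolve a TR-grid series on the microtime grid, then z-score.

    The series is an ongoing state, so the convolution is padded with the
    initial value: the session starts in steady state rather than with an
    artificial kernel-onset ramp.
    """
    kernel, dt = hrf_kernel(hrf, tr)
    bins = hrf.microtime_bins
    n = series.size
    t_scan = (np.arange(n) + 0.5) * tr
    grid = np.arange(n * bins) * dt
    dense = np.interp(grid, t_scan, series)
    pad = np.full(kernel.size, dense[0])
    conv = np.convolve(np.concatenate([pad, dense]), kernel)[
        kernel.size : kernel.size + dense.size]
    col = conv[np.arange(n) * bins]
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else np.zeros(n)


def _network_maps(label_volume: np.ndarray) -> dict[str, np.ndarray]:
    """Two resting-network templates: a medial default-mode-like map
    (precuneus + posterior cingulate) and a visual map, lightly smoothed."""
    dmn = (
        region_mask(label_volume, "precuneus")
        | region_mask(label_volume, "dorsal_posterior_cingulate_cortex")
    ).astype(float)
    vis = region_mask(label_volume, "secondary_visual_cortex").astype(float)
    out = {}
    for name, m in (("dmn", dmn), ("visual", vis)):
        sm = gaussian_filter(m, 0.7)
        out[name] = sm / sm.max()
    return out


def true_motion_trace(spec: CohortSpec, rng) -> MotionTrace:
    """Slow drift plus jitter; displacement grows toward the session end,
    the discomfort signature seen in long scanner sessions."""
    n = spec.n_scans
    t = np.linspace(0, 1, n)
    trans = np.empty((n, 3))
    rots = np.empty((n, 3))
    for j in range(3):
        trans[:, j] = 0.5 * t * rng.uniform(0.5, 1.5) + _slow_process(
            rng, n, 1 / spec.tr, 0.02, 0.08)
        rots[:, j] = 0.3 * t * rng.uniform(0.5, 1.5) + _slow_process(
            rng, n, 1 / spec.tr, 0.02, 0.05)
    trans -= trans[0]
    rots -= rots[0]
    return MotionTrace(translations=trans, rotations=rots)


# ---------------------------------------------------------------------------
# per-subject assembly


_TRUE_COLUMNS = ("A", "T", "blp_alpha", "blp_theta", "blp_delta")


def simulate_subject(
    spec: CohortSpec,
    group: str,
    subject_id: str,
    seed_seq,
    label_volume: np.ndarray,
    with_eeg: bool = True,
    with_bold: bool = True,
    with_artifacts: bool = True,
    hrf: HRFSpec = HRFSpec(),
) -> SubjectBundle:
    rng = np.random.default_rng(seed_seq)
    events = simulate_events(spec, group, rng)
    shares = subject_band_shares(spec, group, rng)
    positions, labels = sensor_positions(spec.n_channels)
    planted = _planted_electrodes(positions, spec.spectral_effect.n_electrodes)

    # slow band fluctuation drivers, shared across channels
    drivers = np.stack(
        [np.exp(_slow_process(rng, spec.n_scans, 1 / spec.tr, 0.03, 0.25)) for _ in BAND_NAMES]
    )
    state = _state_occupancy(events, spec.n_scans, spec.tr)
    power_traj = _band_power_trajectory(shares, state, drivers)
    total = power_traj.sum(axis=2, keepdims=True)
    rel_truth = power_traj / total

    clean = None
    eeg = None
    gradient_tmpl = pulse_tmpl = None
    grad_onsets = pulse_onsets = pulse_scales = None
    blink_mix = blink_course = None
    if with_eeg:
        clean = synthesize_clean_eeg(spec, power_traj, rng)
        brain_rms = clean.signal.std()
        first_trigger = int(round(spec.pre_roll * spec.eeg_rate))
        spacing = int(round(spec.tr * spec.eeg_rate))
        grad_onsets = first_trigger + spacing * np.arange(spec.n_scans)
        if with_artifacts:
            art = spec.artifacts
            gradient_tmpl = gradient_template(spec, rng, brain_rms)
            eeg = embed_gradient_artifact(clean, grad_onsets, gradient_tmpl)
            # cardiac beat train with physiological jitter
            mean_rr = 60.0 / art.heart_rate_bpm
            n_beats = int(clean.duration / mean_rr) + 2
            rr = np.clip(
                mean_rr + art.heart_jitter_sd * rng.standard_normal(n_beats), 0.5, 1.5)
            beats = 0.3 + np.cumsum(rr)
            beats = beats[beats < clean.duration - 0.8]
            pulse_tmpl = pulse_template(spec, rng, brain_rms)
            eeg, pulse_scales = embed_pulse_artifact(
                eeg, beats, pulse_tmpl, art.pulse_scale_sd, rng)
            pulse_onsets = np.round(beats * spec.eeg_rate).astype(int)
            # eye blinks: frontal-weighted fixed mixing, spiky time course
            front = np.clip(positions[:, 1], 0, None) ** 2
            blink_mix = front / front.max() if front.max() > 0 else front
            blink_mix = blink_mix * art.blink_rms_ratio * brain_rms * 3.0
            n_blinks = rng.poisson(art.blink_rate_hz * clean.duration)
            blink_times = np.sort(rng.uniform(0.5, clean.duration - 0.5, n_blinks))
            course = np.zeros(clean.n_samples)
            bl = int(0.35 * spec.eeg_rate)
            bump = np.exp(-0.5 * ((np.arange(bl) - bl / 2) / (bl / 6)) ** 2)
            for bt in blink_times:
                s = int(bt * spec.eeg_rate)
                course[s : s + bl] += bump[: clean.n_samples - s]
            blink_course = course
            eeg.signal += np.outer(blink_mix, blink_course)
            eeg.reference = "synthetic-contaminated"
        else:
            eeg = embed_gradient_artifact(clean, grad_onsets, np.zeros_like(
                clean.signal[:, : spacing]), amplitude=0.0)
            eeg.reference = "synthetic-clean+triggers"

    bold = None
    true_betas = None
    true_design = None
    motion = true_motion_trace(spec, rng)
    if with_bold:
        n_scans = spec.n_scans
        cols = {}
        for cond in ("A", "T"):
            sel = events.for_condition(cond)
            cols[cond] = occurrence_regressor(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), hrf, n_scans, spec.tr)
        for band in ("alpha", "theta", "delta"):
            bi = BAND_NAMES.index(band)
            driver = rel_truth[:, :, bi].mean(axis=0)
            cols[f"blp_{band}"] = _hrf_convolve_zscore(driver, spec.tr, hrf)
        wake = events.for_condition("wake")
        wake_col = occurrence_regressor(
            wake["onset"].to_numpy(), wake["duration"].to_numpy(), hrf, n_scans, spec.tr)
        names = list(_TRUE_COLUMNS) + ["initial_wake", "intercept"]
        X = np.column_stack([cols[c] for c in _TRUE_COLUMNS] + [wake_col, np.ones(n_scans)])
        roles = ["condition", "condition", "blp", "blp", "blp", "initial_wake", "intercept"]
        true_design = DesignMatrix(matrix=X, names=names, roles=roles, tr=spec.tr)

        n_vox = int(np.prod(spec.grid_shape))
        flat_labels = label_volume.reshape(-1)
        true_betas = np.zeros((n_vox, len(names)))
        true_betas[:, names.index("intercept")] = spec.bold_baseline
        frontal = flat_labels == LABEL_IDS["frontal"]
        true_betas[frontal, names.index("A")] = spec.condition_amplitude
        true_betas[frontal, names.index("T")] = 0.75 * spec.condition_amplitude
        true_betas[:, names.index("initial_wake")] = 0.5  # scanner-placement response
        for eff in spec.effect_table:
            if eff.group != group or eff.coupling_sign == 0:
                continue
            col = names.index(f"blp_{eff.band}")
            vox = flat_labels == LABEL_IDS[eff.region_mask_id]
            true_betas[vox, col] = eff.coupling_sign * eff.coupling_amplitude
        bold = generate_bold(
            true_design, true_betas, 0.0, spec.grid_shape, spec.tr)
        # resting-network structure plus measurement noise
        nets = _network_maps(label_volume)
        for m in nets.values():
            course = _slow_process(rng, n_scans, 1 / spec.tr, 0.05, 1.0)
            bold.data += spec.network_amplitude * m[..., None] * course
        if spec.bold_noise_sd > 0:
            bold.data += spec.bold_noise_sd * rng.standard_normal(bold.data.shape)
        bold.voxel_size = (spec.voxel_size,) * 3

    truth = GroundTruth(
        clean_eeg=clean,
        gradient_template=gradient_tmpl,
        gradient_onsets=grad_onsets,
        pulse_template=pulse_tmpl,
        pulse_onsets=pulse_onsets,
        pulse_scales=pulse_scales,
        blink_mixing=blink_mix,
        blink_course=blink_course,
        true_motion=motion,
        true_betas=true_betas,
        true_design=true_design,
        planted_electrodes=planted,
        event_table=events,
        band_shares=shares,
        rel_power_truth=rel_truth,
    )
    return SubjectBundle(
        subject_id=subject_id, group=group, eeg=eeg, bold=bold, events=events, truth=truth)


def iter_subjects(
    spec: CohortSpec,
    with_eeg: bool = True,
    with_bold: bool = True,
    with_artifacts: bool = True,
):
    """Generate subject bundles one at a time (memory-friendly)."""
    spec.validate()
    label_volume = make_label_volume(spec.grid_shape)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_controls + spec.n_patients)
    k = 0
    for group, n in zip(GROUPS, (spec.n_controls, spec.n_patients)):
        for j in range(n):
            yield simulate_subject(
                spec, group, f"{group}-{j + 1:02d}", children[k], label_volume,
                with_eeg=with_eeg, with_bold=with_bold, with_artifacts=with_artifacts)
            k += 1


def simulate_cohort(
    spec: CohortSpec,
    with_eeg: bool = True,
    with_bold: bool = True,
    with_artifacts: bool = True,
) -> Cohort:
    """Materialise a full cohort; deterministic given ``spec.seed``."""
    spec.validate()
    label_volume = make_label_volume(spec.grid_shape)
    subjects = list(
        iter_subjects(spec, with_eeg=with_eeg, with_bold=with_bold,
                      with_artifacts=with_artifacts))
    return Cohort(
        spec=spec, subjects=subjects, label_volume=label_volume,
        label_names={v: k for k, v in LABEL_IDS.items()})
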