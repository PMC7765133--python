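"""Shared containers and error types for the EEG-fMRI sleep pipeline.

All heavy numerics live in the stage modules; the classes here are thin,
explicit data carriers so every stage has an unambiguous contract about
units (microvolts, seconds, millimetres) and array layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A parameter or spec field is invalid before any data is touched."""


class DataError(ValueError):
    """The data violate an assumption (negative power, unknown label, ...)."""


class DimensionError(ValueError):
    """Array shapes are inconsistent between inputs."""


class PreconditionError(ValueError):
    """An operation's entry condition is not met (too few beats, no triggers)."""


class NumericalError(RuntimeError):
    """A decomposition or solve failed (rank deficiency, non-convergence)."""


VOLUME_TRIGGER = "volume_trigger"
HEARTBEAT = "heartbeat"

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``signal`` is channels x samples in microvolts.

    ``events`` is a list of ``(sample_index, code)`` pairs; codes are free
    strings but ``volume_trigger`` and ``heartbeat`` are recognised by the
    preprocessing stages. ``positions`` are 3D sensor coordinates in
    arbitrary (unit-sphere normalisable) units, one row per channel.
    ``meta`` accumulates provenance flags as stages run.
    """

    signal: np.ndarray
    rate: float
    labels: list[str]
    positions: np.ndarray | None = None
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise DimensionError("signal must be channels x samples")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")
        if len(self.labels) != self.signal.shape[0]:
            raise DimensionError("label count != channel count")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def event_samples(self, code: str) -> np.ndarray:
        return np.array([s for s, c in self.events if c == code], dtype=int)

    def copy(self, **updates) -> "EEGRecording":
        out = EEGRecording(
            signal=self.signal.copy(),
            rate=self.rate,
            labels=list(self.labels),
            positions=None if self.positions is None else self.positions.copy(),
            events=list(self.events),
            reference=self.reference,
            meta=dict(self.meta),
        )
        for k, v in updates.items():
            setattr(out, k, v)
        return out


@dataclass
class EventTable:
    """Sleep-event annotations: onset/duration in seconds on the session clock.

    Conditions ``A`` (awakening), ``T`` (transition to sleep) and ``wake``
    (initial wakefulness after placement in the scanner) are the ones the
    downstream design builder understands.
    """

    frame: pd.DataFrame

    REQUIRED = ("onset", "duration", "condition")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise DataError(f"event table missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple[float, float, str]]) -> "EventTable":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.frame[self.frame["condition"] == condition]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class VolumeSeries:
    """4D BOLD grid: ``data`` is X x Y x Z x T in arbitrary intensity units."""

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError("data must be X x Y x Z x T")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel_size must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy(self) -> "VolumeSeries":
        return VolumeSeries(self.data.copy(), self.tr, self.voxel_size, self.origin)


@dataclass
class MotionTrace:
    """Rigid-body head motion per volume: translations in mm, rotations in degrees."""

    translations: np.ndarray  # T x 3, mm
    rotations: np.ndarray  # T x 3, degrees about x/y/z

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise DimensionError("translations and rotations must both be T x 3")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def as_columns(self) -> np.ndarray:
        """6-column array in SPM order (3 translations mm, 3 rotations)."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class BandPowerSeries:
    """Windowed relative band power: ``values`` is channels x windows x 4 bands.

    Per (channel, window) the four band values sum to one; band order is
    delta, theta, alpha, beta.
    """

    values: np.ndarray
    window_centers: np.ndarray  # seconds on the session clock
    window_length: float
    step: float
    taper_params: tuple[float, int] = (2.0, 3)
    bands: tuple[str, ...] = BAND_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.window_centers = np.asarray(self.window_centers, float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.bands):
            raise DimensionError("values must be channels x windows x n_bands")
        if self.values.shape[1] != self.window_centers.size:
            raise DimensionError("window count mismatch")
        if np.any(np.diff(self.window_centers) <= 0):
            raise DataError("window centers must be strictly increasing")

    def band_index(self, band: str) -> int:
        try:
            return self.bands.index(band)
        except ValueError:
            raise DataError(f"unknown band {band!r}") from None

    def band(self, band: str) -> np.ndarray:
        """channels x windows slice for one band."""
        return self.values[:, :, self.band_index(band)]

    def to_long_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        rows = []
        for ci, lab in enumerate(labels):
            for wi, wc in enumerate(self.window_centers):
                for bi, band in enumerate(self.bands):
                    rows.append((lab, wc, band, self.values[ci, wi, bi]))
        return pd.DataFrame(rows, columns=["channel", "window_center", "band", "value"])


@dataclass
class DesignMatrix:
    """First-level GLM design: scans x columns with role tags per column.

    Roles are ``condition``, ``blp``, ``motion``, ``initial_wake`` and
    ``intercept``; motion plus initial wake make up the 7-column
    interference block.
    """

    matrix: np.ndarray
    names: list[str]
    roles: list[str]
    tr: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2:
            raise DimensionError("design must be scans x columns")
        if not (len(self.names) == len(self.roles) == self.matrix.shape[1]):
            raise DimensionError("names/roles must match column count")
        if len(set(self.names)) != len(self.names):
            raise DataError("duplicated column names")
        if self.roles.count("intercept") != 1:
            raise DataError("exactly one intercept column required")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name: str) -> int:
        return self.names.index(name)

    def columns_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def contrast_for(self, name: str) -> np.ndarray:
        c = np.zeros(self.n_columns)
        c[self.column_index(name)] = 1.0
        return c


@dataclass
class GLMFit:
    """Per-voxel OLS result; ``betas`` is voxels x columns on a flattened grid."""

    betas: np.ndarray
    residual_variance: np.ndarray
    df: int
    design: DesignMatrix
    grid_shape: tuple[int, int, int]

    def beta_volume(self, column: str) -> np.ndarray:
        idx = self.design.column_index(column)
        return self.betas[:, idx].reshape(self.grid_shape)


@dataclass
class StatMap:
    """A t-statistic volume with its degrees of freedom."""

    t_values: np.ndarray  # 3D
    df: int
    level: str = "first"
    contrast: np.ndarray | None = None

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, float)
        if self.t_values.ndim != 3:
            raise DimensionError("t_values must be a 3D volume")
        if self.df < 1:
            raise DataError("df must be >= 1")


@dataclass
class ThresholdedMap:
    """Binary suprathreshold mask with per-voxel sign and labelled clusters."""

    mask: np.ndarray  # 3D bool
    sign: np.ndarray  # 3D in {-1, 0, +1}
    cluster_labels: np.ndarray  # 3D int, 0 = background
    cluster_sizes: dict[int, int]
    p_threshold: float
    min_extent: int
    df: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)
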