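"""First-level design construction: HRF kernel, condition and BLP regressors.

Condition occurrence vectors (awakening ``A``, transition-to-sleep ``T``,
the initial-wake interval) are boxcars on a microtime grid convolved with a
canonical double-gamma hemodynamic response function and sampled at scan
onsets. Band-limited-power regressors interpolate the windowed relative
power of a chosen electrode set onto the same grid before convolution.
The assembled matrix carries the seven-column interference block: six
rigid-body motion parameters plus the initial-wake response.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import gamma as _gamma

from .core import (
    BandPowerSeries,
    ConfigurationError,
    DataError,
    DesignMatrix,
    DimensionError,
    EventTable,
    MotionTrace,
)


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (seconds).

    Defaults follow the widely used SPM parameterisation: a positive gamma
    peaking ~5 s after onset minus a 1/6-amplitude undershoot gamma.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    amplitude_ratio: float = 6.0
    kernel_length: float = 32.0
    microtime_bins: int = 16

    def validate(self) -> None:
        if self.kernel_length < self.peak_delay:
            raise ConfigurationError("kernel_length shorter than peak_delay")
        if min(self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ConfigurationError("dispersions must be positive")
        if self.microtime_bins < 1:
            raise ConfigurationError("microtime_bins must be >= 1")


def hrf_kernel(spec: HRFSpec = HRFSpec(), tr: float = 1.0) -> tuple[np.ndarray, float]:
    """Sample the double-gamma kernel on the microtime grid.

    Returns ``(kernel, dt)`` with the kernel normalised to peak value 1;
    ``kernel[0] = 0`` because both gamma shapes exceed 1.
    """
    spec.validate()
    dt = tr / spec.microtime_bins
    t = np.arange(0.0, spec.kernel_length + dt / 2, dt)
    peak = _gamma.pdf(t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = _gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    h = peak - under / spec.amplitude_ratio
    return h / h.max(), dt


def _convolve_and_decimate(
    dense: np.ndarray, kernel: np.ndarray, n_scans: int, bins: int
) -> np.ndarray:
    conv = np.convolve(dense, kernel)[: dense.size]
    return conv[np.arange(n_scans) * bins]


def event_regressor(
    events: EventTable,
    condition: str,
    hrf: HRFSpec,
    n_scans: int,
    tr: float,
) -> np.ndarray:
    """HRF-convolved, mean-centered occurrence vector for one condition."""
    if condition not in set(events.frame["condition"]):
        known = sorted(set(events.frame["condition"]))
        raise DataError(f"condition {condition!r} not in event table (has {known})")
    sel = events.for_condition(condition)
    kernel, dt = hrf_kernel(hrf, tr)
    bins = hrf.microtime_bins
    dense = np.zeros(n_scans * bins)
    t_end = n_scans * tr
    for onset, duration in zip(sel["onset"], sel["duration"]):
        if onset < 0 or onset >= t_end:
            raise DataError(f"event onset {onset} outside [0, {t_end})")
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + duration) / dt)), dense.size)
        dense[i0:i1] = 1.0
    col = _convolve_and_decimate(dense, kernel, n_scans, bins)
    if not dense.any():
        warnings.warn(f"condition {condition!r} has zero total duration; zero column")
        return col
    return col - col.mean()


def occurrence_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    hrf: HRFSpec,
    n_scans: int,
    tr: float,
    center: bool = True,
) -> np.ndarray:
    """Same construction as :func:`event_regressor` from raw onset arrays."""
    tbl = EventTable.from_records(
        [(float(o), float(d), "x") for o, d in zip(onsets, durations)]
        or [(0.0, 0.0, "x")]
    )
    col = event_regressor(tbl, "x", hrf, n_scans, tr)
    return col if center else col + col.mean()


def blp_regressor(
    blp: BandPowerSeries,
    band: str,
    electrodes: np.ndarray | list[int],
    hrf: HRFSpec,
    n_scans: int,
    tr: float,
) -> np.ndarray:
    """HRF-convolved, z-scored band-power regressor for an electrode set.

    The windowed relative power is averaged over ``electrodes`` (integer
    channel indices), linearly interpolated onto the microtime grid with
    edge-value extrapolation, convolved, decimated to scan onsets and
    z-scored so betas are comparable across bands.
    """
    electrodes = np.asarray(electrodes, dtype=int)
    if electrodes.size == 0:
        raise ConfigurationError("empty electrode set (apply the all-channel fallback first)")
    series = blp.band(band)[electrodes].mean(axis=0)
    kernel, dt = hrf_kernel(hrf, tr)
    bins = hrf.microtime_bins
    grid = np.arange(n_scans * bins) * dt
    if blp.window_centers[-1] < (n_scans - 1) * tr - blp.step:
        warnings.warn("BLP series ends before the scan interval; edge values extrapolated")
    dense = np.interp(grid, blp.window_centers, series)
    # band power is an ongoing state, not an event starting at t=0: pad
    # with the initial value so the kernel onset transient vanishes (a
    # constant series then maps to an exactly constant column)
    pad = np.full(kernel.size, dense[0])
    conv = np.convolve(np.concatenate([pad, dense]), kernel)[
        kernel.size : kernel.size + dense.size]
    col = conv[np.arange(n_scans) * bins]
    sd = col.std()
    if sd <= 1e-12 * max(1.0, np.abs(col).max()):
        return np.zeros(n_scans)
    return (col - col.mean()) / sd


def assemble_design(
    condition_cols: dict[str, np.ndarray],
    blp_cols: dict[str, np.ndarray],
    motion: MotionTrace,
    wake_col: np.ndarray,
    tr: float,
    collinearity_r: float = 0.99,
) -> DesignMatrix:
    """Stack columns as [conditions | BLP | 6 motion | initial_wake | intercept].

    Motion columns are mean-removed but not rescaled. The interference
    block (motion + initial wake) always has seven columns. Near-collinear
    pairs (|r| > ``collinearity_r``) are reported in a warning; a rank
    check guards the subsequent OLS fit.
    """
    if not condition_cols and not blp_cols:
        raise ConfigurationError("no condition or BLP regressors supplied")
    wake_col = np.asarray(wake_col, float)
    n = wake_col.size
    cols, names, roles = [], [], []
    for name, col in condition_cols.items():
        cols.append(np.asarray(col, float))
        names.append(name)
        roles.append("condition")
    for name, col in blp_cols.items():
        cols.append(np.asarray(col, float))
        names.append(name)
        roles.append("blp")
    mcols = motion.as_columns()
    if mcols.shape[0] != n:
        raise DimensionError("motion trace length != scan count")
    for j, mname in enumerate(["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]):
        cols.append(mcols[:, j] - mcols[:, j].mean())
        names.append(mname)
        roles.append("motion")
    cols.append(wake_col)
    names.append("initial_wake")
    roles.append("initial_wake")
    cols.append(np.ones(n))
    names.append("intercept")
    roles.append("intercept")
    for c, name in zip(cols, names):
        if c.size != n:
            raise DimensionError(f"column {name!r} has length {c.size}, expected {n}")
    X = np.column_stack(cols)
    # near-collinearity report on non-constant columns
    sd = X.std(axis=0)
    varying = np.flatnonzero(sd > 0)
    if varying.size >= 2:
        corr = np.corrcoef(X[:, varying].T)
        ii, jj = np.triu_indices(varying.size, k=1)
        bad = np.abs(corr[ii, jj]) > collinearity_r
        if bad.any():
            pairs = [
                (names[varying[a]], names[varying[b]])
                for a, b in zip(ii[bad], jj[bad])
            ]
            warnings.warn(f"near-collinear design columns: {pairs}")
    return DesignMatrix(matrix=X, names=names, roles=roles, tr=tr)
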