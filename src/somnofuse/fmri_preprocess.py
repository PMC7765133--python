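"""Rigid-body motion estimation/realignment and Gaussian smoothing for 4D BOLD.

Realignment estimates six parameters (translations in mm, rotations in
degrees about the grid centre) per volume by minimising the mean squared
intensity difference to a reference, seeded by an integer-shift
cross-correlation search and refined with Powell's method. A first pass
aligns to volume 0; the second pass aligns to the mean of the first-pass
result, which serves as the final reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from scipy import optimize as _opt
from scipy import stats as _stats

from .core import ConfigurationError, MotionTrace, VolumeSeries

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _rigid_matrix(params: np.ndarray, shape, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space affine for 6 rigid parameters (mm translations, degree
    rotations about the grid centre), for use with affine_transform."""
    tx, ty, tz, rx, ry, rz = params
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    vs = np.asarray(voxel_size, float)
    center = (np.asarray(shape, float) - 1) / 2
    t_vox = np.array([tx, ty, tz]) / vs
    # affine_transform maps output coords through matrix+offset to input
    offset = center - R @ center + t_vox
    return R, offset


def apply_rigid(
    volume: np.ndarray, params: np.ndarray, voxel_size, cval: float, order: int = 1
) -> np.ndarray:
    """Resample a volume under the rigid transform (trilinear by default)."""
    R, offset = _rigid_matrix(params, volume.shape, voxel_size)
    return _ndi.affine_transform(volume, R, offset=offset, order=order, cval=cval)


def _integer_shift(volume: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best integer voxel shift via FFT cross-correlation."""
    f1 = np.fft.fftn(reference)
    f2 = np.fft.fftn(volume)
    cc = np.fft.ifftn(f1 * np.conj(f2)).real
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    shift = np.array(peak, float)
    for ax, n in enumerate(volume.shape):
        if shift[ax] > n // 2:
            shift[ax] -= n
    return shift


def estimate_motion(
    series: VolumeSeries, reference: str | int = "mean", two_pass: bool = True
) -> tuple[MotionTrace, VolumeSeries]:
    """Estimate 6-parameter rigid motion per volume and realign.

    ``reference="mean"`` reproduces the two-pass scheme: align to volume 0
    first, then to the mean of the realigned series. Constant series come
    back with all-zero parameters.
    """
    if series.n_volumes < 2:
        raise ConfigurationError("need at least 2 volumes")
    data = series.data
    cval = float(data.min())
    if np.ptp(data) == 0:
        zeros = np.zeros((series.n_volumes, 3))
        return MotionTrace(zeros, zeros.copy()), series.copy()

    margin = tuple(min(3, max(1, s // 5)) for s in series.grid_shape)
    region = tuple(slice(m, s - m) for m, s in zip(margin, series.grid_shape))

    def align_all(ref_vol: np.ndarray, init: np.ndarray | None = None) -> np.ndarray:
        n = series.n_volumes
        params = np.zeros((n, 6))
        vs = np.asarray(series.voxel_size, float)
        for t in range(n):
            vol = data[..., t]
            if init is not None:
                p0 = init[t].copy()
            else:
                shift_vox = _integer_shift(vol, ref_vol)
                p0 = np.zeros(6)
                # the transform that aligns vol to ref samples vol at +shift
                p0[:3] = -shift_vox * vs

            def cost(p, vol=vol):
                # fixed eroded-interior region: independent of p, so
                # neither edge fill nor overlap shrinkage can game the
                # objective (valid while |shift| < margin voxels). Cubic
                # interpolation avoids the trilinear smoothing bias that
                # pulls rotation estimates toward zero.
                moved = apply_rigid(vol, p, vs, 0.0, order=3)
                return float(np.mean((moved[region] - ref_vol[region]) ** 2))

            # physiological head-motion bounds keep the search away
            # from distant spurious minima of the small cost region
            bounds = [(p0[j] - 10.0, p0[j] + 10.0) for j in range(3)] + [
                (p0[j] - 8.0, p0[j] + 8.0) for j in range(3, 6)]
            res = _opt.minimize(
                cost, p0, method="Powell", bounds=bounds,
                options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 400})
            params[t] = res.x
        return params

    if reference == "mean" and two_pass:
        first = align_all(data[..., 0])
        vs = series.voxel_size
        realigned1 = np.stack(
            [apply_rigid(data[..., t], first[t], vs, cval) for t in range(series.n_volumes)],
            axis=-1)
        ref_vol = realigned1.mean(axis=-1)
        params = align_all(ref_vol, init=first)
    else:
        idx = 0 if reference == "mean" else int(reference)
        params = align_all(data[..., idx])
    # convention: the reference volume (closest to zero motion) is exact zero
    ref_t = int(np.argmin(np.abs(params).sum(axis=1)))
    params = params - params[ref_t]
    realigned = np.stack(
        [apply_rigid(data[..., t], params[t], series.voxel_size, cval)
         for t in range(series.n_volumes)],
        axis=-1)
    trace = MotionTrace(translations=params[:, :3], rotations=params[:, 3:])
    out = VolumeSeries(realigned, series.tr, series.voxel_size, series.origin)
    return trace, out


def smooth(series: VolumeSeries, fwhm_voxels=(8.0, 8.0, 8.0)) -> VolumeSeries:
    """Separable Gaussian smoothing per volume with edge renormalisation.

    ``fwhm_voxels`` is in voxel units; the truncated kernel is divided by
    its local mass so constants (and the global mean, closely) survive at
    the edges.
    """
    fwhm = np.asarray(fwhm_voxels, float)
    if np.any(fwhm < 0):
        raise ConfigurationError("fwhm must be non-negative")
    if np.all(fwhm == 0):
        return series.copy()
    sigma = fwhm / FWHM_TO_SIGMA
    norm = _ndi.gaussian_filter(np.ones(series.grid_shape), sigma, mode="constant", truncate=6.0)
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        out[..., t] = _ndi.gaussian_filter(
            series.data[..., t], sigma, mode="constant", truncate=6.0) / norm
    return VolumeSeries(out, series.tr, series.voxel_size, series.origin)


@dataclass
class MotionSummary:
    max_abs: np.ndarray  # per parameter, mm / degrees
    framewise_displacement: np.ndarray  # per volume, mm
    drift_statistic: float  # rank correlation of time vs displacement


def motion_summary(trace: MotionTrace, sphere_radius_mm: float = 50.0) -> MotionSummary:
    """Framewise displacement (rotations mapped to arc length on a 50 mm
    sphere) and a monotone-drift statistic flagging growing discomfort."""
    cols = trace.as_columns()
    max_abs = np.abs(cols).max(axis=0)
    rot_mm = np.deg2rad(trace.rotations) * sphere_radius_mm
    combined = np.hstack([trace.translations, rot_mm])
    fd = np.zeros(trace.n_volumes)
    fd[1:] = np.abs(np.diff(combined, axis=0)).sum(axis=1)
    disp = np.linalg.norm(combined, axis=1)
    if np.ptp(disp) == 0:
        drift = 0.0
    else:
        drift = float(_stats.spearmanr(np.arange(disp.size), disp).statistic)
    return MotionSummary(max_abs=max_abs, framewise_displacement=fd, drift_statistic=drift)
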