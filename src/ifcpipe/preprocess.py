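"""Quality control and temporal preprocessing of BOLD series.

Covers the per-subject steps that precede any connectivity estimate:
discarding initial volumes, head-motion and tSNR quality control with
exclusion thresholds, zero-phase Butterworth band-pass filtering of the
slow-fluctuation band, nuisance regression, and SVD reduction of a seed's
voxel time courses to a single representative course.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import signal

from .grids import Grid
from .rois import RoiMask

# exclusion thresholds for excessive head motion
CUMULATIVE_TRANSLATION_MM = 3.0
MEAN_P2P_TRANSLATION_MM = 0.15
MEAN_P2P_ROTATION_DEG = 0.1

DEFAULT_BAND_HZ = (0.009, 0.08)


@dataclass
class VolumeSeries:
    """One subject's 4-D BOLD acquisition as a voxel x time matrix."""

    data: np.ndarray  # (n_voxels, n_volumes)
    grid: Grid
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ValueError("data must be a voxel x time matrix with >=1 volume")
        if self.data.shape[0] != self.grid.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[0]} voxels but grid has {self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in volume series")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters over time.

    Translations are in millimetres, rotations in degrees. SPM-style
    ``rp_*.txt`` files store rotations in radians; :meth:`from_spm_file`
    converts on read.
    """

    translations_mm: np.ndarray  # (3, n_volumes)
    rotations_deg: np.ndarray  # (3, n_volumes)

    def __post_init__(self):
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape[0] != 3 or self.rotations_deg.shape[0] != 3:
            raise ValueError("expected 3 translation and 3 rotation parameters")
        if self.translations_mm.shape[1] != self.rotations_deg.shape[1]:
            raise ValueError("translation and rotation lengths differ")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[1]

    @classmethod
    def from_spm_file(cls, path) -> "MotionTrace":
        """Read a 6-column whitespace-delimited realignment file.

        Columns 1-3 are translations in mm, columns 4-6 rotations in
        radians (converted to degrees here).
        """
        arr = np.loadtxt(path)
        arr = np.atleast_2d(arr)
        if arr.shape[1] != 6:
            raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
        return cls(
            translations_mm=arr[:, :3].T,
            rotations_deg=np.degrees(arr[:, 3:].T),
        )

    def to_spm_array(self) -> np.ndarray:
        """(n_volumes, 6) array in the on-disk dialect (mm, radians)."""
        return np.hstack([self.translations_mm.T, np.radians(self.rotations_deg.T)])

    def trim(self, n: int) -> "MotionTrace":
        """Drop the first ``n`` volumes, mirroring :func:`discard_initial`."""
        return MotionTrace(self.translations_mm[:, n:], self.rotations_deg[:, n:])


@dataclass
class QcReport:
    """Per-subject motion/tSNR quality metrics and the exclusion decision."""

    cumulative_translation_mm: float
    mean_p2p_translation_mm: float
    mean_p2p_rotation_deg: float
    rms_translation_mm: float
    tsnr: float
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    subject_id: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class TsnrResult(NamedTuple):
    tsnr: float
    n_constant_voxels: int


@dataclass
class RoiTimeCourse:
    """Representative course of one seed: zero mean, unit variance."""

    name: str
    values: np.ndarray  # (n_volumes,)
    sign_convention: str = "positive-mean-correlation"


def discard_initial(series: VolumeSeries, n: int) -> VolumeSeries:
    """Remove the first ``n`` volumes (magnetisation-equilibration scans).

    The caller is responsible for trimming the motion trace consistently
    (:meth:`MotionTrace.trim`).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= series.n_volumes:
        raise ValueError(f"cannot discard {n} of {series.n_volumes} volumes")
    if n == 0:
        return series
    return replace(series, data=series.data[:, n:])


def qc_motion(
    trace: MotionTrace,
    series: VolumeSeries | None = None,
    *,
    cumulative_mm: float = CUMULATIVE_TRANSLATION_MM,
    p2p_translation_mm: float = MEAN_P2P_TRANSLATION_MM,
    p2p_rotation_deg: float = MEAN_P2P_ROTATION_DEG,
    cumulative_mode: str = "max-displacement",
) -> QcReport:
    """Motion quality metrics and the exclusion decision.

    Point-to-point motion of a volume is the Euclidean displacement of the
    three translation (rotation) parameters relative to the previous
    volume. Cumulative translation is, by default, the maximum Euclidean
    displacement from the first volume; ``cumulative_mode="sum-p2p"``
    instead sums the point-to-point steps. RMS pools the three translation
    series.

    A subject is excluded when cumulative translation exceeds
    ``cumulative_mm`` (3 mm) or the mean point-to-point translation or
    rotation exceeds ``p2p_translation_mm`` (0.15 mm) or
    ``p2p_rotation_deg`` (0.1 deg).
    """
    if series is not None and trace.n_volumes != series.n_volumes:
        raise ValueError(
            f"motion trace has {trace.n_volumes} volumes, series has {series.n_volumes}"
        )
    t = trace.translations_mm
    r = trace.rotations_deg
    p2p_t = np.linalg.norm(np.diff(t, axis=1), axis=0)
    p2p_r = np.linalg.norm(np.diff(r, axis=1), axis=0)
    mean_p2p_t = float(p2p_t.mean()) if p2p_t.size else 0.0
    mean_p2p_r = float(p2p_r.mean()) if p2p_r.size else 0.0
    disp = np.linalg.norm(t - t[:, :1], axis=0)
    if cumulative_mode == "max-displacement":
        cumulative = float(disp.max())
    elif cumulative_mode == "sum-p2p":
        cumulative = float(p2p_t.sum())
    else:
        raise ValueError(f"unknown cumulative_mode {cumulative_mode!r}")
    rms = float(np.sqrt(np.mean(t**2)))

    reasons = []
    if cumulative > cumulative_mm:
        reasons.append(f"cumulative translation {cumulative:.3g} mm > {cumulative_mm} mm")
    if mean_p2p_t > p2p_translation_mm:
        reasons.append(
            f"mean point-to-point translation {mean_p2p_t:.3g} mm > {p2p_translation_mm} mm"
        )
    if mean_p2p_r > p2p_rotation_deg:
        reasons.append(
            f"mean point-to-point rotation {mean_p2p_r:.3g} deg > {p2p_rotation_deg} deg"
        )
    tsnr = float("nan")
    if series is not None:
        tsnr = compute_tsnr(series).tsnr
    return QcReport(
        cumulative_translation_mm=cumulative,
        mean_p2p_translation_mm=mean_p2p_t,
        mean_p2p_rotation_deg=mean_p2p_r,
        rms_translation_mm=rms,
        tsnr=tsnr,
        excluded=bool(reasons),
        reasons=reasons,
        subject_id=series.subject_id if series is not None else "",
    )


def compute_tsnr(series: VolumeSeries, mask: RoiMask | None = None) -> TsnrResult:
    """Temporal signal-to-noise ratio: voxelwise mean/SD averaged over a mask.

    Voxels with zero temporal SD are excluded from the average and counted.
    """
    if series.n_volumes < 2:
        raise ValueError("tSNR requires at least 2 volumes")
    data = series.data if mask is None else series.data[mask.indices]
    mu = data.mean(axis=1)
    sd = data.std(axis=1)
    ok = sd > 0
    n_const = int((~ok).sum())
    if not ok.any():
        raise ValueError("tSNR undefined: every voxel is temporally constant")
    return TsnrResult(tsnr=float(np.mean(mu[ok] / sd[ok])), n_constant_voxels=n_const)


def bandpass_sos(
    low_hz: float, high_hz: float, tr_seconds: float, order: int = 4
) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass used throughout."""
    nyq = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyq:.4g}) Hz"
        )
    return signal.butter(order, [low_hz, high_hz], btype="band", fs=1.0 / tr_seconds, output="sos")


def bandpass(
    tc: np.ndarray,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    tr_seconds: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Filtering is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the square of the single-pass filter
    and the phase is zero. Output length equals input length; the DC
    component is removed (it lies far below ``low_hz``).
    """
    sos = bandpass_sos(low_hz, high_hz, tr_seconds, order)
    return signal.sosfiltfilt(sos, np.asarray(tc, float), axis=-1)


def regress_nuisance(tc: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residual of ``tc`` on an intercept plus nuisance regressors.

    The residual is orthogonal to every regressor column (and to the
    intercept, i.e. mean-zero).

    Raises
    ------
    ValueError
        If the design (with intercept) is rank deficient; the message names
        the offending columns.
    """
    tc = np.asarray(tc, float)
    R = np.atleast_2d(np.asarray(regressors, float))
    if R.shape[0] != tc.shape[-1]:
        if R.shape[1] == tc.shape[-1]:
            R = R.T
        else:
            raise ValueError(
                f"regressors have {R.shape[0]} rows, time course has {tc.shape[-1]} points"
            )
    X = np.column_stack([np.ones(R.shape[0]), R])
    # rank check with named collinear columns
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        cols = ", ".join(
            "intercept" if j == 0 else f"regressor {j - 1}" for j in bad
        )
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {cols}")
    beta, *_ = np.linalg.lstsq(X, tc.T if tc.ndim > 1 else tc, rcond=None)
    fitted = X @ beta
    return tc - (fitted.T if tc.ndim > 1 else fitted)


def svd_timecourse(submatrix: np.ndarray, name: str = "") -> RoiTimeCourse:
    """First right-singular vector of a voxel x time block, standardized.

    The block is centred over time first. Sign indeterminacy of the SVD is
    resolved by requiring non-negative correlation with the block's mean
    time course.
    """
    sub = np.asarray(submatrix, float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(sub):
        raise ValueError(f"ROI {name!r}: all-zero (constant) submatrix")
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    v = vt[0]
    if np.dot(v, sub.mean(axis=0)) < 0:
        v = -v
    v = v - v.mean()
    v = v / v.std()
    return RoiTimeCourse(name=name, values=v)


def extract_roi_timecourse(series: VolumeSeries, mask: RoiMask) -> RoiTimeCourse:
    """Reduce a seed's voxel courses to one representative course by SVD.

    The representative is the first right-singular vector of the centred
    voxel x time submatrix (equivalently the first principal component
    score over time), scaled to unit variance; see :func:`svd_timecourse`
    for the sign convention.
    """
    return svd_timecourse(series.data[mask.indices], name=mask.name)
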