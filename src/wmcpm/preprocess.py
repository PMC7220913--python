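"""Time-series preprocessing and participant-level quality control.

Operations are applied in the fixed order: initial-volume discard, nuisance
regression, band-pass filtering, motion scrubbing.  Censored frames are
dropped (never interpolated) before any correlation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "MotionTrace",
    "QCLimits",
    "QCReport",
    "discard_initial",
    "compute_fd",
    "build_motion24",
    "regress_nuisance",
    "bandpass",
    "scrub",
    "qc_participant",
    "exclude_outliers",
]


@dataclass
class TimeSeries:
    """Frames-by-channels signal with a per-frame retention flag.

    ``tr_seconds`` is the sampling interval (2.0 s by default).
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    frame_retained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValueError("time series needs at least one frame")
        if self.frame_retained is None:
            self.frame_retained = np.ones(self.n_frames, dtype=bool)
        self.frame_retained = np.asarray(self.frame_retained, dtype=bool)
        if len(self.frame_retained) != self.n_frames:
            raise ValueError("frame_retained length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def retention(self) -> float:
        """Fraction of frames retained."""
        return float(self.frame_retained.mean())

    def retained_values(self) -> np.ndarray:
        return self.values[self.frame_retained]

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t")

    @classmethod
    def read(cls, path: str | Path, tr_seconds: float = 2.0) -> "TimeSeries":
        return cls(values=np.loadtxt(path, delimiter="\t", ndmin=2), tr_seconds=tr_seconds)


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame: translations (mm) then rotations (rad)."""

    params: np.ndarray
    fd: np.ndarray = field(default=None)
    rotation_unit: str = "rad"

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(f"motion trace needs 6 columns, got {self.params.shape[1]}")
        if self.rotation_unit not in ("rad", "deg"):
            raise ValueError("rotation_unit must be 'rad' or 'deg'")
        if self.rotation_unit == "deg":
            self.params = self.params.copy()
            self.params[:, 3:] = np.deg2rad(self.params[:, 3:])
            self.rotation_unit = "rad"
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if len(self.fd) != self.n_frames:
                raise ValueError("fd length must equal frame count")
            if (self.fd < 0).any():
                raise ValueError("fd must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def mean_fd(self) -> float:
        if self.fd is None:
            raise ValueError("fd not computed; call compute_fd first")
        return float(self.fd.mean())

    @property
    def max_translation(self) -> float:
        return float(np.abs(self.params[:, :3]).max())

    @property
    def max_rotation_deg(self) -> float:
        return float(np.rad2deg(np.abs(self.params[:, 3:]).max()))

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.params, delimiter="\t")

    @classmethod
    def read(cls, path: str | Path, rotation_unit: str = "rad") -> "MotionTrace":
        return cls(params=np.loadtxt(path, delimiter="\t", ndmin=2),
                   rotation_unit=rotation_unit)


@dataclass
class QCLimits:
    """Participant exclusion thresholds."""

    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    max_mean_fd_mm: float = 0.15
    min_retention: float = 0.80


@dataclass
class QCReport:
    participant_id: str
    max_translation_exceeded: bool = False
    max_rotation_exceeded: bool = False
    mean_fd_exceeded: bool = False
    retention_below_threshold: bool = False
    gf_outlier: bool = False

    @property
    def included(self) -> bool:
        return not (
            self.max_translation_exceeded
            or self.max_rotation_exceeded
            or self.mean_fd_exceeded
            or self.retention_below_threshold
            or self.gf_outlier
        )


def discard_initial(ts: TimeSeries, n_discard: int) -> TimeSeries:
    """Drop the first ``n_discard`` frames (e.g. 242 acquired -> 235 analyzed)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_frames} frames"
        )
    return TimeSeries(values=ts.values[n_discard:], tr_seconds=ts.tr_seconds,
                      frame_retained=ts.frame_retained[n_discard:])


def compute_fd(motion: MotionTrace, head_radius_mm: float = 50.0) -> MotionTrace:
    """Framewise displacement: sum of absolute backward differences.

    Rotations are converted to arc length on a sphere of ``head_radius_mm``.
    ``fd[0]`` is defined as 0.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    deltas = np.abs(np.diff(motion.params, axis=0))
    fd = np.zeros(motion.n_frames)
    fd[1:] = deltas[:, :3].sum(axis=1) + head_radius_mm * deltas[:, 3:].sum(axis=1)
    return replace(motion, fd=fd)


def build_motion24(motion: MotionTrace) -> np.ndarray:
    """Friston-style 24-column motion design: [p, dp, p^2, dp^2] (dp[0] = 0)."""
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames")
    p = motion.params
    dp = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    return np.hstack([p, dp, p**2, dp**2])


def regress_nuisance(ts: TimeSeries, regressors: np.ndarray) -> TimeSeries:
    """Replace each channel with its least-squares residual on [1, regressors].

    Rank-deficient designs are handled by the pseudoinverse (equivalent to
    dropping redundant columns); a warning is logged.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.n_frames:
        raise ValueError("regressor rows must equal frame count")
    design = np.column_stack([np.ones(ts.n_frames), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("nuisance design is rank deficient (rank %d of %d); "
                       "redundant columns effectively dropped", rank, design.shape[1])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    residuals = ts.values - design @ beta
    return TimeSeries(values=residuals, tr_seconds=ts.tr_seconds,
                      frame_retained=ts.frame_retained.copy())


def bandpass(ts: TimeSeries, low_hz: float = 0.01, high_hz: float = 0.10) -> TimeSeries:
    """Zero-phase Butterworth band-pass; frame count preserved, DC removed."""
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0.0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist})"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return TimeSeries(values=filtered, tr_seconds=ts.tr_seconds,
                      frame_retained=ts.frame_retained.copy())


def censored_frames(fd: np.ndarray, fd_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of frames censored by the scrubbing window.

    A supra-threshold frame censors itself, one frame forward and two frames
    back; windows are clipped at the boundaries and unioned across spikes.
    """
    n = len(fd)
    censored = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(fd > fd_threshold):
        censored[max(0, i - 2): min(n, i + 2)] = True
    return censored


def scrub(ts: TimeSeries, motion: MotionTrace, fd_threshold: float = 0.5) -> TimeSeries:
    """Mark frames inside any spike window as not retained."""
    if motion.fd is None:
        raise ValueError("fd not computed; call compute_fd first")
    if motion.n_frames != ts.n_frames:
        raise ValueError("motion trace and time series frame counts differ")
    retained = ts.frame_retained & ~censored_frames(motion.fd, fd_threshold)
    return TimeSeries(values=ts.values, tr_seconds=ts.tr_seconds, frame_retained=retained)


def qc_participant(motion: MotionTrace, retention: float,
                   limits: QCLimits | None = None,
                   participant_id: str = "") -> QCReport:
    """Apply the motion/retention exclusion rules (2 mm, 2 deg, 0.15 mm, 80%)."""
    limits = limits or QCLimits()
    if motion.fd is None:
        raise ValueError("fd not computed; call compute_fd first")
    return QCReport(
        participant_id=participant_id,
        max_translation_exceeded=motion.max_translation > limits.max_translation_mm,
        max_rotation_exceeded=motion.max_rotation_deg > limits.max_rotation_deg,
        mean_fd_exceeded=motion.mean_fd > limits.max_mean_fd_mm,
        retention_below_threshold=retention < limits.min_retention,
    )


def exclude_outliers(scores, k_sd: float = 2.0) -> np.ndarray:
    """Indices of scores within mean +/- k_sd * SD (single pass, no iteration)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")
    mean = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        return np.arange(len(scores))
    return np.flatnonzero(np.abs(scores - mean) <= k_sd * sd)
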