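"""Per-micrograph quality statistics: ice thickness, beam-induced motion,
intensity histograms and particle-alignment summaries.

Ice thickness follows Beer-Lambert attenuation of the zero-loss beam by
inelastic scattering, t = MFP * ln(I0/I), with I0 the open-beam intensity
measured in empty holes and I the mean micrograph intensity.  The inelastic
mean free path is instrument-specific; the defaults are 395 nm without an
objective aperture and 322 nm with one (the aperture removes part of the
elastically scattered beam too, shortening the apparent MFP).

Beam-induced motion is summarized by endpoint displacements of the
whole-frame shift trajectory rather than cumulative path length: with many
frames and small shifts a path sum is dominated by inter-frame shift noise.
The *early* displacement runs from frame 1 to the frame where the
accumulated exposure reaches ~4 e/A^2 (where most irreversible early motion
has happened); the *total* displacement runs from the first frame to the
last.  Both can under-report non-monotonic (U-turn) motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MFP_NO_APERTURE_NM",
    "MFP_APERTURE_NM",
    "DEFAULT_EARLY_DOSE",
    "IceThicknessModel",
    "ShiftTrajectory",
    "AlignmentStats",
    "NegativeThicknessError",
    "InvalidIntensityError",
    "InsufficientFramesError",
    "mfp_for_aperture",
    "ice_thickness",
    "ice_thickness_table",
    "intensity_histogram",
    "early_frame_index",
    "early_displacement",
    "total_displacement",
    "summarize_alignment",
]

MFP_NO_APERTURE_NM = 395.0
MFP_APERTURE_NM = 322.0
DEFAULT_EARLY_DOSE = 4.0  # e/A^2


class NegativeThicknessError(ValueError):
    """Micrograph brighter than the open beam: apparent thickness < 0."""


class InvalidIntensityError(ValueError):
    """Non-positive intensity."""


class InsufficientFramesError(ValueError):
    """Trajectory too short for the requested displacement."""


def mfp_for_aperture(aperture: bool) -> float:
    """Inelastic mean free path (nm) for the with/without-aperture optics.

    The two calibrated constants are never interpolated.
    """
    return MFP_APERTURE_NM if aperture else MFP_NO_APERTURE_NM


@dataclass(frozen=True)
class IceThicknessModel:
    """Beer-Lambert thickness model for one acquisition session."""

    mfp: float  # nm
    i0: float  # open-beam counts/pixel

    def __post_init__(self) -> None:
        if not self.mfp > 0:
            raise ValueError("mfp must be > 0")
        if not self.i0 > 0:
            raise ValueError("i0 must be > 0")

    def thickness(self, i: float) -> float:
        return ice_thickness(i, self.i0, self.mfp)


def ice_thickness(i: float, i0: float, mfp: float) -> float:
    """Ice thickness t = MFP * ln(I0/I) in nm.

    Raises rather than clips when the micrograph is brighter than the open
    beam (apparent negative thickness) or the intensity is non-positive.
    """
    if not mfp > 0 or not i0 > 0:
        raise ValueError("mfp and i0 must be > 0")
    if i <= 0:
        raise InvalidIntensityError(f"intensity must be > 0, got {i}")
    if i > i0:
        raise NegativeThicknessError(
            f"intensity {i} exceeds open-beam {i0}: apparent thickness < 0"
        )
    return mfp * math.log(i0 / i)


def ice_thickness_table(
    intensities: Sequence[float], i0: float, mfp: float
) -> pd.DataFrame:
    """Per-micrograph thickness with flags; flagged rows excluded from summaries.

    Returns columns ``intensity``, ``thickness_nm`` (NaN where undefined) and
    ``flag`` ('ok', 'negative_thickness', 'invalid_intensity').  Summarize
    with ``df.loc[df.flag == 'ok', 'thickness_nm']``.
    """
    i = np.asarray(intensities, dtype=float)
    flag = np.where(i <= 0, "invalid_intensity", np.where(i > i0, "negative_thickness", "ok"))
    t = np.full_like(i, np.nan)
    ok = flag == "ok"
    t[ok] = mfp * np.log(i0 / i[ok])
    return pd.DataFrame({"intensity": i, "thickness_nm": t, "flag": flag})


def intensity_histogram(
    intensities: Sequence[float], bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Electron-count histogram of per-micrograph mean intensities."""
    return np.histogram(np.asarray(intensities, dtype=float), bins=bins)


@dataclass(frozen=True)
class ShiftTrajectory:
    """Whole-frame beam-induced motion path of one movie (1-based frames)."""

    positions: np.ndarray  # (n_frames, 2), A
    exposure_per_frame: float  # e/A^2/frame

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n_frames >= 2, 2) array")
        if not self.exposure_per_frame > 0:
            raise ValueError("exposure_per_frame must be > 0")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def early_frame_index(
    exposure_per_frame: float, target_dose: float = DEFAULT_EARLY_DOSE
) -> int:
    """1-based index of the frame where accumulated exposure reaches the target.

    Formalized as ceil(target/exposure_per_frame) + 1: the first frame whose
    *start* lies at or past the target dose (frame k starts after k-1 full
    frames of exposure).  Reproduces the conventional anchors: frame 5 at
    1.03 e/A^2/frame and frame 6 at 0.87 e/A^2/frame for a ~4 e/A^2 target.
    """
    if not exposure_per_frame > 0 or not target_dose > 0:
        raise ValueError("exposure_per_frame and target_dose must be > 0")
    return math.ceil(target_dose / exposure_per_frame) + 1


def early_displacement(
    traj: ShiftTrajectory, target_dose: float = DEFAULT_EARLY_DOSE
) -> float:
    """Euclidean displacement (A) from frame 1 to the ~target-dose frame.

    Endpoint distance, not a path sum.
    """
    idx = early_frame_index(traj.exposure_per_frame, target_dose)
    if traj.n_frames < idx:
        raise InsufficientFramesError(
            f"trajectory has {traj.n_frames} frames; early frame is {idx}"
        )
    return float(np.linalg.norm(traj.positions[idx - 1] - traj.positions[0]))


def total_displacement(traj: ShiftTrajectory) -> float:
    """Euclidean displacement (A) from the first frame to the last."""
    return float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))


@dataclass(frozen=True)
class AlignmentStats:
    """Per-particle and per-run alignment quality from 3D refinement.

    ``significant_samples`` holds the per-particle number of significant
    orientation samples (lower = more confident alignment); the angular and
    translational accuracies are run-level scalars (``nan`` = unavailable).
    """

    significant_samples: np.ndarray
    angular_accuracy_deg: float = float("nan")
    translational_accuracy_ang: float = float("nan")

    def __post_init__(self) -> None:
        s = np.asarray(self.significant_samples)
        if s.size and s.min() < 1:
            raise ValueError("significant-sample counts must be >= 1")
        object.__setattr__(self, "significant_samples", s)


def summarize_alignment(stats: AlignmentStats) -> dict:
    """Median significant-sample count plus pass-through accuracies.

    The even-length median is the mean of the central pair.
    """
    from .rh_model import InsufficientDataError

    if stats.significant_samples.size == 0:
        raise InsufficientDataError("no particles to summarize")
    return {
        "median_significant_samples": float(np.median(stats.significant_samples)),
        "n_particles": int(stats.significant_samples.size),
        "angular_accuracy_deg": stats.angular_accuracy_deg,
        "translational_accuracy_ang": stats.translational_accuracy_ang,
    }
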