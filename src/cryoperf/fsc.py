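"""Fourier shell correlation and threshold-based resolution estimation.

Two half-maps reconstructed from disjoint particle halves share signal but
have independent noise; their normalized cross-correlation in concentric
Fourier shells,

    FSC(s) = Re<F1 F2*> / sqrt(<|F1|^2><|F2|^2>),

decays from ~1 at low frequency toward 0 where noise dominates.  The global
resolution is read off at the first crossing below a threshold (0.143, the
gold-standard criterion for independently refined halves), with linear
interpolation between shells.  The FSC computed here is unmasked — no
solvent mask, no phase-randomization correction.

The analytic counterpart used by the simulator and the fit-consistency
checks models the per-shell spectral signal-to-noise ratio as

    SSNR(d) = N * c * exp(-B/(2 d^2)),     FSC = SSNR/(SSNR + 1),

where N is the particle count, c a per-particle SSNR scale and B the
Rosenthal-Henderson B-factor; solving FSC = t for d makes 1/d^2 linear in
ln N with slope 2/B, which is exactly the line rh_model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FSCCurve",
    "VolumePair",
    "ResolutionEstimate",
    "UndefinedCorrelationError",
    "NoSignalError",
    "FSC_GOLD_STANDARD",
    "shell_radii",
    "compute_fsc",
    "resolution_at_threshold",
    "predicted_resolution",
]

FSC_GOLD_STANDARD = 0.143


class UndefinedCorrelationError(ValueError):
    """Correlation requested against an all-zero volume."""


class NoSignalError(ValueError):
    """FSC is already below the threshold in the lowest-frequency shell."""


@dataclass(frozen=True)
class VolumePair:
    """Two half-maps of the same particle on identical cubic grids."""

    map1: np.ndarray
    map2: np.ndarray
    pixel_size: float  # A

    def __post_init__(self) -> None:
        if self.map1.shape != self.map2.shape:
            raise ValueError("half-maps must have identical shapes")
        if self.map1.ndim != 3 or len(set(self.map1.shape)) != 1:
            raise ValueError("half-maps must be cubic 3D volumes")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def box_size(self) -> int:
        return self.map1.shape[0]


@dataclass(frozen=True)
class FSCCurve:
    shell_frequencies: np.ndarray  # 1/A, monotone increasing, <= Nyquist
    fsc_values: np.ndarray  # dimensionless, in [-1, 1]
    pixel_size: float  # A
    box_size: int  # voxels

    def __post_init__(self) -> None:
        if len(self.shell_frequencies) != len(self.fsc_values):
            raise ValueError("frequencies and FSC values must align")


@dataclass(frozen=True)
class ResolutionEstimate:
    """A resolution in A plus a flag marking bound-only results.

    ``saturated=True`` means the number is not a genuine threshold crossing:
    either the curve never fell below the threshold (the value is then the
    Nyquist resolution 2*pixel_size) or the analytic model has no solution
    (the value is then ``inf``).
    """

    resolution: float
    saturated: bool = False


def shell_radii(box_size: int) -> np.ndarray:
    """Integer radial shell index of every voxel of an FFT grid.

    Radius is measured in voxel-frequency units (cycles per box edge) with
    the usual FFT wraparound, rounded to the nearest integer.
    """
    k = np.fft.fftfreq(box_size) * box_size
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    return np.rint(np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)).astype(int)


def compute_fsc(pair: VolumePair, n_shells: int | None = None) -> FSCCurve:
    """Shell-wise normalized cross-correlation of the pair's Fourier transforms.

    Shells are integer radii in voxel-frequency units from 1 up to Nyquist
    (box/2); shells with zero power in either map are excluded.  ``n_shells``
    optionally regroups the integer radii into that many contiguous bins
    (correlation sums are pooled, not averaged, within a bin).
    """
    n = pair.box_size
    if n < 8:
        raise ValueError("box side must be >= 8")
    if not np.any(pair.map1) or not np.any(pair.map2):
        raise UndefinedCorrelationError("all-zero volume has no correlation")

    f1 = np.fft.fftn(pair.map1)
    f2 = np.fft.fftn(pair.map2)
    r = shell_radii(n)
    nyq = n // 2

    num = np.real(f1 * np.conj(f2))
    p1 = np.abs(f1) ** 2
    p2 = np.abs(f2) ** 2
    # per-integer-radius sums; radii beyond Nyquist discarded
    max_r = nyq
    flat_r = r.ravel()
    keep = (flat_r >= 1) & (flat_r <= max_r)
    rk = flat_r[keep]
    sums_num = np.bincount(rk, weights=num.ravel()[keep], minlength=max_r + 1)
    sums_p1 = np.bincount(rk, weights=p1.ravel()[keep], minlength=max_r + 1)
    sums_p2 = np.bincount(rk, weights=p2.ravel()[keep], minlength=max_r + 1)

    radii = np.arange(1, max_r + 1)
    if n_shells is not None:
        if n_shells < 1:
            raise ValueError("n_shells must be >= 1")
        edges = np.linspace(0.5, max_r + 0.5, n_shells + 1)
        idx = np.clip(np.digitize(radii, edges) - 1, 0, n_shells - 1)
        sums_num = np.bincount(idx, weights=sums_num[radii], minlength=n_shells)
        sums_p1 = np.bincount(idx, weights=sums_p1[radii], minlength=n_shells)
        sums_p2 = np.bincount(idx, weights=sums_p2[radii], minlength=n_shells)
        centers = np.array(
            [radii[idx == i].mean() if np.any(idx == i) else np.nan for i in range(n_shells)]
        )
    else:
        sums_num = sums_num[radii]
        sums_p1 = sums_p1[radii]
        sums_p2 = sums_p2[radii]
        centers = radii.astype(float)

    denom = np.sqrt(sums_p1 * sums_p2)
    populated = (denom > 0) & np.isfinite(centers)
    fsc = sums_num[populated] / denom[populated]
    freqs = centers[populated] / (n * pair.pixel_size)
    return FSCCurve(
        shell_frequencies=freqs,
        fsc_values=np.clip(fsc, -1.0, 1.0),
        pixel_size=pair.pixel_size,
        box_size=n,
    )


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = FSC_GOLD_STANDARD
) -> ResolutionEstimate:
    """Resolution at the first crossing of the FSC below ``threshold``.

    Scans from low to high frequency and linearly interpolates the crossing
    frequency between the adjacent shells (the first-crossing rule is stable
    under high-frequency noise spikes).  A curve that never falls below the
    threshold saturates at the Nyquist resolution 2*pixel_size.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fsc = curve.fsc_values
    freq = curve.shell_frequencies
    if len(fsc) == 0:
        raise ValueError("empty FSC curve")
    if fsc[0] < threshold:
        raise NoSignalError(
            f"FSC {fsc[0]:.3f} below threshold {threshold} in the lowest shell"
        )
    below = np.nonzero(fsc < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(2.0 * curve.pixel_size, saturated=True)
    j = below[0]
    f_lo, f_hi = freq[j - 1], freq[j]
    v_lo, v_hi = fsc[j - 1], fsc[j]
    f_star = f_lo + (f_hi - f_lo) * (v_lo - threshold) / (v_lo - v_hi)
    return ResolutionEstimate(1.0 / f_star, saturated=False)


def predicted_resolution(
    n: float,
    bfactor: float,
    c: float,
    threshold: float = FSC_GOLD_STANDARD,
    nyquist_resolution: float | None = None,
    worst_resolution: float | None = None,
) -> ResolutionEstimate:
    """Resolution the analytic SSNR model predicts for ``n`` particles.

    Solves N*c*exp(-B/(2 d^2)) = t/(1-t), i.e.
    1/d^2 = (2/B) * ln(N*c*(1-t)/t) — linear in ln N with slope 2/B, which
    ties the simulator to the Rosenthal-Henderson fit.  Returns ``inf`` with
    ``saturated=True`` when there is no crossing: the SSNR never reaches the
    threshold, or (with ``worst_resolution``, the lowest measurable
    frequency, e.g. the box extent) the crossing lies outside the measurable
    band, as in the large-B limit.  Clips at ``nyquist_resolution`` when
    given.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not bfactor > 0 or not c > 0:
        raise ValueError("bfactor and c must be > 0")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    arg = n * c * (1.0 - threshold) / threshold
    if arg <= 1.0:
        return ResolutionEstimate(math.inf, saturated=True)
    d = math.sqrt(bfactor / (2.0 * math.log(arg)))
    if worst_resolution is not None and d > worst_resolution:
        return ResolutionEstimate(math.inf, saturated=True)
    if nyquist_resolution is not None and d < nyquist_resolution:
        return ResolutionEstimate(nyquist_resolution, saturated=True)
    return ResolutionEstimate(d, saturated=False)
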