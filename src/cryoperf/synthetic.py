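"""Seeded generators for every input the analysis pipeline consumes.

Each generator inverts the model its analysis stage assumes, with the ground
truth retained, so every stage can be validated end-to-end without real
micrographs:

* resolution-vs-particle-count points from the Rosenthal-Henderson line
  1/d^2 = (2/B) ln N + a with Gaussian noise on 1/d^2 (the fit's linear
  coordinate; optional noise on d itself for robustness checks);
* half-map volume pairs whose per-shell expected FSC is exactly
  s/(s+1) with s = N*c*exp(-B/(2 d^2)) — a shared blob-built signal volume
  plus independent per-half noise scaled shell-by-shell;
* whole-frame drift trajectories with fast early motion decaying
  exponentially with accumulated dose ("carbon"-like) or slow throughout
  ("gold"-like), plus white tracking jitter;
* per-micrograph mean intensities from Beer-Lambert attenuation
  I = I0*exp(-t/MFP) over a uniform ice-thickness distribution.

Defaults sit in the regimes of a modern 300 kV / K3 membrane-protein
collection: B in the 80-190 A^2 range (100 by default), subsets 5 k-500 k
particles, ~17.5 nm mean ice, 0.87 e/A^2/frame over 75 frames.  All
generators are pure functions of their config: same config, same bytes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .fsc import VolumePair, shell_radii
from .micrograph_qc import ShiftTrajectory
from .rh_model import SubsetPoint

__all__ = [
    "GeneratorConfig",
    "InfeasibleConfigError",
    "RHPointSet",
    "IntensitySet",
    "gen_rh_points",
    "gen_halfmaps",
    "gen_trajectories",
    "gen_micrograph_intensities",
]

# salts giving each generator an independent, config-determined stream
_SALT_RH, _SALT_MAPS, _SALT_TRAJ, _SALT_ICE = 11, 23, 37, 53


class InfeasibleConfigError(ValueError):
    """The configured line/noise combination cannot produce valid points."""


def _default_subsets() -> tuple[int, ...]:
    return tuple(int(round(n)) for n in np.geomspace(5_000, 500_000, 9))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters shared by all generators.

    ``offset_true`` (-0.0823 A^-2) and ``ssnr_scale`` (2.7e-3) are chosen so
    that at B = 100 A^2 the line predicts ~2.6 A from 100 k particles, the
    regime of a well-behaved GPCR dataset.
    """

    seed: int = 0
    # Rosenthal-Henderson line
    b_true: float = 100.0  # A^2
    offset_true: float = -0.0823  # A^-2
    subset_sizes: tuple[int, ...] = field(default_factory=_default_subsets)
    noise_sigma_y: float = 0.001  # A^-2, on 1/d^2
    noise_on_resolution: bool = False  # alternative: same sigma applied to d (A)
    # half-map simulation
    ssnr_scale: float = 2.7e-3  # per-particle SSNR scale c
    box_size: int = 64
    pixel_size: float = 1.0  # A
    n_blobs: int = 40
    noise_scale: float = 1.0  # multiplies the per-half noise amplitude
    # ice model
    thickness_range: tuple[float, float] = (15.0, 20.0)  # nm
    mfp: float = 322.0  # nm
    i0: float = 36.0  # counts/pixel
    intensity_noise: float = 0.01  # multiplicative sd
    # motion model
    n_frames: int = 75
    exposure_per_frame: float = 0.87  # e/A^2/frame
    drift_rate_carbon: float = 2.5  # A per e/A^2, initial
    drift_rate_gold: float = 0.5
    drift_decay_dose: float = 2.5  # e/A^2
    jitter_sigma: float = 0.1  # A per frame

    def __post_init__(self) -> None:
        if self.b_true <= 0 or self.ssnr_scale <= 0 or self.pixel_size <= 0:
            raise ValueError("scales must be positive")
        if self.thickness_range[0] <= 0 or self.thickness_range[1] < self.thickness_range[0]:
            raise ValueError("thickness_range must be positive and ordered")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])

    @property
    def slope_true(self) -> float:
        return 2.0 / self.b_true


class RHPointSet(NamedTuple):
    points: list[SubsetPoint]
    slope_true: float
    offset_true: float
    b_true: float


class IntensitySet(NamedTuple):
    intensities: np.ndarray  # counts/pixel
    thicknesses: np.ndarray  # nm, ground truth


def gen_rh_points(cfg: GeneratorConfig, max_resample: int = 1000) -> RHPointSet:
    """Noisy resolution-vs-N points from the configured line.

    y = slope_true*ln N + offset_true + N(0, noise_sigma_y); d = 1/sqrt(y).
    Draws yielding y <= 0 (unphysical resolution) are rejected and resampled
    with a warning; a configuration that cannot produce a valid draw raises.
    With ``noise_on_resolution`` the noise is applied to d instead of y.
    """
    if len(cfg.subset_sizes) < 3:
        raise ValueError("need >= 3 subset sizes")
    rng = cfg.rng(_SALT_RH)
    points = []
    for n in cfg.subset_sizes:
        y_clean = cfg.slope_true * math.log(n) + cfg.offset_true
        d = None
        for attempt in range(max_resample):
            eps = rng.normal(0.0, cfg.noise_sigma_y) if cfg.noise_sigma_y > 0 else 0.0
            if cfg.noise_on_resolution:
                if y_clean <= 0:
                    break
                cand = y_clean ** -0.5 + eps
                if cand > 0:
                    d = cand
                    break
            else:
                y = y_clean + eps
                if y > 0:
                    d = y ** -0.5
                    break
            if attempt == 0:
                warnings.warn(f"resampling unphysical draw at N={n}")
        if d is None:
            raise InfeasibleConfigError(
                f"could not draw a physical resolution at N={n} "
                f"(clean 1/d^2 = {y_clean:.4g})"
            )
        points.append(SubsetPoint(n_particles=n, resolution=d))
    return RHPointSet(points, cfg.slope_true, cfg.offset_true, cfg.b_true)


def gen_halfmaps(cfg: GeneratorConfig, n_particles: int) -> VolumePair:
    """Half-map pair whose per-shell expected FSC is s/(s+1).

    A shared signal volume is built from randomly placed 3D Gaussian blobs,
    then its Fourier amplitudes are damped per shell by exp(-B/(4 d^2)) (the
    amplitude half of the B-factor envelope).  Each half adds independent
    noise whose per-shell power is scaled to signal_power/s with
    s = n_particles*c*exp(-B/(2 d^2)), so the expected shell FSC is exactly
    the analytic s/(s+1) regardless of the blob spectrum.
    """
    n = cfg.box_size
    if n < 32:
        raise ValueError("box size must be >= 32")
    rng = cfg.rng(_SALT_MAPS)

    signal = np.zeros((n, n, n))
    ax = np.arange(n)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    for _ in range(cfg.n_blobs):
        cx, cy, cz = rng.uniform(n * 0.2, n * 0.8, size=3)
        sigma = rng.uniform(1.5, 3.5)
        amp = rng.uniform(0.5, 1.5)
        signal += amp * np.exp(
            -((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2) / (2 * sigma ** 2)
        )

    r = shell_radii(n)
    with np.errstate(divide="ignore"):
        freq = r / (n * cfg.pixel_size)  # 1/A
        inv_d2 = freq ** 2
    damp = np.exp(-cfg.b_true * inv_d2 / 4.0)
    f_sig = np.fft.fftn(signal) * damp
    ssnr = n_particles * cfg.ssnr_scale * np.exp(-cfg.b_true * inv_d2 / 2.0)

    r_flat = r.ravel()
    max_r = int(r_flat.max())
    counts = np.bincount(r_flat, minlength=max_r + 1)
    p_sig = np.bincount(r_flat, weights=(np.abs(f_sig) ** 2).ravel(), minlength=max_r + 1)
    p_sig = p_sig / np.maximum(counts, 1)
    ssnr_shell = np.bincount(r_flat, weights=ssnr.ravel(), minlength=max_r + 1)
    ssnr_shell = ssnr_shell / np.maximum(counts, 1)

    halves = []
    for _ in range(2):
        noise = rng.standard_normal((n, n, n))
        f_noise = np.fft.fftn(noise)
        p_noise = np.bincount(
            r_flat, weights=(np.abs(f_noise) ** 2).ravel(), minlength=max_r + 1
        ) / np.maximum(counts, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.sqrt(p_sig / (ssnr_shell * p_noise))
        gain = np.where(np.isfinite(gain), gain, 0.0)
        f_noise *= gain[r] * cfg.noise_scale
        halves.append(signal_real(f_sig + f_noise))
    return VolumePair(map1=halves[0], map2=halves[1], pixel_size=cfg.pixel_size)


def signal_real(f: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifftn(f))


def gen_trajectories(
    cfg: GeneratorConfig, n_micrographs: int, preset: str = "carbon"
) -> list[ShiftTrajectory]:
    """Whole-frame drift paths: exponential dose-decay drift plus jitter.

    Per micrograph a random drift direction is drawn; the drift speed at
    accumulated dose D is rate0*exp(-D/decay) (A per e/A^2), integrated over
    each frame's exposure.  The two presets differ only in the initial rate:
    "carbon" (fast early motion of carbon-film supports) vs "gold" (stiff
    gold-foil grids).
    """
    rates = {"carbon": cfg.drift_rate_carbon, "gold": cfg.drift_rate_gold}
    if preset not in rates:
        raise ValueError(f"preset must be one of {sorted(rates)}")
    if cfg.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = cfg.rng(_SALT_TRAJ)
    rate0 = rates[preset]
    f = cfg.exposure_per_frame
    doses = np.arange(cfg.n_frames - 1) * f  # dose at the start of each step
    speeds = rate0 * np.exp(-doses / cfg.drift_decay_dose) * f  # A per frame step

    trajectories = []
    for _ in range(n_micrographs):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        steps = speeds[:, None] * direction[None, :]
        if cfg.jitter_sigma > 0:
            steps = steps + rng.normal(0.0, cfg.jitter_sigma, size=steps.shape)
        positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        trajectories.append(
            ShiftTrajectory(positions=positions, exposure_per_frame=f)
        )
    return trajectories


def gen_micrograph_intensities(cfg: GeneratorConfig, n_micrographs: int) -> IntensitySet:
    """Per-micrograph mean intensities with known ice thicknesses.

    t ~ Uniform(thickness_range); I = I0*exp(-t/MFP)*(1 + eps) with small
    multiplicative noise eps ~ N(0, intensity_noise).  With zero noise the
    Beer-Lambert inversion recovers t exactly and I never exceeds I0.
    """
    rng = cfg.rng(_SALT_ICE)
    t = rng.uniform(*cfg.thickness_range, size=n_micrographs)
    i = cfg.i0 * np.exp(-t / cfg.mfp)
    if cfg.intensity_noise > 0:
        i = i * (1.0 + rng.normal(0.0, cfg.intensity_noise, size=n_micrographs))
    return IntensitySet(intensities=i, thicknesses=t)
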