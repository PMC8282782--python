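# Methods

## The B-factor model

A single-particle reconstruction from N randomly drawn particles has an
expected squared reciprocal resolution that is linear in ln N:

    1/d² = slope·ln N + offset,    B = 2/slope  [Å²].

The slope captures the exponential decay of usable signal with spatial
frequency (one B-factor aggregating sample disorder, beam-induced motion,
optical envelopes and processing losses); the offset captures the overall
per-particle signal-to-noise ratio. `fit_rh` estimates the line by
unweighted ordinary least squares over the included points (the conventional
B-factor-plot procedure is unweighted; a weighted fit is available behind
the `weights` argument but off by default). Standard errors and the
slope–offset covariance come from the textbook OLS formulas with n−2
residual degrees of freedom (statsmodels.OLS underneath, cross-checked in
the tests against hand-written normal equations). With exactly two points
the residual variance is undefined and all errors are reported as `nan`
rather than zero.

Points from very small subsets (below ~1–2 k particles) fall off the line
because refinement fails to lock onto secondary-structure periodicity.
That failure is not diagnosable from the metadata alone, so
`exclude_outliers` applies a pure count threshold, default 2000 particles,
configurable. Points are flagged, never deleted.

The natural logarithm is used for the x axis. The base cancels in B (slope
and ln both rescale) but not in the offset, so one convention must be fixed
for reproducibility; natural log keeps the offset directly comparable to
the analytic SSNR model below.

## Derived measures and error propagation

Two views of the same line are reported: d(N_ref) = (slope·ln N_ref +
offset)^(−1/2) at N_ref = 100 000, and N(d_ref) = exp((1/d_ref² −
offset)/slope) at d_ref = 3.0 Å. Together with B they are mutually
determined — any two reconstruct the third (`reconstruct_fit`), which is
also how published summary tables are validated without the underlying
points.

Standard errors use the delta method with the full 2×2 covariance of
(slope, offset). Whether published error bars of this kind include the
covariance term is typically unstated; it is included here by default
because OLS slope and intercept are strongly anticorrelated (cov =
−x̄·var(slope)) and dropping it overstates the error at interpolated N,
and an `include_covariance=False` flag reproduces the variance-only
convention for comparison. Particle counts are carried as real numbers;
rounding to thousands happens only in the report layer. Derived metrics are
always computed from full-precision fit parameters, never from rounded
printed values.

Pairwise device effects (`compare_subsets`) treat the two subsets as
independent (they come from independent fits), so SEs add in quadrature for
differences; percent changes and fold ratios use the first-order
(log-normal) ratio approximation se(a/b) ≈ |a/b|·sqrt(cv_a² + cv_b²).
Percent changes are reported raw and signed (positive B-factor change =
worse); the orientation to "improvement" lives in `improvement_flags`, and
one operation serves devices and high/low settings alike.

## FSC and the analytic bridge

`compute_fsc` is the standard unmasked shell correlation: FSC(s) =
Re⟨F₁F₂*⟩/√(⟨|F₁|²⟩⟨|F₂|²⟩) over integer-radius shells in voxel-frequency
units (rounded radius, shells beyond Nyquist discarded, empty shells
dropped). No solvent mask and no phase-randomization correction are
applied, so absolute resolutions are not comparable to masked published
values — within the package the same convention is used on both the
simulation and analysis side, which is what the recovery tests require.
`resolution_at_threshold` takes the *first* crossing below the threshold
(default 0.143), linearly interpolated between shells; first-crossing is
standard practice and stable when noise makes the tail oscillate. A curve
that never crosses saturates at the Nyquist resolution 2·pixel size and is
flagged.

The analytic model SSNR(d) = N·c·exp(−B/(2d²)), FSC = SSNR/(SSNR+1) links
the simulator to the fit: solving FSC = t gives 1/d² = (2/B)·ln(N·c·(1−t)/t),
exactly the fitted line with slope 2/B. `predicted_resolution` returns the
closed-form crossing, with flags for no-solution (SSNR below threshold
everywhere, or a crossing beyond a supplied worst-resolution band limit, as
in the large-B limit) and for Nyquist clipping.

## Micrograph statistics

Ice thickness: t = MFP·ln(I₀/I), MFP 395/322 nm (no aperture / 100 µm
objective aperture); the constants are instrument-calibrated values treated
as configurable defaults, selected strictly by the aperture flag, never
interpolated. I₀ must be measured per session from images in empty holes;
when absent, thickness is reported unavailable rather than guessed from the
intensity histogram. Micrographs brighter than I₀ (apparent negative
thickness) raise in the scalar API and are flagged and excluded from
summaries in the table API.

Displacements are endpoint Euclidean distances, not path sums: with 60–75
frames the summed inter-frame shifts are dominated by tracking noise. The
early window ends at the frame where accumulated exposure reaches ~4 e/Å²,
formalized as index = ceil(D/f) + 1 (1-based; f = exposure per frame,
D = 4 e/Å² default) — the first frame starting at or past the target dose.
Whether the conventional anchor frames were chosen by dose at frame start,
end or midpoint is not stated anywhere authoritative; this rule is one
consistent formalization and reproduces both common anchors (frame 5 at
1.03, frame 6 at 0.87–0.89 e/Å²/frame). Endpoint metrics can under-report
U-turn motion (a closed loop scores 0); this is accepted and documented.

Alignment summaries take the median of per-particle significant-sample
counts (even length: mean of the central pair) and pass run-level
angular/translational accuracies through unchanged.

## Synthetic data: what it emulates and what it does not

Every generator inverts the model its analysis stage assumes and keeps the
ground truth, making each stage's recovery testable end to end. Defaults
describe a well-behaved 300 kV / K3 membrane-protein collection: B = 100 Å²
(published subsets span ~80–190 Å²), offset −0.0823 Å⁻² and SSNR scale
c = 2.7×10⁻³ chosen so d(100 k) ≈ 2.6 Å, nine subset sizes log-spaced
5 k–500 k, noise σ = 0.001 Å⁻² on 1/d², ice uniform on 15–20 nm (mean
17.5 nm, the thin-ice regime), I₀ = 36 counts/pixel with 1% multiplicative
noise, 75 frames at 0.87 e/Å²/frame, and drift decaying exponentially with
dose (decay constant 2.5 e/Å²) at initial rates 2.5 ("carbon") vs 0.5
("gold") Å per e/Å² plus 0.1 Å/frame jitter.

Noise is placed on 1/d² because that is the fit's linear coordinate (a
`noise_on_resolution` flag moves it to d for robustness checks). Half-map
pairs share one blob-built signal volume, Fourier-damped by exp(−B/(4d²)) in
amplitude, plus per-half independent noise rescaled shell-by-shell to
signal_power/SSNR — so the expected shell FSC equals SSNR/(SSNR+1) exactly,
regardless of the blob spectrum. The uniform thickness distribution is the
simplest stand-in for real (unimodal, skewed) ice histograms.

None of this is physical image formation: no CTF, no detector DQE, no
radiation-damage spectrum, no per-particle motion. Passing tests therefore
demonstrate that the *estimators* are correct and self-consistent under the
stated models, not that the models capture every property of real
micrographs.

All generators are pure functions of `GeneratorConfig`: the seed plus a
per-generator salt feeds `numpy.random.default_rng`, so identical configs
give identical bytes and different generators draw independent streams.

## Numerical and interface choices

* Fit errors: `nan` (not 0) marks non-estimable quantities throughout;
  reconstructed fits from summary pairs carry `nan` errors.
* `resolution_at_particles` raises out-of-fit-range when the line predicts
  1/d² ≤ 0 instead of returning a complex/NaN resolution.
* STAR files are parsed with gemmi (loops and single-value blocks,
  whitespace-delimited, `#` comments, case-sensitive `rln` names);
  malformed files raise `ParseError` with the underlying location. Writers
  round-trip exactly through their own readers.
* Report rendering: resolutions 2 decimals, B-factors 1 decimal, particle
  counts in units of 10³ (1 decimal below 100 k, integer above), percents as
  integers. The machine-readable JSON keeps full precision and regenerating
  the text table from it is byte-identical. The table has a fixed 12-row
  layout; subset ids must reconcile across all inputs or the build fails
  listing the orphans.
* Ledger invariants (used ≤ after-CTF ≤ total micrographs, final ≤ picked
  particles) are hard construction errors.
* CLI runs write a `<out>.log.json` with parameters, package versions and
  SHA-256 digests of the inputs.

## Problem sizes

Validation uses desk-scale problems: 64³ half-map boxes at six particle
counts for the end-to-end FSC→fit recovery, 1000 replicates for coverage
checks, 10⁵ draws for the Monte-Carlo propagation oracle, 5000 micrographs
for thickness convergence. These sizes give statistical resolution well
below the tolerances being checked.

## Known limitations

* Unmasked FSC only; absolute resolutions from masked published pipelines
  are out of reach by design.
* The ±3·SE coverage of the fitted B-factor is t-distributed (n−2 degrees
  of freedom), ~98% for 9-point fits, not the Gaussian 99.7% — small-sample
  fits genuinely have heavier-tailed error estimates.
* The early-frame rule is one formalization of an approximate convention;
  alternative dose-at-midpoint rules shift the index by at most one frame.
* Orientation-distribution efficiency scoring and any reconstruction-side
  processing (motion correction, CTF fitting, classification, polishing)
  are out of scope; the package consumes their outputs.
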