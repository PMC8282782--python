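"""Pairwise effect measures for experimental-parameter comparisons.

Each acquisition device or setting (Volta phase plate, zero-loss energy
filter, objective lens aperture, defocus range, total exposure) is assessed
by comparing two matched dataset subsets — one collected *with* the device or
high setting and one *without* / at the low setting — on three performance
measures derived from their Rosenthal-Henderson fits:

* resolution from the reference particle count, as a difference in A
  (oriented so positive = the device improved resolution);
* B-factor, as the raw percent change 100*(B_with - B_without)/B_without
  (negative = improvement, since lower B is better);
* particles to reach the reference resolution, as the same raw percent
  change (negative = improvement).

Standard errors combine the two subsets' fit errors assuming independence;
ratio errors use a first-order (log-normal) approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .rh_model import DerivedMetrics, Measurement, RHFit

__all__ = [
    "Performance",
    "ComparisonResult",
    "UndefinedRatioError",
    "compare_subsets",
    "fold_ratio_particles",
    "effects_table",
    "plot_effects",
]


class UndefinedRatioError(ZeroDivisionError):
    """Percent change or fold ratio against a zero baseline."""


class Performance(NamedTuple):
    """A subset's fitted line together with its derived metrics."""

    fit: RHFit
    metrics: DerivedMetrics


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    delta_resolution: Measurement  # A; positive = improvement with the device
    pct_change_bfactor: Measurement  # raw %, negative = improvement
    pct_change_particles: Measurement  # raw %, negative = improvement
    improvement_flags: dict[str, bool]


def compare_subsets(
    metrics_with: Performance, metrics_without: Performance, label: str
) -> ComparisonResult:
    """Effect of a device/setting on the three performance measures.

    ``delta_resolution`` is res(without) - res(with), so an improvement is
    positive.  Percent changes are signed from the without-baseline; the
    ``improvement_flags`` dict orients each measure so True = better with the
    device ("with" improves resolution if delta > 0, improves B-factor or
    particle count if the percent change is negative).
    """
    for perf in (metrics_with, metrics_without):
        if perf.fit.slope <= 0:
            raise ValueError("both fits must have positive slope")

    res_w = metrics_with.metrics.resolution_at_ref
    res_wo = metrics_without.metrics.resolution_at_ref
    delta = Measurement(
        res_wo.value - res_w.value, _hypot(res_w.se, res_wo.se)
    )
    pct_b = _pct_change(
        Measurement(metrics_with.fit.bfactor, metrics_with.fit.se_bfactor),
        Measurement(metrics_without.fit.bfactor, metrics_without.fit.se_bfactor),
    )
    pct_n = _pct_change(
        metrics_with.metrics.particles_at_ref,
        metrics_without.metrics.particles_at_ref,
    )
    return ComparisonResult(
        label=label,
        delta_resolution=delta,
        pct_change_bfactor=pct_b,
        pct_change_particles=pct_n,
        improvement_flags={
            "resolution": delta.value > 0,
            "bfactor": pct_b.value < 0,
            "particles": pct_n.value < 0,
        },
    )


def fold_ratio_particles(
    metrics_a: DerivedMetrics, metrics_b: DerivedMetrics
) -> Measurement:
    """Fold ratio of particles needed to reach the reference resolution.

    ratio = N_a / N_b.  The SE uses the first-order log-normal
    approximation: se(ratio) = ratio * sqrt(cv_a^2 + cv_b^2) with cv the
    coefficients of variation of the two counts.
    """
    n_a, n_b = metrics_a.particles_at_ref, metrics_b.particles_at_ref
    if n_b.value == 0:
        raise UndefinedRatioError("denominator particle count is zero")
    ratio = n_a.value / n_b.value
    cv_a = n_a.se / n_a.value if n_a.value else float("nan")
    cv_b = n_b.se / n_b.value
    return Measurement(ratio, abs(ratio) * _hypot(cv_a, cv_b))


def effects_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Summary table of a batch of comparisons, one row per label."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "delta_resolution_A": r.delta_resolution.value,
                "se_delta_resolution_A": r.delta_resolution.se,
                "pct_change_bfactor": r.pct_change_bfactor.value,
                "se_pct_change_bfactor": r.pct_change_bfactor.se,
                "pct_change_particles": r.pct_change_particles.value,
                "se_pct_change_particles": r.pct_change_particles.se,
                "improves_resolution": r.improvement_flags["resolution"],
                "improves_bfactor": r.improvement_flags["bfactor"],
                "improves_particles": r.improvement_flags["particles"],
            }
        )
    return pd.DataFrame(rows)


def plot_effects(results: Sequence[ComparisonResult], path: str) -> None:
    """Three-panel bar chart of the effect measures, upward = improvement.

    Resolution deltas are plotted as-is (positive already means better);
    percent changes of B-factor and particle count are negated so that an
    upward bar always marks an improvement.  Error bars are the combined
    standard errors.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.label for r in results]
    panels = [
        ("Resolution from ref. particles [A]", 1.0,
         [r.delta_resolution for r in results]),
        ("B-factor change [%]", -1.0, [r.pct_change_bfactor for r in results]),
        ("Particles to ref. resolution [%]", -1.0,
         [r.pct_change_particles for r in results]),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, (title, orient, values) in zip(axes, panels):
        heights = [orient * v.value for v in values]
        errs = [0.0 if math.isnan(v.se) else v.se for v in values]
        ax.bar(labels, heights, yerr=errs, capsize=3)
        ax.axhline(0.0, lw=0.8, color="k")
        ax.set_title(title, fontsize=9)
    fig.suptitle("Upward bar = improvement", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _pct_change(with_: Measurement, without: Measurement) -> Measurement:
    if without.value == 0:
        raise UndefinedRatioError("baseline value is zero")
    ratio = with_.value / without.value
    pct = 100.0 * (ratio - 1.0)
    # var(a/b) ~= (a/b)^2 * (se_a^2/a^2 + se_b^2/b^2), subsets independent
    if with_.value == 0:
        se = float("nan")
    else:
        se = 100.0 * abs(ratio) * _hypot(with_.se / with_.value, without.se / without.value)
    return Measurement(pct, se)


def _hypot(a: float, b: float) -> float:
    if math.isnan(a) or math.isnan(b):
        return float("nan")
    return math.hypot(a, b)
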