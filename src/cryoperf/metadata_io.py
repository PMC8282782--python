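"""Metadata I/O, particle-budget accounting and report assembly.

Readers and writers for the table formats a cryo-EM performance analysis
touches: resolution-vs-particle-count points (CSV/TSV or the two-column text
emitted by B-factor-plot scripts), particle metadata in STAR format (RELION
``rln`` column conventions, parsed with gemmi), per-micrograph frame-shift
trajectories (STAR or plain text), and half-map volumes in MRC format.

Also houses the bookkeeping of a dataset subset (micrograph/particle
retention, exposure accounting) and the final report: a machine-readable
JSON record per subset plus a fixed 12-row human-readable table of the
standard per-subset summary rows.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import gemmi

from .micrograph_qc import AlignmentStats, ShiftTrajectory
from .rh_model import DerivedMetrics, RHFit, SubsetPoint

__all__ = [
    "SubsetLedger",
    "ExposureRecord",
    "ParseError",
    "ReconciliationError",
    "retention_percent",
    "per_micrograph",
    "total_exposure",
    "read_points",
    "read_bfactor_log",
    "read_particle_table",
    "write_particle_table",
    "particle_alignment_stats",
    "read_shift_star",
    "read_shift_log",
    "read_volume",
    "write_volume",
    "fit_record",
    "Report",
    "REPORT_ROWS",
    "build_report",
    "write_run_log",
]


class ParseError(ValueError):
    """A metadata file violates its format's structural rules."""


class ReconciliationError(ValueError):
    """Subset ids are inconsistent across the report inputs."""


# ---------------------------------------------------------------- accounting


@dataclass(frozen=True)
class SubsetLedger:
    """Micrograph/particle budget of one dataset subset.

    Count monotonicity (used <= after_ctf <= total, final <= picked) is
    enforced at construction; violating input is a hard error.
    """

    micrographs_total: int
    micrographs_after_ctf: int
    micrographs_used: int
    picked_particles: int
    final_particles: int
    defocus_range_um: tuple[float, float]
    resolution: float  # A

    def __post_init__(self) -> None:
        if not (
            0 <= self.micrographs_used
            <= self.micrographs_after_ctf
            <= self.micrographs_total
        ):
            raise ValueError(
                "micrograph counts must satisfy used <= after_ctf <= total; got "
                f"{self.micrographs_used} <= {self.micrographs_after_ctf} "
                f"<= {self.micrographs_total}"
            )
        if not 0 <= self.final_particles <= self.picked_particles:
            raise ValueError(
                f"final particles ({self.final_particles}) must not exceed "
                f"picked ({self.picked_particles})"
            )
        lo, hi = self.defocus_range_um
        if lo > hi:
            raise ValueError("defocus range must be (min, max)")


@dataclass(frozen=True)
class ExposureRecord:
    """Exposure accounting of one acquisition: rate x time over n frames."""

    exposure_rate: float  # e/A^2/s
    exposure_time: float  # s
    n_frames: int

    def __post_init__(self) -> None:
        if not (self.exposure_rate > 0 and self.exposure_time > 0 and self.n_frames > 0):
            raise ValueError("exposure rate, time and frame count must all be > 0")

    @property
    def exposure_per_frame(self) -> float:
        return total_exposure(self) / self.n_frames

    def validate(
        self, rate_e_per_pix_s: float | None = None, pixel_size: float | None = None
    ) -> list[str]:
        """Cross-check the per-area rate against a per-pixel rate, if known.

        Published acquisition tables sometimes list both and they can
        disagree; the per-area (e/A^2/s) figure is authoritative here and a
        mismatch beyond 0.5% (more than printed-precision rounding explains)
        is surfaced as a warning string.
        """
        notes: list[str] = []
        if rate_e_per_pix_s is not None and pixel_size is not None:
            implied = rate_e_per_pix_s / pixel_size ** 2
            if abs(implied - self.exposure_rate) > 0.005 * self.exposure_rate:
                notes.append(
                    f"per-pixel rate {rate_e_per_pix_s} e/pix/s at {pixel_size} A/px "
                    f"implies {implied:.2f} e/A^2/s, but record says "
                    f"{self.exposure_rate}; using the e/A^2/s figure"
                )
        return notes


def retention_percent(kept: int, total: int) -> float:
    """Retained fraction as a percentage (full precision; report layer rounds)."""
    if total <= 0:
        raise ZeroDivisionError("total must be > 0")
    if not 0 <= kept <= total:
        raise ValueError(f"kept must be in [0, total], got {kept}/{total}")
    return 100.0 * kept / total


def per_micrograph(count: int, micrographs: int) -> float:
    """Average particles per micrograph (full precision)."""
    if micrographs <= 0:
        raise ZeroDivisionError("micrographs must be > 0")
    return count / micrographs


def total_exposure(rec: ExposureRecord) -> float:
    """Total exposure in e/A^2: rate x time."""
    return rec.exposure_rate * rec.exposure_time


# ------------------------------------------------------------- point tables


def read_points(path: str | Path) -> list[SubsetPoint]:
    """Read subset points from CSV/TSV with columns
    ``subset_id, n_particles, resolution_angstrom``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"n_particles", "resolution_angstrom"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        SubsetPoint(int(r.n_particles), float(r.resolution_angstrom))
        for r in df.itertuples()
    ]


def read_bfactor_log(path: str | Path) -> list[SubsetPoint]:
    """Read the two-column ``n_particles resolution`` text emitted by
    B-factor-plot helper scripts ('#' comments, whitespace-delimited)."""
    points = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        fields = body.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'n_particles resolution'")
        try:
            n, d = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        points.append(SubsetPoint(int(round(n)), d))
    return points


# --------------------------------------------------------------------- STAR


def _read_star(path: str | Path) -> gemmi.cif.Document:
    try:
        return gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_particle_table(path: str | Path) -> pd.DataFrame:
    """Read a STAR particles loop into a typed DataFrame.

    Looks for the first block containing a loop of ``_rln*`` tags (RELION's
    ``data_particles`` convention, with ``data_`` accepted for older files).
    Numeric columns are converted; unknown columns are preserved as-is.  An
    empty loop yields an empty frame with a warning.
    """
    doc = _read_star(path)
    for block in doc:
        tags = [item.loop.tags for item in block if item.loop is not None]
        for tag_list in tags:
            if any(t.startswith("_rln") for t in tag_list):
                table = block.find(list(tag_list))
                data = {
                    tag: [row[i] for row in table] for i, tag in enumerate(tag_list)
                }
                df = pd.DataFrame(data)
                for col in df.columns:
                    converted = pd.to_numeric(df[col], errors="coerce")
                    if len(df) == 0 or not converted.isna().any():
                        df[col] = converted
                if len(df) == 0:
                    warnings.warn(f"{path}: particles loop has 0 rows")
                return df
    raise ParseError(f"{path}: no particles loop with _rln columns found")


def write_particle_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a RELION-style ``data_particles`` STAR loop."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("", list(df.columns))
    for row in df.itertuples(index=False):
        loop.add_row([_star_token(v) for v in row])
    doc.write_file(str(path))


def _star_token(v) -> str:
    s = str(v)
    return s if s and not any(ch.isspace() for ch in s) else f'"{s}"'


def particle_alignment_stats(df: pd.DataFrame) -> AlignmentStats:
    """Build AlignmentStats from a particle table.

    Missing optional columns degrade gracefully: absent significant-sample
    counts give an empty array, absent accuracies are ``nan``.
    """
    sig = (
        df["_rlnNrOfSignificantSamples"].to_numpy()
        if "_rlnNrOfSignificantSamples" in df.columns
        else np.array([], dtype=int)
    )

    def _run_level(col: str) -> float:
        if col not in df.columns or len(df) == 0:
            return float("nan")
        return float(np.asarray(df[col], dtype=float)[0])

    return AlignmentStats(
        significant_samples=sig,
        angular_accuracy_deg=_run_level("_rlnAccuracyRotations"),
        translational_accuracy_ang=_run_level("_rlnAccuracyTranslationsAngst"),
    )


def read_shift_star(
    path: str | Path,
    exposure_per_frame: float | None = None,
    scale: float = 1.0,
) -> ShiftTrajectory:
    """Read a motion-correction metadata STAR file into a ShiftTrajectory.

    Expects a ``data_global_shift`` loop with ``_rlnMicrographShiftX/Y`` (one
    row per frame) and, optionally, ``_rlnMicrographDoseRate`` in the
    ``data_general`` block; an explicit ``exposure_per_frame`` overrides the
    latter.  ``scale`` converts shift units to A (1.0 if already A).
    """
    doc = _read_star(path)
    dose = exposure_per_frame
    xs = ys = None
    for block in doc:
        if dose is None:
            val = block.find_value("_rlnMicrographDoseRate")
            if val is not None:
                dose = float(val)
        col_x = list(block.find_loop("_rlnMicrographShiftX"))
        col_y = list(block.find_loop("_rlnMicrographShiftY"))
        if col_x and col_y:
            xs = np.array(col_x, dtype=float)
            ys = np.array(col_y, dtype=float)
    if xs is None:
        raise ParseError(f"{path}: no _rlnMicrographShiftX/Y loop found")
    if dose is None:
        raise ParseError(
            f"{path}: no _rlnMicrographDoseRate; pass exposure_per_frame explicitly"
        )
    positions = np.column_stack([xs, ys]) * scale
    return ShiftTrajectory(positions=positions, exposure_per_frame=dose)


def read_shift_log(
    path: str | Path, exposure_per_frame: float, scale: float = 1.0
) -> ShiftTrajectory:
    """Read a plain two-column (x y per frame) shift log into a trajectory."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        fields = body.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'x y'")
        rows.append((float(fields[0]), float(fields[1])))
    if len(rows) < 2:
        raise ParseError(f"{path}: need >= 2 frames, got {len(rows)}")
    return ShiftTrajectory(
        positions=np.array(rows) * scale, exposure_per_frame=exposure_per_frame
    )


# ---------------------------------------------------------------------- MRC


def read_volume(path: str | Path, pixel_size: float | None = None) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 volume; pixel size from the header unless overridden."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    if pixel_size is None:
        pixel_size = m.grid.unit_cell.a / m.grid.nu
    return arr, float(pixel_size)


def write_volume(arr: np.ndarray, pixel_size: float, path: str | Path) -> None:
    """Write a cubic volume as an MRC/CCP4 map with the given pixel size."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(arr, dtype=np.float32))
    n = arr.shape[0]
    m.grid.unit_cell = gemmi.UnitCell(
        n * pixel_size, n * pixel_size, n * pixel_size, 90, 90, 90
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ------------------------------------------------------------------- report


def fit_record(fit: RHFit, metrics: DerivedMetrics) -> dict:
    """JSON-ready record of one subset's fit and derived metrics."""
    return {
        "slope": fit.slope,
        "offset": fit.offset,
        "se_slope": fit.se_slope,
        "se_offset": fit.se_offset,
        "cov": fit.cov_slope_offset,
        "bfactor": fit.bfactor,
        "se_bfactor": fit.se_bfactor,
        "res_100k": metrics.resolution_at_ref.value,
        "se_res_100k": metrics.resolution_at_ref.se,
        "particles_3A": metrics.particles_at_ref.value,
        "se_particles_3A": metrics.particles_at_ref.se,
        "ref_n": metrics.ref_n,
        "ref_resolution": metrics.ref_resolution,
        "n_points_used": fit.n_points_used,
    }


REPORT_ROWS = (
    "Micrographs",
    "Micrographs after CTF fits (retention)",
    "Micrographs used",
    "Measured defocus [um]",
    "Picked particles [x10^3] (per micrograph)",
    "Final particle set [x10^3] (retention) (per micrograph)",
    "Resolution [A]",
    "B-factor [A^2]",
    "Particles to reach reference resolution [x10^3]",
    "Resolution from reference particles [A]",
    "Median number of significant samples",
    "Alignment accuracy [deg / A]",
)


@dataclass(frozen=True)
class Report:
    """Machine-readable subset records plus a fixed-layout summary table.

    ``subsets`` maps subset id to its full-precision record (ledger counts,
    fit parameters, derived metrics, optional alignment QC and provenance);
    the text table is rendered deterministically from those records, so a
    report regenerated from its own JSON is byte-identical.
    """

    subsets: dict[str, dict]
    comparisons: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"subsets": self.subsets, "comparisons": self.comparisons}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        obj = json.loads(text)
        return cls(subsets=obj["subsets"], comparisons=obj.get("comparisons", []))

    def rows(self) -> dict[str, list[str]]:
        """Formatted cell values, one list (per subset, in order) per row."""
        out = {label: [] for label in REPORT_ROWS}
        for rec in self.subsets.values():
            cells = _format_subset_cells(rec)
            for label in REPORT_ROWS:
                out[label].append(cells[label])
        return out

    def to_text(self) -> str:
        ids = list(self.subsets)
        rows = self.rows()
        label_w = max(len(r) for r in REPORT_ROWS)
        col_w = [
            max(len(i), max(len(rows[r][k]) for r in REPORT_ROWS))
            for k, i in enumerate(ids)
        ]
        lines = [
            " | ".join([" " * label_w] + [i.ljust(w) for i, w in zip(ids, col_w)]).rstrip()
        ]
        for label in REPORT_ROWS:
            cells = [c.ljust(w) for c, w in zip(rows[label], col_w)]
            lines.append(" | ".join([label.ljust(label_w)] + cells).rstrip())
        return "\n".join(lines) + "\n"


def _fmt_k(particles: float) -> str:
    """Particle counts in units of 10^3: one decimal below 100 k, else integer."""
    k = particles / 1000.0
    return f"{k:.1f}" if k < 100 else f"{k:.0f}"


def _fmt_se(value: str, se: float | None) -> str:
    if se is None or (isinstance(se, float) and math.isnan(se)):
        return value
    return f"{value} ({se:.3g})"


def _format_subset_cells(rec: dict) -> dict[str, str]:
    led, fit, qc = rec["ledger"], rec["fit"], rec.get("qc")
    ctf_ret = retention_percent(led["micrographs_after_ctf"], led["micrographs_total"])
    fin_ret = retention_percent(led["final_particles"], led["picked_particles"])
    picked_pm = per_micrograph(led["picked_particles"], led["micrographs_used"])
    final_pm = per_micrograph(led["final_particles"], led["micrographs_used"])
    lo, hi = led["defocus_range_um"]
    cells = {
        "Micrographs": str(led["micrographs_total"]),
        "Micrographs after CTF fits (retention)": (
            f"{led['micrographs_after_ctf']} ({ctf_ret:.0f}%)"
        ),
        "Micrographs used": str(led["micrographs_used"]),
        "Measured defocus [um]": f"{lo:g}-{hi:g}",
        "Picked particles [x10^3] (per micrograph)": (
            f"{_fmt_k(led['picked_particles'])} ({picked_pm:.0f})"
        ),
        "Final particle set [x10^3] (retention) (per micrograph)": (
            f"{_fmt_k(led['final_particles'])} ({fin_ret:.0f}%) ({final_pm:.0f})"
        ),
        "Resolution [A]": f"{led['resolution']:.2f}",
        "B-factor [A^2]": _fmt_se(f"{fit['bfactor']:.1f}", fit["se_bfactor"]),
        "Particles to reach reference resolution [x10^3]": _fmt_se(
            _fmt_k(fit["particles_3A"]),
            fit["se_particles_3A"] / 1000.0
            if fit["se_particles_3A"] is not None
            and not math.isnan(fit["se_particles_3A"])
            else float("nan"),
        ),
        "Resolution from reference particles [A]": _fmt_se(
            f"{fit['res_100k']:.2f}", fit["se_res_100k"]
        ),
    }
    if qc:
        cells["Median number of significant samples"] = (
            f"{qc['median_significant_samples']:.0f}"
        )
        ang, tra = qc["angular_accuracy_deg"], qc["translational_accuracy_ang"]
        cells["Alignment accuracy [deg / A]"] = f"{ang:.2f} / {tra:.2f}"
    else:
        cells["Median number of significant samples"] = "n/a"
        cells["Alignment accuracy [deg / A]"] = "n/a"
    return cells


def build_report(
    ledgers: Mapping[str, SubsetLedger],
    fits: Mapping[str, RHFit],
    metrics: Mapping[str, DerivedMetrics],
    comparisons: Sequence[dict] | None = None,
    qc: Mapping[str, dict] | None = None,
) -> Report:
    """Assemble the per-subset summary report.

    All mappings must cover exactly the same subset ids; orphans on either
    side raise a ReconciliationError listing them.  ``qc`` (alignment
    summaries) is optional per subset.
    """
    if not ledgers:
        raise ValueError("at least one subset is required")
    ids = set(ledgers)
    for name, mapping in (("fits", fits), ("metrics", metrics)):
        if set(mapping) != ids:
            orphans = sorted(set(mapping) ^ ids)
            raise ReconciliationError(f"subset ids inconsistent with {name}: {orphans}")
    if qc is not None and not set(qc) <= ids:
        raise ReconciliationError(
            f"qc ids not in ledgers: {sorted(set(qc) - ids)}"
        )

    subsets = {}
    for sid in ledgers:
        led = ledgers[sid]
        rec = {
            "ledger": {
                "micrographs_total": led.micrographs_total,
                "micrographs_after_ctf": led.micrographs_after_ctf,
                "micrographs_used": led.micrographs_used,
                "picked_particles": led.picked_particles,
                "final_particles": led.final_particles,
                "defocus_range_um": list(led.defocus_range_um),
                "resolution": led.resolution,
            },
            "fit": fit_record(fits[sid], metrics[sid]),
        }
        if qc and sid in qc:
            rec["qc"] = qc[sid]
        subsets[sid] = rec
    return Report(subsets=subsets, comparisons=list(comparisons or []))


# ------------------------------------------------------------------ run log


def write_run_log(path: str | Path, params: dict, inputs: Sequence[str | Path] = ()) -> None:
    """Write a JSON log of a CLI run: parameters, versions, input digests."""
    from . import __version__

    digests = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    log = {
        "params": params,
        "versions": {
            "cryoperf": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_sha256": digests,
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str) + "\n")
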