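"""Readers/writers, accounting and report assembly."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from cryoperf import (
    ExposureRecord,
    ParseError,
    ReconciliationError,
    Report,
    SubsetLedger,
    build_report,
    derived_metrics,
    fit_record,
    fit_rh,
    per_micrograph,
    read_bfactor_log,
    read_particle_table,
    read_points,
    read_shift_log,
    read_shift_star,
    read_volume,
    reconstruct_fit,
    retention_percent,
    total_exposure,
    write_particle_table,
    write_volume,
)
from cryoperf.metadata_io import REPORT_ROWS, particle_alignment_stats
from conftest import exact_line_points


class TestAccounting:
    def test_particle_retention_worked_example(self):
        # 479 k of 2387 k picked particles survive classification
        assert retention_percent(479_000, 2_387_000) == pytest.approx(20.07, abs=0.01)
        assert round(retention_percent(479_000, 2_387_000)) == 20

    def test_retention_bounds(self):
        assert retention_percent(5, 5) == 100.0
        assert retention_percent(0, 5) == 0.0
        with pytest.raises(ZeroDivisionError):
            retention_percent(0, 0)
        with pytest.raises(ValueError):
            retention_percent(6, 5)

    def test_per_micrograph_worked_example(self):
        v = per_micrograph(479_000, 3_466)
        assert v == pytest.approx(138.2, abs=0.05)
        assert round(v) == 138

    def test_per_micrograph_grouping_oracle(self, rng):
        mics = rng.integers(0, 50, size=2_000)
        counts = pd.Series(mics).value_counts()
        assert per_micrograph(len(mics), 50) == pytest.approx(counts.sum() / 50)

    def test_total_exposure_worked_examples(self):
        assert total_exposure(ExposureRecord(17.2, 3.72, 62)) == pytest.approx(63.98, abs=0.005)
        assert total_exposure(ExposureRecord(21.8, 3.0, 75)) == pytest.approx(65.4)

    def test_exposure_per_frame(self):
        rec = ExposureRecord(21.8, 3.0, 75)
        assert rec.exposure_per_frame == pytest.approx(65.4 / 75)

    def test_exposure_rate_inconsistency_is_warned_not_fatal(self):
        rec = ExposureRecord(17.2, 3.72, 62)
        notes = rec.validate(rate_e_per_pix_s=11.75, pixel_size=0.83)
        assert len(notes) == 1 and "e/A^2/s" in notes[0]
        assert rec.validate(rate_e_per_pix_s=17.2 * 0.83 ** 2, pixel_size=0.83) == []

    def test_ledger_monotonicity_is_enforced(self):
        with pytest.raises(ValueError):
            SubsetLedger(100, 110, 90, 1000, 500, (0.5, 1.5), 2.8)
        with pytest.raises(ValueError):
            SubsetLedger(100, 90, 80, 1000, 1500, (0.5, 1.5), 2.8)
        ok = SubsetLedger(100, 90, 80, 1000, 500, (0.5, 1.5), 2.8)
        assert ok.micrographs_used == 80


class TestPointTables:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "pts.csv"
        path.write_text(
            "subset_id,n_particles,resolution_angstrom\n1,5000,3.4\n2,50000,2.9\n"
        )
        pts = read_points(path)
        assert [p.n_particles for p in pts] == [5000, 50000]
        assert pts[1].resolution == 2.9

    def test_missing_column_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subset_id,n\n1,5000\n")
        with pytest.raises(ParseError):
            read_points(path)

    def test_bfactor_log_with_comments(self, tmp_path):
        path = tmp_path / "plot.dat"
        path.write_text("# N resolution\n5000 3.40\n50000 2.90  # keeper\n\n")
        pts = read_bfactor_log(path)
        assert [(p.n_particles, p.resolution) for p in pts] == [(5000, 3.4), (50000, 2.9)]

    def test_bfactor_log_bad_line_located(self, tmp_path):
        path = tmp_path / "plot.dat"
        path.write_text("5000 3.40\nnot-a-number\n")
        with pytest.raises(ParseError, match=":2"):
            read_bfactor_log(path)


class TestStarIO:
    def test_write_read_round_trip_exact(self, tmp_path):
        df = pd.DataFrame(
            {
                "_rlnNrOfSignificantSamples": [12, 7, 31],
                "_rlnDefocusU": [9800.5, 12100.0, 15000.25],
                "_rlnMicrographName": ["mic1.mrc", "mic2.mrc", "mic1.mrc"],
            }
        )
        path = tmp_path / "particles.star"
        write_particle_table(df, path)
        back = read_particle_table(path)
        assert list(back.columns) == list(df.columns)
        assert back["_rlnNrOfSignificantSamples"].tolist() == [12, 7, 31]
        assert back["_rlnDefocusU"].tolist() == [9800.5, 12100.0, 15000.25]
        assert back["_rlnMicrographName"].tolist() == df["_rlnMicrographName"].tolist()

    def test_missing_optional_columns_degrade(self, tmp_path):
        df = pd.DataFrame({"_rlnDefocusU": [9800.5]})
        path = tmp_path / "particles.star"
        write_particle_table(df, path)
        stats = particle_alignment_stats(read_particle_table(path))
        assert stats.significant_samples.size == 0
        assert math.isnan(stats.angular_accuracy_deg)

    def test_malformed_loop_is_a_parse_error(self, tmp_path):
        path = tmp_path / "broken.star"
        path.write_text("data_particles\nloop_\n_rlnA\n_rlnB\n1\n")
        with pytest.raises(ParseError):
            read_particle_table(path)

    def test_large_synthetic_table_medians(self, tmp_path, rng):
        # generator ground truth: geometric counts with a known median
        counts = rng.geometric(p=0.05, size=100_000) + 1
        df = pd.DataFrame({"_rlnNrOfSignificantSamples": counts})
        path = tmp_path / "big.star"
        write_particle_table(df, path)
        stats = particle_alignment_stats(read_particle_table(path))
        assert np.median(stats.significant_samples) == np.median(counts)

    def test_shift_star_with_dose_rate(self, tmp_path):
        path = tmp_path / "mic.star"
        path.write_text(
            "data_general\n_rlnMicrographDoseRate 0.87\n\n"
            "data_global_shift\nloop_\n"
            "_rlnMicrographFrameNumber\n_rlnMicrographShiftX\n_rlnMicrographShiftY\n"
            + "".join(f"{i+1} {i*0.5} {i*0.25}\n" for i in range(8))
        )
        traj = read_shift_star(path)
        assert traj.exposure_per_frame == 0.87
        assert traj.n_frames == 8
        assert traj.positions[3, 0] == pytest.approx(1.5)

    def test_shift_log_plain_text(self, tmp_path):
        path = tmp_path / "mic.txt"
        path.write_text("0 0\n1 1\n2 2\n")
        traj = read_shift_log(path, exposure_per_frame=1.03, scale=2.0)
        assert traj.positions[2, 1] == 4.0


class TestVolumeIO:
    def test_mrc_round_trip(self, tmp_path, rng):
        vol = rng.standard_normal((16, 16, 16)).astype(np.float32)
        path = tmp_path / "map.mrc"
        write_volume(vol, 0.83, path)
        back, px = read_volume(path)
        assert px == pytest.approx(0.83)
        assert np.allclose(back, vol, atol=1e-6)

    def test_pixel_size_override(self, tmp_path, rng):
        vol = rng.standard_normal((16, 16, 16)).astype(np.float32)
        path = tmp_path / "map.mrc"
        write_volume(vol, 0.83, path)
        _, px = read_volume(path, pixel_size=1.2)
        assert px == 1.2


def _report_inputs(n_subsets=2):
    ledgers, fits, metrics, qc = {}, {}, {}, {}
    for i in range(n_subsets):
        sid = f"S{i+1}"
        ledgers[sid] = SubsetLedger(
            4000 + i, 3700, 3500, 2_400_000, 480_000, (0.5, 1.5), 2.8 + 0.1 * i
        )
        pts = exact_line_points(0.02 + 0.002 * i, -0.09, np.geomspace(5e3, 5e5, 9))
        fits[sid] = fit_rh(pts)
        metrics[sid] = derived_metrics(fits[sid])
        qc[sid] = {
            "median_significant_samples": 24.0,
            "n_particles": 480_000,
            "angular_accuracy_deg": 0.96,
            "translational_accuracy_ang": 0.38,
        }
    return ledgers, fits, metrics, qc


class TestReport:
    def test_two_subsets_twelve_rows(self):
        report = build_report(*_report_inputs()[:3], qc=_report_inputs()[3])
        rows = report.rows()
        assert tuple(rows) == REPORT_ROWS
        assert len(REPORT_ROWS) == 12
        assert all(len(cells) == 2 for cells in rows.values())

    def test_round_trip_through_json_is_byte_identical(self):
        ledgers, fits, metrics, qc = _report_inputs()
        report = build_report(ledgers, fits, metrics, qc=qc)
        again = Report.from_json(report.to_json())
        assert again.to_text() == report.to_text()
        assert json.loads(again.to_json()) == json.loads(report.to_json())

    def test_reconciliation_error_lists_orphans(self):
        ledgers, fits, metrics, _ = _report_inputs()
        del fits["S2"]
        with pytest.raises(ReconciliationError, match="S2"):
            build_report(ledgers, fits, metrics)

    def test_printed_derived_rows_match_published_style(self, table2):
        # a report built from reconstructed published fits prints the
        # published derived values at table precision
        fit = reconstruct_fit(*table2["-VPP"][:2], 100_000)
        report = build_report(
            {"-VPP": SubsetLedger(3617, 3466, 3466, 2_791_000, 793_000, (0.7, 1.7), 2.80)},
            {"-VPP": fit},
            {"-VPP": derived_metrics(fit)},
        )
        rows = report.rows()
        assert rows["B-factor [A^2]"][0] == "135.5"
        assert rows["Resolution from reference particles [A]"][0] == "3.14"
        assert rows["Micrographs after CTF fits (retention)"][0] == "3466 (96%)"
        assert rows["Final particle set [x10^3] (retention) (per micrograph)"][0] == (
            "793 (28%) (229)"
        )
        # particles to 3 A recomputed from the line: within rounding of 191
        printed = rows["Particles to reach reference resolution [x10^3]"][0]
        assert abs(float(printed) - table2["-VPP"][2]) / table2["-VPP"][2] < 0.03

    def test_fit_record_keys(self):
        _, fits, metrics, _ = _report_inputs(1)
        rec = fit_record(fits["S1"], metrics["S1"])
        assert {"slope", "offset", "se_slope", "se_offset", "cov", "bfactor",
                "se_bfactor", "res_100k", "se_res_100k", "particles_3A",
                "se_particles_3A", "n_points_used"} <= set(rec)
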