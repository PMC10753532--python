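"""I/O round trips, format validation, and standards compliance."""

import shutil
import subprocess

import numpy as np
import pytest

from msikit.formats_io import (
    AnnotationRecord,
    LibraryEntry,
    MzMLParseError,
    PositionLog,
    RawRun,
    Scan,
    UnsupportedSpectrumModeError,
    ValidationError,
    read_annotation_table,
    read_library_folder,
    read_library_xml,
    read_msp,
    read_mzml_run,
    read_position_log,
    write_annotation_table,
    write_library_xml,
    write_msp,
    write_mzml_run,
    write_position_log,
)


def _toy_run():
    scans = [
        Scan(0, 0.5, 1, np.array([150.0, 300.5, 600.25]), np.array([10.0, 20.0, 5.0])),
        Scan(1, 0.8, 2, np.array([160.1, 200.2]), np.array([3.0, 4.0]),
             precursor_mz=300.5, isolation_width=1.0),
        Scan(2, 1.1, 1, np.array([300.5]), np.array([18.0])),
    ]
    return RawRun(scans=scans, polarity="positive", mass_range=(150.0, 900.0))


def _toy_entries():
    return [
        LibraryEntry("C1", "alpha", "C6H12O6", 180.063388,
                     np.array([85.0, 127.0]), np.array([100.0, 40.0]),
                     adduct="[M+H]+", collision_energy=40.0, provenance="predicted"),
        LibraryEntry("C1", "alpha", "C6H12O6", 180.063388,
                     np.array([85.0, 127.0, 163.0]), np.array([60.0, 100.0, 10.0]),
                     adduct="[M+H]+", collision_energy=20.0),
        LibraryEntry("C2", "beta", "", 255.2, np.array([99.5]), np.array([100.0])),
    ]


class TestScanValidation:
    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValidationError):
            Scan(0, 0.0, 1, np.array([200.0, 150.0]), np.array([1.0, 1.0]))

    def test_ms2_requires_precursor(self):
        with pytest.raises(ValidationError):
            Scan(0, 0.0, 2, np.array([150.0]), np.array([1.0]))

    def test_tic_is_intensity_sum(self):
        scan = Scan(0, 0.0, 1, np.array([150.0, 151.0]), np.array([2.5, 7.5]))
        assert scan.tic == pytest.approx(10.0, rel=1e-9)

    def test_out_of_order_times_rejected(self):
        scans = [
            Scan(0, 2.0, 1, np.array([150.0]), np.array([1.0])),
            Scan(1, 1.0, 1, np.array([150.0]), np.array([1.0])),
        ]
        with pytest.raises(ValidationError):
            RawRun(scans=scans)

    def test_peak_outside_mass_range_rejected(self):
        with pytest.raises(ValidationError):
            RawRun(
                scans=[Scan(0, 0.0, 1, np.array([950.0]), np.array([1.0]))],
                mass_range=(150.0, 900.0),
            )


class TestMzML:
    def test_round_trip_preserves_scans(self, tmp_path):
        run = _toy_run()
        path = tmp_path / "toy.mzML"
        write_mzml_run(run, path)
        back = read_mzml_run(path)
        assert len(back.scans) == 3
        assert back.polarity == "positive"
        assert back.mass_range == pytest.approx((150.0, 900.0))
        for a, b in zip(run.scans, back.scans):
            assert b.ms_level == a.ms_level
            assert b.time_s == pytest.approx(a.time_s, rel=1e-6)
            np.testing.assert_allclose(b.mz, a.mz, rtol=1e-6)
            np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-6)
        ms2 = back.scans[1]
        assert ms2.precursor_mz == pytest.approx(300.5)
        assert ms2.isolation_width == pytest.approx(1.0)

    def test_empty_run_round_trips(self, tmp_path):
        path = tmp_path / "empty.mzML"
        write_mzml_run(RawRun(scans=[]), path)
        back = read_mzml_run(path)
        assert back.scans == []

    def test_out_of_order_file_rejected(self, tmp_path):
        path = tmp_path / "bad_order.mzML"
        write_mzml_run(_toy_run(), path)
        text = path.read_text()
        assert 'value="0.5"' in text and 'value="1.1"' in text
        path.write_text(text.replace('value="0.5"', 'value="9.9"', 1))
        with pytest.raises(ValidationError):
            read_mzml_run(path)

    def test_malformed_xml_names_byte_offset(self, tmp_path):
        path = tmp_path / "trunc.mzML"
        write_mzml_run(_toy_run(), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(MzMLParseError, match="byte offset"):
            read_mzml_run(path)

    def test_profile_mode_rejected_not_centroided(self, tmp_path):
        path = tmp_path / "profile.mzML"
        write_mzml_run(_toy_run(), path)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path.write_text(text)
        with pytest.raises(UnsupportedSpectrumModeError):
            read_mzml_run(path)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_writer_output_readable_by_mzr(self, tmp_path):
        """Independent standards check: Bioconductor mzR parses our mzML."""
        run = _toy_run()
        path = tmp_path / "toy.mzML"
        write_mzml_run(run, path)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(mzR))\n"
            f"h <- openMSfile('{path}')\n"
            "hdr <- header(h)\n"
            "cat(nrow(hdr), sum(hdr$msLevel==2), sum(hdr$totIonCurrent), '\\n')\n"
            "p <- peaks(h, 1)\n"
            "cat(nrow(p), sprintf('%.6f %.3f', p[1,1], p[1,2]), '\\n')\n"
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        lines = proc.stdout.strip().splitlines()
        n_scans, n_ms2, tic_sum = lines[0].split()
        assert (int(n_scans), int(n_ms2)) == (3, 1)
        assert float(tic_sum) == pytest.approx(sum(s.tic for s in run.scans), rel=1e-6)
        n_peaks, mz0, int0 = lines[1].split()
        assert int(n_peaks) == 3
        assert float(mz0) == pytest.approx(150.0)
        assert float(int0) == pytest.approx(10.0)


class TestPositionLog:
    def test_round_trip(self, tmp_path):
        log = PositionLog(
            lines=[(0, 0.0, 6.0, 0.0), (1, 7.2, 13.2, 100.0)],
            laser_intervals=[(0.0, 6.0), (7.2, 13.2)],
        )
        path = tmp_path / "pos.xml"
        write_position_log(log, path)
        back = read_position_log(path)
        assert back.lines == log.lines
        assert back.laser_intervals == log.laser_intervals

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError):
            PositionLog(lines=[(0, 0.0, 1.0, 0.0)], laser_intervals=[(5.0, 2.0)])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValidationError):
            PositionLog(
                lines=[(0, 0.0, 1.0, 0.0)],
                laser_intervals=[(0.0, 3.0), (2.0, 4.0)],
            )

    def test_empty_laser_element_means_never_active(self, tmp_path):
        from msikit.geometry import laser_active

        path = tmp_path / "pos.xml"
        path.write_text(
            '<position_log><lines><line index="0" t_start="0" t_end="5" y_um="0"/></lines>'
            "<laser/></position_log>"
        )
        log = read_position_log(path)
        assert log.laser_intervals == []
        assert not laser_active(2.5, log)

    def test_missing_lines_rejected(self, tmp_path):
        path = tmp_path / "pos.xml"
        path.write_text("<position_log><laser/></position_log>")
        with pytest.raises(ValidationError):
            read_position_log(path)


class TestLibraries:
    def test_msp_round_trip(self, tmp_path):
        entries = _toy_entries()
        path = tmp_path / "lib.msp"
        write_msp(entries, path)
        back = read_msp(path)
        assert len(back) == 3
        for a, b in zip(entries, back):
            assert (b.compound_id, b.adduct, b.collision_energy) == (
                a.compound_id, a.adduct, a.collision_energy
            )
            assert b.exact_mass == pytest.approx(a.exact_mass)
            np.testing.assert_allclose(b.mz, a.mz)
            np.testing.assert_allclose(b.intensity, a.intensity)
            assert b.provenance == a.provenance

    def test_msp_and_xml_dialects_equivalent(self, tmp_path):
        """The two library readers produce identical entries from equal content."""
        entries = _toy_entries()
        write_msp(entries, tmp_path / "lib.msp")
        write_library_xml(entries, tmp_path / "lib.xml")
        from_msp = read_msp(tmp_path / "lib.msp")
        from_xml = read_library_xml(tmp_path / "lib.xml")
        for a, b in zip(from_msp, from_xml):
            assert a.compound_id == b.compound_id
            assert a.exact_mass == pytest.approx(b.exact_mass)
            assert a.adduct == b.adduct
            assert a.collision_energy == b.collision_energy
            np.testing.assert_allclose(a.mz, b.mz)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_same_compound_two_collision_energies_both_kept(self, tmp_path):
        write_msp(_toy_entries(), tmp_path / "lib.msp")
        entries = read_library_folder(tmp_path)
        c1 = [e for e in entries if e.compound_id == "C1"]
        assert {e.collision_energy for e in c1} == {40.0, 20.0}

    def test_folder_concatenates_all_files(self, tmp_path):
        entries = _toy_entries()
        write_msp(entries[:2], tmp_path / "a.msp")
        write_library_xml(entries[2:], tmp_path / "b.xml")
        assert len(read_library_folder(tmp_path)) == 3

    def test_empty_folder_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_library_folder(tmp_path)

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ValidationError):
            LibraryEntry("X", "x", "", 100.0, np.empty(0), np.empty(0))

    def test_unparseable_msp_names_file_and_line(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text("NAME: x\nEXACTMASS: not_a_number\nNum Peaks: 1\n100 1\n\n")
        with pytest.raises(Exception, match=r"bad\.msp:\d+"):
            read_msp(path)


class TestAnnotationTable:
    def _records(self):
        return [
            AnnotationRecord(3, 301.1407, "[M+H]+", 300.1334, "C1", "C6H12O6",
                             1.2, 0.93, "predicted", pixel=(2, 5)),
            AnnotationRecord(9, 523.3, "[M+Na]+", 500.3108, "C2", "",
                             -3.4, 0.51, "experimental", pixel=None),
        ]

    def test_round_trip_lossless(self, tmp_path):
        records = self._records()
        path = tmp_path / "ann.tsv"
        write_annotation_table(records, path)
        back = read_annotation_table(path)
        assert len(back) == 2
        for a, b in zip(records, back):
            assert (b.scan_index, b.compound_id, b.adduct, b.pixel) == (
                a.scan_index, a.compound_id, a.adduct, a.pixel
            )
            assert b.precursor_mz == pytest.approx(a.precursor_mz)
            assert b.ppm_error == pytest.approx(a.ppm_error)
            assert b.cosine_score == pytest.approx(a.cosine_score)

    def test_zero_records_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_annotation_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("scan_index\t")

    def test_two_records_three_lines(self, tmp_path):
        path = tmp_path / "two.tsv"
        write_annotation_table(self._records(), path)
        assert len(path.read_text().strip().splitlines()) == 3
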