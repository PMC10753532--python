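"""Readers and writers for every external artifact the pipeline touches.

Covered formats:

* mzML (PSI standard, centroided spectra) — read and write.  The writer
  emits a minimal non-indexed document; the reader understands the cvParam
  vocabulary that MSConvert and vendor converters emit for centroided
  MS1/MS2 scan streams.
* The position/laser log — a small documented XML dialect (see
  :func:`read_position_log`) carrying raster-line timing and laser-active
  intervals.
* MS2 spectral libraries — NIST-style MSP text and a minimal XML dialect
  with one ``<compound>`` element per entry.
* Annotation tables — TSV, lossless round trip.

Conventions used throughout the package: times are seconds from run start,
m/z is in Thomson, pixel coordinates are 0-based ``(row, col)`` with row =
raster line index.
"""

from __future__ import annotations

import base64
import math
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Scan",
    "RawRun",
    "PositionLog",
    "LibraryEntry",
    "AnnotationRecord",
    "ValidationError",
    "MzMLParseError",
    "UnsupportedSpectrumModeError",
    "LibraryParseError",
    "read_mzml_run",
    "write_mzml_run",
    "read_position_log",
    "write_position_log",
    "read_msp",
    "write_msp",
    "read_library_xml",
    "write_library_xml",
    "read_library_folder",
    "write_annotation_table",
    "read_annotation_table",
]


class ValidationError(ValueError):
    """An in-memory object or parsed file violates a structural invariant."""


class MzMLParseError(ValueError):
    """The mzML document is not well formed; message names the byte offset."""


class UnsupportedSpectrumModeError(ValueError):
    """A spectrum is stored in profile mode; only centroided data is accepted."""


class LibraryParseError(ValueError):
    """A spectral-library file could not be parsed; message names file and line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Scan:
    """One mass spectrum (MS1 or MS2) from the acquisition stream.

    Parameters
    ----------
    index:
        Ordinal position in the run, 0-based.
    time_s:
        Acquisition start time in seconds from run start.
    ms_level:
        1 (survey/full scan) or 2 (fragmentation scan).
    mz, intensity:
        Centroid peak arrays; ``mz`` strictly increasing, intensities >= 0.
    precursor_mz, isolation_width:
        Present for MS2 scans: the isolation target and total isolation
        window width in Thomson.
    """

    index: int
    time_s: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError(
                f"scan {self.index}: mz and intensity must be 1-D arrays of equal length"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError(
                f"scan {self.index}: peak m/z values must be strictly increasing"
            )
        if np.any(self.intensity < 0):
            raise ValidationError(f"scan {self.index}: negative peak intensity")
        if self.ms_level not in (1, 2):
            raise ValidationError(f"scan {self.index}: ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValidationError(f"scan {self.index}: MS2 scan without precursor_mz")

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all centroid intensities."""
        return float(self.intensity.sum())

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class RawRun:
    """A complete time-ordered scan stream with run-level metadata."""

    scans: list[Scan]
    polarity: str = "positive"
    mass_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        times = [s.time_s for s in self.scans]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("scan times must be non-decreasing")
        lo, hi = self.mass_range
        eps = 1e-9
        for s in self.scans:
            if s.mz.size and (s.mz[0] < lo - eps or s.mz[-1] > hi + eps):
                raise ValidationError(
                    f"scan {s.index}: peak outside mass range [{lo}, {hi}]"
                )

    def ms1_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.scans) if s.ms_level == 1]

    def ms2_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.scans) if s.ms_level == 2]


@dataclass
class PositionLog:
    """Raster-line timing and laser-active intervals from the source log.

    ``lines`` holds ``(line_index, t_start_s, t_end_s, y_um)`` records;
    ``laser_intervals`` holds ``(t_on_s, t_off_s)`` half-open intervals
    during which the laser fires.
    """

    lines: list[tuple[int, float, float, float]]
    laser_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda r: r[1])
        self.laser_intervals = sorted(self.laser_intervals)
        for idx, t0, t1, _ in self.lines:
            if not t0 < t1:
                raise ValidationError(f"line {idx}: t_start must precede t_end")
        for t_on, t_off in self.laser_intervals:
            if not t_on < t_off:
                raise ValidationError(f"laser interval [{t_on}, {t_off}) is empty")
        for (_, a_off), (b_on, _) in zip(self.laser_intervals, self.laser_intervals[1:]):
            if b_on < a_off:
                raise ValidationError("laser intervals overlap")


_ADDUCT_LABELS = ("[M+H]+", "[M+Na]+", "[M-H]-", "[M+Cl]-")


def _canonical_adduct(label: Optional[str]) -> Optional[str]:
    """Normalize unicode minus and whitespace in adduct labels."""
    if label is None:
        return None
    lab = label.strip().replace("−", "-")
    if not lab:
        return None
    if lab not in _ADDUCT_LABELS:
        raise ValidationError(f"unknown adduct label {label!r}")
    return lab


@dataclass
class LibraryEntry:
    """A library compound: identity, neutral monoisotopic mass, MS2 spectrum.

    ``adduct`` and ``collision_energy`` may be None (unspecified); the same
    compound may legitimately appear several times at different collision
    energies.  ``provenance`` distinguishes predicted from experimental
    reference spectra.
    """

    compound_id: str
    name: str
    formula: str
    exact_mass: float
    mz: np.ndarray
    intensity: np.ndarray
    adduct: Optional[str] = None
    collision_energy: Optional[float] = None
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        self.adduct = _canonical_adduct(self.adduct)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.exact_mass <= 0:
            raise ValidationError(f"{self.compound_id}: exact_mass must be positive")
        if self.mz.size == 0:
            raise ValidationError(f"{self.compound_id}: empty peak list")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0) or not np.any(self.intensity > 0):
            raise ValidationError(
                f"{self.compound_id}: intensities must be >= 0 with at least one > 0"
            )
        if self.provenance not in ("predicted", "experimental"):
            raise ValidationError(f"{self.compound_id}: bad provenance {self.provenance!r}")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class AnnotationRecord:
    """A QC-valid MS2 spectrum bound to its best library match."""

    scan_index: int
    precursor_mz: float
    adduct: str
    neutral_mass_hypothesis: float
    compound_id: str
    formula: str
    ppm_error: float
    cosine_score: float
    provenance: str
    pixel: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cosine_score <= 1.0 + 1e-12:
            raise ValidationError("cosine_score outside [0, 1]")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions understood by the reader.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEGATIVE = "MS:1000129"
_ACC_POSITIVE = "MS:1000130"
_ACC_TIC = "MS:1000285"
_ACC_SCAN_START = "MS:1000016"
_ACC_WINDOW_UPPER = "MS:1000500"
_ACC_WINDOW_LOWER = "MS:1000501"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"

_UNIT_MINUTE = "UO:0000031"
_UNIT_MILLISECOND = "UO:0000028"


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _cv_params(element) -> dict[str, str]:
    """Accession -> value for cvParam children directly under *element*."""
    out: dict[str, str] = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _find_child(element, localname: str):
    for child in element:
        if _local(child.tag) == localname:
            return child
    return None


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = _find_child(bda, "binary")
    text = binary.text or "" if binary is not None else ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(element, ordinal: int) -> tuple[Scan, Optional[str], tuple[float, float]]:
    params = _cv_params(element)
    if _ACC_PROFILE in params:
        raise UnsupportedSpectrumModeError(
            f"spectrum {element.get('id', ordinal)} is profile mode; "
            "centroid the data before analysis (profile spectra are not "
            "silently centroided)"
        )
    ms_level = int(params.get(_ACC_MS_LEVEL, "1"))
    polarity = None
    if _ACC_POSITIVE in params:
        polarity = "positive"
    elif _ACC_NEGATIVE in params:
        polarity = "negative"

    time_s = 0.0
    window = (math.inf, -math.inf)
    scan_list = _find_child(element, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            for child in scan:
                if _local(child.tag) != "cvParam":
                    continue
                if child.get("accession") == _ACC_SCAN_START:
                    value = float(child.get("value", "0"))
                    unit = child.get("unitAccession", "")
                    if unit == _UNIT_MINUTE:
                        value *= 60.0
                    elif unit == _UNIT_MILLISECOND:
                        value /= 1000.0
                    time_s = value
            swl = _find_child(scan, "scanWindowList")
            if swl is not None:
                sw = _find_child(swl, "scanWindow")
                if sw is not None:
                    wp = _cv_params(sw)
                    if _ACC_WINDOW_LOWER in wp and _ACC_WINDOW_UPPER in wp:
                        window = (float(wp[_ACC_WINDOW_LOWER]), float(wp[_ACC_WINDOW_UPPER]))

    precursor_mz = None
    isolation_width = None
    plist = _find_child(element, "precursorList")
    if plist is not None:
        precursor = _find_child(plist, "precursor")
        if precursor is not None:
            iso = _find_child(precursor, "isolationWindow")
            if iso is not None:
                ip = _cv_params(iso)
                if _ACC_ISO_TARGET in ip:
                    precursor_mz = float(ip[_ACC_ISO_TARGET])
                if _ACC_ISO_LOWER in ip and _ACC_ISO_UPPER in ip:
                    isolation_width = float(ip[_ACC_ISO_LOWER]) + float(ip[_ACC_ISO_UPPER])
            sil = _find_child(precursor, "selectedIonList")
            if sil is not None:
                si = _find_child(sil, "selectedIon")
                if si is not None:
                    sp = _cv_params(si)
                    if _ACC_SELECTED_MZ in sp:
                        precursor_mz = float(sp[_ACC_SELECTED_MZ])

    mz = np.empty(0)
    intensity = np.empty(0)
    bdal = _find_child(element, "binaryDataArrayList")
    if bdal is not None:
        for bda in bdal:
            if _local(bda.tag) != "binaryDataArray":
                continue
            params_b = _cv_params(bda)
            if _ACC_MZ_ARRAY in params_b:
                mz = _decode_binary_array(bda)
            elif _ACC_INT_ARRAY in params_b:
                intensity = _decode_binary_array(bda)

    scan_obj = Scan(
        index=ordinal,
        time_s=time_s,
        ms_level=ms_level,
        mz=mz,
        intensity=intensity,
        precursor_mz=precursor_mz,
        isolation_width=isolation_width,
    )
    return scan_obj, polarity, window


def read_mzml_run(path) -> RawRun:
    """Read a centroided mzML scan stream into a :class:`RawRun`.

    Scan times are converted to seconds; MS2 scans carry the selected-ion
    m/z (falling back to the isolation target) and the isolation-window
    width.  Run polarity is taken from scan metadata.  Profile-mode spectra
    raise :class:`UnsupportedSpectrumModeError`; malformed XML raises
    :class:`MzMLParseError` naming the byte offset.
    """
    path = Path(path)
    scans: list[Scan] = []
    polarity: Optional[str] = None
    lo, hi = math.inf, -math.inf
    saw_window = False
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, element in context:
            if _local(element.tag) != "spectrum":
                continue
            scan, pol, window = _parse_spectrum(element, len(scans))
            scans.append(scan)
            if pol is not None:
                polarity = polarity or pol
            if math.isfinite(window[0]):
                saw_window = True
                lo = min(lo, window[0])
                hi = max(hi, window[1])
            element.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        # lxml reports (line, column); recover the byte offset of that line.
        line_no = exc.position[0] if exc.position else 0
        offset = 0
        if line_no > 1:
            with open(path, "rb") as handle:
                for _ in range(line_no - 1):
                    offset += len(handle.readline())
        offset += (exc.position[1] if exc.position else 0)
        raise MzMLParseError(
            f"{path.name}: malformed mzML near byte offset {offset}: {exc.msg}"
        ) from exc

    if not saw_window:
        for s in scans:
            if s.mz.size:
                lo = min(lo, float(s.mz[0]))
                hi = max(hi, float(s.mz[-1]))
    if not math.isfinite(lo):
        lo, hi = 0.0, math.inf
    return RawRun(scans=scans, polarity=polarity or "positive", mass_range=(lo, hi))


def _encode_binary(values: np.ndarray) -> str:
    return base64.b64encode(zlib.compress(np.asarray(values, dtype="<f8").tobytes())).decode()


def _binary_array_xml(parent, values: np.ndarray, accession: str, name: str) -> None:
    encoded = _encode_binary(values)
    bda = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(encoded)))
    for acc, nm in ((_ACC_F64, "64-bit float"), (_ACC_ZLIB, "zlib compression"), (accession, name)):
        etree.SubElement(bda, "cvParam", cvRef="MS", accession=acc, name=nm, value="")
    etree.SubElement(bda, "binary").text = encoded


def write_mzml_run(run: RawRun, path) -> None:
    """Write *run* as a minimal, standards-compliant non-indexed mzML file.

    Peak arrays are stored as zlib-compressed 64-bit floats, so a write/read
    cycle reproduces every scan bit-for-bit up to float64 precision.
    """
    nsmap = {None: _MZML_NS}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="UNIT-ONTOLOGY",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    etree.SubElement(fcontent, "cvParam", cvRef="MS", accession="MS:1000579",
                     name="MS1 spectrum", value="")
    etree.SubElement(fcontent, "cvParam", cvRef="MS", accession=_ACC_CENTROID,
                     name="centroid spectrum", value="")
    soft_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(soft_list, "software", id="msikit", version="0.1.0")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="dp1")
    etree.SubElement(dp, "processingMethod", order="0", softwareRef="msikit")

    run_el = etree.SubElement(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    spec_list = etree.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)), defaultDataProcessingRef="dp1"
    )
    pol_acc, pol_name = (
        (_ACC_POSITIVE, "positive scan")
        if run.polarity == "positive"
        else (_ACC_NEGATIVE, "negative scan")
    )
    lo, hi = run.mass_range
    for i, scan in enumerate(run.scans):
        spectrum = etree.SubElement(
            spec_list, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(scan.mz.size),
        )
        level_name = "MS1 spectrum" if scan.ms_level == 1 else "MSn spectrum"
        level_acc = "MS:1000579" if scan.ms_level == 1 else "MS:1000580"
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession=_ACC_MS_LEVEL,
                         name="ms level", value=str(scan.ms_level))
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession=level_acc,
                         name=level_name, value="")
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession=_ACC_CENTROID,
                         name="centroid spectrum", value="")
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession=pol_acc,
                         name=pol_name, value="")
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession=_ACC_TIC,
                         name="total ion current", value=repr(float(scan.tic)))

        scan_list = etree.SubElement(spectrum, "scanList", count="1")
        etree.SubElement(scan_list, "cvParam", cvRef="MS", accession="MS:1000795",
                         name="no combination", value="")
        scan_el = etree.SubElement(scan_list, "scan")
        etree.SubElement(
            scan_el, "cvParam", cvRef="MS", accession=_ACC_SCAN_START,
            name="scan start time", value=repr(float(scan.time_s)),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second",
        )
        if math.isfinite(hi):
            swl = etree.SubElement(scan_el, "scanWindowList", count="1")
            sw = etree.SubElement(swl, "scanWindow")
            etree.SubElement(sw, "cvParam", cvRef="MS", accession=_ACC_WINDOW_LOWER,
                             name="scan window lower limit", value=repr(float(lo)))
            etree.SubElement(sw, "cvParam", cvRef="MS", accession=_ACC_WINDOW_UPPER,
                             name="scan window upper limit", value=repr(float(hi)))

        if scan.ms_level == 2:
            plist = etree.SubElement(spectrum, "precursorList", count="1")
            precursor = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(precursor, "isolationWindow")
            etree.SubElement(iso, "cvParam", cvRef="MS", accession=_ACC_ISO_TARGET,
                             name="isolation window target m/z", value=repr(float(scan.precursor_mz)))
            half = (scan.isolation_width or 1.0) / 2.0
            etree.SubElement(iso, "cvParam", cvRef="MS", accession=_ACC_ISO_LOWER,
                             name="isolation window lower offset", value=repr(half))
            etree.SubElement(iso, "cvParam", cvRef="MS", accession=_ACC_ISO_UPPER,
                             name="isolation window upper offset", value=repr(half))
            sil = etree.SubElement(precursor, "selectedIonList", count="1")
            si = etree.SubElement(sil, "selectedIon")
            etree.SubElement(si, "cvParam", cvRef="MS", accession=_ACC_SELECTED_MZ,
                             name="selected ion m/z", value=repr(float(scan.precursor_mz)))
            etree.SubElement(si, "cvParam", cvRef="MS", accession="MS:1000041",
                             name="charge state", value="1")
            activation = etree.SubElement(precursor, "activation")
            etree.SubElement(activation, "cvParam", cvRef="MS", accession="MS:1000133",
                             name="collision-induced dissociation", value="")

        bdal = etree.SubElement(spectrum, "binaryDataArrayList", count="2")
        _binary_array_xml(bdal, scan.mz, _ACC_MZ_ARRAY, "m/z array")
        _binary_array_xml(bdal, scan.intensity, _ACC_INT_ARRAY, "intensity array")

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Position / laser log
# ---------------------------------------------------------------------------


def read_position_log(path) -> PositionLog:
    """Read the documented position-log XML dialect.

    Schema::

        <position_log>
          <lines>
            <line index="0" t_start="0.0" t_end="14.4" y_um="0.0"/>
            ...
          </lines>
          <laser>
            <interval t_on="0.0" t_off="14.4"/>
            ...
          </laser>
        </position_log>

    All times in seconds from run start.  Laser intervals are half-open
    ``[t_on, t_off)`` and must not overlap.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"{path}: malformed position log: {exc.msg}") from exc
    root = tree.getroot()
    lines_el = _find_child(root, "lines")
    if lines_el is None:
        raise ValidationError(f"{path}: missing <lines> element")
    lines = []
    for line in lines_el:
        if _local(line.tag) != "line":
            continue
        lines.append(
            (
                int(line.get("index")),
                float(line.get("t_start")),
                float(line.get("t_end")),
                float(line.get("y_um", "0")),
            )
        )
    if not lines:
        raise ValidationError(f"{path}: no <line> records")
    laser_el = _find_child(root, "laser")
    intervals = []
    if laser_el is not None:
        for interval in laser_el:
            if _local(interval.tag) != "interval":
                continue
            intervals.append((float(interval.get("t_on")), float(interval.get("t_off"))))
    return PositionLog(lines=lines, laser_intervals=intervals)


def write_position_log(log: PositionLog, path) -> None:
    root = etree.Element("position_log")
    lines_el = etree.SubElement(root, "lines")
    for idx, t0, t1, y in log.lines:
        etree.SubElement(
            lines_el, "line", index=str(idx), t_start=repr(float(t0)), t_end=repr(float(t1)), y_um=repr(float(y))
        )
    laser_el = etree.SubElement(root, "laser")
    for t_on, t_off in log.laser_intervals:
        etree.SubElement(laser_el, "interval", t_on=repr(float(t_on)), t_off=repr(float(t_off)))
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Spectral libraries: MSP and the XML dialect
# ---------------------------------------------------------------------------

_MSP_KEYS = {
    "NAME": "name",
    "COMPOUND_ID": "compound_id",
    "FORMULA": "formula",
    "EXACTMASS": "exact_mass",
    "PRECURSORMZ": "precursor_mz",
    "ADDUCT": "adduct",
    "PRECURSORTYPE": "adduct",
    "COLLISIONENERGY": "collision_energy",
    "PROVENANCE": "provenance",
}

_PEAK_LINE = re.compile(r"^\s*([0-9.eE+-]+)[\s;,]+([0-9.eE+-]+)")


def read_msp(path) -> list[LibraryEntry]:
    """Parse a NIST-style MSP text library.

    Recognized header keys: NAME, COMPOUND_ID, FORMULA, EXACTMASS,
    PRECURSORMZ, ADDUCT (or PRECURSORTYPE), COLLISIONENERGY, PROVENANCE,
    ``Num Peaks``.  Peak lines are ``mz intensity`` pairs.  COMPOUND_ID
    falls back to NAME when absent.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expected_peaks: Optional[int] = None
    start_line = 1

    def flush(line_no: int) -> None:
        nonlocal fields, peaks, expected_peaks
        if not fields and not peaks:
            return
        if expected_peaks is not None and expected_peaks != len(peaks):
            raise LibraryParseError(
                f"{path.name}:{start_line}: Num Peaks={expected_peaks} "
                f"but {len(peaks)} peak lines found"
            )
        try:
            entry = LibraryEntry(
                compound_id=fields.get("compound_id") or fields.get("name", ""),
                name=fields.get("name", ""),
                formula=fields.get("formula", ""),
                exact_mass=float(fields.get("exact_mass", "nan")),
                mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]),
                adduct=fields.get("adduct"),
                collision_energy=(
                    float(fields["collision_energy"]) if "collision_energy" in fields else None
                ),
                provenance=fields.get("provenance", "experimental"),
            )
        except (ValidationError, ValueError) as exc:
            raise LibraryParseError(f"{path.name}:{start_line}: {exc}") from exc
        entries.append(entry)
        fields, peaks, expected_peaks = {}, [], None

    line_no = 0
    with open(path, encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                flush(line_no)
                start_line = line_no + 1
                continue
            if ":" in line:
                key, _, value = line.partition(":")
                key_norm = key.strip().upper()
                if key_norm == "NUM PEAKS":
                    expected_peaks = int(value.strip())
                    continue
                if key_norm in _MSP_KEYS:
                    if key_norm == "NAME" and fields:
                        # A NAME line starts a new record even without a blank separator.
                        flush(line_no)
                        start_line = line_no
                    fields[_MSP_KEYS[key_norm]] = value.strip()
                    continue
                if not _PEAK_LINE.match(line):
                    continue  # unknown header key: tolerated, skipped
            match = _PEAK_LINE.match(line)
            if match:
                peaks.append((float(match.group(1)), float(match.group(2))))
            else:
                raise LibraryParseError(f"{path.name}:{line_no}: unparseable line {line!r}")
    flush(line_no)
    return entries


def write_msp(entries: Sequence[LibraryEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for entry in entries:
            handle.write(f"NAME: {entry.name}\n")
            handle.write(f"COMPOUND_ID: {entry.compound_id}\n")
            handle.write(f"FORMULA: {entry.formula}\n")
            handle.write(f"EXACTMASS: {float(entry.exact_mass)!r}\n")
            if entry.adduct is not None:
                handle.write(f"ADDUCT: {entry.adduct}\n")
            if entry.collision_energy is not None:
                handle.write(f"COLLISIONENERGY: {float(entry.collision_energy)!r}\n")
            handle.write(f"PROVENANCE: {entry.provenance}\n")
            handle.write(f"Num Peaks: {entry.mz.size}\n")
            for mz, inten in zip(entry.mz, entry.intensity):
                handle.write(f"{float(mz)!r} {float(inten)!r}\n")
            handle.write("\n")


def read_library_xml(path) -> list[LibraryEntry]:
    """Parse the minimal XML library dialect (one ``<compound>`` per entry).

    Schema::

        <library>
          <compound id="C1" name="..." formula="C6H12O6" exact-mass="180.0634"
                    adduct="[M+H]+" collision-energy="40" provenance="predicted">
            <peak mz="85.0295" intensity="100.0"/>
            ...
          </compound>
        </library>
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line = exc.position[0] if exc.position else 0
        raise LibraryParseError(f"{path.name}:{line}: malformed XML: {exc.msg}") from exc
    entries = []
    for compound in tree.getroot():
        if _local(compound.tag) != "compound":
            continue
        peaks = [
            (float(p.get("mz")), float(p.get("intensity")))
            for p in compound
            if _local(p.tag) == "peak"
        ]
        ce = compound.get("collision-energy")
        try:
            entries.append(
                LibraryEntry(
                    compound_id=compound.get("id", ""),
                    name=compound.get("name", ""),
                    formula=compound.get("formula", ""),
                    exact_mass=float(compound.get("exact-mass", "nan")),
                    mz=np.array([p[0] for p in peaks]) if peaks else np.empty(0),
                    intensity=np.array([p[1] for p in peaks]) if peaks else np.empty(0),
                    adduct=compound.get("adduct"),
                    collision_energy=float(ce) if ce is not None else None,
                    provenance=compound.get("provenance", "experimental"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise LibraryParseError(
                f"{path.name}:{compound.sourceline}: {exc}"
            ) from exc
    return entries


def write_library_xml(entries: Sequence[LibraryEntry], path) -> None:
    root = etree.Element("library")
    for entry in entries:
        attrs = {
            "id": entry.compound_id,
            "name": entry.name,
            "formula": entry.formula,
            "exact-mass": repr(float(entry.exact_mass)),
            "provenance": entry.provenance,
        }
        if entry.adduct is not None:
            attrs["adduct"] = entry.adduct
        if entry.collision_energy is not None:
            attrs["collision-energy"] = repr(float(entry.collision_energy))
        compound = etree.SubElement(root, "compound", **attrs)
        for mz, inten in zip(entry.mz, entry.intensity):
            etree.SubElement(compound, "peak", mz=repr(float(mz)), intensity=repr(float(inten)))
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def read_library_folder(path) -> list[LibraryEntry]:
    """Concatenate entries from every ``.msp`` / ``.xml`` library in a folder.

    Duplicate (compound_id, adduct, collision_energy) tuples are retained:
    the same compound may appear at several collision energies.
    """
    folder = Path(path)
    if not folder.is_dir():
        raise FileNotFoundError(f"library folder {folder} does not exist")
    files = sorted(p for p in folder.iterdir() if p.suffix.lower() in (".msp", ".xml"))
    if not files:
        raise ValidationError(f"no .msp or .xml library files in {folder}")
    entries: list[LibraryEntry] = []
    for file in files:
        if file.suffix.lower() == ".msp":
            entries.extend(read_msp(file))
        else:
            entries.extend(read_library_xml(file))
    return entries


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "scan_index",
    "precursor_mz",
    "adduct",
    "neutral_mass_hypothesis",
    "compound_id",
    "formula",
    "ppm_error",
    "cosine_score",
    "provenance",
    "pixel_row",
    "pixel_col",
]


def write_annotation_table(records: Sequence[AnnotationRecord], path) -> None:
    """Write annotation records as TSV with a stable column order."""
    rows = []
    for record in records:
        row = {
            "scan_index": record.scan_index,
            "precursor_mz": record.precursor_mz,
            "adduct": record.adduct,
            "neutral_mass_hypothesis": record.neutral_mass_hypothesis,
            "compound_id": record.compound_id,
            "formula": record.formula,
            "ppm_error": record.ppm_error,
            "cosine_score": record.cosine_score,
            "provenance": record.provenance,
            "pixel_row": record.pixel[0] if record.pixel is not None else pd.NA,
            "pixel_col": record.pixel[1] if record.pixel is not None else pd.NA,
        }
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation_table(path) -> list[AnnotationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"adduct": str, "compound_id": str})
    records = []
    for _, row in frame.iterrows():
        pixel = None
        if pd.notna(row["pixel_row"]) and pd.notna(row["pixel_col"]):
            pixel = (int(row["pixel_row"]), int(row["pixel_col"]))
        records.append(
            AnnotationRecord(
                scan_index=int(row["scan_index"]),
                precursor_mz=float(row["precursor_mz"]),
                adduct=str(row["adduct"]),
                neutral_mass_hypothesis=float(row["neutral_mass_hypothesis"]),
                compound_id=str(row["compound_id"]),
                formula="" if pd.isna(row["formula"]) else str(row["formula"]),
                ppm_error=float(row["ppm_error"]),
                cosine_score=float(row["cosine_score"]),
                provenance=str(row["provenance"]),
                pixel=pixel,
            )
        )
    return records
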