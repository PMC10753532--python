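"""Two-criterion validity filter for DDA MS2 spectra.

An MS2 event in a raster MSI run is only trustworthy when (i) the laser was
actually firing when the spectrum was acquired, and (ii) the selected
precursor persists in the survey spectra recorded after the one in which it
was chosen — two consecutive MS1 scans for parallel acquisition, one for
sequential — within the run's ppm tolerance.  Spectra failing either
criterion are artifacts (laser-off noise, transient ions) and are dropped
before annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .formats_io import PositionLog, RawRun, Scan, ValidationError
from .geometry import laser_active

__all__ = [
    "QCVerdict",
    "QCSummary",
    "consistency_window",
    "precursor_consistent",
    "assess_run",
    "qc_report_frame",
]


@dataclass
class QCVerdict:
    """Per-MS2 validity verdict: laser criterion, consistency criterion."""

    scan_index: int
    laser_ok: bool
    consistency_ok: bool
    checked_scan_indices: tuple[int, ...] = ()

    @property
    def valid(self) -> bool:
        return self.laser_ok and self.consistency_ok


class QCSummary(NamedTuple):
    """The three nested counts: all MS2, laser-active MS2, fully valid MS2."""

    total_ms2: int
    laser_active_ms2: int
    valid_ms2: int


def consistency_window(mode: str) -> int:
    """Number of following MS1 scans the precursor must persist in.

    Two consecutive scan events for parallel acquisition, one for
    sequential.
    """
    if mode == "parallel":
        return 2
    if mode == "sequential":
        return 1
    raise ValidationError(f"unknown acquisition mode {mode!r}")


def _has_peak_within_ppm(
    scan: Scan, target_mz: float, tol_ppm: float, min_intensity: float
) -> bool:
    tol_da = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol_da, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol_da, side="right")
    if hi <= lo:
        return False
    return bool(np.any(scan.intensity[lo:hi] >= min_intensity))


def precursor_consistent(
    ms2: Scan,
    run: RawRun,
    window: int,
    tol_ppm: float,
    min_intensity: float = 0.0,
) -> tuple[bool, tuple[int, ...]]:
    """Check that the precursor persists in the next *window* MS1 scans.

    Only MS1 full scans strictly after the MS2 scan count toward the
    window (interleaved MS2 scans are skipped — a precursor can only be
    re-observed in a survey spectrum).  If fewer than *window* MS1 scans
    remain in the run, the check fails rather than being skipped.

    Returns ``(consistent, checked_ms1_indices)``.
    """
    if ms2.ms_level != 2:
        raise ValidationError("precursor_consistent requires an MS2 scan")
    following = [
        i
        for i in range(ms2.index + 1, len(run.scans))
        if run.scans[i].ms_level == 1
    ][:window]
    if len(following) < window:
        return False, tuple(following)
    ok = all(
        _has_peak_within_ppm(run.scans[i], ms2.precursor_mz, tol_ppm, min_intensity)
        for i in following
    )
    return ok, tuple(following)


def assess_run(
    run: RawRun,
    log: PositionLog,
    mode: str,
    tol_ppm: float,
    min_intensity: float = 0.0,
) -> tuple[list[QCVerdict], QCSummary]:
    """Apply both validity criteria to every MS2 scan in the run.

    The laser criterion is evaluated at the MS2 scan's own start time.
    Returns one verdict per MS2 scan plus the three nested counts
    (total, laser-active, valid).
    """
    window = consistency_window(mode)
    verdicts = []
    for i in run.ms2_indices():
        scan = run.scans[i]
        laser_ok = laser_active(scan.time_s, log)
        consistent, checked = precursor_consistent(
            scan, run, window, tol_ppm, min_intensity
        )
        verdicts.append(
            QCVerdict(
                scan_index=i,
                laser_ok=laser_ok,
                consistency_ok=consistent,
                checked_scan_indices=checked,
            )
        )
    summary = QCSummary(
        total_ms2=len(verdicts),
        laser_active_ms2=sum(v.laser_ok for v in verdicts),
        valid_ms2=sum(v.valid for v in verdicts),
    )
    return verdicts, summary


def qc_report_frame(run: RawRun, verdicts: list[QCVerdict]) -> pd.DataFrame:
    """Tabular QC report: one row per MS2 scan."""
    rows = []
    for v in verdicts:
        scan = run.scans[v.scan_index]
        rows.append(
            {
                "scan_index": v.scan_index,
                "time_s": scan.time_s,
                "precursor_mz": scan.precursor_mz,
                "laser_ok": v.laser_ok,
                "consistency_ok": v.consistency_ok,
                "valid": v.valid,
                "checked_scan_indices": ",".join(map(str, v.checked_scan_indices)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scan_index", "time_s", "precursor_mz",
            "laser_ok", "consistency_ok", "valid", "checked_scan_indices",
        ],
    )
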