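"""Adduct-resolved library annotation of QC-valid MS2 spectra.

The cascade, per MS2 event:

1. From the reported precursor m/z, generate one neutral-mass hypothesis
   per common MALDI adduct of the run polarity ([M+H]+ and [M+Na]+ in
   positive mode, [M-H]- and [M+Cl]- in negative mode; singly charged).
2. Match every hypothesis against the exact neutral masses of every
   library compound within a user ppm tolerance.  This deliberately
   over-generates: isomers, multiple adducts, multiple collision energies
   of the same compound all survive to the scoring stage.
3. Score each surviving candidate by cosine similarity between the
   empirical MS2 spectrum and the library spectrum.
4. Retain only the highest-scoring candidate (ties broken by smaller
   absolute ppm error, then lexicographic compound id).

Mass-shift constants include the electron mass, so e.g. the [M+Cl]- shift
is m(Cl) + m(e) = 34.96940126 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    AnnotationRecord,
    LibraryEntry,
    PositionLog,
    RawRun,
    Scan,
    ValidationError,
)
from .geometry import RasterGeometry, scan_to_pixel
from .qc import QCVerdict

__all__ = [
    "AdductDef",
    "ADDUCTS",
    "adducts_for_polarity",
    "FragmentTolerance",
    "CandidateMatch",
    "neutral_hypotheses",
    "ppm_error",
    "match_library",
    "cosine_score",
    "annotate",
    "annotate_run",
    "compound_summary",
]

#: Proton mass (Da): m(H) - m(e).
PROTON_MASS = 1.00727646688
#: Sodium cation mass (Da): m(Na) - m(e).
SODIUM_CATION_MASS = 22.98922070
#: Chloride anion mass (Da): m(Cl) + m(e).
CHLORIDE_ANION_MASS = 34.96940126


@dataclass(frozen=True)
class AdductDef:
    """A singly charged adduct: observed m/z = neutral mass + mass_shift_da."""

    label: str
    polarity: str
    mass_shift_da: float


ADDUCTS: tuple[AdductDef, ...] = (
    AdductDef("[M+H]+", "positive", +PROTON_MASS),
    AdductDef("[M+Na]+", "positive", +SODIUM_CATION_MASS),
    AdductDef("[M-H]-", "negative", -PROTON_MASS),
    AdductDef("[M+Cl]-", "negative", +CHLORIDE_ANION_MASS),
)

_ADDUCT_BY_LABEL = {a.label: a for a in ADDUCTS}


def adducts_for_polarity(polarity: str) -> tuple[AdductDef, ...]:
    out = tuple(a for a in ADDUCTS if a.polarity == polarity)
    if not out:
        raise ValidationError(f"unknown polarity {polarity!r}")
    return out


@dataclass(frozen=True)
class FragmentTolerance:
    """Matching tolerance for fragment-peak pairing in cosine scoring.

    The effective window at fragment m/z is
    ``max(mz * ppm * 1e-6, floor_da)``: ppm-scaled for high-resolution MS2
    with an absolute floor for low-resolution ion-trap spectra.
    """

    ppm: float = 5.0
    floor_da: float = 0.01

    def window_da(self, mz: float) -> float:
        return max(mz * self.ppm * 1e-6, self.floor_da)


@dataclass
class CandidateMatch:
    """A (library entry, adduct) pair whose exact mass fits a hypothesis."""

    entry: LibraryEntry
    adduct: AdductDef
    neutral_mass_hypothesis: float
    ppm_err: float
    cosine: Optional[float] = None


def neutral_hypotheses(
    precursor_mz: float, polarity: str
) -> list[tuple[AdductDef, float]]:
    """All neutral-mass hypotheses for a precursor under the polarity's adducts.

    One hypothesis per adduct: M = precursor_mz - mass_shift; hypotheses
    with non-positive neutral mass are dropped.
    """
    if precursor_mz <= 0:
        raise ValidationError("precursor_mz must be positive")
    out = []
    for adduct in adducts_for_polarity(polarity):
        neutral = precursor_mz - adduct.mass_shift_da
        if neutral > 0:
            out.append((adduct, neutral))
    return out


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if calculated <= 0:
        raise ValidationError("calculated mass must be positive")
    return (observed - calculated) / calculated * 1e6


def match_library(
    hypotheses: Sequence[tuple[AdductDef, float]],
    library: Sequence[LibraryEntry],
    tol_ppm: float,
) -> list[CandidateMatch]:
    """Every (hypothesis, entry) pair within the ppm tolerance.

    Entries declaring an adduct that conflicts with the hypothesis adduct
    are excluded; entries with unspecified adduct are eligible under every
    hypothesis.  No other pre-filtering: candidate explosion is resolved at
    the scoring stage.
    """
    matches = []
    for adduct, neutral in hypotheses:
        for entry in library:
            if entry.adduct is not None and entry.adduct != adduct.label:
                continue
            err = ppm_error(neutral, entry.exact_mass)
            if abs(err) <= tol_ppm:
                matches.append(
                    CandidateMatch(
                        entry=entry,
                        adduct=adduct,
                        neutral_mass_hypothesis=neutral,
                        ppm_err=err,
                    )
                )
    return matches


def _pair_peaks(
    mz_a: np.ndarray, mz_b: np.ndarray, tol: FragmentTolerance
) -> list[tuple[int, int]]:
    """Greedy nearest-m/z pairing, each peak used at most once.

    Candidate pairs within tolerance are accepted in order of increasing
    m/z distance, which makes the result deterministic and independent of
    input peak order.
    """
    candidates = []
    j0 = 0
    for i, ma in enumerate(mz_a):
        window = tol.window_da(ma)
        while j0 < mz_b.size and mz_b[j0] < ma - window:
            j0 += 1
        j = j0
        while j < mz_b.size and mz_b[j] <= ma + window:
            candidates.append((abs(ma - mz_b[j]), i, j))
            j += 1
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def cosine_score(
    empirical: tuple[np.ndarray, np.ndarray],
    library: tuple[np.ndarray, np.ndarray],
    frag_tol: FragmentTolerance = FragmentTolerance(),
    sqrt_weight: bool = False,
) -> float:
    """Cosine similarity between two centroid spectra after peak pairing.

    Peaks are paired greedily by nearest m/z within the fragment tolerance;
    the score is the paired intensity dot product over the product of the
    full intensity-vector norms, so unpaired peaks penalize only through
    the norms.  1 for identical spectra, 0 when nothing pairs.  Plain
    (unweighted) intensities by default — scale-invariant in either
    spectrum; ``sqrt_weight`` damps base-peak dominance by scoring on
    square-root intensities.
    """
    mz_a, int_a = (np.asarray(v, dtype=float) for v in empirical)
    mz_b, int_b = (np.asarray(v, dtype=float) for v in library)
    if mz_a.size == 0 or mz_b.size == 0:
        raise ValidationError("cannot score an empty spectrum")
    if sqrt_weight:
        int_a = np.sqrt(int_a)
        int_b = np.sqrt(int_b)
    norm = float(np.linalg.norm(int_a) * np.linalg.norm(int_b))
    if norm == 0:
        return 0.0
    dot = sum(float(int_a[i] * int_b[j]) for i, j in _pair_peaks(mz_a, mz_b, frag_tol))
    return min(dot / norm, 1.0)


def _tie_key(candidate: CandidateMatch):
    return (-candidate.cosine, abs(candidate.ppm_err), candidate.entry.compound_id)


def annotate(
    ms2: Scan,
    candidates: list[CandidateMatch],
    frag_tol: FragmentTolerance = FragmentTolerance(),
) -> Optional[AnnotationRecord]:
    """Score every candidate against the MS2 spectrum; keep the best hit.

    Ties on cosine score break toward smaller absolute ppm error, then
    lexicographic compound id.  Returns None when no candidates exist or
    the MS2 spectrum is empty.
    """
    if not candidates or ms2.mz.size == 0:
        return None
    for candidate in candidates:
        candidate.cosine = cosine_score(
            (ms2.mz, ms2.intensity),
            (candidate.entry.mz, candidate.entry.intensity),
            frag_tol,
        )
    best = min(candidates, key=_tie_key)
    return AnnotationRecord(
        scan_index=ms2.index,
        precursor_mz=ms2.precursor_mz,
        adduct=best.adduct.label,
        neutral_mass_hypothesis=best.neutral_mass_hypothesis,
        compound_id=best.entry.compound_id,
        formula=best.entry.formula,
        ppm_error=best.ppm_err,
        cosine_score=best.cosine,
        provenance=best.entry.provenance,
    )


def annotate_run(
    run: RawRun,
    verdicts: Sequence[QCVerdict],
    library: Sequence[LibraryEntry],
    tol_ppm: float = 5.0,
    frag_tol: Optional[FragmentTolerance] = None,
    geom: Optional[RasterGeometry] = None,
    log: Optional[PositionLog] = None,
) -> list[AnnotationRecord]:
    """Annotate every QC-valid MS2 scan; attach pixel coordinates if geometry given."""
    if frag_tol is None:
        frag_tol = FragmentTolerance(ppm=tol_ppm)
    records = []
    for verdict in verdicts:
        if not verdict.valid:
            continue
        scan = run.scans[verdict.scan_index]
        hypotheses = neutral_hypotheses(scan.precursor_mz, run.polarity)
        candidates = match_library(hypotheses, library, tol_ppm)
        record = annotate(scan, candidates, frag_tol)
        if record is None:
            continue
        if geom is not None and log is not None:
            record.pixel = scan_to_pixel(scan.time_s, geom, log)
        records.append(record)
    return records


def compound_summary(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Per-compound roll-up: best score, supporting events, adducts observed."""
    if not records:
        return pd.DataFrame(
            columns=["compound_id", "formula", "n_events", "best_cosine", "adducts"]
        )
    frame = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "formula": [r.formula for r in records],
            "cosine_score": [r.cosine_score for r in records],
            "adduct": [r.adduct for r in records],
        }
    )
    grouped = (
        frame.groupby("compound_id")
        .agg(
            formula=("formula", "first"),
            n_events=("cosine_score", "size"),
            best_cosine=("cosine_score", "max"),
            adducts=("adduct", lambda a: ",".join(sorted(set(a)))),
        )
        .reset_index()
        .sort_values(["best_cosine", "compound_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return grouped
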