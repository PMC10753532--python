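"""Synthetic MSI-DDA instrument: phantom tissue, matrix background, DDA engine.

The simulator emits a complete raster acquisition — one MS1 survey scan per
pixel at a fixed cycle period, MS2 scans chosen by a TopN DDA engine with
minimum precursor intensity, a fixed exclusion list, and occurrence-based
dynamic exclusion — together with the position/laser log and a ground-truth
manifest, so the QC, annotation and imaging stages can be validated without
instrument data.

Physical realism is deliberately limited to what the pipeline is sensitive
to: a single monoisotopic centroid per ion species, multiplicative
log-normal intensity noise, Gaussian m/z jitter in ppm, matrix ions that
are brighter off tissue than on (the tissue insulates the conductive
slide), and low-level ambient ions that persist while the laser is off
during line turnaround — which is what produces laser-off MS2 events in
real runs.

Acquisition modes: ``sequential`` interleaves up to ``top_n`` MS2 scans
into each full-scan cycle; ``parallel`` models a multi-analyzer instrument
whose MS2 acquisition does not consume cycle time, so every eligible
precursor (up to the optional ``top_n_parallel`` cap) is fragmented each
cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

from .annotation import _ADDUCT_BY_LABEL, adducts_for_polarity
from .formats_io import (
    LibraryEntry,
    PositionLog,
    RawRun,
    Scan,
    ValidationError,
    write_msp,
    write_mzml_run,
    write_position_log,
)
from .geometry import RasterGeometry

__all__ = [
    "DynamicExclusion",
    "SimCompound",
    "BackgroundIon",
    "SimConfig",
    "GroundTruth",
    "simulate_run",
    "make_library",
    "exclusion_region_mask",
    "disk_mask",
    "make_phantom_config",
    "write_simulation",
]


class DynamicExclusion(NamedTuple):
    """Occurrence-triggered exclusion: after *max_occurrences* selections
    within *occurrence_window_s*, the precursor is ineligible for
    *exclusion_duration_s*."""

    max_occurrences: int = 2
    occurrence_window_s: float = 3.0
    exclusion_duration_s: float = 5400.0


@dataclass
class SimCompound:
    """A planted compound: library ground truth, phantom mask, abundance."""

    entry: LibraryEntry
    mask: np.ndarray
    abundance: float

    @property
    def ion_mz(self) -> float:
        adduct = _ADDUCT_BY_LABEL[self.entry.adduct]
        return self.entry.exact_mass + adduct.mass_shift_da


@dataclass
class BackgroundIon:
    """A matrix or ambient ion with fixed on/off-tissue intensities.

    ``ambient`` ions persist while the laser is off (source background);
    matrix ions require the laser.  Fragments are the pseudo-MS2 the DDA
    engine acquires when it selects this ion.
    """

    mz: float
    off_tissue_intensity: float
    on_tissue_intensity: float
    ambient: bool = False
    fragment_mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    fragment_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if np.size(self.fragment_mz) == 0:
            # Deterministic pseudo-fragments: two neutral losses + precursor.
            self.fragment_mz = np.array([self.mz * 0.55, self.mz * 0.8, self.mz])
            self.fragment_intensity = np.array([30.0, 60.0, 100.0])
        self.fragment_mz = np.asarray(self.fragment_mz, dtype=float)
        self.fragment_intensity = np.asarray(self.fragment_intensity, dtype=float)

    @property
    def label(self) -> str:
        kind = "ambient" if self.ambient else "matrix"
        return f"{kind}@{self.mz:.4f}"


@dataclass
class SimConfig:
    """Full description of one synthetic acquisition."""

    n_lines: int
    n_cols: int
    compounds: list[SimCompound]
    background_ions: list[BackgroundIon] = field(default_factory=list)
    polarity: str = "positive"
    mass_range: tuple[float, float] = (150.0, 900.0)
    mode: str = "sequential"
    top_n: int = 4
    top_n_parallel: Optional[int] = None
    cycle_period_s: float = 0.6
    pixel_pitch_um: float = 100.0
    line_spacing_um: float = 100.0
    turnaround_s: float = 1.2
    min_precursor_intensity: float = 500.0
    isolation_width: float = 1.0
    dynamic_exclusion: Optional[DynamicExclusion] = DynamicExclusion()
    exclusion_list: tuple[float, ...] = ()
    exclusion_tol_ppm: float = 5.0
    noise_cv: float = 0.1
    mz_jitter_ppm: float = 0.5
    tissue_mask: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "parallel"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.dynamic_exclusion is not None:
            de = self.dynamic_exclusion
            if de.max_occurrences < 1 or de.occurrence_window_s <= 0 or de.exclusion_duration_s <= 0:
                raise ValidationError("dynamic exclusion parameters must be positive")
        shape = (self.n_lines, self.n_cols)
        for compound in self.compounds:
            if compound.mask.shape != shape:
                raise ValidationError(
                    f"{compound.entry.compound_id}: mask shape {compound.mask.shape} "
                    f"does not match grid {shape}"
                )
            if compound.entry.adduct is None:
                raise ValidationError(
                    f"{compound.entry.compound_id}: planted compounds need an explicit adduct"
                )
            adduct = _ADDUCT_BY_LABEL[compound.entry.adduct]
            if adduct.polarity != self.polarity:
                raise ValidationError(
                    f"{compound.entry.compound_id}: adduct {adduct.label} "
                    f"inconsistent with {self.polarity} polarity"
                )
        if self.tissue_mask is not None and self.tissue_mask.shape != shape:
            raise ValidationError("tissue_mask shape does not match grid")

    @property
    def geometry(self) -> RasterGeometry:
        return RasterGeometry(
            plate_velocity_um_s=self.pixel_pitch_um / self.cycle_period_s,
            line_spacing_um=self.line_spacing_um,
            cycle_period_s=self.cycle_period_s,
            n_lines=self.n_lines,
            n_cols=self.n_cols,
            pixel_pitch_um=self.pixel_pitch_um,
        )

    def effective_tissue_mask(self) -> np.ndarray:
        if self.tissue_mask is not None:
            return self.tissue_mask
        mask = np.zeros((self.n_lines, self.n_cols), dtype=bool)
        for compound in self.compounds:
            mask |= compound.mask
        return mask


class TruthEvent(NamedTuple):
    """Ground truth for one emitted MS2 scan."""

    scan_index: int
    time_s: float
    pixel: tuple[int, int]
    compound_id: str
    adduct: Optional[str]
    true_mz: float
    precursor_mz: float


@dataclass
class GroundTruth:
    """Per-MS2 provenance plus per-compound phantom masks and abundances."""

    events: list[TruthEvent]
    compound_masks: dict[str, np.ndarray]
    compound_abundances: dict[str, float]

    def planted_events(self) -> list[TruthEvent]:
        """Events whose precursor came from a planted compound (not background)."""
        return [e for e in self.events if e.compound_id in self.compound_masks]


class _ExclusionState:
    """Dynamic-exclusion bookkeeping over ppm-clustered precursor m/z."""

    def __init__(self, rule: Optional[DynamicExclusion], tol_ppm: float):
        self.rule = rule
        self.tol_ppm = tol_ppm
        self.clusters: list[dict] = []

    def _find(self, mz: float) -> dict:
        for cluster in self.clusters:
            if abs(mz - cluster["mz"]) <= cluster["mz"] * self.tol_ppm * 1e-6:
                return cluster
        cluster = {"mz": mz, "times": [], "until": -np.inf}
        self.clusters.append(cluster)
        return cluster

    def eligible(self, mz: float, t: float) -> bool:
        if self.rule is None:
            return True
        cluster = self._find(mz)
        if t < cluster["until"]:
            return False
        recent = sum(1 for x in cluster["times"] if x > t - self.rule.occurrence_window_s)
        return recent < self.rule.max_occurrences

    def record(self, mz: float, t: float) -> None:
        if self.rule is None:
            return
        cluster = self._find(mz)
        cluster["times"].append(t)
        recent = [x for x in cluster["times"] if x > t - self.rule.occurrence_window_s]
        if len(recent) >= self.rule.max_occurrences:
            cluster["until"] = t + self.rule.exclusion_duration_s


class _PeakSource(NamedTuple):
    mz: float
    intensity: float
    compound_id: str
    adduct: Optional[str]
    true_mz: float
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _jitter(rng: np.random.Generator, mz, ppm: float):
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm * 1e-6, size=np.shape(mz) or None))


def simulate_run(config: SimConfig) -> tuple[RawRun, PositionLog, GroundTruth]:
    """Run the synthetic instrument; deterministic for a fixed seed.

    Emits one MS1 scan per pixel (compound adduct peaks where the phantom
    mask is set, matrix ions brighter off tissue, ambient ions always) and
    MS2 scans chosen by the DDA engine, then continues cycling through the
    laser-off line turnaround where only ambient ions are visible.
    """
    rng = np.random.default_rng(config.seed)
    tissue = config.effective_tissue_mask()
    exclusion = _ExclusionState(config.dynamic_exclusion, config.exclusion_tol_ppm)
    lo, hi = config.mass_range

    scans: list[Scan] = []
    events: list[TruthEvent] = []
    lines = []
    laser_intervals = []
    line_duration = config.n_cols * config.cycle_period_s
    turnaround_cycles = int(round(config.turnaround_s / config.cycle_period_s))

    def emit_ms1(t: float, sources: list[_PeakSource]) -> list[_PeakSource]:
        order = np.argsort([s.mz for s in sources], kind="stable")
        mz_list, int_list, kept = [], [], []
        for k in order:
            source = sources[k]
            if not lo <= source.mz <= hi:
                continue
            if mz_list and source.mz == mz_list[-1]:
                int_list[-1] += source.intensity
                continue
            mz_list.append(source.mz)
            int_list.append(source.intensity)
            kept.append(source)
        scans.append(
            Scan(
                index=len(scans),
                time_s=t,
                ms_level=1,
                mz=np.array(mz_list),
                intensity=np.array(int_list),
            )
        )
        return kept

    def run_dda(t0: float, sources: list[_PeakSource], pixel: tuple[int, int]) -> None:
        eligible = [
            s
            for s in sources
            if s.intensity >= config.min_precursor_intensity
            and not any(
                abs(s.mz - x) <= x * config.exclusion_tol_ppm * 1e-6
                for x in config.exclusion_list
            )
            and exclusion.eligible(s.mz, t0)
        ]
        eligible.sort(key=lambda s: -s.intensity)
        if config.mode == "sequential":
            cap = config.top_n
        else:
            cap = config.top_n_parallel if config.top_n_parallel is not None else len(eligible)
        selected = eligible[:cap]
        for k, source in enumerate(selected):
            exclusion.record(source.mz, t0)
            t_ms2 = t0 + (k + 1) * config.cycle_period_s / (len(selected) + 1)
            scale = source.intensity / max(float(source.fragment_intensity.max()), 1e-12)
            frag_int = source.fragment_intensity * scale * _lognormal_factor(
                rng, config.noise_cv, source.fragment_intensity.size
            )
            frag_mz = _jitter(rng, source.fragment_mz, config.mz_jitter_ppm)
            keep = (frag_mz >= lo) & (frag_mz <= hi)
            frag_mz, frag_int = frag_mz[keep], frag_int[keep]
            order = np.argsort(frag_mz)
            scans.append(
                Scan(
                    index=len(scans),
                    time_s=t_ms2,
                    ms_level=2,
                    mz=frag_mz[order],
                    intensity=frag_int[order],
                    precursor_mz=source.mz,
                    isolation_width=config.isolation_width,
                )
            )
            events.append(
                TruthEvent(
                    scan_index=len(scans) - 1,
                    time_s=t_ms2,
                    pixel=pixel,
                    compound_id=source.compound_id,
                    adduct=source.adduct,
                    true_mz=source.true_mz,
                    precursor_mz=source.mz,
                )
            )

    t = 0.0
    for row in range(config.n_lines):
        line_start = t
        lines.append((row, line_start, line_start + line_duration, row * config.line_spacing_um))
        laser_intervals.append((line_start, line_start + line_duration))
        for col in range(config.n_cols):
            t0 = line_start + col * config.cycle_period_s
            sources: list[_PeakSource] = []
            for compound in config.compounds:
                if not compound.mask[row, col]:
                    continue
                intensity = compound.abundance * float(
                    _lognormal_factor(rng, config.noise_cv)
                )
                sources.append(
                    _PeakSource(
                        mz=float(_jitter(rng, compound.ion_mz, config.mz_jitter_ppm)),
                        intensity=intensity,
                        compound_id=compound.entry.compound_id,
                        adduct=compound.entry.adduct,
                        true_mz=compound.ion_mz,
                        fragment_mz=compound.entry.mz,
                        fragment_intensity=compound.entry.intensity,
                    )
                )
            for ion in config.background_ions:
                base = ion.on_tissue_intensity if tissue[row, col] else ion.off_tissue_intensity
                if base <= 0:
                    continue
                sources.append(
                    _PeakSource(
                        mz=float(_jitter(rng, ion.mz, config.mz_jitter_ppm)),
                        intensity=base * float(_lognormal_factor(rng, config.noise_cv)),
                        compound_id=ion.label,
                        adduct=None,
                        true_mz=ion.mz,
                        fragment_mz=ion.fragment_mz,
                        fragment_intensity=ion.fragment_intensity,
                    )
                )
            kept = emit_ms1(t0, sources)
            run_dda(t0, kept, (row, col))
        t = line_start + line_duration
        if row < config.n_lines - 1:
            # Laser off during turnaround; only ambient ions persist.
            for k in range(turnaround_cycles):
                t0 = t + k * config.cycle_period_s
                sources = [
                    _PeakSource(
                        mz=float(_jitter(rng, ion.mz, config.mz_jitter_ppm)),
                        intensity=ion.off_tissue_intensity
                        * float(_lognormal_factor(rng, config.noise_cv)),
                        compound_id=ion.label,
                        adduct=None,
                        true_mz=ion.mz,
                        fragment_mz=ion.fragment_mz,
                        fragment_intensity=ion.fragment_intensity,
                    )
                    for ion in config.background_ions
                    if ion.ambient and ion.off_tissue_intensity > 0
                ]
                kept = emit_ms1(t0, sources)
                run_dda(t0, kept, (row, -1))
            t += turnaround_cycles * config.cycle_period_s

    run = RawRun(scans=scans, polarity=config.polarity, mass_range=config.mass_range)
    log = PositionLog(lines=lines, laser_intervals=laser_intervals)
    truth = GroundTruth(
        events=events,
        compound_masks={c.entry.compound_id: c.mask for c in config.compounds},
        compound_abundances={c.entry.compound_id: c.abundance for c in config.compounds},
    )
    return run, log, truth


def make_library(config: SimConfig, decoy: bool = False) -> list[LibraryEntry]:
    """Library entries for the planted compounds.

    With ``decoy=True`` the fragment m/z values are shuffled across the
    whole library (deterministically from the config seed), preserving
    intensities and exact masses — precursors still ppm-match but the MS2
    spectra no longer do, which calibrates the cosine-score floor.
    """
    entries = [
        LibraryEntry(
            compound_id=c.entry.compound_id,
            name=c.entry.name,
            formula=c.entry.formula,
            exact_mass=c.entry.exact_mass,
            mz=c.entry.mz.copy(),
            intensity=c.entry.intensity.copy(),
            adduct=c.entry.adduct,
            collision_energy=c.entry.collision_energy,
            provenance=c.entry.provenance,
        )
        for c in config.compounds
    ]
    if decoy:
        rng = np.random.default_rng(config.seed + 1)
        originals = [e.mz.copy() for e in entries]
        sizes = [e.mz.size for e in entries]
        owner = np.repeat(np.arange(len(entries)), sizes)
        pool = np.concatenate(originals)
        perm = rng.permutation(pool.size)
        assigned = pool[perm]
        assigned_owner = owner.copy()  # owner of each slot, not of each value

        def self_collision(slot: int, value: float) -> bool:
            return bool(
                np.any(np.abs(originals[assigned_owner[slot]] - value) < 0.1)
            )

        # Repair self-assignments: a decoy fragment must not fall near any of
        # its own entry's original fragments, or the entry is not a decoy.
        for slot in range(assigned.size):
            if not self_collision(slot, assigned[slot]):
                continue
            for other in rng.permutation(assigned.size):
                if other == slot:
                    continue
                if not self_collision(slot, assigned[other]) and not self_collision(
                    other, assigned[slot]
                ):
                    assigned[[slot, other]] = assigned[[other, slot]]
                    break
        offset = 0
        for entry in entries:
            n = entry.mz.size
            new_mz = assigned[offset : offset + n]
            offset += n
            order = np.argsort(new_mz)
            entry.mz = new_mz[order]
            entry.intensity = entry.intensity[order]
    return entries


def exclusion_region_mask(
    roi_mask: np.ndarray,
    margin_um: float,
    pixel_pitch_um: float = 100.0,
    line_spacing_um: float = 100.0,
) -> np.ndarray:
    """Pixels at least *margin_um* from every ROI pixel.

    Used to build the acquisition region for exclusion-list generation:
    matrix-only area far enough from the tissue that delocalized analytes
    cannot leak into the list.  An over-large margin yields an empty mask.
    """
    if margin_um < 0:
        raise ValidationError("margin_um must be >= 0")
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        return ~roi
    distance = ndimage.distance_transform_edt(
        ~roi, sampling=(line_spacing_um, pixel_pitch_um)
    )
    return (~roi) & (distance >= margin_um)


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def _default_background() -> list[BackgroundIon]:
    # CHCA matrix: protonated matrix at 190.0499 and the characteristic
    # cluster ion near m/z 265.96; both brighter off tissue.  One low-level
    # ambient contaminant persists while the laser is off.
    return [
        BackgroundIon(mz=190.0499, off_tissue_intensity=4.0e4, on_tissue_intensity=8.0e3),
        BackgroundIon(mz=265.96, off_tissue_intensity=3.0e4, on_tissue_intensity=5.0e3),
        BackgroundIon(
            mz=371.1012, off_tissue_intensity=1.5e3, on_tissue_intensity=1.5e3, ambient=True
        ),
    ]


def make_phantom_config(
    n_lines: int = 24,
    n_cols: int = 24,
    n_compounds: int = 20,
    mode: str = "sequential",
    seed: int = 0,
    exclude_matrix: bool = True,
    dynamic_exclusion: Optional[DynamicExclusion] = DynamicExclusion(),
    polarity: str = "positive",
) -> SimConfig:
    """A realistic demonstration phantom: disk-shaped compound distributions
    on a tissue region, CHCA-like matrix background, ambient contamination.

    Compound neutral masses are drawn so that all masses — and all masses
    offset by the H/Na adduct-mass difference — are separated by > 0.1 Da,
    guaranteeing unambiguous exact-mass matches at a 5 ppm tolerance.
    Fragment spectra are random 4-8 peak patterns with base peak 100.
    """
    rng = np.random.default_rng(seed)
    shape = (n_lines, n_cols)
    tissue = disk_mask(shape, (n_lines / 2 - 0.5, n_cols / 2 - 0.5), min(n_lines, n_cols) * 0.38)

    background = _default_background()
    adduct_defs = adducts_for_polarity(polarity)
    pos_adducts = [a.label for a in adduct_defs]
    cross_offset = abs(adduct_defs[1].mass_shift_da - adduct_defs[0].mass_shift_da)
    masses: list[float] = []
    while len(masses) < n_compounds:
        m = float(rng.uniform(200.0, 850.0))
        clashes = any(
            abs(m - x) < 0.1 or abs(abs(m - x) - cross_offset) < 0.1 for x in masses
        ) or any(
            abs(m + a.mass_shift_da - ion.mz) < 0.1
            for a in adduct_defs
            for ion in background
        )
        if not clashes:
            masses.append(m)

    compounds = []
    for i, mass in enumerate(masses):
        n_frag = int(rng.integers(4, 9))
        frag_mz = np.sort(rng.uniform(150.0, max(mass - 20.0, 160.0), size=n_frag))
        while np.any(np.diff(frag_mz) < 1.0):
            frag_mz = np.sort(rng.uniform(150.0, max(mass - 20.0, 160.0), size=n_frag))
        frag_int = rng.uniform(5.0, 100.0, size=n_frag)
        frag_int[rng.integers(n_frag)] = 100.0
        adduct = pos_adducts[0] if rng.random() < 0.75 else pos_adducts[1]
        entry = LibraryEntry(
            compound_id=f"CPD{i:03d}",
            name=f"phantom compound {i}",
            formula="",
            exact_mass=mass,
            mz=frag_mz,
            intensity=frag_int,
            adduct=adduct,
            collision_energy=40.0,
            provenance="predicted",
        )
        center = (
            rng.uniform(n_lines * 0.25, n_lines * 0.75),
            rng.uniform(n_cols * 0.25, n_cols * 0.75),
        )
        radius = rng.uniform(0.15, 0.3) * min(n_lines, n_cols)
        mask = disk_mask(shape, center, radius) & tissue
        if not mask.any():
            mask = tissue.copy()
        compounds.append(
            SimCompound(entry=entry, mask=mask, abundance=float(rng.uniform(2e3, 2e4)))
        )

    exclusion_list = (
        tuple(ion.mz for ion in background if not ion.ambient) if exclude_matrix else ()
    )
    return SimConfig(
        n_lines=n_lines,
        n_cols=n_cols,
        compounds=compounds,
        background_ions=background,
        polarity=polarity,
        mode=mode,
        dynamic_exclusion=dynamic_exclusion,
        exclusion_list=exclusion_list,
        tissue_mask=tissue,
        seed=seed,
    )


def write_simulation(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write run.mzML, positions.xml, library/, truth.tsv, config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run, log, truth = simulate_run(config)
    paths = {
        "mzml": outdir / "run.mzML",
        "positions": outdir / "positions.xml",
        "library": outdir / "library",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_mzml_run(run, paths["mzml"])
    write_position_log(log, paths["positions"])
    paths["library"].mkdir(exist_ok=True)
    write_msp(make_library(config), paths["library"] / "library.msp")
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        handle.write(
            "scan_index\ttime_s\tpixel_row\tpixel_col\tcompound_id\tadduct\ttrue_mz\tprecursor_mz\n"
        )
        for e in truth.events:
            handle.write(
                f"{e.scan_index}\t{e.time_s!r}\t{e.pixel[0]}\t{e.pixel[1]}\t"
                f"{e.compound_id}\t{e.adduct or ''}\t{e.true_mz!r}\t{e.precursor_mz!r}\n"
            )
    provenance = {
        "seed": config.seed,
        "mode": config.mode,
        "polarity": config.polarity,
        "grid": [config.n_lines, config.n_cols],
        "cycle_period_s": config.cycle_period_s,
        "pixel_pitch_um": config.pixel_pitch_um,
        "line_spacing_um": config.line_spacing_um,
        "top_n": config.top_n,
        "min_precursor_intensity": config.min_precursor_intensity,
        "isolation_width": config.isolation_width,
        "dynamic_exclusion": (
            list(config.dynamic_exclusion) if config.dynamic_exclusion else None
        ),
        "exclusion_list": list(config.exclusion_list),
        "noise_cv": config.noise_cv,
        "mz_jitter_ppm": config.mz_jitter_ppm,
        "mass_range": list(config.mass_range),
        "compounds": [
            {
                "compound_id": c.entry.compound_id,
                "exact_mass": c.entry.exact_mass,
                "adduct": c.entry.adduct,
                "abundance": c.abundance,
                "mask_pixels": int(c.mask.sum()),
            }
            for c in config.compounds
        ],
    }
    with open(paths["config"], "w", encoding="utf-8") as handle:
        json.dump(provenance, handle, indent=2)
    return paths
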