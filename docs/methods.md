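# Methods

## Scope and data model

`msikit` analyzes a single MSI-DDA acquisition given three inputs: a
centroided mzML scan stream, a position/laser log, and a folder of MS2
spectral libraries. All times are seconds from run start, all m/z values
Thomson, all pixel coordinates 0-based `(row, col)` with row = raster line
index. Precursors are assumed singly charged throughout: MALDI of small
molecules overwhelmingly produces 1+/1− ions, and the supported adduct set
([M+H]⁺, [M+Na]⁺ in positive mode; [M−H]⁻, [M+Cl]⁻ in negative mode)
contains only single-charge species.

The position-log schema (raster lines with start/end times and y
coordinates, plus half-open laser-on intervals) is a minimal documented
dialect defined by this package; source-control software emits proprietary
logs, and an adapter to a specific vendor format can be layered on top of
`read_position_log` without touching the rest of the pipeline. Likewise
the XML library dialect is a minimal stand-in mirroring the fields of
`LibraryEntry`; NIST-style MSP is supported natively.

mzML reading and writing are implemented in this package on top of lxml.
The reader understands the standard PSI-MS controlled vocabulary for
centroided MS1/MS2 streams (ms level, scan start time with unit
conversion, selected-ion and isolation-window parameters, polarity,
zlib/64-bit/32-bit binary arrays) and refuses profile-mode spectra rather
than silently centroiding them. The writer emits minimal non-indexed
documents; the test suite verifies them against Bioconductor's mzR as an
independent standards check, and verifies write→read round trips to
float64 precision.

## Raster geometry

A constant-speed raster moves the plate at `plate_velocity_um_s` while the
instrument cycles every `cycle_period_s`; the along-track pixel pitch
therefore defaults to velocity × cycle period, and can be overridden when
the acquisition was configured differently. Columns are assigned by
`floor((t − t_line_start) · v / pitch)`, clipped to the grid; a `1e-9`
epsilon is added before the floor so that scans falling exactly on a pixel
boundary (the common case when the simulator emits one scan per cycle) are
not pushed one column early by floating-point rounding. Serpentine rasters
are supported by reversing odd-numbered lines. Multiple scans landing in
one pixel are summed, never averaged, so the TIC map conserves total ion
count; pixels never visited are NaN (missing), not zero.

## MS2 quality control

Two criteria, both configurable only through the run-level ppm tolerance
(default 5 ppm, matching common internally calibrated Orbitrap accuracy):

* **Laser criterion** — evaluated at the MS2 scan's own start time against
  the half-open laser intervals. This is the simplest defensible reading
  of "the laser must be active"; isolation actually spans a short window,
  but sub-cycle timing is not recorded in the log.
* **Consistency criterion** — the precursor must be re-observed, within
  the ppm tolerance, in each of the next *w* MS1 scans strictly after the
  MS2 event: *w* = 2 for parallel acquisition, 1 for sequential.
  Interleaved MS2 scans are skipped when counting the window, because a
  precursor can only be re-observed in a survey spectrum. Any matching
  centroid counts regardless of intensity (a configurable floor exists,
  default 0). If fewer than *w* MS1 scans remain at end of run the event
  fails — conservative, so the surviving set stays trustworthy. Only
  following scans are checked, never preceding ones.

The three nested counts (total MS2, laser-active, fully valid) summarize a
run; validity requires both criteria, so the counts are always nested.

## Annotation cascade

Per valid MS2 event the pipeline generates one neutral-mass hypothesis per
polarity-matched adduct, `M = precursor_mz − Δ`, dropping non-positive
masses. The adduct mass shifts carry the electron-mass correction
(Δ[M+H]⁺ = +1.00727646688, Δ[M+Na]⁺ = +22.98922070, Δ[M−H]⁻ =
−1.00727646688, Δ[M+Cl]⁻ = +34.96940126 Da), so hypothesis generation and
re-addition of the shift round-trip to well below 1e-9 Da. The precursor
m/z used is the instrument-reported isolation target; no recalibration or
re-centroiding is applied.

Candidate generation is deliberately permissive: every (hypothesis,
library entry) pair within the ppm tolerance survives — isomers at the
same exact mass, the same compound at several collision energies,
different adducts — excluding only entries whose *declared* adduct
contradicts the hypothesis. Hundreds of candidates per spectrum are
acceptable; disambiguation happens at scoring. Predicted and experimental
library spectra are scored identically, with provenance carried through to
the report.

**Cosine scoring.** Peaks are paired greedily by nearest m/z, each peak
used at most once, accepting candidate pairs in order of increasing m/z
distance — deterministic and independent of input order. The score is the
paired intensity dot product divided by the product of the full
intensity-vector norms, so unpaired peaks penalize through the norms; the
result is scale-invariant and symmetric, 1 for identical spectra, 0 when
nothing pairs. Intensities are used unweighted by default; square-root
weighting, which damps base-peak dominance, is available as an option but
never applied implicitly. The pairing window at
fragment m/z is `max(mz · ppm · 1e-6, floor_da)` with a 0.01 Da default
floor: a pure ppm window suits Orbitrap MS2, but ion-trap MS2 detectors
need an absolute floor. The independent cross-check in the test suite
compares against matchms `CosineGreedy` on spectra whose peaks are
separated by more than the window, where the two greedy strategies
provably coincide.

**Best-hit retention.** The single highest cosine wins; ties break toward
smaller |ppm error|, then lexicographic compound id, making annotation
fully deterministic. TIC normalization is an imaging-only toggle — cosine
similarity is scale-invariant, so normalization cannot affect scoring.

## Imaging

EIMs accumulate, per MS1 scan, the summed intensity within a symmetric
ppm window of the target (consistent with the pipeline's single ppm
parameter, rather than a fixed-Da window). TIC normalization divides each
pixel by its own TIC after accumulation; no global rescaling factor is
applied afterwards. Zero-TIC or never-visited pixels are NaN, serialized
as empty CSV cells and rendered black in PNG. Display scaling clips at the
99.5th intensity percentile at export only — stored grids are never
modified, and the CSV export is the bit-exact test surface. Channel
merging min–max scales each of 2–3 images independently before RGB
compositing.

## The synthetic instrument

The simulator emulates exactly the features the pipeline is sensitive to,
with defaults chosen as the acquisition conditions the analysis targets:

* one MS1 survey per pixel at a 0.6 s cycle and 100 µm pitch (velocity
  derived as pitch/cycle), mass range m/z 150–900, positive polarity;
* a TopN DDA engine (default TopN 4 sequential) with minimum precursor
  intensity (default 500 counts), a fixed exclusion list matched at the
  run ppm tolerance, and occurrence-based dynamic exclusion — a precursor
  cluster selected 2 times within 3 s is excluded for 5400 s. Dynamic
  exclusion may be disabled (`None`) for scenarios that probe sustained
  TopN behavior. Precursor priority is descending intensity;
* *parallel* acquisition modeled as MS2 events that consume no cycle time
  (quasi-simultaneous multi-analyzer operation), so every eligible
  precursor is fragmented each cycle unless capped; *sequential* caps at
  TopN. Exact vendor scheduling is not reproduced;
* matrix ions (CHCA-like, at m/z 190.0499 and 265.96) brighter **off**
  tissue than on — the tissue insulates the conductive slide — and a
  low-level ambient contaminant ion that persists while the laser is off
  during line turnaround. The ambient ion is a modeling device that
  reproduces the real-world phenomenon of laser-off MS2 events without
  claiming a specific chemical identity;
* multiplicative log-normal intensity noise (default CV 0.1) and Gaussian
  m/z jitter (default 0.5 ppm, representative of an internally calibrated
  Orbitrap). Each ion is a single monoisotopic centroid; isotope patterns,
  peak shape, detector saturation and plume physics are not modeled —
  so passing tests demonstrate the correctness of the *pipeline logic*
  under calibrated noise, not robustness to every artifact of real data.

The phantom generator draws compound neutral masses so that all masses,
and all masses offset by the between-adduct mass difference, are separated
by > 0.1 Da from each other and from the background ions: exact-mass
matches at 5 ppm are then unambiguous by construction, which is what lets
annotation recovery isolate scoring behavior from accidental mass
collisions. Decoy libraries shuffle fragment m/z values across the whole
library (seeded), preserving intensities and exact masses; a repair pass
swaps any fragment that would land within 0.1 Da of its own entry's
original fragments, since a self-assigned base peak makes an entry a
partial true positive rather than a decoy.

Ground truth records, per emitted MS2 scan, the source compound (or
background ion), adduct, true and observed precursor m/z, and pixel.

## Numerical and degenerate-input choices

* ppm error is signed: `(observed − calculated)/calculated · 1e6`.
* Laser intervals are half-open `[on, off)`; line intervals likewise.
* An empty MS2 peak list cannot be scored (error), and an event with no
  candidates annotates to nothing rather than a low-score placeholder.
* An empty mzML run is valid input everywhere; an empty library folder is
  an error.
* Scan streams must be time-ordered and within the declared mass range;
  violations raise validation errors at construction, not downstream.
* The exclusion-region utility computes Euclidean distance in µm
  (anisotropic pixel sampling respected) from the ROI via a distance
  transform; margin 0 gives the exact ROI complement, an oversized margin
  an empty mask.

## Known limitations

* Chimeric (mixed-precursor) MS2 spectra are scored as-is and will simply
  receive low cosine scores; no deconvolution is attempted.
* No formula generation from exact mass, no in-silico fragmentation.
* imzML and vendor raw formats are out of scope; inputs are mzML plus the
  documented log dialect.
* The QC laser criterion uses the MS2 start time only; events straddling a
  laser edge are classified by their start.
* Problem sizes in the test suite and acceptance script (grids up to
  24 × 24, 20 compounds, 100 randomized QC runs) were chosen as the
  smallest scenarios that exercise every code path with comfortable event
  counts; all scale linearly if enlarged.
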