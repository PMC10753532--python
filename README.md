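# msikit

Automated compound annotation and relative quantitation for MALDI
mass-spectrometry-imaging (MSI) runs acquired with data-dependent
acquisition (DDA).

## The problem

MALDI-MSI maps the spatial distribution of small molecules across a tissue
section, but annotation from MS1 exact mass alone is ambiguous and is
usually propped up by a separate bulk LC-MS/MS experiment, which samples
different chemistry than laser desorption does. When the imaging run itself
is acquired in DDA mode, every pixel's survey scan can trigger MS2
fragmentation scans, and those fragmentation spectra identify compounds *in
situ* — provided the MS2 stream is rigorously quality-filtered first, since
a raster acquisition keeps scanning while the laser is off and while
transient ions appear and vanish between scan events.

`msikit` implements that workflow for single raw files converted to mzML:

1. **MS2 quality control.** An MS2 event is valid iff (i) the laser was
   active at its acquisition time (from the position/laser log) and (ii)
   its precursor is re-observed within a ppm tolerance in the following
   MS1 scans — two consecutive survey scans for parallel (multi-analyzer)
   acquisition, one for sequential.
2. **Adduct-resolved annotation.** For each valid MS2 event with precursor
   m/z *p*, neutral-mass hypotheses are generated per polarity-matched
   adduct (singly charged): M = p − Δ(adduct), with Δ([M+H]⁺) = 1.007276,
   Δ([M+Na]⁺) = 22.989221, Δ([M−H]⁻) = −1.007276, Δ([M+Cl]⁻) = 34.969401 Da.
   Every library compound whose exact neutral mass satisfies
   |(M − M_lib)/M_lib| · 10⁶ ≤ tol_ppm becomes a candidate — isomers,
   alternative adducts and duplicate collision energies included. Each
   candidate is scored by cosine similarity between the empirical and
   library MS2 spectra (greedy nearest-m/z peak pairing, unweighted
   intensities), and only the highest-scoring hit is retained.
3. **Imaging.** Per-pixel total-ion-current (TIC) maps and extracted ion
   maps (EIMs) over symmetric ppm windows, with optional per-pixel TIC
   normalization, raster time-to-pixel mapping from a constant-speed stage
   model, and PNG/CSV export.
4. **Simulation.** A synthetic MSI-DDA instrument (phantom compound
   distributions, CHCA-like matrix background, TopN selection, minimum
   precursor intensity, exclusion lists, occurrence-based dynamic
   exclusion) that writes mzML, the position log, MSP libraries and a
   ground-truth manifest, so the entire pipeline is testable end to end
   without instrument data.

## Worked example

Simulate a small sequential acquisition (8 × 10 pixels, 5 planted
compounds, TopN 4, CHCA-like matrix on the exclusion list) and analyze it:

```sh
msikit simulate --mode sequential --n-lines 8 --n-cols 10 \
    --n-compounds 5 --seed 3 --out demo
msikit qc --mzml demo/run.mzML --positions demo/positions.xml \
    --mode sequential --out demo/out
```

```
total MS2:        13
laser-active MS2: 13
valid MS2:        11
```

Thirteen MS2 events were triggered; all were laser-active, and 11 also
passed the precursor-consistency check (the other two were fired on the
last pixel a compound occupied, so the precursor was gone from the next
survey scan).

```sh
msikit annotate --mzml demo/run.mzML --positions demo/positions.xml \
    --library demo/library --mode sequential \
    --velocity 166.667 --cycle 0.6 --n-lines 8 --n-cols 10 --out demo/out
```

```
annotated 9 MS2 events (5 distinct compounds)
```

`demo/out/annotations.tsv` holds one row per annotated event — precursor
m/z, chosen adduct, neutral-mass hypothesis, signed ppm error, cosine
score, and the pixel it came from:

```
scan_index  precursor_mz  adduct   neutral_mass_hypothesis  compound_id  ppm_error  cosine_score  pixel
19          354.9341578   [M+H]+   353.9268813              CPD001       0.147      0.997         (1,4)
35          721.8356940   [M+H]+   720.8284175              CPD002       0.021      0.994         (2,5)
```

`demo/out/compound_summary.tsv` rolls this up per compound (supporting
events, best score, adducts observed), and `demo/out/images/` holds one
EIM per annotated (compound, adduct) pair plus the TIC map. All five
planted compounds are recovered with cosine scores above 0.99; dynamic
exclusion (2 occurrences within 3 s, 5400 s exclusion) limits each
compound to about two MS2 events, exactly as a long-exclusion DDA method
is designed to do.

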