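# Methods

This note documents the models and numerical choices behind
`platescreen`: what each stage computes, which parameters matter, what
the synthetic-data generators do and do not emulate, and where the
design was genuinely open.

## Matching model

A target library entry is a point (RT, m/z) with an optional MS/MS
spectrum; an extract feature is the same kind of point with a peak area.
Matching is a box test: a feature is a candidate for an entry when
`|Δm/z| ≤ mz_tol` **and** `|ΔRT| ≤ rt_tol`. Both tolerances are
instrument properties, not fit parameters:

| parameter | default | units | rationale |
|---|---|---|---|
| `mz_tol` | 0.3 | amu | unit-resolution ion-trap mass accuracy |
| `rt_tol` | 0.1 | min | peak-width-scale reproducibility on a 6-min gradient |
| `ms2_threshold` | 0.7 | – | square-root cosine confirmation cutoff |
| `bin_width` | 0.5 | amu | MS/MS binning at unit resolution |

When several features fall in the box, the hit is the feature with the
smallest mass error, ties broken by RT error, then input order — mass is
the more diagnostic coordinate at these tolerances. One feature per
entry is reported; quantity is the raw peak area with no
internal-standard normalization (relative comparisons between wells of
one experiment are the intended use).

Observed masses are matched exactly as observed. No adduct or charge
inference is attempted: whether a printed mass is [M+H]⁺, [M+Na]⁺ or
effectively neutral is usually unknown for a library built from an
uncharacterized extract, and the screen only needs reproducibility, not
identity of the ion species.

### MS/MS similarity

Spectra are summed onto a fixed grid of `bin_width` (floor(m/z / w)),
square-root transformed, and compared by normalized dot product. The
square root damps the dominance of the base peak, a standard choice for
library matching of unit-resolution spectra. The score is symmetric,
in [0, 1], and invariant to uniform intensity scaling; an empty spectrum
is defined to score 0 (with a warning) rather than raise, so a single
corrupt scan cannot abort a plate screen. An independent cross-check
against a greedy peak-pairing cosine (matchms) on bin-center-aligned
spectra agrees to ≈1e-9.

The 0.7 threshold is conservative for same-instrument comparisons:
replicate measurements of the same compound under the default noise
model score ≥ 0.95, while unrelated random spectra almost never exceed
0.3. Raising the threshold can only shrink the confirmed set
(monotonicity is tested).

## Feature extraction

The toolkit accepts pre-extracted feature tables (CSV) or centroided
mzML. For mzML, MS1 peaks are chained across consecutive scans into
extracted-ion traces: a peak joins the trace whose running
intensity-weighted mean m/z is nearest within `mz_tol`; a trace closes
at the first scan with no matching peak (no gap bridging). Traces with
≥ `min_scans` points (default 3) and apex height ≥ `min_height` become
features; area is the trapezoidal integral of intensity over time, so
the sum of feature areas can never exceed the run's total-ion-current
integral. MS2 scans attach to the feature nearest in precursor m/z
(within `mz_tol`) whose RT span contains the scan. This is a deliberately
simple picker — no peak-shape fitting, deconvolution, isotope grouping
or cross-run RT alignment — adequate for well-separated features at the
simulated noise levels; real co-eluting isobars closer than `mz_tol`
will merge.

## Oligomer series detection

Given observed masses, `detect_series` reports every maximal subset
whose sorted consecutive differences all lie within `tol` of their own
mean (the estimated repeat mass); `candidate_repeats` optionally
restricts the repeat to given values ± `tol`. The search is a
depth-first enumeration of increasing chains pruned on difference
spread: a chain whose difference spread exceeds 2·`tol` can never
satisfy the residual bound (best achievable residual is spread/2) and
the spread only grows, so the pruning is exact. Validity is then checked
against the actual mean, maximality by subset comparison among valid
chains. Worst-case cost is exponential in the number of masses whose
pairwise differences are mutually compatible — dense inputs (many
near-duplicate masses) should be consolidated first
(`consolidate_masses`, single-linkage within `tol`, cluster mean), which
is what the CLI does with screen reports.

Reporting: series are sorted by member count descending; a series
sharing ≥ 2 members with a *longer* reported series is suppressed, so
one chemical family is reported once rather than as all of its
near-maximal fragments. Equal-length overlapping series are all kept —
with only two shared members there is no principled basis to prefer one.

The repeat-mass estimator is the mean of consecutive differences, which
telescopes to (max − min)/(n − 1); under i.i.d. Gaussian mass error σ
its standard deviation is σ√2/(n − 1), so recovery within
3σ/√(n − 1) holds with ≥ 95% probability for n ≥ 2 (tested over 1000
simulated ladders at σ = 0.05 amu).

Oligomer masses use the linear-ester convention: n condensed residues
plus one water for the chain ends, atomic masses from the standard
tables shipped with pyteomics (monoisotopic by default, average
available). For 3-hydroxybutyric acid (C₄H₆O₂, 86.0368 amu) this gives
534.231 / 620.268 / 706.305 amu for the 6/7/8-mers. Note a known data
quirk: the printed observed mass of the 6-mer ion in the original screen
is 534.4 amu, 0.17 amu above the computed hexamer value, while the 7-
and 8-mer observations match to one decimal. The toolkit does not
reconcile this (it matches observed values as observed); series
detection on the printed triple still estimates an 85.95-amu repeat,
which rounds to the 86-amu family signature.

## Plate and factorial design

The enrichment layout is a fixed 8 × 4 media/pH grid (nutrient broths,
marine broths, minimal media with different carbon sources, buffered pH
series 5.8–8.0) repeated across three four-column antibiotic blocks
(none / penicillin G / kanamycin), giving 96 distinct conditions per
plate. Screen expansion is pure combinatorics:
`n_enrichment × wells` cultures, `n_enrichment × subcultures` plates,
and their product in screened conditions.

The factorial design enumerates the Cartesian product of factor levels
with the **last factor varying fastest**, ids assigned positionally
(`TB01`…). The reference is each factor's middle level; with factors
ordered tryptone (3/12/18 g/L), yeast extract (6/24/36 g/L), glycerol
(1/4/8 g/L), the all-mid standard Terrific Broth formulation lands at
position 14, matching its conventional `TB14` label. The enumeration
order was an open choice — nothing external pins which of the 27
combinations carries which label — and "last factor fastest from
low to high" is the convention that places the reference at 14.

Fold change is the formulation's mean titer (arithmetic mean over
strains and replicates; the summary statistic was another open choice)
divided by the reference mean, so the reference is exactly 1.0 and the
statistic is invariant to rescaling all titers. Main effects are
marginal means: the average titer over every record at a given level of
a factor, with a trend label that requires a *strict* ordering of the
level means (any tie → `non-monotone`). No significance testing is
performed — with duplicate cultures of three strains the design supports
ranking and trend reading, not inference.

## Synthetic data

The generators emulate the *structure* of a plate screen, not its
physics:

- **Extracts** — each spiked library target becomes one feature at the
  entry's coordinates plus Gaussian jitter (RT σ = 0.02 min, m/z
  σ = 0.05 amu) with log-normal area (median 1e5 counts·min, σ = 0.3
  log-units) and a perturbed copy of the entry's MS/MS spectrum
  (±0.01 amu fragment jitter, ±0.2 log-units intensity).
  Background is a Poisson number of features (mean 30) uniform over
  100–1000 amu and the gradient, log-normal intensities
  (median 1e4, σ = 1), carrying no MS/MS. Defaults give clean
  separation at the default tolerances; doubling the jitter sigmas is
  the intended stress test.
- **Screen experiments** — 16 plates (named
  `plate-<enrichment>-<subculture>`) of 96 wells; designated producer
  wells receive all spiked targets, everything else background only.
  One generator stream in a fixed well order makes the whole set
  reproducible per seed.
- **Factorial responses** — titer = baseline × per-factor level
  multipliers × log-normal noise (σ = 0.1). The default effect model
  (tryptone 0.6/1.0/1.5, yeast extract 1.6/1.0/0.5, glycerol
  0.8/1.0/0.9) plants the qualitative trends the optimization is meant
  to detect, with a best-formulation fold of ≈2.4× over the reference —
  inside the 1.3–5.23× band such optimizations plausibly yield. The
  per-formulation titers behind that band are not public, so the band is
  used only as a plausibility check on the generator, never as a fitted
  quantity.

What passing tests therefore show: the matching, confirmation,
aggregation, series-detection and effect-recovery logic is correct under
idealized, well-separated signals. What they do not show: robustness to
real chromatographic drift, co-elution, adduct multiplicity, matrix
suppression, or media-component interference — real data would need the
tolerances revisited and possibly RT alignment, which is out of scope.

The synthetic 82-entry library stands in for a real screening library
whose full characterization table was never published; it plants the
three printed oligomer characterizations (2.48 min/534.4 amu,
2.59/620.3, 2.75/706.3) at their published coordinates among 79 random
metabolites, every entry with a synthetic MS/MS spectrum, and respects
the dedup guarantee (no two entries within both build tolerances).

## File formats and numerics

- Feature CSVs: columns `mz, rt_apex, rt_start, rt_end, area, height`,
  floats written as shortest exact `repr` and read back with
  round-trip-precision parsing, so write→read is lossless. Optional
  `ms2_*` columns carry fragmentation spectra when present.
- Libraries: NIST-style MSP text (Name / PRECURSORMZ / RETENTIONTIME /
  Num Peaks + peak lines) and a lossless native JSON dialect.
- mzML: minimal centroided writer (uncompressed base64 little-endian
  float64) and an accession-driven reader (32/64-bit floats, zlib or
  none, second- or minute-unit scan times). Profile-mode spectra are
  rejected explicitly rather than mis-centroided.
- Degenerate inputs are defined, not crashed on: empty runs and
  libraries round-trip, empty extracts screen to empty hit lists, an
  empty MS/MS spectrum scores 0, and a zero-mean reference titer raises
  a specific undefined-fold error.

## Problem sizes in the test suite

The bundled tests run the full pipeline at the original screen's scale
(16 × 96 wells, 82-entry library) for 20 seeds, 200 random well
instances against the brute-force matching oracle, exhaustive
subset-enumeration checks of series detection for ≤ 12 masses, and 1000
simulated mass ladders; the complete suite runs in well under five
minutes on one CPU.

## Known limitations

- One MS/MS spectrum per feature/entry; no spectral merging.
- No RT alignment across runs; libraries and extracts must share the
  chromatographic method.
- Series detection assumes a single repeat unit per family; mixed
  copolymer ladders (alternating repeats) are reported as fragments.
- The quantity scale is arbitrary (area); cross-instrument comparison
  requires external calibration.
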