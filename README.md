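# platescreen

A toolkit for chemically guided screening of microbial cultures grown in
96-well plates, analyzed by UPLC/MS. It is written for natural-product
chemists and microbiologists who want to find which wells of a large
plate-based cultivation experiment produce particular target metabolites —
for example, compounds originally observed in a marine invertebrate
extract — without manually inspecting thousands of chromatograms.

## What it does

The screening method works from a **target-molecule library**: each
metabolite of interest is characterized once by its retention time (RT,
minutes), the mass of its most abundant ion (amu), and optionally its
MS/MS fragmentation spectrum. Culture-broth extracts from each plate well
are then matched against that library:

1. **Match** — a library entry *hits* a well when the extract contains a
   chromatographic feature with `|Δm/z| ≤ mz_tol` (default 0.3 amu,
   unit-resolution ion trap) and `|ΔRT| ≤ rt_tol` (default 0.1 min on a
   6-minute gradient). The best candidate is the one with the smallest
   mass error, then the smallest RT error.
2. **Quantify** — the hit's quantity is the matched feature's peak area
   (trapezoidal integration of its extracted-ion trace, counts·min).
3. **Confirm** — when both the entry and the feature carry MS/MS spectra,
   identity is confirmed by a binned square-root cosine similarity

   score(A, B) = Σ√aᵢ·√bᵢ / (‖√a‖‖√b‖), bins of 0.5 amu,

   with a confirmation threshold of 0.7.

Around this core the package models the rest of the workflow:

- **Oligomer series detection** — homologous metabolite families (e.g.
  polyhydroxybutyrate-type oligoesters) appear as arithmetic progressions
  of ion masses. `detect_series` recovers all maximal progressions whose
  consecutive differences agree within a tolerance; `oligomer_mass`
  computes the neutral mass of a linear oligomer, n·M(residue) + M(H₂O).
  For the 3-hydroxybutyric acid residue C₄H₆O₂ (86.0368 amu,
  monoisotopic) the 7- and 8-mers are 620.268 and 706.305 amu.
- **Plate-experiment design** — the 96-condition enrichment-plate layout
  (media × pH × antibiotic grid), the enrichment → subculture expansion
  arithmetic (4 plates × 96 wells × 4 subcultures = 384 cultures,
  16 plates, 1536 screened conditions), and a 3×3×3 full-factorial
  Terrific Broth optimization (27 formulations, all-mid reference TB14)
  with fold-change and main-effect analyses.
- **Synthetic data** — seeded generators for plate extract sets (library
  targets spiked into producer wells with RT/mass jitter and log-normal
  intensities, plus background noise peaks) and factorial titer tables
  with planted factor effects, so the entire pipeline is testable without
  instrument data. A minimal centroided-mzML writer/reader supports
  round-tripping simulated runs.

## Worked example

Simulate a 16-plate screen with two producer wells, screen it, and look
for repeat-unit families among the confirmed hits:

```
$ platescreen simulate screen --seed 7 -o sim
wrote library.json, plate_map.csv and 1536 extract CSVs to sim

$ platescreen screen --lib sim/library.json --extracts sim/extracts -o report.csv
screened 1536 wells: 98 matches, 2 wells with confirmed hits
  confirmed: plate-1-1 D5
  confirmed: plate-2-1 B1

$ platescreen series --masses report.csv --tol 0.3
3-member series, repeat 85.90 amu (residual 0.104): 534.5, 620.3, 706.3
```

Of the 98 tolerance matches across 1536 wells, only the two wells where
producers were planted survive MS/MS confirmation, and the three
confirmed ion masses differ by ~86 amu — the 3-hydroxybutyrate repeat
unit, identifying them as members of one oligomer family (6-, 7- and
8-mers). The media-optimization side:

```
$ platescreen design -o design.csv
$ platescreen simulate factorial --seed 7 -o fact
$ platescreen optimize-report --design design.csv --responses fact/titers.csv
reference: TB14
best formulation: TB20 (2.35-fold) with levels {'tryptone': 18.0, 'yeast_extract': 6.0, 'glycerol': 4.0}
9 formulations beat the reference (range 0.24-2.35 fold)
tryptone: increasing (3 g/L: 5.44e+04, 12 g/L: 9.28e+04, 18 g/L: 1.37e+05)
yeast_extract: decreasing (6 g/L: 1.47e+05, 24 g/L: 9.18e+04, 36 g/L: 4.6e+04)
glycerol: non-monotone (1 g/L: 8.49e+04, 4 g/L: 1.06e+05, 8 g/L: 9.38e+04)
```

Fold changes are formulation mean titers relative to the standard TB
formulation (TB14); the main-effect lines give the marginal mean titer at
each level of each media component with a monotonicity label — here the
generator's planted effects (titers rising with tryptone, falling with
yeast extract) are recovered.

The same operations are available as a library; see the module
docstrings under `src/platescreen/` and `docs/methods.md` for the model
details.

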