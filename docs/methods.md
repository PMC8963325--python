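# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `laims`, in the spirit of a methods supplement.

## Acquisition model and its inversion

A section is ablated in unidirectional, left-to-right line scans with line
spacing equal to the spot size (15 µm).  Each isotope channel integrates for
its own dwell time (75 ms for ⁶⁴Zn/⁶⁶Zn, 50 ms for ³¹P/⁵⁷Fe), so at
45 µm/s the native along-scan sampling is 3.375 µm (Zn) and 2.25 µm (P, Fe).
A channel's reading count per line is ceil(line length / (speed × dwell)).

`lines_to_map` assigns reading *r* the position speed·(t_r − t₀) plus half a
native sampling interval (its centre) and averages readings into bins of the
target pixel width (default 15 µm, matching spot size and line spacing).
Averaging is the only mean-preserving resampling, and because a reading's
centre always falls inside exactly one target pixel, the noiseless
simulate→convert round trip is exact, not merely approximate — a property
the tests assert.  Rows of unequal length are truncated to the shortest
width with a logged warning; map coordinates are raster-style (row = line,
column = bin, origin upper-left).

## Synthetic phantom

The phantom emulates a peripheral-zone prostate section at 15 µm/px:

- **Grid and tissue.** 120 × 170 px; the tissue is an ellipse with semi-axes
  (850, 1230) µm, i.e. a scaled section that leaves room for the 100 × 150 px
  analysis crop plus an off-tissue margin.  The off-tissue fraction of the
  full grid (~28%) is deliberate: the tissue-detection contrast stretch
  (0.25–0.50 quantile clip) requires at least a quarter of the pixels to be
  background.
- **Glands.** Epithelium annuli around lumen disks, outer radius uniform in
  100–280 µm, lumen radius half the outer radius.  Glands are placed by
  rejection sampling under a separation constraint (centre distance ≥
  max(ro_i + ri_j, ro_j + ri_i) + 30 µm) that guarantees every lumen stays
  fully enclosed by its own epithelium — the topology the lumen-detection
  rule requires.  By default glands are added until epithelium reaches 40%
  of solid tissue (gland/(gland+stroma)); a bounded attempt budget applies
  and a shortfall beyond 10 points raises an explicit geometry error.
- **Hotspots.** Dense zinc deposits (corpora amylacea / prostatic calculi)
  are disks sampled from 150–400 µm diameter, placed centrally inside the
  largest lumina and clamped to leave a ≥ 2 px luminal margin; three by
  default.
- **Concentrations** (µg/g): Zn 450 gland / 340 stroma / 850 hotspot,
  typical of normal peripheral-zone prostate; P gives the strong gland/stroma contrast the
  segmentation exploits (3000 / 1200, lumen 30) with P-poor hotspots (80,
  i.e. 850 cps at default sensitivity — below the 1100 cps tissue offset, as
  observed for these deposits); Fe 150 / 120.  The lumen-to-gland size ratio
  (0.5) was chosen so the crop composition lands on the expected per-class
  pixel shares of such tissue (≈44% stroma, ≈34% gland, ≈4% hotspot,
  remainder lumen and off-tissue).

**Washout** is modelled as one multiplicative retention factor per (element,
compartment) — the simplest model that reproduces both the aggregate
recovery rates and the compartment-differential pattern (hotspots retained
under fixation).  Defaults: FF 1.0 everywhere; RTV 0.97 Zn / 0.999 P /
0.962 Fe; FFix Zn 0.41 in gland/stroma/lumen but 1.0 in hotspots, P 0.619,
Fe 0.630; FFPS Zn 0.16 (hotspots 0.50), P 0.610, Fe 0.614.

**Noise.** A reading is M_line · (sensitivity·concentration + background) +
ε, floored at 0, with M_line lognormal (unit mean, CV 5% by default, one
draw per line and channel) and ε Gaussian per reading (sd 30 cps).  The
multiplicative term models line-to-line ablation/transport efficiency drift;
drawing it per line rather than per reading is what makes the between-line
RSD of a 10-line standard ≈ the configured CV (readings-level noise would
average out over ~667 readings per line).  Per-element sensitivities
(50/28/10/5 cps per µg/g for ⁶⁴Zn/⁶⁶Zn/³¹P/⁵⁷Fe) and backgrounds
(200/120/50/40 cps) are plausible quadrupole values.  One global seed feeds
independent derived streams for geometry and noise, so runs are
bit-reproducible.

What the generator does **not** emulate: sectioning and biological
variability between serial sections (so simulated intersectional RSDs are
~0.5%, far below the 1.5–6.8% of real replicate sections), plasma/aerosol
physics, isotopic interferences, detector dead time, drift within a run, and
sub-pixel tissue texture.  Passing tests therefore demonstrate correctness
of the computation, not instrument realism.

## Calibration conventions

- The spike mass uses density 1 g/mL (aqueous standards); this is required
  to reproduce the printed 0.9–450 µg/g range exactly.
- σ for the 3σ/10σ criteria is the sample sd (n−1) of the blank's line
  means.  The fit is unweighted OLS; R² is the squared Pearson correlation.
- Back-calculated concentrations are floored at 0 after intercept
  subtraction; concentrations are physical and this keeps statistics finite.
- No gas-blank subtraction precedes calibration — the intercept absorbs the
  background.

## Segmentation conventions

- All quantiles use linear interpolation between order statistics.
- Otsu's threshold is computed over the fixed 256-bin histogram by
  exhaustive maximization of between-class variance; ties take the lowest
  threshold; foreground is strictly above the threshold.  A constant image
  raises (and the gland/stroma stage treats that as "no gland contours",
  yielding all-stroma tissue).
- Contours follow connected-component semantics: foreground components use
  8-connectivity, holes the complementary 4-connectivity; "on or inside a
  contour" means membership in the filled component; equal largest areas
  break ties by scan order.
- Gaussian blur derives sigma from the kernel size (0.3·((k−1)/2 − 1) + 0.8
  = 1.1 for 5×5), truncated to the kernel footprint, reflective borders.
- The 8-bit rescale maps min→0, max→255 with half-up rounding; a constant
  grid maps to zeros by convention.
- "Full ³¹P dataset" quantiles (lumen rule) and the gland-classification
  median are computed per section; the median uses raw on-tissue values.
- Stage composition: tissue and lumen detection run on the full grid (they
  need the off-tissue fraction for contrast); the gland/stroma and hotspot
  statistics are computed over the 100 × 150 px analysis crop, auto-centred
  on the tissue bounding box (overridable).  On a grid with ≥ 25%
  background, the hotspot cutoff Q0.75 + 1.5·IQR would degenerate to
  ≈ 2.5 × the stroma level (= 850 µg/g at the default concentrations, i.e.
  exactly the hotspot level); the rule is only discriminative when stroma
  sits near Q0.25 and gland near Q0.75, which is the crop's mostly-on-tissue
  composition.  This ordering is therefore a deliberate design choice.

## Quantification conventions

- The ³¹P ≥ 1100 cps mask applies to raw intensity (the threshold is an
  instrument count rate), before calibration.
- Whole-tissue recovery uses the P-masked mean of *calibrated* zinc maps;
  for P and Fe no calibration exists and recovery is intensity-based.  The
  gas background then biases low-signal elements' recoveries upward by a few
  points (e.g. Fe at ~700 cps signal over 40 cps background reads ~65%
  recovery for a true 63%); zinc, being calibrated, is unbiased.
- RSDs use the sample sd (n−1); box statistics use Tukey whiskers (1.5·IQR
  from the box edges, clamped to the data range).
- Freehand hotspot ROIs are replaced by mask-based ROIs (connected
  components of the hotspot layer) for reproducibility.

## Problem sizes

Tests and the acceptance script run the full simulated comparison at its
native desk scale:
120 × 170 px phantoms, 4 protocols × 3 replicates, 7-level calibrations with
10 lines per standard, segmentation fidelity over 5–10 phantom seeds and
~105 simulated standards for the RSD band.  The complete acceptance run
takes a few seconds; the test suite under ten.

## Known limitations

- The multiplicative-retention washout model has no spatial diffusion or
  edge effects; washout is uniform within a compartment.
- Lumen detection requires lumina to be topological holes of the tissue
  component; lumina touching the section edge are not detected (none are
  generated by default).
- The phantom's discrete concentration levels make class medians sharper
  than real tissue; accuracy figures on phantoms are optimistic bounds.
- No drift correction, internal standardization, or interference correction
  is implemented; ⁶⁴Zn/⁶⁶Zn correlation is the only interference check.
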