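# Methods

`ficollnmr` reimplements, on fully synthetic data, an NMR metabolomics
workflow for blood plasma that was separated on a Ficoll density gradient:
spectral processing with contaminated-region exclusion, supervised latent-
variable classification under Monte-Carlo cross-validation, a multilevel
(paired) variant for pre/post-anesthesia contrasts, and univariate
Wilcoxon/FDR/fold-change screening.

## The problem

Ficoll (a ~400 kDa sucrose–epichlorohydrin copolymer used in density-gradient
separation of blood) contaminates plasma and produces a broad, intense NMR
envelope centered at 3.80 ppm (effectively spanning 3.30–4.64 ppm) plus sharp
resonances at 1.81, 1.84, 2.26, 5.42 and 5.58 ppm. CPMG spin-echo filtering,
which normally suppresses macromolecule signals, does not remove the Ficoll
signals (its internal polymer dynamics defeat relaxation-based selection), so
the analysis must instead exclude the contaminated central region of the
spectrum and work with the restricted active area.

## Spectral processing

1. **Apodization/FT** — FIDs are multiplied by `exp(-π·lb·t)` (`lb` in Hz,
   default 1.0), Fourier transformed, and the real part is kept. The window
   is 1 at t = 0, so the total spectral sum is conserved exactly for any
   `lb`; each line's FWHM grows by `lb` Hz.
2. **Calibration** — the ppm axis is shifted so the reference feature (the
   anomeric glucose doublet, 5.24 ppm) sits at its nominal position. The
   reference is located as the height-weighted centroid of the two tallest
   local maxima in the search window when they form a plausible doublet
   (≤ 0.05 ppm apart, comparable heights), falling back to the single tallest
   maximum; sub-grid precision comes from a 3-point parabola. A flat window
   (nothing above the noise floor, estimated as median + 5·1.4826·MAD) raises
   `CalibrationError`.
3. **Bucketing** — 0.20–10.00 ppm is segmented into 0.02-ppm buckets
   (left-closed, right-open), each valued by the trapezoidal integral of the
   intensity over the bucket, evaluated through the cumulative integral so
   the bucket sum telescopes exactly to the window integral. This gives
   490 buckets.
4. **Exclusion** — buckets whose *center* falls strictly inside any excluded
   range are dropped; the default range (3.30, 6.00) removes 135 buckets and
   retains 355. (The lower bound is quoted both as 3.30 and 3.33 in the
   source material; 3.30 is the default and the bound is configurable.)
5. **Normalization** — each retained bucket row is divided by its total area,
   removing dilution and receiver-gain differences. Scale-invariant and
   idempotent by construction.

Phase and baseline correction are assumed done upstream by vendor software;
only an optional iterative polynomial lower-envelope baseline is provided
(off by default).

## Classification

**PLS-CA** — partial least squares against a one-hot class response
(mean-centered columns, no unit-variance scaling since the buckets are
already total-area normalized), followed by a Fisher linear discriminant on
the latent scores; prediction is nearest class in canonical space. The
per-variable influence on the decision is the product of the PLS rotations
and the LDA scalings.

**Multilevel PLS (MPLS)** — for paired designs each row is centered on its
subject mean; the two within-subject rows of a pair are exact negatives.
PLS-CA is then fit on the within-subject part with timepoint labels, so
between-subject variation is removed and only treatment-related variation
drives the model.

**Monte-Carlo cross-validation** — repeated random stratified train/test
splits (default 90/10, 500 iterations, seeded), pooled confusion counts, and
accuracy/sensitivity/specificity in percent with an explicit positive-class
convention (lexicographically first label unless configured). For MPLS the
resampling unit is the *subject*: a pre/post pair never straddles the split,
and a held-out pair is centered on its own pair mean before prediction —
within-subject information only, no leakage from training subjects. The PLS
component count is either fixed or chosen by an inner stratified 5-fold CV
over 1–10 components inside every training split (ties break toward the
smaller model).

A caution that the tests make explicit: the MC-CV accuracy of a *single*
cohort concentrates on a dataset-specific value whose spread across cohorts
is roughly `sqrt(0.25 / n_units)` — with 20 subjects a null cohort can
legitimately score 30% or 65%. Null-behaviour tests therefore either average
over several independent cohorts or use a cohort large enough (300 samples)
for the ±5% chance band to be meaningful.

## Univariate screening

Per metabolite: two-sided Wilcoxon rank-sum (unpaired contrasts) or
signed-rank on post − pre differences (paired contrasts); Benjamini–Hochberg
step-up adjustment across the metabolites of one contrast; significance at
adjusted p < 0.05. Rank-sum uses exact enumeration when the combined sample
size is ≤ 12 with no ties, otherwise the normal approximation with tie and
continuity correction. Signed-rank drops zero differences (classic Wilcoxon,
count reported) and enumerates all 2^n sign patterns with midranks for up to
14 nonzero pairs — valid under tied magnitudes, where textbook exact tables
are not.

Fold changes are reported as `-log2(median_A / median_B)`; the (A, B) order
is carried in the output metadata and a plain-language `direction` column
removes the sign ambiguity that plagues fold-change tables. Metabolite
relative concentrations are integrated signal areas over per-metabolite
quantification windows, divided by the sample's total spectral area over the
retained (exclusion-complement) window — the same total-area convention as
the bucket table.

Total-area normalization couples metabolites: a genuine concentration change
shifts the denominator and hence *every* normalized value. With the
default synthetic world the quantified metabolite lines are a minority of
the retained area, so the coupling from a 3-metabolite 2-fold effect is a
few percent — below the 10% between-subject variability but not zero. The
recovery tests that demand an *exact* significant set therefore screen the
known-truth concentration table (subject-level noise only); the end-to-end
spectral route is exercised by the multivariate recovery tests, where the
coupling is part of what PLS legitimately uses.

## The synthetic cohort generator

The generator emulates the three plasma spectrum types with component
weights (small-molecule, macromolecule): NOESY (1, 1), CPMG (1, 0.2),
diffusion-edited (0.1, 1); contaminant and drug signals always weigh 1,
reproducing the observation that CPMG does not filter Ficoll. One sample is:

* 20 named metabolites at textbook 1H shifts (Lorentzian multiplets, HWHM
  0.0025 ppm ≈ 1.5 Hz at 600 MHz), base concentrations roughly matching
  plasma relative levels (glucose dominant, aromatic amino acids low). A
  seed-dependent jitter (0.002 ppm on centers, 5% lognormal on levels)
  emulates cohort-level referencing/population differences while keeping
  libraries deterministic per seed;
* broad Gaussian macromolecular humps (lipids/glycoproteins at 0.90, 1.30,
  2.02, 3.21, 5.30 ppm) and a residual water band at 4.70 ppm inside the
  excluded window (its presence verifies that exclusion works);
* Ficoll contamination: the 3.80-ppm Gaussian envelope plus the five sharp
  lines, scaled per sample by a lognormal factor (σ = 0.3) around the design
  level — the batch-to-batch intensity variability is not quantified
  anywhere, so this is a declared guess;
* design effects: multiplicative per-metabolite group effects, a global
  multiplicative post-anesthesia decrease (default 0.85), drug peaks
  (a synthetic cefuroxime stand-in at 6.15 and 2.72 ppm, positions invented,
  placed outside the excluded window) added only to post samples;
* lognormal between-subject factors (σ = 0.10 per subject × metabolite) and
  additive Gaussian spectral noise (σ = 0.05 intensity units against peak
  heights of order 1–10).

Everything is a pure function of the design (including its seed); identical
designs give bit-identical cohorts. `synthesize_fid` inverts a rendered
spectrum to a complex FID (inverse FFT on the uniform grid), so the
apodization/FT path is round-trip testable: `process_fid(lb=0)` recovers the
spectrum to machine precision.

What the generator does **not** emulate: phase/shimming errors, 13C
satellites, ring-current or pH-dependent shift changes, peak-shape
distortions, correlated biological covariance between metabolites, or any
pulse-sequence physics beyond the three-weight abstraction. A green test on
this world establishes the statistical machinery, not instrument realism.

## Numerical choices

* Bucket membership for exclusion is tested on bucket centers with strict
  inequalities; integration is trapezoidal on the native grid via the
  cumulative integral (bucket sums telescope exactly).
* Subject-mean centering reconstructs the data to within one rounding ulp;
  tests assert at `1e-15` of the data scale (bitwise where inputs are
  dyadic).
* On the uniform periodic FFT grid, total-integral conservation is checked
  with the rectangle rule; trapezoid end-corrections are an artifact of
  treating a periodic signal as non-periodic.
* Undefined rates (zero confusion-matrix denominators) and undefined fold
  changes (non-positive medians) are reported as NaN, never as 0.
* Degenerate signed-rank inputs (all differences zero) return p = 1 with a
  degeneracy marker rather than an error.

## Pipeline

`run_pipeline` executes simulate (or load) → validate → process → classify →
screen, with per-stage seeds derived from the master seed by hashing
(`sha256(master:stage)`, reduced below 2^31), a config snapshot and hash
embedded in the report, and stage-named error propagation. The YAML config
round-trips exactly. Real data enters through the Bruker `1r`/`procs`
adapter or the tabular spectral-matrix format; no attempt is made to fetch
public repositories.

## Known limitations

* The real study's cohort accuracies (74–93% depending on spectrum type and
  contrast) are properties of the deposited clinical dataset and are *not*
  reproduced or asserted here; the synthetic world's accuracies depend on
  the declared effect sizes.
* PLS-CA canonical analysis is Fisher LDA on the score space; other readings
  of "canonical analysis" (e.g. CCA against the response) exist.
* The exact MC-CV geometry of the original analysis (split ratio, iteration
  count, component choice) is unreported; defaults here are common
  chemometrics practice and all reports carry their parameters and seed.
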