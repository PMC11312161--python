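# Methods

This note documents the statistical procedures implemented in `oleonir`,
the synthetic data model used to exercise them, and the numerical and
design choices a maintainer should know about.

## Scope and data model

The package targets a specific, classical calibration workflow: predicting
essential-oil constituent concentrations (% w/w in the peel oil) of intact
citrus fruit from 600–1100 nm diffuse-reflectance absorbance spectra
measured on a 2 nm grid (251 points), with fruit sampled across a
cold-storage time course. Spectra travel as a `SpectraSet` (a shared
`WavelengthGrid` plus per-fruit absorbance vectors); reference
concentrations as a long-format `ReferenceTable`
(sample_id, storage_day, constituent, concentration_pct). On-disk formats
are plain CSV; floats are written in shortest round-tripping form and read
back with correctly-rounded parsing, so file round trips are bit-exact.

## Pipeline stages

Stages run in a fixed, leakage-safe order:

1. **Window truncation.** The analysis window defaults to 663–961 nm,
   interpreted as inclusive bounds intersected with the measured grid —
   the 149 points 664–960 nm. (663 and 961 nm are not grid points; taking
   the interior intersection is the only reading that uses measured
   channels.)
2. **Scan averaging.** Repeated scans are averaged per fruit (arithmetic
   mean per wavelength) before any pretreatment, mirroring how multi-spot
   instruments report a fruit spectrum. Averaging is idempotent.
3. **PCA outlier screen.** Mean-centered PCA by SVD; Hotelling T² over the
   first k score dimensions (default k = 4) against the F-based limit
   k(n−1)/(n−k)·F_conf(k, n−k), and the Q residual against the
   Jackson–Mudholkar limit computed from the residual eigenvalues
   (confidence 0.95). Screening only *reports*; removal requires an
   explicit id list in the configuration, because thresholds on real fruit
   data are a judgement call.
4. **Rectangle trimming (optional, off by default).** Equal-width bins over
   the reference range; over-full bins keep the `cap` samples closest to
   the bin center (ties by sample id), and samples holding the global
   extremes always stay represented. This flattens a peaked concentration
   distribution so prediction error is more uniform across the range.
5. **Rank-ordered 5:2 split.** Samples sorted ascending by reference value
   (ties by sample id) are dealt out in a repeating
   5-calibration / 2-prediction pattern; any prediction sample holding the
   global minimum or maximum is then moved to calibration. The procedure
   is deliberately deterministic — no RNG — so a split is a pure function
   of the reference values, and the prediction range is always contained
   in the calibration range.
6. **Pretreatment.** One of raw, full MSC, or Savitzky–Golay second
   derivative, configured per constituent (defaults: MSC for nootkatone
   and geranial, 11-point second derivative for β-phellandrene, raw for
   limonene). The MSC reference is the calibration-set mean and is *never*
   refit on prediction data.
7. **PLS1 with PRESS factor selection** and evaluation (below).

## PLS and factor selection

`nipals_pls1_fit` implements classical NIPALS deflation with mean-centering.
For a single response the weight of each factor is the normalised
covariance direction Eᵀf, so no inner iteration is needed; a zero-norm
weight (exactly fitted y, or rank-exhausted X) truncates the model with a
warning rather than failing. Invariants checked in the test suite: unit-norm
weights, mutually orthogonal scores (1e-8), and agreement of the
coefficient-vector prediction path with the score-space path (1e-10). The
fitted values agree with scikit-learn's PLS implementation to better than
1e-6 relative on random problems; scikit-learn appears in the test suite
only as that independent oracle.

Cross-validation defaults to leave-one-out (contiguous-segment k-fold is
available), refitting the centering in every fold. For MSC pipelines the
scatter reference is by default fitted once on the full calibration set
(the classical practice of pretreating before modelling); a strict mode
(`strict_cv_msc`) refits the reference inside each fold for users who want
to quantify that small leakage. PRESS is accumulated for every candidate
factor count in a single NIPALS pass per fold.

Factor selection follows the Haaland–Thomas criterion: with h* the PRESS
minimiser, select the smallest h ≤ h* whose F(h) = PRESS(h)/PRESS(h*) is
below F₁₋α(n, n), α = 0.25. If PRESS(h*) is exactly zero the smallest h
reaching zero is returned. Note the direction of the α effect: raising α
lowers the acceptance quantile, so the selected count is non-decreasing in
α. `h_max` defaults to min(15, n/3); `fixed_h` bypasses selection entirely
(useful for recovery experiments where the question is "can enough factors
reproduce the truth", not "how many does CV pick").

## Evaluation statistics

With d = X − Y (measured minus predicted): bias = Σd/N,
SEP = √[(Σd² − (Σd)²/N)/(N−1)] (bias-corrected dispersion; reported as SEC
on calibration residuals), RMSEP = √(Σd²/N), and RPD = set SD / SEP. These
satisfy RMSEP² = SEP²(N−1)/N + bias² identically, which the tests assert at
1e-9 relative. SEC deliberately uses the same N−1 formula as SEP (not
N−h−1): the symmetric definition is what makes SEP:SEC ≈ 1 a meaningful
statement about matched set distributions, and it reproduces the published
ratio values. RPD is defined against the *evaluated set's* reference SD,
which reproduces the published RPDs (0.19/0.11 → 1.7, 0.90/0.59 → 1.5,
2.39/1.82 → 1.3) exactly at one-decimal rounding. Model grades follow the
Williams correlation bands with inclusive upper edges: r < 0.51 not
applicable, <0.71 poor, ≤0.80 very rough to rough screening, ≤0.90
screening / approximate calibration, above that quantitative.

Interpretation utilities locate local extrema of |regression coefficient|
above a prominence threshold (default 10 % of the maximum) and attach the
nearest literature band assignment within tolerance (chlorophyll 662/680,
protein 708/808/908, C–H fourth overtones 740/746, aliphatic C–H 827, oil
928, water ~961 nm; tolerances 4–14 nm).

## Storage-trend statistics

`duncan_mrt` implements Duncan's multiple range test on top of one-way
ANOVA. Critical ranges use the studentized-range quantile at Duncan's
protection level (1−α)^(p−1) for a span of p sorted means — computed from
`scipy.stats.studentized_range` rather than interpolated printed tables;
the classical 5 % table values (e.g. 2.95 at p = 2, df = 20) are reproduced
to two decimals in the tests. Unequal group sizes use the harmonic-mean
(Kramer) adjustment. The sweep applies range protection — sub-spans of a
non-significant span are never declared significant — which makes the letter
partition order-consistent. A Monte-Carlo helper calibrates the span-2
critical range under the null (all groups equal): for pairs of groups
adjacent in label order the false-difference rate is α by construction,
and the simulation confirms ~5 % at α = 0.05. (The rate for *rank-adjacent*
sorted means is far below α — those are the smallest gaps — so the span-2
size property is the meaningful calibration target.)

## Synthetic data model

`synthetic.generate_dataset` emulates the study design the package is
aimed at: 9 storage days (0–120 in 15-day steps) × 15 fruits, four
constituents drawn per fruit from truncated-at-zero normals with per-day
means/SDs following the published trajectories — nootkatone rising from
below the detection limit to 0.63 ± 0.22 % w/w at day 120, β-phellandrene
and geranial U-shaped with minima near day 60, limonene mirroring them
with a maximum of 84.61 % at day 60. "Not detectable" early nootkatone
days are drawn uniform on (0, 0.02 %); 0.02 % is the lower edge of the
published nootkatone calibration range and serves as the detection limit.
The limonene-vs-monoterpene anti-correlation is induced through the day
trends themselves rather than an explicit copula.

Spectra follow a Beer–Lambert mixture: per-constituent Gaussian bands
(nootkatone 740/746/827/930 nm — the distinctive C–H fourth-overtone pair;
β-phellandrene 908/930; geranial 925/950; limonene 827/930 nm), a
chlorophyll background at 680 nm whose amplitude decays exponentially with
storage day (degreening; time constant 30 days, 0.5 → 0.25 AU), a constant
water band at 960 nm (0.5 AU), then a multiplicative scatter factor
(1 + m), additive offset o and per-wavelength noise ε, all Gaussian with
SDs 0.05, 0.01 AU and 0.002 AU. Band amplitudes are scaled so each
constituent contributes a plausible fraction of a fruit spectrum at its
typical concentration (~0.04–0.25 AU). Every fruit has its own RNG
substream keyed on (seed, day, replicate, purpose), so any subset of the
dataset is reproducible independently.

What the generator deliberately does **not** emulate: radiative-transfer
scattering physics, temperature and moisture effects, instrument drift,
peel-thickness variation, and — most importantly — the weak, confounded
relationship between surface reflectance and oil-gland chemistry in real
fruit. Synthetic spectra encode the concentrations by construction, so
pipeline correlations here (r ≈ 0.99 for well-posed constituents) are far
above what intact-fruit calibrations achieve (r ≈ 0.67–0.82); passing
tests demonstrate that the *algorithms* are correct and leakage-free, not
that the spectroscopy works that well. Two features of real data are
reproduced qualitatively and are asserted in tests: zero-noise data are
recovered essentially exactly (r ≥ 0.999 with enough factors), and a
constituent with distinct bands plus a day-correlated pigment covariate
(nootkatone) consistently outperforms one whose bands are heavily
overlapped and whose relative variation is small (limonene).

On zero-noise synthetic data the spectra are an exact linear function of
the concentrations plus the day-dependent background, and raw or
derivative pipelines recover r = 1 to machine precision. The MSC pipelines
recover r ≈ 0.9995 rather than 1.0: dividing by a per-sample fitted slope
is mildly nonlinear across samples with different band compositions, so
"full MSC" on scatter-free data is a small model misspecification — a
known property of MSC, not an implementation artifact.

## Numerical choices and degenerate inputs

* NIPALS stops early (warning, truncated model) on zero-norm weights or
  degenerate scores; zero-variance y is an error.
* MSC requires |b| ≥ 1e-12; flat spectra are rejected as degenerate.
* Savitzky–Golay edges use the polynomial fitted to the nearest full
  window (no NaN padding), keeping the grid length stable for PLS.
  Derivative units default to per-index; per-nm rescales by step² and
  cannot change PLS predictions.
* Rank-ordered splitting and rectangle trimming break all ties by sample
  id, so both are deterministic for any input.
* Duncan's test with MSE = 0 and unequal means declares every pair
  different (the degenerate limit of a zero critical range); identical
  groups share one letter.
* All randomness flows from explicit seeds: the synthetic generator from
  its config seed, test fixtures from fixed seeds, and the acceptance
  script from `--seed`.

## Problem sizes used in checks

The packaged checks run at the study's own design size where that matters
(135 fruits for recovery and ranking experiments) and at small classical
sizes elsewhere (40 × 30 random PLS problems; 5 × 15 groups and 10,000
replicates for the Duncan calibration; 20 seeded pipeline runs for the
constituent-ranking experiment). These sizes give the Monte-Carlo
assertions comfortable margins at sub-minute runtimes.
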