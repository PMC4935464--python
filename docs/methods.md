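# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Conventions

All stimulus intervals and measurement windows are half-open
`[t_start, t_end)`: a sample exactly on a boundary belongs to the later
interval, which makes pulse assignment unambiguous.  Pixel coordinates are
0-based row-major, and ROIs are explicit flat-index lists (JSON sidecars),
not masks.  CSV files are comma-separated UTF-8 with a mandatory header.
Every pipeline output table carries the config hash and seed that produced
it, and a JSON run manifest records versions and outputs.

## Chemotaxis scoring and learning statistics

The chemotaxis index uses only animals that left the origin; plates with
fewer than `min_outside` (default 50) such animals are excluded so the
index reflects a population rather than a handful of animals.  The unit of
replication is the plate: animal counts are never pooled across plates.

The learning test is the interaction term of a two-factor linear model on
plate-level indices, fitted by OLS with sum-to-zero coding and type-II sums
of squares (statsmodels).  Type II was chosen because real assay designs
are unbalanced (replicate counts vary widely between cells); for the 2×2
designs analyzed here the interaction term coincides with the type-III
term under sum-to-zero coding, and type II is the more stable choice for
the main effects.  Tests are two-sided throughout; significance tiers
(p<0.05, p<0.001) are reported alongside exact p-values, never hard-coded
into logic.  A descriptive learning index (naive mean CI − conditioned
mean CI) is reported for plotting only.

Average plate concentration is plain dilution arithmetic,
`n_spots · V_spot · C_spot / V_plate`; with two 1-µl spots of 11 mM odor in
a 110-ml plate this gives 200 nM, and 20 µM for the 100-fold more
concentrated appetitive variant.

## Nuclear-localization quantification

The nuclear index is the ratio of ROI mean intensities,
F_nucleus / F_cytoplasm.  The ratio form was chosen as the simplest
statistic that increases with nuclear enrichment and is invariant to
overall image scaling; the bounded alternative (F_n − F_c)/(F_n + F_c) is
available behind a config switch (`nuclear_index_form: contrast`).  ROI
*means* (not integrated sums) are used so the index is robust to ROI size.
Optional background subtraction (off-cell median, config
`background_subtract`) is off by default.

Automatic segmentation is deliberately simple and deterministic: a global
Otsu threshold isolates the cell (largest connected component, holes
filled), a second Otsu threshold within the cell isolates the brightest
concentric subregion as the nucleus, and the cytoplasm is the remainder.
It assumes one bright cell on a darker background and a nucleus brighter
than the cytoplasm, which holds for the enriched condition it is meant to
segment; images with supplied ROIs bypass it entirely.

Distributions are compared with a hand-rolled exhaustive-sup two-sample KS
statistic (exact over the pooled support, ties collapse to single ECDF
jumps) and the asymptotic Kolmogorov p-value
Q_KS(D·√(n_a·n_b/(n_a+n_b))).  No finite-sample continuity correction is
applied; a warning is emitted below n = 5 per group.  The synthetic
populations model the AWC<sup>ON</sup>/AWC<sup>OFF</sup> ambiguity of the
assay: imaged cells are an unmarked 50:50 mixture and conditioning shifts
the index (1.0 → 1.5, between-animal SD 0.1) only in the
AWC<sup>ON</sup>-like half, so the KS comparison must detect a mixture
shift, not a clean location shift.  Cohort size follows the assay design
(80 cells per condition).

## Calcium dose-response analysis

**Normalizations.**  ΔF/F_max rescales each trace so the means of its
lowest and highest 5% of *sample values* map to 0 and 1; the "pixel
intensity" tails are read as tails of the integrated-ROI trace itself,
since the analysis operates on per-animal fluorescence time series.  The
tail fraction is config.  ΔF/F₀ divides by the sample nearest a fixed
baseline time (default t = 1700 s).  Whether that time is absolute or
protocol-relative is not externally fixed; it is treated as absolute
recording time, and the default recording (protocol ends at 1380 s plus
360 s of post-recording) places it late in the final recovery, where the
trace has returned near baseline.

**Metrics.**  Response magnitude is measured at the *first* pulse of each
concentration block (mean over [onset−2 s, onset) minus mean over the last
10 s of the pulse), reported positive for suppression, matching the sign
convention that attractive odor decreases AWC calcium.  Recovery half-time
is measured at the *last* pulse of the block: the peak magnitude is the
pre-pulse baseline minus the within-pulse minimum (the deepest
suppression, not the post-removal overshoot peak), and the half-time is
the first sample after removal at which f ≥ baseline − magnitude/2.  The
recovery window extends to the next odor onset (or end of trace); if the
level is not reached the result is a *lower bound* equal to the window
length, propagated as a flag — never silently as a number.  Half-times are
only computed when the suppression reaches the responder threshold
(default 0.075 on the normalized scale), and cohort half-time averages are
suppressed unless at least half of the animals responded.  Note the
half-time is defined relative to the local pre-pulse baseline, which after
repeated pulses sits below the resting level, so measured half-times are
shorter than the underlying recovery time constant times ln 2; the τ·ln 2
identity holds exactly (to one sample period, verified at 2/10/50 Hz) for
isolated exponential recoveries.

**Dynamic-range shift.**  Detection threshold = lowest concentration whose
cohort mean magnitude exceeds the responder threshold; saturation = lowest
concentration reaching 90% of the fitted Hill plateau; EC50 from a
least-squares Hill fit `A·c^h/(c^h + EC50^h)` performed in log10
concentration (bounded, initialized at the half-max crossing).  All three
are conditioned/naive ratios.  Welch t-tests (Welch–Satterthwaite df)
compare cohorts per concentration.

## Reversal detection and optogenetic statistic

The original tracking software is unpublished, so the detector is a
defined stand-in with all thresholds exposed: an onset is a heading change
greater than `angle_threshold` (150°) relative to a smoothed run heading,
sustained for `min_duration` (1 s); onsets closer than 2 s are one event.
Implementation details that matter: headings come from lightly smoothed
centroid differences (0.75 s window); the reference run heading is an
exponential circular average updated *only* from forward-coherent samples
(within 90° of the reference) so that mid-flip samples cannot drag it; a
bout ends when the heading returns within 90° of the reference; the
reference re-anchors if it receives no update for 3 s, and bouts are
force-closed after 8 s (reversal bouts are seconds-long).  Stationary
tracks (median speed < 0.01 mm/s) yield no events.  Fidelity to the
original detector cannot be verified — only internal consistency against
the generator's ground truth (hit rate ≥ 0.9, false discovery ≤ 0.1 under
the default study conditions).

The per-pulse statistic counts onsets in [light-on, +20 s) minus onsets in
[light-off, +20 s), the after-window abutting the stimulation window,
summed over animals; pulses 6–10 of the ten-pulse schedule are analyzed
(the later pulses, once the response has stabilized), the per-pulse mean is
the trial-level value, and trials — not animals — are the replication unit
for the Welch comparison.

## Synthetic-data generators

The generators reproduce the statistical structure the analyses assume,
with known ground truth; they are not biophysical models.

* **Plates**: multinomial end-point draws over the four zones — the index
  depends only on end-point counts, so no spatial walk is simulated.
  Scenario probabilities give naive CI ≈ 0.66 and conditioned CI ≈ −0.05.
* **Calcium traces**: piecewise first-order kinetics.  During odor at
  concentration c the trace relaxes toward f₀(1 − d(c)) with
  d(c) = d_max·c^h/(c^h + EC50_eff^h); the on-time constant (2 s) is a free
  choice since on-kinetics are not otherwise constrained.  After removal it
  relaxes back with τ_rec, plus an alpha-function overshoot (amplitude
  proportional to the evoked depth) and, optionally, a damped sinusoid to
  emulate the oscillating-mutant phenotype (off by default).  Conditioning
  acts through exactly three channels: EC50_eff = shift_fold·EC50 (default
  10), τ_rec scaled by 0.4, overshoot scaled by 0.5 — with all three scales
  at unity, conditioned and naive traces are bit-identical.  Defaults:
  f₀ = 1, EC50 = 200 nM, h = 1, d_max = 0.9, τ_rec = 25 s, overshoot 0.08,
  additive Gaussian noise SD 0.02, 10 Hz sampling (the imaging rate is not
  externally fixed and is exposed as config).  Overshoot amplitudes are
  free parameters, not calibrated to data.
* **Cell images**: concentric disks (cell radius 0.35·size, nucleus
  0.12·size) whose mean-intensity ratio equals the target exactly before
  noise; ROIs are returned as ground truth.
* **Tracks**: persistent runs at 0.15 mm/s with heading diffusion
  (10°·√s), 4 Hz sampling, 0.005 mm centroid noise.  Reversal initiations
  are a piecewise-constant-rate Poisson process (r_base = 2/min,
  r_stim = 10/min inside light pulses); a bout flips the heading 180°, lasts
  1.5 s plus an exponential tail (mean 2.5 s total), and ends with a small
  course change (SD 25°).  Initiations are suppressed while a bout is
  ongoing — a reversing animal cannot initiate another reversal — which
  introduces a dead time: the realized onset rate is r/(1 + r·E[bout]),
  and the closed-form expectation used as a test oracle carries this
  correction.  The floor on bout duration exists so every true bout is
  long enough to satisfy the detector's persistence requirement; without
  it, sub-second bouts would be undetectable by construction.

What the generators do **not** emulate — photobleaching, motion artifacts,
focus drift, odor-delivery delays, posture-dependent centroid jitter,
omega turns, plate-edge effects, inter-animal parameter heterogeneity
beyond the modeled channels — bounds what passing tests show: the pipeline
recovers the programmed effects under the assumed noise structure, not
under all real-data pathologies.

## Statistical kernels

Welch t is computed from the explicit formula with the Welch–Satterthwaite
df; two zero-variance samples with equal means return t = 0, p = 1 by
convention, and with unequal means raise (degenerate df).  The ANOVA
kernel delegates the fit to statsmodels but validates the design first
(≥2 levels per factor, ≥2 observations per cell, empty cells named in the
error).  The KS p-value is the plain asymptotic Kolmogorov survival
function; an exact/permutation small-sample p is out of scope.  All
kernels are pure: identical inputs give bit-identical outputs.

## Problem sizes and runtime

The study conditions are: 24 animals per calcium arm (six concentrations,
~1740-s traces at 10 Hz), 80 cells per nuclear condition (48×48 px), 7
trials × 20 animals × 1200 s per optogenetic group, 10 plates × 120
animals per chemotaxis cell.  Repetition counts in the acceptance checks
(100 seeded cohorts for the KS detection rate and the reversal-statistic
sign behavior, 20 seeds for dose-response direction checks at 8
animals/arm) keep the full test suite and the acceptance script in the
tens of seconds on one core.

## Known limitations

* The nuclear segmentation assumes a nucleus brighter than the cytoplasm;
  naive-like cells (index ≈ 1) are not segmentable without supplied ROIs.
* The asymptotic KS p-value is anti-conservative for very small samples
  (warned below n = 5) and omits the continuity correction some packages
  apply, so p-values differ from theirs at extreme D even though D itself
  is exact.
* The Hill-fit EC50 ratio inherits a small upward bias (a few percent)
  from measuring magnitudes on each trace's own 0–1 scale.
* The reversal detector is an internal standard, not a reimplementation of
  any published tracker; thresholds are config and results should be
  reported with them.
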