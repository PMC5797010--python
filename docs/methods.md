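# Methods

`qscreen` implements the analysis layer of a quantitative high-throughput
screening (qHTS) cell-viability campaign: every compound is tested as a full
titration, so concentration–response curves (CRCs) come directly out of the
primary screen, and activity decisions combine curve quality, a signal-based
detection criterion, potency and efficacy. The package also contains a
synthetic-screen generator with planted ground truth, which is what every
quantitative guarantee in the test suite is measured against.

## Response model

All viability responses are expressed in percent activity, anchored plate-wise
at the intra-plate controls: 0 at the DMSO (neutral) level and −100 at the
positive-control level (a proteasome-inhibitor-class cytotoxic at a saturating
concentration). Sample wells are normalized as

    response = 100 · (value − mean_neutral) / (mean_neutral − mean_positive),

using sample means and n−1 standard deviations of the control populations
(means because the Z′ formula is defined on means; a median option exists but
is off by default). Fitting uses the four-parameter logistic (Hill) model in
log concentration,

    r(c) = s0 + (s_inf − s0) / (1 + (10^L / c)^h),   L = log10 IC50,

with r in percent activity. The reported IC50 is the *relative* IC50 — the
concentration at the midpoint of the fitted asymptotes.

One deliberate unit subtlety: the positive control itself retains a small
residual viability (5% by default in the generator), so a biologically
complete kill normalizes to 100/(1 − 0.05) ≈ −105.3%, not −100%. Planted and
fitted efficacies are therefore compared on the percent-activity scale
(`true_response_magnitude` converts ground truth to that scale); comparing a
fitted asymptote against a raw "percent viability loss" number would build in
a spurious ~5% bias.

## Plate quality control

Z′ = 1 − 3(SD_pos + SD_neu)/|Mean_pos − Mean_neu|. The absolute value in the
denominator is the standard Zhang definition; with a signed denominator a
cytotoxicity readout (positive mean < neutral mean) would yield Z′ > 1,
which is inconsistent with Z′'s role as a quality index bounded by 1.
Signal-to-background is mean_neutral/mean_positive. Layouts require at least
16 wells per control population so the SD estimates entering Z′ and the
six-SD criterion are stable; `control_stats` itself only demands 2.

## Curve fitting

`fit_hill` is a bounded multi-start least-squares fit (SciPy's trust-region
reflective solver behind our surface): bounds L ∈ [min tested − 2 decades,
max tested + 2], h ∈ [0.3, 10], s0 ∈ [−30, 30], s_inf ∈ [−150, 30]; three
deterministic starts with L at the tested-range midpoint and ±1 decade; the
lowest-cost solution wins, so fitting involves no randomness. Responses below
−150% are clipped first (they indicate control misestimation, not biology).
A fit is unconverged when the optimizer fails, the series is flat, or r² < 0
with no point beyond the 30% response floor. Degenerate inputs: < 5 points is
an error; duplicated points and point order do not change the result.

## Curve classification

Classes follow the qHTS convention — 1.x complete (both plateaus observed in
range), 2.x incomplete (upper plateau outside range), 3 single-point, 4
inactive, negative sign for signal-decreasing (cytotoxic) curves. The exact
subclass boundaries of the original screening software are conventions, so
every threshold is configurable (`ClassThresholds`), with defaults: response
floor 30%, lower-plateau tolerance 10 points, upper-plateau tolerance 10% of
the fitted efficacy, subclass .1 at efficacy > 80% with r² ≥ 0.9, demotion of
sub-30%-efficacy shapes to class 3. The decision cascade tests observed
points first (floor, single-top-point) and the fitted curve second
(plateaus, efficacy, r²), so unfittable-but-responding series degrade to
class 3 rather than erroring.

## Curve AUC

The activity summary used for profile heatmaps is the normalized area under
the fitted |response| over the tested log-concentration span (1000-point
trapezoid), scaled so a constant −100% response scores 100. Class-4 and
unconverged curves score 0. Integrating the fitted curve (not the raw
points) makes AUC monotone in efficacy at fixed potency and monotone as IC50
decreases at fixed efficacy — both are property-tested.

## Activity calling

A replicate is active when all four criteria hold (inclusive comparisons):
high-quality class (|class| ∈ {1.1, 1.2, 2.1, 2.2}); at least one raw well
beyond six neutral SDs from the neutral mean *toward the positive-control
level* (for a luminescence readout this is "six SDs below the neutral
population"; phrasing it directionally lets the same rule serve the
PI/Hoechst ratio, which rises on death); IC50 ≤ 10 μM; maximal fitted
response magnitude ≥ 65%. Published wordings mix strict and inclusive
comparisons at the cutoffs; inclusive was fixed once, and boundary ties are
measure-zero under the generator. Replicated assays use a 2-of-3 quorum
(single-replicate calls pass through unchanged); summary potency is the
median IC50 of passing replicates — the aggregation is not dictated by any
formula, the median is robust at n ≤ 3.

Categorization: pan-active = active in ≥ 17 panel lines; potent = active
with IC50 strictly below 100 nM somewhere; fibroblast-clean = not active in
the counter-screen line; selective for tumor type T = active in ≥ 2 lines of
T and in none outside T (the exclusivity clause makes "selective" disjoint
from pan-active whenever several types are present).

## Profile analysis

AUC matrices put 0 in inactive cells; log-IC50 matrices leave them missing
(grey in heatmaps). Row/column clustering defaults to complete-linkage
Euclidean — the original visualization environment does not record its
metric, so both are configurable. Missing values use pairwise-complete
distances rescaled to the full dimension (√(p/m · Σ over m shared cells)),
with pairs sharing fewer than 3 finite cells pushed to the maximum observed
distance; all-missing rows are dropped with a warning. Rows are sorted by id
before clustering so leaf order is deterministic and permutation-invariant.

Enrichment of target/indication categories among a hit set is the one-sided
hypergeometric upper tail against the background of screened compounds with
a non-empty annotation for that facet, with Benjamini–Hochberg adjustment
across the tested categories.

2D-vs-3D comparison uses Spearman rank correlation of log potencies over
compounds active (finite potency ≤ 10 μM) in both formats; censored
potencies are excluded from the correlation but kept in the four-way
concordance labels (concordant-active / concordant-inactive / 2D-only /
3D-only).

## Spheroid readouts

The 384-well spheroid assay is multiparametric: CellTiter-Glo luminescence,
PI and Hoechst mean intensities from imaging, and a caspase-3/7 channel, in
triplicate. The imaging viability statistic is the per-well PI/Hoechst
mean-intensity ratio, normalized per plate against the control-well ratios
(per-plate rather than per-screen, for consistency with how the luminescence
channel is normalized). Caspase activation is reported as percent of the
staurosporine positive-control anchor. CTG is the default calling readout
(better assay statistics in practice), with imaging as the secondary; both
reuse the identical 4-criterion rule and 2-of-3 consensus. Wells without a
formed spheroid (diameter below a configurable floor) or with non-positive
Hoechst signal are excluded before normalization, with warnings.

## Synthetic-screen generator

The generator is first-class, tested code; it defines the conditions every
guarantee is measured under.

* **Plate formats**: 1536-well (32×48) monolayer plates with 32 DMSO and 32
  positive-control wells by default (control counts are unpublished for the
  original screens, so they are configurable with a 16-well floor); 384-well
  spheroid plates with 16+16 controls. Dilutions: 11-point 1:3 and 8-point
  1:5 series topping at 46 μM.
* **Noise model**: multiplicative Gaussian, signal = baseline · v(c) · (1+ε),
  ε ~ N(0, cv), truncated at 0 — luminescence CVs scale with signal, and no
  published noise model exists to copy. Default well CV 5%, a typical value
  for a well-behaved CellTiter-Glo assay. Each physical plate draws its own
  baseline (log-normal, 15% CV) so plate-wise normalization has real
  plate-to-plate variation to remove (a tested invariant).
* **Archetypes** (largest-remainder rounding gives exact counts per mix):
  `complete_full` (efficacy 85–100%), `complete_partial` (40–75%,
  straddling the 65% cutoff), `incomplete` (IC50 drawn within half a decade
  below the top tested concentration, Hill 0.8–1.1 — placed so at least two
  points exceed the 30% floor while the upper plateau stays out of range,
  producing class −2 curves by construction), `single_point` (steep curve
  centred at the top concentration → class −3), `inactive`. Complete
  archetypes draw Hill slopes in [0.8, 2.0] and IC50 log-uniform over the
  configurable range (default 1 nM–30 μM) *clipped to the
  plateau-observable band* for the drawn slope (concentration-ratio margin
  15×) — without the clip, an IC50 near the range edge would produce a
  genuinely incomplete curve and the archetype would not mean what its name
  says.
* **Spheroids**: one latent dead fraction d(c) per well drives all four
  channels (luminescence ∝ 1−d, PI ∝ floor+d, Hoechst near-constant,
  caspase ∝ apoptotic fraction). The 3D IC50 is the 2D value times a
  configurable shift (default 3×; published 2D/3D comparisons report low to
  moderate correlation without a quantitative model, so the shift is a
  single interpretable knob). Non-apoptotic killers scale the caspase
  coupling down (5% of d), reproducing the high-PI/low-caspase pattern.
* **Determinism**: everything is driven by `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical libraries and plates.

What the generator does *not* emulate — and what passing tests therefore do
not show about real screens: spatial plate artifacts (edge/row/column
effects; the pipeline deliberately applies no spatial correction),
compound-specific noise or dispensing failures, cross-well contamination,
assay-interference compounds (luciferase inhibitors, autofluorescence), and
cell-line-specific response heterogeneity beyond a log-normal potency shift.
Sensitivity/specificity numbers measured here are upper bounds for real
data.

## Problem sizes and tolerances

The validation suite uses 500-compound screens for fit-recovery and
caller-fidelity measurements, 50 compounds per archetype for the
classification confusion matrix, ≤ 6-row matrices against the brute-force
clustering oracle (exhaustive agglomeration is O(n³) and serves as an
independent reference, not a production path), N ≤ 30 for exact rational
hypergeometric enumeration, and 10-compound triplicate spheroid panels.
These sizes make every oracle exactly computable while keeping the whole
suite and the acceptance script comfortably reproducible on a laptop.
Floating-point comparisons: enrichment p-values match enumeration to 1e-12;
noise-free round trips are asserted at 0.01–0.05 log-unit tolerances
(optimizer termination, not statistical, error); noisy-recovery assertions
use medians, which are stable across seeds at n = 500.

## Known limitations

* Censoring is handled by rule (class/potency cutoffs), not by a censored
  regression model; potencies near the top tested concentration are
  extrapolations of the fit.
* No outlier masking during fitting; a single corrupted well shifts the fit.
* The enrichment background ("annotated screened compounds") is the natural
  choice here but differs from genome-wide enrichment conventions; K, k, n,
  N are all reported so any other background can be recomputed.
* Pairwise-complete distances are not a metric in the strict sense when
  overlap patterns differ wildly; with the default AUC matrices (no missing
  cells) this never engages.
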