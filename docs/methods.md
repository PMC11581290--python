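# Methods

This note documents the quantitative model behind `gelflq`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions, in enough detail to audit or adapt
the pipeline.

## Signal model and coordinate conventions

A gel image is a matrix of non-negative gray values (AU) with light bands
on a dark background (8- or 16-bit). A *lane profile* is the sequence of
mean gray values across a fixed-width rectangular box, one value per pixel
position along the migration axis. Two conventions are fixed package-wide:

- **Bottom-first indexing.** Index 0 is always the migration front (gel
  bottom); the last index is the well side. Readers normalize orientation
  via a `flip` flag, and images carry a `bottom_edge` label that rotation
  updates. All downstream quantities are per index; physical distance is
  used only to validate that an export is uniformly sampled (mixed-unit
  files are rejected rather than guessed).
- **Mean, not sum, across the box.** Profile values are arithmetic means
  across the box's short axis, matching the plot-profile convention of
  interactive tools and keeping profile magnitudes comparable to
  spreadsheet exports. Since all scores are ratios of AUCs taken with the
  same box, the mean-vs-sum choice cancels; it matters only for comparing
  raw AU values across sources. Boxes are whole-pixel; all lanes of a gel
  must use an identical box so profiles align index by index.

## Background gradient

The model is strictly per-lane and linear along the migration axis —
brighter toward the wells — which matches what gel-documentation images
show; no 2-D background surface is attempted. Two estimators:

- **Measured** (`background_from_lanes`): pointwise mean of one blank lane
  or ≥3 narrow inter-lane strips (a warning below 3 when averaging). The
  *raw* per-index means are subtracted; the OLS line through them is
  reported for diagnostics only. Rationale: the raw profile captures local
  texture a line would miss, and averaging already suppresses noise.
- **Computed** (`background_computed`): when no blank lane exists, the mean
  gray value of the bottom `edge_fraction` of indexes and of the top
  `edge_fraction` are joined by a straight line, each mean anchored at its
  segment's centre index. Centre anchoring reproduces a perfectly linear
  gradient without bias; anchoring at the profile ends would leave a
  systematic offset and tilt of about half an edge segment. Default
  `edge_fraction = 0.05` (5% of indexes per end) — small enough that
  products and ladder bands stay clear of the segments on typical layouts,
  large enough to average noise; it is a parameter because band layouts
  vary. The interpolated line is what gets subtracted for this estimator.

Subtraction is index-wise and floored at 0: stain fluorescence cannot be
negative, and AUCs must be non-negative. Over-subtraction is therefore
clipped, which slightly biases near-zero baselines upward; this is
irrelevant to zone ratios but is the reason baseline flatness checks in the
tests subtract the generator's exact gradient.

## Zoning and integration

The dominant product is the lane's global maximum (ties broken toward the
smallest index — the most-migrated position, the conservative choice for
degradation). The **peak zone** is the half-open window [m−w/2, m+w−w/2)
with default width w = 20 samples. A window "of 20 indexes around the
maximum" cannot be both 20 samples long and symmetric-inclusive (±10
inclusive is 21 samples); 20 samples is taken as authoritative and the
right endpoint is dropped. The width is configurable because the
appropriate window scales with gel resolution. Near a profile edge the
window is clipped, never re-expanded on the other side.

The **degradation zone** is [floor, peak.start): only the low-molecular-
weight side. Signal above the peak window (high-MW side) is integrated
separately and reported (`high_mw_auc`) — useful for synthesis doublets —
but enters no score by default. The floor defaults to 0 and can be raised
to exclude primer or dye fronts.

Zone signal is integrated by the trapezoidal rule with unit index spacing;
windows with fewer than two samples have zero area. Note the two zones are
disjoint half-open windows, so the segment between the degradation zone's
last sample and the peak window's first sample is counted in neither; with
20-sample windows this is a sub-percent effect and keeps window bookkeeping
unambiguous.

For total RNA, the two most prominent local maxima at least
`min_separation` (default 20) indexes apart are taken as 18S (lower index)
and 28S (higher index). Prominence-ranked greedy selection is used — of two
maxima closer than the separation, the less prominent is skipped. Each peak
gets its own window; the 28S degradation zone runs from the end of the 18S
window to the start of the 28S window, the 18S zone from the floor to the
18S window. Whether real degradation zones should stop at a dye-front
cutoff rather than index 0 is layout-dependent; the floor parameter covers
both readings. No Gaussian-mixture deconvolution is attempted: zones
integrate raw signal.

## Scores

With peak and degradation AUCs in hand, the single-product preservation
score is

    P = AUC_peak / (AUC_peak + AUC_degradation)  ∈ (0, 1],

equal to 1 for fully preserved product and driven down both by loss of
peak signal and by growth of the smear — the two ingredients of
degradation. This particular combination is a design choice of this
package: it is bounded, dimensionless, uses exactly those two ingredients,
and reproduces the expected qualitative behaviour (monotone decline with
degradation, reduced replicate variance after normalization). Because
different labs weight the ingredients differently, the formula is
injectable via `ScoringOptions.strategy`.

Normalization divides by the control lane's value (fold change), so the
control's normalized peak AUC, preservation and combined scores are exactly
1 by construction. Normalization cancels lane-level gain differences
(exposure, staining), which is why it reduces replicate scatter; the test
suite checks the coefficient of variation shrinks under simulated gain
jitter.

For total RNA: preservation = (18S AUC / control 18S AUC) × (28S AUC /
control 28S AUC); the combined score is Π_k P_k / P_k(control) with P_k the
per-peak single-product score, so it reduces to normalized preservation for
single-peak lanes and additionally penalizes each subunit's degradation
zone. Denominators are floored at 10⁻¹² so division by zero surfaces as a
clean "control lane has no measurable signal" error.

## Molecular-weight calibration

Migration distance is linear in log size over a gel's resolving range, so
under bottom-first indexing `size(x) = a·e^(b·x)` with a, b > 0. Ladder
band positions are detected by prominence (same greedy rule as above,
default `min_separation` 8) and paired with the manufacturer-declared sizes
— always user-supplied, never inferred. The fit is OLS of ln(size) on
index; R² is the log-scale coefficient of determination. The log-linear
estimator is exact for noise-free data, numerically stable, and weights
relative (not absolute) size errors — appropriate since gel size accuracy
is multiplicative. A direct nonlinear least-squares refinement is available
behind a flag for sensitivity checks. Extrapolation outside the fitted band
range is permitted (degraded fragments migrate past the smallest band) but
flagged (`mw_extrapolated`). Peak shift is reported both as
control-minus-sample size difference (nt) and as the sample/control ratio;
which one a given figure plots is a presentation choice, so both are
always computed.

## Statistics

Time-course comparisons use classical one-way fixed-effects ANOVA followed
by Tukey HSD (Tukey–Kramer for unequal group sizes), with stars at
adjusted p < 0.05/0.01/0.001. Repeated-measures structure in time courses
is ignored — a documented limitation, not an oversight: with N = 3 gels per
group a mixed model is not estimable in any robust way. Degenerate input
(zero within-group variance everywhere) is an error, not a p-value.
Unadjusted pooled-variance pairwise t-tests are reported alongside so the
adjustment is visible; adjusted p ≥ raw p always. Correlations with
external integrity numbers are reported as the R² of an OLS fit with the
two-sided slope p-value (t, n−2 df), fitting whatever rows are supplied —
pooling replicates or not is the caller's decision.

## The synthetic generator

`synthetic` emulates exactly the structure the analysis assumes, with
known ground truth:

- bands are Gaussians centred at the migration-law index of their size,
  with width `band_sigma` (default 3 indexes) and peak amplitude
  `band_amplitude` (default 2000 AU on the 16-bit scale);
- degradation moves `smear_fraction` of each band's analytic mass
  A·σ·√(2π) into a smear over [0, band centre], densest at the migration
  front and decaying exponentially toward the band (`smear_decay` per
  index, default 0.02). Mass is conserved, so peak and degradation AUCs are
  reciprocal by construction, and at smear_fraction = 1 the lane no longer
  peaks at the product position — matching how fully degraded lanes look;
- a linear background from 0 AU (bottom) to 400 AU (top) by default, the
  gradient magnitude typical of 16-bit gel-doc images;
- additive Gaussian noise (default SD 5 AU), floored at 0; rendered images
  additionally round to integer pixels.

The default experiment is a triplicate 0/2/4/7/10-day time course of a
single ~2.1 knt product against a 10-band 0.5–9 knt ladder on 420-index
lanes, with the per-day dominant-product sizes and the migration law
(a = 74.215 nt, b = 0.013 per index) set to published measurements of such
a course, smear fractions growing 0.05 → 0.70 and amplitudes decaying
1.0 → 0.55. These problem sizes keep any single pipeline run in seconds
while leaving every detection step (band finding, argmax, zoning)
non-trivial. All randomness flows from the base seed; per-lane seeds are
base + lane ordinal, so any lane is individually reproducible.

What the generator does **not** emulate: lane tilt and "smiling",
compression, saturation, spatially correlated illumination, EtBr-specific
noise physics, and secondary-structure artefacts of non-denaturing gels.
Passing tests therefore demonstrate the pipeline's correctness on gels
that satisfy its geometric assumptions (straight lanes, per-lane linear
background), not robustness to acquisition artefacts — on real images
those must be handled upstream or by box placement.

## Numerical and degenerate-input conventions

- All-zero (no-signal) lanes, empty score-record lists, missing control
  lanes, ragged workbooks and non-numeric cells raise errors naming the
  lane/cell, never silent defaults.
- Lanes shorter than 30 indexes are rejected at scoring time (cannot host
  a 20-index window plus a degradation zone); short profiles are still
  representable for IO round trips.
- Score tables round-trip through CSV at full precision (shortest
  round-trip float representation on write, exact parsing on read).
- Ties: argmax ties break to the smallest index; equal-prominence maxima
  keep insertion order of the underlying sort (stable).
- The two-point calibration case bypasses regression (exact solution,
  R² = 1 by convention).

## Known limitations

- Single-gel relative scoring: scores are normalized within a gel; there
  is no cross-gel batch correction, so conditions to be compared must run
  on the same gel.
- The preservation formula is a declared design choice (see above), not a
  community standard; compare absolute score values only within one
  formula.
- No automatic lane finding or tilt correction; box placement is the
  caller's responsibility.
- Absolute concentration estimation is out of scope — scores quantify
  distribution of signal, not amount loaded.
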