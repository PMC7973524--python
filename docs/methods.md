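# Methods

## Problem and model

`hicloops` annotates chromatin loops and significant contacts in balanced
(bias-corrected) intrachromosomal Hi-C matrices. A loop appears as a focal
enrichment — a bright pixel cluster — against a background whose intensity
distribution depends strongly on genomic separation. The package therefore
models each matrix diagonal *d* (all pixels at separation `d × resolution`)
separately with a two-parameter Weibull distribution

    f(x; k, λ_d) ,  S(x) = exp(−(x/λ_d)^k_d) ,

which describes distance-stratified Hi-C contact frequencies better than
normal, log-normal or gamma alternatives and whose closed-form survival
function makes upper-tail p-values cheap and exact. The location parameter
is fixed at 0 because balanced intensities are non-negative.

Per pixel, `p = S(x)` is the probability of an equally or more intense
pixel under the diagonal's background. Benjamini–Hochberg correction is
applied **within each diagonal** (the model, and the optional scaling
adjustment, are both per-diagonal objects; a `bh_scope="matrix"` switch
corrects across all tested pixels instead). Optionally q-values are divided
by distance-decay ("scaling") coefficients — the per-diagonal mean contact
frequency normalised to 1 at the first diagonal of a selected range — which
relaxes the effective threshold at large separations; significance is then
judged against `scaling_q_value_trhd` instead of `q_value_trhd`.

Significant pixels are grouped with DBSCAN at neighbourhood radius 1
(Euclidean). On an integer lattice, distance ≤ 1 means 4-adjacency —
diagonal neighbours are √2 apart and are *not* neighbours — and with every
point a core point the clusters are exactly the 4-connected components of
the significant-pixel set (an 8-connectivity switch is provided, since the
original neighbourhood geometry cannot be pinned down beyond the stated
radius). Components smaller than `min_cluster` are noise. The cluster
centre — the brightest member by default (ties: lexicographically smallest
`(i, j)`), or the per-axis mean rounded half-up — gives the loop
coordinates.

## Tunable parameters

| name | default | meaning |
|---|---|---|
| `q` | 0.95 | upper quantile of a diagonal's values retained for the background fit; brighter pixels are trimmed as putative signal but still receive p-values |
| `q_value_trhd` | 0.1 | q-value threshold for significance (scaling off) |
| `adjust_by_scale` | off | divide q-values by the distance-decay coefficients |
| `scaling_q_value_trhd` | 0.1 | threshold on the adjusted q-value (scaling on) |
| `min_cluster` | 3 | minimum pixels per cluster |
| `filter_zeros` | off (presets: 2) | max zero pixels tolerated in the 3×3 centre neighbourhood |
| `filter_APA` | off (presets: 1.7–1.9) | min ratio of centre intensity to the mean of a 3×3 corner of the 11×11 window |
| `filter_PA` | off (presets: 1) | min mean ratio of the 8 centre-adjacent pixels to the same corner |
| `filter_intensity` | off (presets: 0.1–0.3) | min balanced centre intensity (units of the balanced matrix) |
| `max_distance` | none | upper bound on genomic separation of tested pixels (2 Mb default for EP contact scans) |

Named presets (`human-gm12878`, `mouse-ch12lx`, `celegans`, `yeast`) bundle
published per-species settings; the `default` preset keeps every optional
stage off, as the pipeline's own defaults do.

## Interpretation and numerical choices

Several parameter semantics are underdetermined by their names alone; the
package fixes them explicitly:

- **`q` is a fit quantile, not a significance level.** It is listed
  alongside the fitting stage and a separate `q_value_trhd` exists, so the
  only coherent reading is upper-quantile trimming of the fit sample: loop
  pixels must not inflate the background scale. Trimming deliberately
  biases the fit on a *pure-null* sample (≈5 % of mass removed), which is
  why calibration diagnostics use `fit_quantile=1.0`.
- **Zero handling.** Mappable zero pixels are excluded from fitting by
  default (`include_zeros` overrides) and always receive p = 1: a zero is
  never evidence of enrichment, and structural zeros from unmappable bins
  would distort the MLE. Bins with non-finite balancing weights are masked
  outright.
- **Minimum fit size 50.** Diagonals with fewer usable values after
  masking and trimming are unmodelled; their pixels get p = 1. A
  two-parameter MLE on fewer points is too unstable to calibrate.
- **BH batch.** Per diagonal, zeros included with p = 1 (they are tested
  pixels and make the correction conservative, never liberal).
- **APA/PA corner.** "The corner" of the 11×11 window is fixed to the 3×3
  patch pointing toward the matrix diagonal (shorter genomic distance),
  the conventional background patch of aggregate peak analysis; any of the
  four corners can be selected in `FilterConfig`.
- **`filter_zeros`.** Defined as the zero count in the 3×3 centre
  neighbourhood — the natural guard against loops called on unmappable
  speckle. Out-of-bounds cells are not counted.
- **Edge exemption.** A loop whose 11×11 window is clipped by the matrix
  edge is exempt from window-based filters (scored NaN) rather than
  dropped, avoiding a resolution-dependent bias against short-range calls.
- **Decay check.** Non-strict monotone rings: centre ≥ mean(ring 1) ≥
  mean(ring 2).
- **Cross-resolution merging** keeps the finer call when a fine and a
  coarse loop overlap reciprocally at ≥ 70 % of each span; anything else
  passes through.
- **Reciprocal overlap** is span-based by default (upstream-anchor start to
  downstream-anchor end); an anchor-wise mode is available because the two
  readings genuinely differ for nested or shifted loops.
- **Promoters** are the strand-aware 1 kb window upstream of the TSS,
  clipped at position 0; a contact with both anchors on promoters emits one
  record per direction, flagged bidirectional. The distance cap for EP
  contact scans defaults to 2 Mb and is configurable.
- **Tie-breaks.** Brightest-centre ties resolve to the smallest `(i, j)`;
  mean centres round half-up per axis. Together with seeded sampling in
  the random-distance filter this makes every run deterministic; the CLI
  writes no timestamps, so reruns are byte-identical.

## Synthetic data generator

`simulate` produces the only inputs the test-suite needs. Background
pixels on diagonal *d* are i.i.d. `Weibull(k, s0·(d+1)^−α)` — exactly the
model the caller assumes, with a power-law distance decay (α = 1 by
default, shape k = 1.8: a moderate-tailed value within the range reported
for distance-stratified contact-frequency fits; s0 = 1). A planted loop
multiplies a Gaussian-decay patch into the background (peak factor `fold`
at the centre, σ = (radius+1)/1.8) plus faint crosshair arms (25 % of the
peak excess, decaying) along the centre row and column. Multiplying a
`Weibull(k, λ)` draw by *m* yields a `Weibull(k, mλ)` pixel — a genuine
local enrichment of contact probability that leaves the distributional
family intact off-focus, which is what makes the null-calibration tests
meaningful.

What the generator does **not** emulate: TADs and compartments (block
structure), the correlation between neighbouring pixels of real Hi-C,
coverage heterogeneity, unmappable-bin patterns, and trans contacts.
Passing tests therefore demonstrate the statistical machinery is correct
under its own model assumptions, not that the defaults are optimal for any
particular organism's data.

Because planting is multiplicative on noise, a planted centre can draw a
dim value: per-pixel detection power at fold 8 is high but not 1, and the
ring-decay property holds in expectation rather than for literally every
planted focus. The clustering stage is what buys the pipeline its
recovery: the acceptance benchmark (500×500 bins, 20 loops, fold 8,
radius 1) yields median precision ≥ 0.8 and recall ≥ 0.9 at ±1-bin
tolerance across 10 seeds, with median 0 calls on loop-free matrices
across 20 seeds.

## Problem sizes

The validation suite fits 10,000-draw samples (50 replicates) for
parameter recovery, uses 500×500-bin matrices (20 null seeds, 10
planted-loop seeds) for calibration and recovery, 1,000 random pixel sets
for the clustering oracle and 1,000 random vectors for the BH oracle —
sizes at which every Monte-Carlo margin in the tests is comfortable while
a full run of suite plus acceptance script stays in the low minutes on one
core.

## Known limitations

- The per-diagonal independence assumption ignores spatial correlation of
  real Hi-C noise; on real data the effective false-discovery rate can
  exceed the nominal BH level, which is precisely why the score filters
  exist.
- Upper-quantile trimming (`q < 1`) makes p-values slightly
  anti-conservative under a pure null; with clustering (`min_cluster ≥ 2`)
  the effect on called loops is negligible (median 0 false loops), but
  single-pixel significant-contact lists at `q_value_trhd = 0.1` do
  contain a sub-percent false-positive rate.
- Unmodelled short diagonals near the matrix edge and the `min_fit_size`
  floor mean very small matrices (≲ 60 bins) are mostly unmodelled.
- APA/PA scores on single loops are noisy (CV comparable to the pixel
  noise); thresholded filtering trades some true-loop attrition (~10 % at
  fold 8) for smudge removal, as quantified in the filter tests.
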