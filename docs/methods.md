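# Methods

## The gene-ratio polarization statistic

For a gene with count $a$ in an astrocyte (AC) spot and count $b$ in an
adjacent blood–brain-barrier (BBB) spot, the gene ratio is
$b/(a+b)$ — the fraction of the pair's transcripts on the vessel side,
interpreted as the share of the gene's mRNA trafficked toward the
astrocyte endfoot. An AC spot with several BBB neighbours takes the
maximum over neighbours (the most-polarized reading). The statistic is
descriptive: it assumes the paired spots capture one astrocyte/endfoot
compartment each, and makes no claim about transport mechanism.

Ratios are computed on **raw counts** within the matched pair. The two
spots sit next to each other on the same section, so library-depth
differences are modest and cancel to first order inside the ratio; a
depth-normalization flag exists but is off by default. 0/0 pairs carry
no information and are dropped rather than imputed as 0 — imputation
would bias the polarization estimate of low-expression genes downward.
Fold changes are ratios of group means, matching the convention of
reporting a single fold-change number per group comparison; records are
pooled across sections by default (a per-sample-averaging flag exists,
but with one section per group the pooled analysis is the informative
one).

## Gating and pairing

Gates use raw detection (count strictly above 0 by default) for
Gfap/Aqp4 (AC) and Pecam1/Flt1 (BBB). CSF-facing regions that express
astrocyte markers without being perivascular (glia limitans, ependyma,
choroid plexus) are excluded from AC, and the choroid plexus from BBB;
the exclusion lists are free-string configuration, not hard-coded
anatomy. A spot passing both gates is labelled BBB (`overlap_policy =
"bbb"`): treating the mixed spot as vessel avoids counting the same
astrocyte soma on both sides of the ratio. `"ac"` and `"drop"` policies
are selectable.

Spots live on a Space-Ranger-style hex lattice: position `(r, c)` valid
when `r + c` is even, neighbours `(r, c±2)` and `(r±1, c±1)`, pixel
coordinates placing adjacent centres 100 µm apart. Pairing uses one
lattice step by default — the conservative reading of "adjacent" — and
is configurable (`max_steps`) because astrocyte processes can span
roughly two spot pitches. Pairing never crosses sections.

## The synthetic generator

`synthdata.generate_tissue` emulates the study conditions: one section
per group (WT, APP/PS1, APP/PS1+MOX), a hex lattice with contiguous
region bands, vessel spots placed uniformly at a configurable density
(default 0.10), and astrocyte spots next to them.

The allocation model is the core. For every allocated gene and every
AC–vessel pair, a total transcript count is drawn as negative binomial
(mean 20, dispersion 10 by default; `math.inf` gives the Poisson limit)
and split **binomially**: a fraction π to the vessel spot, 1−π to the AC
spot. Two consequences are exact, not asymptotic:

* the conditional expectation of the observed ratio given a positive
  pair total is π, for any dispersion (a binomial split conditioned on
  the total is how a Poisson pair with means πT and (1−π)T decomposes,
  and the construction carries that property to the NB case);
* pair totals are invariant to π (allocation conservation).

Pairing at generation time is **one-to-one**: each vessel claims at most
one astrocyte neighbour, and (by default, `single_neighbor_only`) only
neighbours adjacent to no other vessel are eligible. This matters
because the analysis reads the vessel *spot* count: if one vessel served
several astrocytes, each astrocyte's ratio would see the pooled
endfoot counts of its siblings and the estimator would no longer target
π. With `single_neighbor_only=False` astrocytes may abut extra vessels,
exercising the analysis-side max-over-neighbours rule.

Group effects multiply π (default δ = 0.66 for APP/PS1, δ′ = 0.9 for
APP/PS1+MOX, applied to all allocated genes except Gfap; per-gene effect
dicts are supported and used for screening simulations). Effective
shares are clipped to [0, 1] and reported in the returned truth table.

Marker realism: vessel spots draw Pecam1/Flt1 counts, paired astrocytes
draw their Gfap/Aqp4 from the allocation model, and a noise floor raises
any zero marker count to 1 so every generated vessel/astrocyte spot
passes its gate. At the default pair mean of 20 the floor touches well
under 1% of spots and perturbs the mean ratio by ≲0.002. A small
fraction of isolated "orphan" astrocyte-like spots (3%) is added away
from vessels to exercise the perivascular filter, and background genes
with lognormal mean structure (shared across groups) provide material
for expression-bin controls and differential-expression tests; per-group
mean shifts can be injected for specific background genes.

What the generator does **not** emulate: real anatomy (regions are
equal row bands), cluster structure, whole-transcriptome correlation,
spot-size/segmentation effects, or mixed-compartment spots beyond the
marker-overlap case. Passing recovery tests therefore demonstrates that
the estimators measure what they claim under the stated sampling model,
not that real tissue satisfies that model.

## AEG screening cascade

Marker stage: astrocyte mean over the maximum other-cell-type mean,
strictly greater than 100. A denominator of exactly zero (perfectly
astrocyte-specific gene) is replaced by `1e-6 ×` the table maximum so
such genes pass instead of dividing by zero. Endfoot stage: ratio > 0 in
strictly more than 60% of perivascular AC; the denominator is all
perivascular AC of the reference population (WT by default — the
healthy baseline defines "endfoot-positive"; configurable), so spots
where the gene is undetected on both sides count against it.
AD stage: |fold change − 1| > 0.15, unsigned by default to keep the
rule symmetric (a decrease-only mode is a flag; in disease simulations
decreases dominate anyway). The subset chain
`ad_related ⊆ aegs ⊆ markers` holds by construction.

The counts this cascade produces on real deposited data depend on the
external single-cell reference and annotation choices; the package
treats the cascade logic, not those counts, as the testable object, and
ships a clearly-labelled synthetic stand-in reference generator.

## Gene-set (module) scores

Counts are depth-normalised to 10,000 per spot and log1p-transformed.
Genes are ranked by average expression and cut into 24 equal-count bins;
each set gene contributes a control term — the mean expression of up to
100 genes drawn from its own bin without replacement (the whole bin when
it has ≤100 genes). The spot score is the mean over set genes minus the
mean of the per-set-gene control terms. Averaging per-gene control means
(rather than pooling a unique union of controls) keeps every bin
weighted by how many set genes fall in it; with the union, sets
concentrated in few bins acquire a bias of the order of the
between-bin expression spread, and random-set scores stop centring on
zero. The per-gene form also makes small fixtures exactly
hand-computable (set mean minus bin mean). Scores are deterministic
given the seed and invariant to gene order within a set.

The 0.8 score threshold used for the thresholded group comparison is a
reporting convention, config-exposed, with no claimed optimality.

## Statistics

One-way ANOVA and LSD post-hoc tests are written out from their sums of
squares (LSD: pairwise t statistics on the pooled within-group mean
square and its degrees of freedom), Benjamini–Hochberg is the step-up
construction, and Pearson fits delegate to the standard least-squares
routine; all are verified against independent brute-force
implementations to 1e-10 in the test suite. Degenerate inputs are
resolved explicitly: all-identical data give F = 0, p = 1; internally
constant but different groups give an infinite F and p = 0; zero
variance makes a correlation undefined (an error, not a NaN).

The differential-expression screen is a two-sided Wilcoxon rank-sum test
on depth-normalised expression with BH adjustment (Bonferroni
selectable) and the filter |FC| > 1.5 (two-sided on the log scale) with
adjusted p < 0.05. This is a deliberately transparent test: the
original count-model machinery used for such screens is out of scope
here, and the filter logic — which is what downstream stages consume —
is unchanged by the substitution.

qPCR relative quantification is the textbook 2^(−ΔΔCt).

## Vessel-coating quantification

"Positive" pixels are those strictly above the (100−p)th intensity
percentile, p = 1 by default, computed over the whole field (not per
vessel). Vessels are 8-connected CD31-positive components that enclose
a hole of at least `min_lumen_px` pixels (a vacuole; filled blobs are
rejected). The perimeter is the outer boundary of the hole-filled
footprint — the abluminal face where endfeet sit. A vessel's coating
fraction is the share of perimeter pixels within `pairing_radius_px`
(default 3 px) of AQP4-positive signal; the quarter rule is strict
(fraction > 0.25). The pairing radius is the one genuinely free spatial
parameter — the quarter rule and the 1% threshold say nothing about how
close "surrounding" signal must be — so it is config-exposed and
recorded in run manifests. A quadrant-based reading of "more than a
quarter" would be an alternative; the perimeter-fraction reading is
implemented because it is continuous and strictly contains the
quadrant rule's information.

The synthetic field generator paints AQP4 arcs on each vessel's own
perimeter (as detected by the package's detector on the clean CD31
channel) and trims the arc until the covered-pixel count matches the
requested fraction, so noise-free recovery is exact to one perimeter
pixel. Requested fractions below roughly one pairing-radius worth of
pixels (~7 px of a ~65 px perimeter) cannot be represented exactly by a
nonempty arc; the achieved fraction is stored in the field annotations.
Region sampling (six 0.2 mm squares by default on real fields) is seeded
uniform placement without overlap; regions with no vessel are flagged
and skipped.

## Problem sizes and numerical choices

Recovery analyses run at 2000 perivascular AC per group (lattice
240×240, vessel density 0.12), 200 candidate genes with 20 true effects
for the screening benchmark, 1000 spots per group for score
calibration, and 100-instance oracle sweeps for the statistics — sizes
at which the quantities of interest have standard errors an order of
magnitude below the recovery tolerances used in the tests (±0.05 on
fold changes). Ties in the max-over-neighbours rule break toward the
lowest neighbour barcode; all randomness flows from explicit integer
seeds, and rerunning any stage with the same inputs is byte-identical.

## Known limitations

* The gene ratio conflates transcript allocation with any systematic
  AC/BBB capture-efficiency difference; the synthetic model has no such
  difference, real data might.
* One section per group means group and section are confounded, as in
  the emulated design; the per-sample flag only becomes meaningful with
  replicate sections.
* The screen's endfoot-positive fraction uses detection (> 0), which is
  depth-sensitive at very low expression.
* The IF generator draws idealized annuli; irregular vessel shapes are
  handled by the quantifier but not exercised by the generator.
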