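# Methods

This note documents the models, parameter choices and numerical details
behind each stage of the `holosphere` pipeline, and what the synthetic-data
generator does and does not emulate.

## Exact-mass chemistry

**Constants.** Atomic masses and isotopic abundances are IUPAC 2013 values
frozen as literals in `holosphere.constants` so every computed mass is
bit-stable. Adduct mass shifts are electron-corrected (m_e = 0.000549 Da
folded into the shift), so `[M-H]-` subtracts exactly one proton
(1.007276 Da). Published mass tables that ignore the electron differ from
ours by ~1–2 ppm at low mass; at the 0.5 ppm assignment tolerance the
distinction matters and is therefore made explicit.

**Formula enumeration.** The search space is the bounded CHNOPS lattice
(defaults C ≤ 60, H ≤ 100, N ≤ 10, O ≤ 20, P ≤ 3, S ≤ 5 — generous for
dissolved organic matter below 1000 Da). C, N, O, P and S are gridded and
the hydrogen count is solved from the mass residual; this is exhaustive
because any ppm-scale window is far narrower than one hydrogen mass. The
ppm tolerance is applied on the scale of the measurement: on the neutral
mass when a neutral mass is queried, on the ion m/z when an adduct is
given. Constraints: RDBE ≥ 0 is on by default (every closed-shell molecule
satisfies it); the heuristic elemental-ratio filters (H/C ∈ [0.2, 3.1],
N/C ≤ 1.3, O/C ≤ 3, S/C ≤ 0.8) are opt-in because they encode assumptions
about carbon-backbone chemistry that ultra-high-resolution data does not
need. Candidates are ranked by |ppm error|, then lower RDBE, then Hill
notation — a deterministic order that favours the simpler explanation at
equal mass accuracy.

**Isotopic fine structure.** Per element, the isotopologue distribution of
n atoms is the exact multinomial over heavy-isotope counts; element
distributions are convolved, with branches below 1e-12 probability pruned
(prune = 0 gives the exact distribution, whose abundances sum to 1 to
within 1e-9 — asserted as a property test). Isotopologues closer than
merge_window = 0.0002 Da are aggregated at their abundance-weighted mean
mass: 0.2 mDa is the fine-structure resolution of a 12 T FT-ICR instrument
at m/z 400, so merged peaks are exactly those the instrument cannot
separate. Verification follows the all-or-nothing rule: a formula is
accepted only if *every* theoretical peak above the abundance floor has an
observed peak within the ppm tolerance. "Every peak" cannot literally mean
all isotopologues (their number is astronomically large and their
abundances unmeasurably small), so the floor operationalises it; the
pattern default is 0.001 of the base peak, and verification workflows in
this package use 0.01 — the abundance a single FT-ICR spectrum measures
reliably.

## Synthetic cohort

The generator reproduces the sampling design the pipeline targets: two
coral species — a branching *Acropora*-like species with 8 colonies and a
massive *Platygyra*-like species with 10 — each colony sampled at 0, 5 and
50 cm from the surface, half of the colonies diseased. One sample per
colony and distance; within-colony pooling of sampling spots is treated as
already done, so no pooling variance is modelled.

Intensities follow a multiplicative log-normal noise model (the standard
model for LC-MS peak intensities), default sigma 0.2 on the natural-log
scale (~20% CV), and are censored to zero below a 500-count detection
floor — the same cutoff the filtering stage applies, so censoring and
filtering are consistent. Matrix (non-gradient) features have per-feature
backgrounds drawn log-normally around 10 000 counts (log-sd 0.5).

**Gradient features** (default 20% of features) follow
mean(d) = background + A·exp(−k·d) with k uniform on [0.05, 0.3] per cm —
the range in which a 50 cm sample retains between ~8% and ~0% of the
surface excess, bracketing profiles that vanish quickly and ones that decay
visibly but incompletely. Their seawater backgrounds are drawn around 1500
counts (near the detection floor), 60% have no seawater background at all,
and amplitudes are 3–10× the feature's own background. Two considerations
fix this amplitude scale. First, realism: holobiont-derived molecules are
trace components of seawater — strongly surface-enriched but individually
and collectively a small share of total signal. Second, a numerical
consequence of the first: the pipeline normalizes by total sample
intensity, and if planted gradients carried a large fraction of the
surface samples' total ion current (as a naive "gradient features are
huge" design would make them), normalization itself would deflate all 0 cm
intensities and distort — even invert — the very gradients being planted.
Keeping the planted signal a trace of TIC, as it is in real data, keeps
total-intensity normalization benign. With the defaults, 88% of features
are detectable at all three distances, matching the ubiquity level reported
for real transects.

**Disease markers** (default 3%) are drawn from the non-gradient pool and
shift their 0 cm mean by ±2 log2 units (4-fold) in diseased colonies, in a
random direction shared across species — emulating indicator molecules
common to both corals. The shift applies at the surface only, mirroring the
design assumption that disease-linked chemistry concentrates at the colony
surface.

**m/z values** derive from randomly drawn, chemically valid CHNOPS
formulas (integer RDBE ≥ 0, H ≤ 2C + N + 2) ionised as [M-H]-, so
formula annotation is testable end-to-end against planted truth.

**OTU tables.** One *Pelagibacterales*-like taxon takes a fixed fraction
(default 98%) of every library. The residual community is colony-specific
at the surface (Dirichlet-distributed profiles) and mixes linearly toward
one shared seawater profile in proportion to physical distance:
α(d) = distance_mixing · d / d_max. Mixing proportional to *distance* (not
to the index of the distance in the design) is what produces the
characteristic contrast — the 5 cm halo resembles the surface community
while 50 cm does not — because 5 cm is ten times closer to the surface than
the seawater control. Counts are multinomial draws at 100 000 reads per
sample, matching real library sizes.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: chromatographic artefacts (RT drift, peak-shape
variation, co-elution), ionisation suppression, correlated noise across
features, compositional effects beyond the dominant taxon, hydrodynamics of
mixing around coral morphologies, and any species difference in decay rates
(the published cohorts differ markedly — surface-to-5 cm drops of ~7% for
the branching species vs ~47% for the massive one; the generator draws both
species' rates from one range).

## Gradient statistics

Tests run on total-intensity-normalized intensities, log(x + 1)
transformed. Normalization divides each sample by its total and rescales to
the median total; the log pseudo-count of 1 is negligible against the
500-count floor and keeps censored zeros finite. The transform choice (raw
vs log) is exposed; log is the default because multiplicative noise is the
dominant error mode.

The gradient call requires the ordering mean(0) ≥ mean(5) > mean(50) — tie
allowed at the surface, strict against seawater, exactly as the profile
definition demands — plus a one-way ANOVA across the three distances at
α = 0.0086 and Welch tests of both 0 vs 50 and 5 vs 50 at α = 0.0098.
These unusual α values are used as given, interpreted as already
Bonferroni-adjusted per-test thresholds; both are configurable. The Welch
pair set (each near distance against seawater) is the minimal set that
establishes a gradient against background; it is configurable too.
Degenerate inputs are resolved by definition: all-identical groups give
p = 1, zero-variance groups with different means give p = 0.

The decay fit minimises squared residuals of y(d) = A·exp(−k·d) with
k ≥ 0, initialised from the log-linear regression of log(max(y, ε)) on
distance (exact when the profile is exactly exponential). Non-decreasing
profiles take the documented degenerate fit (A = mean, k = 0) rather than
chasing a meaningless optimum. The drop statistic is
(mean(0) − mean(5)) / mean(0), NaN-flagged when the surface mean is zero.

## Disease indicators

The screen is a two-group one-way ANOVA (identically the pooled-variance
t-test, F = t²) on surface samples at α = 0.038, run per species; only 0 cm
samples enter, by design. The intersection step keeps matched pairs
significant in both species with the same direction of change, then
annotates a confirmatory Welch tier: strict (both species' Welch
p ≤ 0.00059), loose (both < 0.0082), or none. The *confirmed* subset
(loose or better) is the indicator list — the two-stage funnel
(screen-and-agree, then confirm) is what keeps the null expectation of
false shared indicators near zero (~0.007 per 200-feature cohort) while a
4-fold planted shift passes both stages essentially always at n = 4 + 4.
Raw and Bonferroni-adjusted screening p-values are reported side by side;
the funnel itself applies no further multiplicity correction, and the
adjusted columns let a user apply one.

## Community analysis

Correlations are Pearson product-moment on relative abundances after
dominant-taxon removal, computed per colony against the colony's own 5 cm
sample (Spearman available by flag; "Pearson's rank correlation" is a
contradiction in terms, and the symbol r with a self-correlation of exactly
1 indicates product-moment). Removing the dominant taxon first matters:
at 98% dominance every profile correlates with every other at r ≈ 1
through the shared dominant component, and the residual community is where
the distance signal lives. The near/far contrast (r(0,5) vs r(50,5) across
colonies) uses the two-sided pooled-variance Student t-test.

## PLS-DA

NIPALS PLS2 against the one-hot class matrix: power iteration per
component (tolerance 1e-10 on the relative change of the score vector,
max 500 iterations, failure raised by component number), deterministic
initialisation from the class-matrix column of largest variance, X deflated
by the rank-one score-loading reconstruction and Y by the score-class
reconstruction. X-deflation makes score vectors mutually orthogonal, which
is asserted (along with explained-variance bounds) on every constructed
model. Per-component explained X-variance is ‖t·pᵀ‖²/‖X₀‖² on the
autoscaled matrix; explained class-variance is the analogous Y quantity.
Both are reported because "percent variance" is ambiguous between them.
Autoscaling (mean 0, unit variance per feature) drops zero-variance
columns with a warning.

## Problem sizes

Default analyses and the acceptance script use cohorts of 500 features ×
54 samples (2 species × 8/10 colonies × 3 distances), 200 random formulas
for round-trip checks, 100 profiles for decay recovery, 50 null cohorts of
200 matched features for the indicator null, and OTU tables of 100 taxa ×
24 samples at 100 000 reads — sizes at which every statistic of interest is
stable across seeds while a full run stays in the tens of seconds.

## Known limitations

* Formula space is CHNOPS only; halogenated or metal-containing compounds
  are out of scope.
* The isotope-verification rule assumes the observed peak list is already
  de-noised (an S/N cutoff upstream); it does not model detector dynamic
  range, so very low-abundance theoretical peaks must be excluded via the
  floor rather than an intensity model.
* `fit_decay` on three points with two parameters cannot distinguish decay
  shapes; it quantifies rate under an assumed exponential, it does not test
  exponentiality.
* The gradient classifier's sensitivity is a property of the planted
  effect sizes as much as of the statistics; the cohort defaults are one
  realistic operating point, not a power analysis.
* PLS-DA is fit without cross-validated component selection; explained
  variance on training data overstates generalisation.
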