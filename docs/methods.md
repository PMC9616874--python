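# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations behind `wellnet`, in the order the pipeline runs.

## Synthetic cultivation arrays

**Seeding model.** A source community is a log-normal rank-abundance vector
(default σ = 1, a typical evenness for freshwater/sediment communities) with
total density `cells_per_ul` (free parameter; absolute homogenate densities
are rarely known, default 10⁶ cells/µl). Dispensing 1 µl of a 10^−d dilution
into a well seeds species *s* with Poisson intensity

    λ_s = cells_per_ul · inoculum_volume_ul · abundance_s · 10^−d,

independent across wells and species. Expected seeding therefore decays
exactly 10× per dilution level, and the fraction of sterile wells is
exp(−Σλ_s). All-zero wells are kept in the table; growth scoring happens
downstream.

**Endpoint interaction model.** Wells are not integrated dynamically.
Seeded species grow to an endpoint in which species *i*'s relative share is
its seeded share multiplied by exp(sign·effect) for every co-seeded planted
partner, renormalized; reads are Multinomial(read_depth, shares), default
depth 10⁴. This is deliberately minimal: the inference consumes endpoint
abundances only, so a multiplicative share perturbation is the cheapest
model that produces the abundance co-variation the statistics measure.

**What this model can and cannot express.** Two facts matter for
interpreting tests built on it:

1. *Closure bias.* Relative abundances of S taxa are compositional; two
   non-interacting taxa have expected pairwise correlation ≈ −1/(S−1). At
   the 40-taxon default this is −0.026, negligible against the |ρ| > 0.6
   edge threshold, but at S ≈ 10 it reaches −0.11 — null tests use S = 40.
2. *A Spearman ceiling under independent seeding.* With independent Poisson
   seeding, a planted positive pair's correlation comes only from the
   three-way partition of wells (absent / present-alone / co-present): the
   co-present group's internal Poisson noise is uncorrelated between
   partners, and the achievable ρ peaks near 0.65 at λ ≈ 1 founding
   cell/well regardless of effect size (we measured recovery of ρ > 0.6 in
   at most ~70–75% of plates at the optimum). Correlated seeding — the
   generator's co-colonization mode, a per-pair shared Bernoulli gate that
   doubles or zeroes both partners' intensities with the mean preserved —
   adds presence correlation and lifts within-plate ρ to 0.83–0.86. Since
   positive network edges in real arrays are expected to reflect joint
   dispersal and cross-feeding as much as in-well facilitation, the demo
   and acceptance ensembles enable this mode; `simulate_plate` itself
   defaults to independent seeding so the two mechanisms can be studied
   separately. Passing tests under the co-colonization regime show the
   inference chain recovers strongly co-varying pairs; they do not show
   that weak, purely endpoint-level facilitation is detectable at 96 wells.

**Planted-pair placement.** Interactions are expressed only where a
species' occupancy has contrast: `plant_pairs` ranks species by
|log(λ/target)| at a reference dilution (the ensemble's middle level) and
plants pairs among the species closest to λ = 1. The demo ensemble is 2
groups × (3 dilutions 10⁻³..10⁻⁵ × 3 replicates) of 96-well plates with 40
taxa, 3 planted positive pairs of effect size 2.5; the most dilute plates
pass the growth filter but contribute no edges, so planted pairs occur in
~6 of 9 group networks (FO ≈ 0.67). These sizes keep a full end-to-end run
under ~5 s while leaving every threshold of the method load-bearing.

**Growth curves.** Mono- and co-culture series are logistic (default rates
0.6/0.5 h⁻¹, capacity 10⁹ cells/ml, 0–36 h) with the co-culture capacity
scaled per interaction archetype (facilitated ×3, suppressed ×0.35,
unaffected ×1) and multiplicative log-normal noise (default sd 0.1).
The six archetypes are emitted by construction; real biphasic dynamics
(exponential growth then crash) are emulated only through the windowed
classifier tests, not the generator.

## Growth filter and prevalence filter

A well *grew* iff its total reads ≥ `min_reads` (default 100) — an
in-silico proxy for visual growth scoring, the only proxy available from a
feature table. A plate is effective iff strictly more than 30% of its wells
grew (29/96 passes, 28/96 does not); the denominator is the design's well
count. Zotu prevalence is computed over growing wells (a flag switches to
all wells) and the Zotu filter is non-strict (≥ 30%), matching the
"filtered below 30%" convention; the plate-level and FO thresholds are
strict (> 30%).

## Network inference

Correlations default to per-well total-sum-scaled abundances (raw-count
mode by flag): sequencing depth varies per well, and Spearman across wells
is not invariant to that variation. ρ is the Pearson correlation of
mid-ranks; p comes from the two-sided t-approximation (p = 0 at |ρ| = 1).
Pairs with constant ranks are skipped and recorded, never assigned ρ = 0.
The t-approximation is adequate from n ≥ 6 (within 0.05 of the exhaustive
permutation p; at n = 4–5 the permutation null has ≤ 120 atoms and the
deviation reaches 0.15) — plates enter inference with ≥ 4, in practice ≥ 29
growing wells, far above that regime.

FDR is Benjamini–Hochberg, computed per plate over all tested pairs (each
network is inferred independently); the implementation is the step-up
definition verbatim, so it agrees bit-for-bit with an O(n²) definitional
oracle. Edges require |ρ| > 0.6 and q < 0.01, both strict. The degree
filter keeps nodes with degree < 5 computed once on the thresholded
network — a single selection of low-degree nodes, not an iterative peel.

## Pair prevalence

FO = Np/Ng with groups keyed by (sample type, medium); dilution level and
replicate are intentionally pooled. FO comparisons use exact rational
arithmetic (`Fraction`), so FO = 3/10 at a 0.30 threshold is dropped
without floating-point ambiguity. FO counts edges regardless of sign; the
consensus sign (majority, ties positive) and a conflict flag are carried so
sign structure is never lost. The top-k report applies no FO cut — the
robust list is a separate output — with ties broken by higher mean |ρ|,
then lexicographic pair id. Jaccard similarity of two empty edge sets is
defined as 0 (logged), since 0/0 is undefined.

## Isolate–Zotu matching

V4 extraction scans for the 515F site (5'→3') and the reverse complement of
806R downstream of it, honoring IUPAC degeneracy on both strings, with a
1-mismatch budget per site; multiple forward hits use the leftmost with a
warning. Identity is global alignment (match +1, mismatch −1, gap −2),
matches over alignment columns; arguments are canonically ordered before
aligning so identity is exactly symmetric.

Neighbor joining follows Saitou–Nei (minimize Q(i,j) = (r−2)d(i,j) − Σd(i,·)
− Σd(j,·)); ties on Q break on the lexicographically first label pair, so
the tree is input-order invariant. Negative branch lengths are clamped to
zero with the deficit shifted to the sister branch, logged. On additive
matrices the tree reproduces all pairwise distances to < 1e−9 and agrees
with an independent NJ implementation.

A match requires identical V4 (identity ≥ 1.0 by default, per the
convention that an isolate *represents* a Zotu only when their amplicons
coincide); below that, the isolate falls to the nearest Zotu leaf by tree
path length, accepted only within a distance cap (default 0.03, roughly
species-level p-distance) so matches never cross genus-scale divergence.
Identity ties break on tree distance and remain unmatched if still tied;
both the cap and tie outcomes are visible in the match table.

## Interaction assay

The effect of partner y on partner x in a window is Δ_x = AUC(log₁₀ co_x) −
AUC(log₁₀ mono_x) (trapezoidal; densities floored at a 1 cell/ml detection
limit), thresholded at ±ε·window_length into {+, 0, −} with ε = 0.2
log₁₀-units per hour. The effect pair maps onto mutualism (+,+),
commensalism (+,0), exploitation (+,−), amensalism (−,0), competition
(−,−), neutralism (0,0); a collapse mode reduces to the on-plate three-way
readout (mutual / competitive / neutral). AUC rather than endpoint density
makes the call robust to single-timepoint noise and lets windowed calls
capture biphasic interactions; ε and the window are reported with every
call because any threshold here is a convention, not a measurement.
Standard curves are OLS of Cq on log₁₀ copies; E = 10^(−1/slope) − 1; Cq
values outside the calibrated range still quantify but warn.

## Determinism and problem sizes

All randomness flows from one seed through `numpy` SeedSequence spawning
(stage keys are fixed integers / CRC32 of sample-type names — never
Python's salted `hash`). Identical configs produce byte-identical reports.
Default test and acceptance problem sizes (18-plate ensembles, 200-vector
oracle sweeps, 20 random trees ≤ 12 taxa, 120 labeled curve sets) run the
full suite in well under a minute while exercising every threshold; larger
arrays are a config change, not a code change.

## Known limitations

- No mechanistic community dynamics (no Lotka–Volterra, no spatial
  structure), no sequencing-error/chimera simulation, no compositional
  network methods (SparCC/SPIEC-EASI) and no conditional-independence
  inference — the correlation thresholds here inherit Spearman's known
  compositional biases.
- Interaction effects are pairwise only; higher-order modulation is out of
  scope.
- The isolate matcher assumes amplicons are orientable with the given
  primers and does not model intragenomic 16S polymorphism: one Zotu can
  legitimately correspond to several strains (and does, in the synthetic
  truth), which is reported, not resolved.
- The six-way interaction classifier is a labeling of AUC divergences, not
  an inference of mechanism; with ε → 0 every pair becomes non-neutral.
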