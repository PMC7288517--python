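# Methods

This note documents the models, conventions and numerical choices behind
`agingaccel`, and what the synthetic experiments do and do not establish.

## Cohort model

The generator (`agingaccel.synthetic`) emulates a multi-platform case/control
expression compendium as a genes × samples Gaussian matrix with planted
structure:

* **Groups and ages.** Young normal (ages uniform on [20, 49]), old normal
  and LOPD samples (both uniform on [50, 95]); the defaults — 140/150/130,
  300 genes, three platforms — are a desk-scale analogue of the hundreds of
  samples per group the method targets at full scale. Ages are integers
  (years).
* **Aging genes** have mean `aging_effect · t(age)` with
  t(age) = 1/(1+exp(−(age−50)/50)). The default slope of 3 expression units
  per transformed-age unit makes the young/old separation clearly detectable
  at 300 genes, analogous to the strong above-chance accuracy the method
  attains on real compendia; the recovery experiments additionally use the
  harder slope of 2 noise SDs that the recovery property is stated at.
* **PD genes** are mean-shifted in PD samples with alternating sign
  (±`pd_effect`). When `masking_latent_sd > 0`, three latent factors with
  Gaussian loadings (SD `masking_latent_sd`) are added to **all** samples,
  and the PD shift vector is orthogonalised against the loadings: the shift
  then lives entirely in the residual space left after removing the young
  principal directions, which is exactly the situation the improved PD
  predictor is designed for. The default loading SD (0.5 noise units) gives
  mild masking; the paired improved-vs-traditional experiment uses 2.0 so the
  masking dominates.
* **Differential edges.** A pair shares a latent factor z:
  g = √ρ·σ·z + √(1−ρ)·σ·ε, with the latent's sign flipped in PD samples for
  the second gene. This is variance-preserving, so planting an edge does not
  change the gene's marginal SD, and the within-group correlation is +ρ /
  −ρ exactly (for genes carrying a single latent). Two layouts exist:
  `random` (disjoint spare-gene pairs, correlation exactly ±ρ — used for the
  edge-recovery experiments) and the default `chain`, which routes pairs as
  aging-gene – bridge – PD-gene chains so that the end-to-end run produces
  non-trivial aging→PD shortest paths; a bridge gene carries two latents, so
  its pair correlations are ρ/√(1+ρ) (≈ 0.60 at ρ = 0.8), still far above
  the 0.5 retention threshold.
* **Platforms** add an independent N(0, `platform_shift_sd`) offset per
  (gene, platform) — the simplest batch structure the z-score/SVD
  normalization should remove.

What the generator does **not** model: probe-level intensities, heavy-tailed
or count-like expression distributions, correlated gene programs beyond the
planted factors, age-dependent variance, or missingness beyond the
zero-filling path. Passing tests therefore demonstrate correctness of the
algorithms under their own statistical assumptions, not performance on real
microarray data.

## Preprocessing

Probe collapse takes the arithmetic mean of probes sharing a symbol. Missing
values become 0, then genes with ≥ 30% exact zeros are dropped, then PD
samples younger than 50 are removed. Normalization runs per platform:
(1) per-gene z-score with all-normal-sample statistics (applied to every
sample on the platform); (2) subtraction of the rank-3 truncated-SVD
reconstruction of the normal block and the PD block separately — computed on
the block as-is, so an exactly rank-≤3 block is annihilated; after step 1 the
blocks are near-centered, making centered and uncentered readings numerically
close; (3) per-gene z-score of all samples with the post-SVD old-normal
statistics, putting platforms on a common old-normal scale. Zero-variance
reference genes yield z = 0 with a warning rather than NaN. Blocks with
fewer than 4 samples skip SVD removal (nothing separates structure from noise
there). Young-residualisation computes the top-3 right singular vectors of
the young-mean-centered young block (samples × genes) and removes each old/PD
sample's orthogonal projection onto them; with an orthonormal basis this
equals the OLS fit obtained from the normal equations, is idempotent, and leaves
vectors orthogonal to the young directions untouched.

## Predictors

Labels are young=0/old=1 and normal=0/PD=1. Gene ranking uses |Pearson r|
with lexicographic gene-id tie-break; zero-variance genes get r = 0. Cosine
distance is 1 − x·y/(‖x‖‖y‖); a zero-norm vector is treated as orthogonal to
everything (distance 1, logged). Neighbour ties resolve in training-sample
index order (stable argsort); an even vote split predicts class 0 (never
triggered at k = 5). The learning curve re-ranks genes inside each CV
training fold by default (leakage-free); `rank_once=True` reproduces the
simpler rank-on-the-whole-training-set variant. Accuracy ties in the curve
select the smallest n (parsimony). The train/test split is stratified
2:1 per class with at least one test sample per stratum. ROC scores are the
k-neighbour vote fractions; AUC is the trapezoid over the step curve.
A subtlety worth recording: a *single* planted gene, however separable in
magnitude, is invisible to cosine kNN (all 1-D vectors are parallel); with
two or more features the vote-fraction geometry works as expected, which is
why the separability tests plant two antagonistic genes.

## Aging scores

The fit is no-intercept least squares of t(age) on the marker expressions,
per the score's definition; an optional intercept flag exists because
z-scored expression is centered while t(age) is not, which costs the
no-intercept fit a level shift (correlations and group contrasts are
unaffected). The fit uses normal samples only by default (scores are then
applied to PD samples; a flag fits on all). Underdetermined fits fall back
to the minimum-norm solution with a warning. Group comparisons use
tie-corrected Kruskal–Wallis with a chi-square (df = 1) tail; identical
pooled values return H = 0, p = 1. The power experiment for a +0.05 score
shift models the control spread as SD 0.02, the order of spread that fitted
scores show on cohorts of this size.

## Network

Correlation p-values come from t = r√(df/(1−r²)) with df = n−2 (plain) or
n−3 (partial). The partial correlation is first-order with the aging score
as the single covariate; |r·z| = 1 degenerates to rp = 0, p = 1 with a
warning. The FDR gate is applied per coefficient family (r and partial r in
each group, BH within family); an edge needs **any** family q < 0.05 by
default (`significance_mode`: any/all/off), the rationale being that at
least one significant coefficient makes a large delta meaningful. Retention
requires both deltas strictly > 0.5. The all-pairs computation is
vectorised; gene count is capped (default 2000) because the all-pairs run at
tens of thousands of genes is cluster-scale. Fisher similarity builds a 2×2
table over all unordered pairs of the common universe (edge-in-A ×
edge-in-B, two-sided). The scale-free check correlates log10 degree with
log10 frequency (counts; using probabilities shifts the log by a constant and
leaves r unchanged) over nodes with degree ≥ 1, and declines (NaN) with
fewer than 3 distinct degrees.

## Bipartite paths

Shortest paths use BFS on the unweighted network (Dijkstra degenerates to
BFS at unit weights) with one deterministic path per pair: the greedy walk
down the distance-to-target field that always takes the smallest-labelled
feasible neighbour, i.e. the lexicographically smallest shortest node
sequence. One-path-per-pair matches the interpretation of betweenness as a
count of marker paths; an all-shortest-paths variant was deliberately left
out of the default. Opposite-sign retention requires r_control · r_pd < 0
strictly (a zero coefficient is not opposite). Betweenness counts interior
nodes only. The permutation null redraws disjoint random aging/PD node sets
of the observed sizes from the network nodes (paths require membership) and
counts reps with permuted betweenness ≥ observed; p = count/reps can be
exactly 0, and a +1-smoothed option exists. In the orchestrated run the
permutation uses the numbers of markers actually present in the network,
since the operation requires n_aging + n_pd ≤ |nodes| and a desk-scale
network is far smaller than the marker panels. The uniformity calibration
draws fresh random 3-regular graphs (40 nodes, 20×8 marker pairs): under the
null the observed betweenness is exchangeable with the permutation draws, so
the p-value is uniform up to discreteness, and the regular topology avoids
the large point mass at p = 1 that low-degree nodes of inhomogeneous random
graphs would produce.

## Enrichment

The hypergeometric upper tail P(X ≥ k) is evaluated through the survival
function in log space. The textbook denominator C(N, n) is used; the form
with C(N, k) in the denominator sometimes seen in print does not normalise
to 1 and is treated as an erratum. BH correction runs across sets within
each path by default (a global option exists). The universe defaults to the
network genes present in the GMT (configurable to the GMT union); note that
on a small synthetic network this universe is nearly saturated by the planted
set, which makes per-path enrichment deliberately conservative there.

## Orchestration and problem sizes

One global seed fans out to per-stage seeds by fixed offsets so stages can be
re-run alone. The manifest records every parameter in use. The default
synthetic run (300 genes, ~420 samples) completes in seconds on one CPU; the
calibration/recovery experiment sizes (20 null seeds, 10 recovery seeds at
300 genes and 150/group, 200 uniformity evaluations at 100 permutations)
were chosen as the smallest scales at which the binomial/KS tolerances of the
corresponding properties are informative.

## Known limitations

* The per-platform SVD step can absorb planted biological structure when a
  cohort has few genes and strong factors; at full scale the top components
  are dominated by technical variation, which is the step's intent.
* Betweenness and enrichment on desk-scale networks involve few paths; their
  outputs are exercised for correctness, not biological interpretation.
* Fisher-similarity p-values on small pair universes are discrete and
  conservative; calibration checks use loose KS bounds for that reason.
* The improved-vs-traditional comparison is guaranteed only under the
  masking construction (PD shift orthogonal to strong young factors); with
  weak masking the two predictors are statistically indistinguishable.
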