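# Methods

## The suitability model

The core estimator is a presence-background maximum-entropy density model.
Let `B` be a sample of `m` background cells describing the available
environment and `P` a set of `n` presence cells. Raw covariates are expanded
into features scaled to [0, 1] over the background:

- **linear** `(x − min)/(max − min)` and **quadratic** (its square);
- **product** features, pairwise products of scaled covariates;
- **hinge** features `clip((x − k)/(max − k), 0, 1)` with knots `k` at
  background quantiles `j/K`, `j = 0..K−1` (default `K = 50` per variable) —
  quantile knots are scale-stable, whereas the classical implementation
  places knots on the value axis; this is a deliberate, documented
  divergence;
- **threshold** features `1[x > k]` at interior background quantiles
  (default 20 per variable).

The model is the Gibbs distribution `p(x) ∝ exp(λ·f(x))` normalized over the
background, fitted by minimizing the convex penalized objective

```
F(λ) = ln Σ_B exp(λ·f)  −  mean_P (λ·f)  +  Σ_j β_j |λ_j|.
```

The per-feature penalty is `β_j = RM · β_class(n) · s_j / √n` where
`β_class(n)` interpolates the published per-class default tables on presence
count (linear/quadratic/product: 1.0 at n ≤ 10 falling to 0.05 at n ≥ 100;
hinge: 0.5; threshold: 2.0 falling to 1.0), `s_j` is the feature's standard
deviation over presences (floored at 1e-3 so features constant at presences
remain bounded), and RM is the user-facing regularization multiplier, so
RM = 1 reproduces the defaults.

**Optimizer.** FISTA (accelerated proximal gradient with soft-thresholding),
with backtracking line search on the smooth part, adaptive momentum restart
when the objective rises, and a step-size recovery factor of 0.9 per
iteration. Convergence is declared when the objective change on an accepted
step falls below `tol (1 + |F|)` with `tol = 1e-7`; non-convergence after
`max_iter` (default 20 000) raises an error carrying the objective trace.
The fitted raw distribution is renormalized with a log-sum-exp, so it sums
to one over the background to machine precision.

**Output scales.** `raw` is `exp(λ·f − ln Z)`; `cumulative(x)` is 100 times
the raw mass at cells with raw ≤ raw(x); `cloglog(x) = 1 − exp(−e^H raw(x))`
with `H` the entropy of the raw distribution over the background. A model
with all-zero coefficients is uniform, giving cloglog `1 − e^{−1}`
everywhere. Projection covariates are clamped to the training background
bounds by default (`clamp=False` disables it).

## Occurrence curation

Records carry greenhouse / summer-only flags (populations persisting outside
the climate envelope) and a collection year. The partition is: flagged →
*excluded*; natural records 1981–2010 → *basic* (the climatology baseline
window); natural 2011–2024 → *expanded_only*. Natural records with a missing
year or outside both windows are excluded with a warning, keeping the
partition exhaustive. Per-cell deduplication keeps the earliest-year record
(input order breaks ties).

Spatial thinning targets Moran's I < 0.2. Because the statistic needs a
variable, it is computed on each environmental layer's values at the
occurrence cells and the **maximum over layers** is thresholded — a
conservative, reproducible stand-in for a single unstated variable choice.
Weights are inverse great-circle distance (coincident points capped at a
configurable maximum; a k-nearest-neighbor weighting is available). Each
iteration locates the closest pair of records and removes the member whose
removal lowers the max Moran's I most (ties drop the later-year record);
thinning below a floor of 30 records raises a diagnosed failure rather than
silently under-powering the model. Whether thinning precedes the train/test
split is unstated in the source workflow; here it precedes everything.

## Predictor screening

Candidates are screened on the background sample (the model's domain):
while any pair has |Pearson r| ≥ 0.8 or any variable has VIF ≥ 10, the
violating variable with the lowest model percent contribution is dropped and
the diagnostics (and, when a refit callback is supplied, the contributions)
are recomputed. Ties prefer dropping the higher-VIF, then lexicographically
later variable. The screen iterates to convergence rather than screening
once against the initial model — an open choice resolved in favor of
self-consistency. Note the rule can only drop threshold violators: an
uninformative but uncorrelated variable (e.g. elevation in the default
synthetic world) survives the screen and is instead neutralized by the model
itself (near-zero contribution).

## Tuning and selection

The candidate space is the Cartesian product of the RM ladder 0.1–5.0 in
steps of 0.1 (50 rungs; RM = 0 is excluded because an unpenalized
hinge/threshold-rich design is degenerate) with all 31 non-empty subsets of
{L, Q, H, P, T}. Each candidate is fitted on one fixed 75/25 presence split
and scored by:

- `AICc = 2k − 2 lnL + 2k(k+1)/(n − k − 1)` with `k` = nonzero coefficients
  and `lnL` the presence log-likelihood of the raw distribution renormalized
  over the **full projection grid** (a background-only normalization is the
  main alternative; the grid convention is exposed through the API);
- omission rates of test presences below the minimum (OR_mtp) and the
  nearest-rank 10th percentile (OR_10) of training predictions;
- a partial-ROC test at error rate E = 0.05: 500 bootstrap resamples of half
  the test presences, each scored by the ratio of the partial area of the
  sensitivity vs proportion-of-area curve (restricted to sensitivity
  ≥ 1 − E) to the same partial area under the chance diagonal; p is the
  fraction of resamples at or below ratio 1.

Selection filters to p < 0.05, then OR_10 ≤ 0.1, then takes minimum AICc
(ties: fewer parameters, then smaller RM). A filter that would empty the
pool is relaxed with a warning so a champion always exists.

## Evaluation

All metrics use held-out presences only. Pseudo-absences are drawn uniformly
from unmasked non-presence cells in equal number to the test presences
(prevalence 0.5). The panel: rank (Mann–Whitney) AUC; TSS, Cohen's Kappa,
Jaccard and Sørensen at the max-TSS threshold (scanned over all observed
prediction values plus a 0.001 ladder, lowest maximizer on ties); the
continuous Boyce index (101 moving windows of width one tenth of the
background prediction range; Spearman correlation of predicted-to-expected
ratios against window midpoints, empty-background windows skipped); and the
two omission rates. At exactly 0.5 prevalence and a common threshold, Kappa
equals TSS algebraically — the package reports both anyway, and any
published pair where they differ must have used different thresholds or
point sets.

## Projection and ensembles

Binary maps use the near-current max-TSS threshold for all periods (no
re-thresholding convention is assumed for futures). Areas are spherical
cell areas `R² Δλ (sin φ_top − sin φ_bottom)`, `R = 6371.0088 km`, so
budgets are latitude-weighted. Change maps classify unmasked cells as
unchanged-suitable / unchanged-unsuitable / gained / lost, with the exact
identities `unchanged_suitable + lost = current suitable` and
`unchanged_suitable + gained = future suitable`. The five-member ensemble is
combined both as a per-cell mean suitability and as a model-agreement
fraction (the two displays used interchangeably in the literature);
replicate consistency maps mark cells where ≥ 95% of replicate binary maps
agree, and replicate variability is the per-cell sample SD.

## Synthetic world

The generator emulates the study's data conditions, not climate physics.
Layers are Gaussian white noise smoothed with a kernel of fixed width (the
autocorrelation length, default 3°), empirically whitened over unmasked
cells, and mixed through the Cholesky factor of a target correlation matrix,
so realized pairwise correlations match the target closely even on modest
grids. A standardized latitudinal gradient is blended into the first
temperature layer only; because the noise fields are pre-orthogonalized
against it, the remaining pairwise correlations stay on target (a gradient
shared by every layer would itself induce cross-correlations exceeding the
generator's own accuracy contract). The default six-layer world contains a
redundant temperature pair (r = 0.9) and a redundant precipitation pair
(r = 0.85) for the screen to act on, plus an uninformative elevation layer.
An irregular nodata mask (default 15% of cells) is carved from another
smoothed field.

Truth is a logistic link of the standardized linear predictor built from
named layer terms (default: unimodal in `tas1`, increasing in `prec1`), with
gain 2. Presences (default 1000) are drawn cell-wise with probability
proportional to truth, **with replacement** (multiple records per cell are
realistic and are later collapsed by deduplication), jittered within the
cell; a contamination fraction (default 10%) is flagged greenhouse or
summer-only and placed where truth < 0.05. Natural years are split ~65/35
between the 1981–2010 and 2011–2024 windows. Five future stacks shift
temperature layers by `scale × 0.5 °C` plus scale-proportional smooth noise
and rescale precipitation layers multiplicatively, with relative scales
(5.4, 4.6, 3.1, 3.0, 2.7) mirroring the equilibrium-climate-sensitivity
spread of a five-model ensemble; zero scales reproduce the input bit-for-bit.

What passing tests show — and what they do not: the synthetic world has
smooth, stationary, jointly Gaussian layers, truth exactly in the model's
feature span, and geographically unbiased sampling. Real occurrence
compilations carry sampling bias, non-stationary covariates, and truth
outside the feature span, so recovery statistics here are upper bounds on
real-data behavior; the tests validate the machinery, not field accuracy.

## Defaults and problem sizes

Background: 10 000 cells within a 500 km buffer of presences (both unstated
in the source workflow; config-exposed). Replicates: 20 random 75/25 splits,
seeds `base_seed + rep`. The bundled demo configuration and the
reproduction script run a 100 × 100 half-degree world with 1000 presences,
4000 background cells, a reduced tuning grid (4 RM × 5 FC), 20 hinge / 10
threshold knots and 20 replicates — sizes chosen so a full run completes in
seconds while exercising every stage; the full 1550-candidate grid and
50-knot features are available through `RunConfig`.

## Known limitations

- No spatially structured cross-validation; the split family is random.
- Categorical covariates and MESS-style extrapolation maps are out of scope;
  clamping plus an extrapolation log is the only projection guard.
- The thinning heuristic is greedy and locally optimal, not globally minimal
  in records removed.
- Percent contribution is permutation importance on training AUC; it is not
  the path-dependent accounting of the classical implementation, though it
  agrees on which variables dominate.
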