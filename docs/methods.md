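# Methods

This note records the models implemented in `pulmopt`, the defaults
that matter, the places where the design was genuinely open and what we
chose, and what the synthetic experiments do and do not demonstrate.

## Optimization substrate

All optimizers minimize a scalar objective over a box `[L_k, U_k]^y`
(maximization callers negate their objective).  Populations are
initialized coordinate-wise uniform inside the box; every run is driven
by a single seeded `numpy` generator, and higher-level stages (cohort
generation, splitting, selection, training) receive independent child
seeds derived from one master seed, so a stage can be re-run in
isolation without reshuffling the others.  Every optimizer retains the
best-so-far solution (elitism) and reports a per-iteration best-fitness
trace, which is therefore non-increasing; the tests assert this on
every run they execute.

## Tasmanian Devil Optimization

Per iteration, each candidate ("devil") takes the carrion branch with
probability `p_explore` (default 0.5; the switching rule is not part of
the algorithm's defining equations, and an even split is the
convention) or the prey branch otherwise.  Both branches pick a random
other member and move per dimension with `S ~ U[0,1]`:

* toward a fitter target: `x + S (target − I·x)`, with the intensity
  `I` drawn fresh per move from {1, 2};
* away from a worse target: `x + S (x − target)`.

The second branch as sometimes written (`x + S (target − x)`) would
attract candidates to *worse* solutions; we implement the
move-away form, which matches the algorithm's escape semantics.  The
prey branch is followed by a multiplicative local search
`x_k ← x_k + (2r − 1) s x_k` with radius `s = 0.01 (1 − t/T)`: the
printed form of this radius is iteration-independent, but a constant
radius contradicts its stated role as a shrinking neighbourhood, so the
schedule decays linearly to zero at the final iteration.  All proposals
are clamped to the box and accepted only on strict improvement, making
the population best monotone.

### Wrapper feature selection

TDO searches `[0,1]^d`; a position thresholds at 0.5 into a mask.  The
fitness is `α · err + (1 − α) · |mask|/d`, where `err` is the
stratified k-fold error of a 1-nearest-neighbour classifier restricted
to the masked columns (scikit-learn's `KNeighborsClassifier` and
`StratifiedKFold`; folds fixed once per fit, mask fitnesses memoized so
the search is deterministic and cheap).  Defaults: `α = 0.9`, 3 folds,
population 20, 60 iterations.  The empty mask scores 2.0, above the
worst feasible value of 1, so it can never win; if thresholding the
returned position would still empty the mask, the largest coordinate is
kept.  The selection objective (classifier, folds, α, penalty) is a
package design: the source algorithm family defines no selection
fitness.  An all-constant feature matrix degrades gracefully to the
sparsity term with a warning.

## Improved Grey Wolf Optimization

The baseline GWO loop ranks the pack, takes the three best as α/β/δ,
and moves each wolf toward the equal-weight leader mean with a step
coefficient decaying linearly from 2 to 0.  The improved variant
changes three things:

1. **Weighted, noisy prey estimate.**
   `M_r = W_β M_α + W_γ M_β + W_δ M_δ + μ_t` with
   `1 ≥ W_β > W_γ > W_δ ≥ 0`, `ΣW = 1` (defaults 0.5/0.3/0.2, enforced
   at construction) and per-dimension Gaussian noise `μ_t` of standard
   deviation `σ_t`.
2. **Two-stage convergence coefficient.**  `h = 0.9 (2 − 2t/T)` for
   `t < T/2` and `h = 1.2 (2 − 2t/T)` after, so `h(0) = 1.8`, an upward
   jump to 1.2 at the halfway point re-opens the step size, and
   `h(T) = 0`.  `h` bounds the random step factor `R = h (2r − 1)` in
   the position update `x' = M_r − R (M_r − x)`; it plays exactly the
   role of the canonical decay coefficient, which is the only slot of
   matching range and function.  The stage switch is placed at `T/2`,
   the unbiased reading of "early stage / later stage".
3. **Sine–cosine escape.**  With probability `p_sc` (default 0.3) a
   wolf is instead replaced by `sinθ·M1 + sinθ cosθ·M2 + cosθ·M3`,
   where `M1/M2/M3` are the three leader-guided candidate positions and
   `θ ~ U[0, π/2]` per application.  Using a random first-quadrant angle
   keeps all mixing weights non-negative and makes the endpoints
   interpretable (`θ = 0` returns the δ-guided candidate, `θ = π/2` the
   α-guided one); a raw iteration index inside the trigonometric terms
   would oscillate meaninglessly with `T`.  The combined position is
   clamped to the box.

Coordinates that leave the box in the position update are repaired by a
random step from the prey estimate toward the violated boundary
(`M_r + v (limit − x)`, `v ~ U[0,1]`) and then clamped, so every
emitted position is feasible.  Replacement is unconditional — the pack
always moves — but the global best is retained separately.

### Noise schedule

The defining constraint on the noise is strict decay, `σ_t > σ_{t+1}`;
the functional form is open.  We use a geometric-style schedule

    σ_t = σ_min + (σ0 − σ_min) · (ρ^u − ρ) / (1 − ρ),   u = t/T,  ρ = 1e−5,

which hits `σ0` at `t = 0` and `σ_min` at `t = T` exactly and shrinks
the scale multiplicatively in between.  We first tried the obvious
linear decay and measured it on sphere and rastrigin (10-D, population
30, 200 iterations, 20 seeds × 5 independent batches): under linear
decay the noise stays so large for so long that the improved variant
loses to the plain baseline on *both* functions (sphere medians 3.7e−4
vs 1.2e−7; rastrigin 23.9 vs 11.5), defeating the variant's purpose.
With the geometric schedule the improved variant wins on both across
all five batches (sphere ≈ 1.5e−11 vs ≈ 7e−8; rastrigin ≈ 5–8 vs
≈ 10–11).  Defaults: `σ0 = 0.1 × mean(U_k − L_k)`,
`σ_min = 1e−6 σ0` — large enough early to hop rastrigin basins, small
enough late that exploitation is not noise-limited.

## Tabular convolutional classifier

Architecture (for `d` input features): valid 1-D cross-correlation with
`F` kernels of width `J` and per-filter bias → batch normalization
(per-filter mean/variance, learnable affine) → ReLU → non-overlapping
max-pool of width 2 (skipped when the conv output has a single
position) → dense hidden layer of width `H` with ReLU → linear output →
softmax over `C` classes.  Defaults `F = 4`, `J = 3`, `H = 8`; `C`
comes from the labels.  All parameters live in one flat vector of
length `FJ + F + 2F + H·F·⌊(d−J+1)/2⌋ + H + CH + C`.

Training is population search, not backpropagation: IGWO minimizes the
full-training-set cross-entropy (probabilities floored at 1e−12) over
the box `[−B, B]^P`.  Because the objective always evaluates the whole
training set, batch-norm statistics are the deterministic full-batch
statistics of the conv outputs under the candidate parameters — the
objective is a pure function of the parameter vector — and the
statistics of the winning parameters are frozen into the model for
prediction, so the recorded best fitness equals the loss of the stored
model exactly.  `B = 0` degenerates to the all-zero network (uniform
predictions; ties at predict time break toward the lowest class
index).

The bound default is `B = 1` with 300 iterations and population 30.
`B` matters more than any other training knob: with `B = 3` the random
parameter vectors that population search must traverse produce
saturated softmax outputs and a nearly flat cross-entropy landscape, and
measured held-out accuracy on the synthetic cohorts collapsed (median
0.60 vs 0.95 across cohort seeds).  Inputs are z-scored with
training-set constants inside the estimator.

## Preprocessing

Missing numeric cells are filled with the within-diagnosis median
(falling back to the global column median when a class has no observed
value), categorical gaps with the within-class mode.  The fill values
are class-conditional because the cohort's groups differ systematically
in exactly those features; observed cells are never altered, and an
entirely missing column is an error.  Encoding: four numeric features
and age z-scored (zero-variance columns map to zeros), gender and
smoking one-hot against fixed category lists (unseen categories are
errors) — ten columns for the full schema.  The stratified split sends
`⌊0.7 n_c⌋` of each class to training after a seeded within-class
shuffle, so proportions are within one sample of 70/30 per class.

## Diagnostic metrics

One-vs-rest confusion counts feed sensitivity `TP/(TP+FN)`, accuracy
`(TP+TN)/n` and precision = PPV `TP/(TP+FP)` (identical in both
conventions), plus two variants of the remaining metrics:

| metric | canonical | as-printed |
| --- | --- | --- |
| specificity | `TN/(TN+FP)` | `TN/(TN+FN)` |
| prevalence | `(TP+FN)/n` | `(TP+TN)/n` (duplicates accuracy) |
| NPV | `TN/(TN+FN)` | `TN/(TN+FP)` |

The "as-printed" column reproduces a literal reading of the formula set
this package accompanies, in which specificity and NPV have their error
terms swapped relative to the standard definitions and prevalence
repeats the accuracy ratio; the canonical column is the default and the
discrepancy is surfaced rather than silently corrected.  Zero
denominators yield an explicit `None`, never 0.  Multiclass aggregation
is the unweighted (macro) mean over the one-vs-rest reports, computed
over the classes where a metric is defined.

Note that one-vs-rest *macro accuracy* is a lenient quantity: a plain
multiclass accuracy of `a` with `C` classes corresponds to roughly
`1 − 2(1 − a)/C` macro accuracy (≈ 0.625 at 4-class chance).  The
pipeline report therefore also carries the plain overall accuracy, and
chance-level checks use that.

## Synthetic cohort generator

`generate_cohort` emulates the *structure* of a small four-group
respiratory cohort: diagnosis drawn from configurable class weights
(default uniform over asthma/COPD/infected/healthy), four numeric
features with unit within-class standard deviation and class means
placed `effect_size` apart (group `c` is shifted on feature `c`, so
groups are pairwise `effect_size·√2` apart; default 3), age uniform on
[20, 80], gender 50/50, smoking 40/30/30, and numeric cells blanked
completely at random at `missing_rate` (default 0.3 in the pipeline
experiments).  All parameters are recorded in the table's metadata and
the CSV sidecar.  The generator makes no attempt at the physics of
saliva permittivity measurements, realistic marginals, covariate
dependence between demographics and diagnosis, or informative
missingness — so passing tests demonstrate that the algorithms work
when the signal is a separable Gaussian mean shift, not that they would
reach the same numbers on clinical data.  `generate_separable` plants
`d_informative` one-hot-style mean-shifted columns among pure-noise
columns and returns the ground-truth index set for recovery scoring.

## Experiment sizes

The shipped experiments are sized for a single CPU: benchmark runs use
10 dimensions, population 30, 200 iterations and 20 seeds with
evaluation budgets equalized at `pop·(iters+1)` calls per run (the TDO
loop, which spends one or two evaluations per candidate per iteration,
is stopped when the budget is exhausted); feature recovery uses n = 500,
d = 20, 5 informative columns, 10 seeds; the pipeline experiments use
n = 400 cohorts and 5 seeds.  `scripts/acceptance.py` re-runs all of
them from scratch in a few minutes.

## Known limitations

* The improvement margin on rastrigin (median ≈ 5–8 vs ≈ 10–11) is
  modest; individual seed pairs can invert even though batch medians
  did not in any of our five batches.
* Gradient-free training scales poorly with parameter count; the
  defaults keep `P` near 100–200, and substantially larger networks
  would need a different trainer.
* The selection fitness uses 1-NN with Euclidean distance on the
  encoded matrix; one-hot demographics and z-scored numerics share one
  metric, which is standard but crude.
* Imputation and encoding are fit on the full table before the split in
  the pipeline (the selector and classifier are fit on training rows
  only); with class-conditional medians this leaks label information
  into the features: every imputed cell of a class carries that class's
  exact median, a repeatable signature the classifier can exploit.  The
  effect is measurable on cohorts with *no* class separation — at 30 %
  missingness the held-out accuracy sits a few points above 4-class
  chance (medians 0.29–0.39 across seed batches, vs 0.25 exactly when
  `missing_rate = 0`).  The transformers support proper fit/transform
  separation for callers who need it.
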