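# Methods

## Scope and data model

The package re-implements, as tested library code, the dual RSM/ANN
optimization workflow of a *Bacillus* biocontrol cultivation study: OFAT
screening statistics, a four-factor Box–Behnken design (BBD), quadratic
response-surface fits for the inhibition-zone diameter against two
*Aspergillus flavus* isolates, autoencoder-based augmentation of the small
designed dataset with a neural predictor, adjusted-R² model comparison, and
Derringer–Suich desirability optimization of the medium.

The study's run-level responses were never published; only summary tables
are available (fitted coefficient sets, screening group means, ANOVA error
terms, normalization ranges, the optimized medium).  Those summaries are
frozen in `medopt.reference` and anchor both the synthetic-data generator
and the validation suite.

## Synthetic experiment generator

`medopt.synthetic` produces every input the pipeline needs.

* **BBD responses.** Responses are the exact quadratic-surface values of the
  reference coefficient sets plus i.i.d. Gaussian replicate noise, seeded.
  The default noise is σ = 0.5 mm, chosen so that the fitted R² of a 27-run
  design lands in the mid-0.9s — the regime the study reports.  One child
  generator per response keeps columns independent.
* **Screening replicates.** Each group of n replicates alternates m ± d with
  d = √(SS_within/(g·n)), so group means are exact and the within-group sum
  of squares is exact.  This makes the published screening ANOVA (between-SS
  70.95, F 9.55 for carbon; 214.33, 18.692 for nitrogen) reproducible to the
  printed precision from means + error SS alone, which is all the study
  prints.

What the generator does *not* emulate: non-Gaussian replicate error,
run-order drift, plate effects, or any lack-of-fit structure beyond the
quadratic surface.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated error model, not robustness of the
original experiment.

## Design of experiments

`generate_bbd` builds the standard three-level BBD: for each of the C(k,2)
factor pairs, the four (±1, ±1) combinations with all other factors at
center, plus a center-replicate block (27 runs for k = 4 with 3 centers).
The canonical pre-randomization order is fixed (pairs lexicographic,
within-pair (−1,−1), (+1,−1), (−1,+1), (+1,+1), centers last) so fixtures
and diffs are stable; the stored run order is a seeded permutation, and a
seed is mandatory.  Coded/natural conversion is the per-factor affine map
x_nat = center + x_coded·(high−low)/2; out-of-range values raise errors
naming the factor and run.

## Screening statistics

One-way ANOVA delegates to statsmodels OLS (`val ~ C(group)`) with explicit
guards for degenerate partitions (all observations equal → F = 0; zero
within-group variance with unequal means → F = +∞, p = 0; guards are
relative to the data's squared scale so floating-point dust cannot flip
them).  p-values are reported to 6 decimals.

Duncan's multiple range test computes the least significant range for a
stretch of p ordered means as R_p = q*(α_p, p, df)·√(MS_error/n) with the
protection level α_p = 1 − (1−α)^(p−1).  Studentized-range quantiles come
from `scipy.stats.studentized_range` (numerical inversion of the CDF), so
any error df is supported without table lookup; the implementation was
checked against the published screening letter displays (df 35 and 25).
Letters follow the step-down rule: the full stretch is tested against R_g;
a significant stretch is split into its two (p−1)-subsets; a non-significant
stretch is declared homogeneous and its interior is not tested further.
Maximal homogeneous stretches receive letters in ascending-mean order
('a' = lowest mean).  Only balanced groups are supported; harmonic-mean n
for unbalanced groups is a possible extension.

## Response-surface modelling

`fit_quadratic` runs OLS on the expanded basis [1, Xᵢ, XᵢXⱼ, Xᵢ²] via
statsmodels.  Fits are in natural units (g/L) by default: the published
coefficient sets evaluated at natural concentrations reproduce the study's
predicted optimum (30.66 / 27.84 mm), so the published models are
natural-unit models.  Coded-unit fitting is available and yields identical
predictions (different coefficients) — a tested invariant.  Rank-deficient
bases raise an error listing aliased terms; n ≤ 15 runs is refused.

R² and the model ANOVA use corrected (mean-centered) totals.  An
`uncorrected` diagnostic mode partitions raw sums of squares, because the
study's printed model/residual SS partition is consistent only with
uncorrected totals; it is never the default and its values are not
reproduction targets.  Adjusted R² is 1 − (1−R²)(n−1)/(n−p) with p counting
the intercept.

Prediction outside the design box raises a range error unless extrapolation
is explicitly enabled — the fitted surface is only trusted inside the
experimental region.

## Autoencoder augmentation and the neural predictor

All six attributes (four factors, two responses) are min–max normalized
with fixed ranges (cellulose 0–50 g/L, the other factors 0–10 g/L,
responses 10–40 mm).  Per isolate, an autoencoder
(5 → 16 → 16 → 4 → 16 → 16 → 5, elu hidden, sigmoid output) is trained
full-batch on the 27 normalized rows to minimize reconstruction MSE
(momentum gradient descent, lr 0.03 decayed ×0.8 every 10,000 epochs, at
most 50,000 epochs, early stop when relative improvement stays below 1e-8
for 2,000 epochs).  Two hidden layers per side are needed: one layer leaves
the response-column reconstruction error (~0.04 normalized) too large for
any downstream predictor to recover the surface.

**Embedding calibration.** New samples are decoded from embedding vectors
drawn i.i.d. uniform over [−1, 2.5] per dimension.  The scale of an
autoencoder embedding is an arbitrary convention — any invertible affine
change of the embedding, undone inside the decoder, leaves the model
unchanged — so the exposed decoder fixes the convention with an affine input
map that sends the sampling interval exactly onto the per-dimension span of
the training-data embeddings.  Without this calibration the sampled region
and the learned manifold are unrelated scales: in our experiments ~94% of
decoded samples then fell outside the design region and the downstream
validation R² collapsed.

The predictor is a three-hidden-layer perceptron (width 16, elu, single
sigmoid output) trained only on the 10,000 augmented rows (factors →
response) with mini-batch Adam (lr 0.003, ×0.9 every 200 epochs, 400
epochs, batch 256) — Adam shares the stepwise-exponential schedule of the
momentum trainer but its adaptive scaling is required to fit the decoded
manifold's fine structure; plain momentum descent plateaus an order of
magnitude above the achievable loss at any width.  Regularization is a
dropout layer after the first hidden layer (p = 0.05) plus an l2 penalty
with coefficient 0.01 under the per-training-sample convention
(penalty = l2·‖W‖²/2n, the same per-sample scale as the MSE loss).  Both
choices matter and both directions fail: dropout on every hidden layer
injects an output-noise floor that flattens the fit, and l2 = 0 degrades
validation performance over repeated seeds.  Hyperparameter search is
available through seeded 5-fold cross-validation (`cross_validate_predictor`,
ties broken toward fewer neurons) and reconstruction-MSE grid search for the
autoencoder.

The 27 original rows never enter training; `validate_on_original` reports
MSE and R² (against the validation set's own mean) on them.  This is the
augmentation-success check: across repeated seed sets the validation R²
averages ≈ 0.82 (range ≈ 0.77–0.87), at the level the study reports for its
own data.  For the family comparison, the neural model's adjusted R² is
computed from this validation R² with p = 5 (four inputs + intercept) on 27
rows — the unique convention that connects the study's reported validation
and adjusted coefficients.

## Desirability optimization

Goals are Derringer–Suich ramps: minimize d = ((high−v)/(high−low))^w,
maximize d = ((v−low)/(high−low))^w, in-range indicator, two-sided target
ramp; weights are exponents in [1, 5] (3 throughout the study's goal set).
Overall D is the geometric mean; any zero goal zeroes D.  `optimize_medium`
maximizes D over the factor box with multi-start bounded Nelder–Mead: all
2^k corners plus the center deterministically, topped up with seeded uniform
interior starts (default 64 total); near-ties in D (1e-9) resolve toward the
lower total nutrient mass.

With the study's goal set the optimum lands on the corner cellulose 5.00,
urea 0.00, phosphate 0.50 g/L — certified analytically: both response
surfaces have negative partial slopes in those three coordinates at the
published optimum, and the cellulose/urea desirabilities also fall in those
directions, so no interior move can raise D.  The ammonium-sulfate
coordinate is interior and depends on the response-desirability bounds,
which the study does not publish; with the instrument range (10–40 mm) the
optimizer settles near 2 g/L, with bounds taken from the observed response
range it settles near 3.7 g/L.  The study's printed overall D = 0.75
likewise depends on those unpublished bounds and is deliberately not a
reproduction target.

## Numerical and engineering choices

* Studentized-range quantiles: scipy's numerical CDF inversion; no Duncan
  tables.
* OLS conditioning: the natural-unit quadratic basis for this design has
  condition number ≈ 7.5e3; statsmodels' pinv-based solve recovers
  noise-free coefficients to ~1e-13 absolute.
* Every stochastic component takes an explicit integer seed; the pipeline
  derives stage seeds from the master seed with CRC-stable labels, so
  reports embed everything needed to reproduce them.
* Networks are plain numpy; gradients were verified against finite
  differences to 1e-11.
* Problem sizes in the test suite: 27-run designs, 200-seed recovery loops,
  8,000-epoch autoencoder fits on a 1,000-row fixture, one full
  augmentation arm (50,000-epoch autoencoder, 10,000 decoded samples,
  400-epoch predictor) — the same sizes the analysis drivers use.

## Known limitations

* Duncan's test supports balanced groups only.
* Lack-of-fit ANOVA from center-replicate pure error is not implemented
  (the study's raw replicates are unavailable to compare against).
* The augmentation branch's validation R² is seed-dependent (≈ ±0.05);
  single runs near the decision threshold should be repeated over seeds.
* The desirability optimizer treats only box constraints; no mixture or
  cost-weighted objectives beyond the goal grammar.
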