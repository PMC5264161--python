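# Methods

## Scope

`fuzzywave` models the removal of dimethyl phthalate (DMP), a priority-pollutant
plasticizer, in a staged anaerobic/anoxic/oxic (AAO) activated-sludge train.
It implements two complementary models and the machinery to compare them:

1. a **fuzzy wavelet neural network (FWNN)** — a data-driven soft sensor that
   predicts effluent DMP from five routine process variables (pH, influent
   DMP, DO, ORP, MLSS), trained by a hybrid genetic-algorithm +
   gradient-descent scheme;
2. a **Monod-type hydrolysis kinetic model** — an ASM2-style mechanistic
   description of per-zone DMP degradation, with parameters estimated by
   double-reciprocal linearization.

Because the plant measurements behind the original study are not publicly
deposited, the package ships a synthetic data generator that emulates the
reactor's stated operating envelope; every experiment in the test suite and
the acceptance script runs on data this generator produces.

## The FWNN

The network is a Takagi–Sugeno–Kang fuzzy system with `R` rules over `n`
inputs (the reference configuration is `R = 8`, `n = 5`):

* **Fuzzification.** Each input `x_i` is matched against rule `j` by a
  Gaussian membership `F_ji = exp(-(x_i - c_ji)^2 / (2 σ_ji^2))`.
* **Rule strength.** Product AND: `μ_j = Π_i F_ji ∈ (0, 1]`.
* **Wavelet consequents.** Each rule carries a wavelet neuron
  `ψ̂_j = w_j Π_i ψ((x_i - b_ji)/a_ji)` with dilations `a`, translations `b`
  and one consequent weight `w_j` per rule.
* **Aggregation.** Default is the TSK normalized weighted mean
  `ŷ = Σ_j μ_j ψ̂_j / Σ_j μ_j`; a plain weighted sum is selectable.

Design choices where the architecture admitted more than one reading:

* **Mother wavelet**: Mexican hat `ψ(z) = (1 - z²) e^{-z²/2}`, the standard
  choice for wavelet networks; Morlet (`cos(5z) e^{-z²/2}`) is available via
  the `wavelet` option. The packaged reference parameter set is evaluated
  with the Mexican hat.
* **Per-input combiner at the wavelet layer**: product across inputs,
  consistent with the single per-rule weight in the reference parameter
  tables and with the product AND at the rule layer.
* **Aggregation**: normalized (TSK) by default. The normalized form is scale
  stable — the output always lies inside `[min_j ψ̂_j, max_j ψ̂_j]` — and is
  what a TSK reading of the architecture implies; `aggregation="sum"`
  reproduces the plain-summation reading.
* **Membership exponent**: the conventional `2σ²` denominator.

Spreads and dilations enter only through even functions, so their sign is
irrelevant; the reference tables contain negative entries and the code
accepts them. Exact zeros are rejected (both are divisors).

### Numerical safeguards

* Exponential arguments are clipped at 700 so single memberships never
  underflow to zero; a product of several memberships still can, and when
  the *summed* firing strength falls below 1e-300 in normalized mode the
  forward pass raises a degenerate-activation error rather than silently
  dividing 0/0 — this signals a probe far outside the fuzzified region.
  During GA search the same condition is converted to fitness 0 so the
  search simply discards such individuals.
* `decode` clamps spread/dilation genes with magnitude below 1e-6 to ±1e-6,
  and gradient-descent steps re-apply the same floor after each update.

## Hybrid training

All training happens on scaled data (symmetric min–max to [-1, 1] by
default, fitted on the training split only).

**Stage 1 — real-coded GA.** Chromosome = concatenation of centers, spreads,
dilations, translations (row-major) and weights. Defaults follow the study
configuration: population 100, crossover rate 0.3, mutation rate 0.09,
200 generations. Operators: tournament selection of size 2, per-gene
arithmetic (blend) crossover, per-gene Gaussian mutation with standard
deviation 10 % of the initialization range, elitism of 2. Initialization
ranges (centers/translations in [-2, 2]; spreads/dilations in [0.1, 3] with
a random sign; weights in [-3, 3]) bracket the magnitudes of the reference
parameter set. Fitness is `1/(1 + MSE)`. The best-so-far trace is
non-decreasing by construction.

**Stage 2 — plain gradient descent.** Full-batch descent on the training
MSE with analytic gradients for every parameter group (validated against
central finite differences to 1e-5 relative in the test suite; a `numeric`
gradient mode exists as a slow fallback). Defaults: learning rate 0.01,
500 epochs, stopping early when the MSE reaches 1e-4. No momentum or
adaptive-rate machinery — refinement is deliberately plain, and the
`groups` argument can freeze parameter groups (used by the tests to check
the weights-only quadratic case against its least-squares solution).

Every stochastic operation takes an explicit seed; identical seeds
reproduce bit-identical traces and reports.

**GA-NN baseline.** The comparison baseline is a single-hidden-layer
perceptron (tanh hidden units, linear output) trained by the identical
GA → GD schedule. With `hidden_units=0` it degenerates to a pure linear
model, which the tests pin against ordinary least squares.

### Known limitation: multimodal recovery

The teacher–student benchmark (2-rule, 2-input teacher, 200 noise-free
samples, GA population 40 × 60 generations, 300 descent epochs) has a
multimodal search landscape: across 20 independent seeds, 13 runs reach
train RMSE < 0.05 while the remainder stall in basins around 0.06–0.12
where one rule is misplaced and gradient descent cannot relocate it. The
recovery tests therefore run at a fixed seed, and the acceptance script
reports the median over five replicates. Stronger recombination variants
(extended intermediate crossover, random immigrants) were evaluated and did
not materially change this spread at the fixed budget.

## Kinetics

With the substrate-to-biomass ratio `u = S/X_H` (ASM2 convention; a pure
substrate variant is available), the specific hydrolysis rate is

    r = η · K · u/(Ks + u) · X_H · [switching functions]

with per-zone switching multipliers `S_O2/(K_O2+S_O2)` (aerobic),
`K_O2/(K_O2+S_O2) · S_NO3/(K_NO3+S_NO3)` (anoxic) and
`K_O2/(K_O2+S_O2) · K_NO3/(K_NO3+S_NO3)` (anaerobic). Switching
coefficients default to 0.2 mg/L (conventional ASM2 values) and the
multipliers can be disabled (`pure_monod=True`) — all parameter estimation
uses the simplified pure-Monod form.

**Estimation.** The double-reciprocal (Lineweaver–Burk) transform
`x = 1/u, y = 1/v` turns the Monod law into the line `y = (Ks/K) x + 1/K`,
fitted by ordinary least squares; then `K = 1/intercept`,
`Ks = slope/intercept`, and the hydrolysis reduction factor of a zone is
`η = K_zone / K_aerobic`, capped at 1 (η ≡ 1 aerobically). Constants are
reported rounded to two decimals; full precision is retained internally.
The reference constants are K = 9.68/11.36/14.27 with Ks =
148.31/180.81/95.89 and η = 0.68/0.80/1 for the anaerobic/anoxic/aerobic
zones. (The aerobic Ks printed alongside the published fit coefficients is
consistent with an unrounded intercept; the closure test allows 0.1 %.)

**Zone chain.** Each zone is a steady-state completely-mixed reactor:
`S_in - S_out = r(S_out) · HRT`, solved by bisection on `[0, S_in]`
(tolerance 1e-9; the rate is monotone in S, so the bracket always holds),
chained anaerobic → anoxic → aerobic. Degenerate cases short-circuit:
zero influent returns zero, zero reaction returns the influent.

**Identifiability caveat.** At operating concentrations the system is deep
in the first-order regime (`u ≪ Ks`), where only the ratio `K/Ks` is well
determined: the double-reciprocal intercept (hence `K` itself) is nearly
unidentifiable from operating data, and noisy fits routinely produce
non-positive intercepts. `coefficients_to_params` treats those as
non-physical and raises; the comparison harness therefore predicts with the
fitted rate *curve* `v(u) = u/(slope + intercept·u)`, which is well behaved
over the observed range regardless, and reports physical `(K, Ks)` only
when the intercept is positive. Separating `K` from `Ks` requires dedicated
rate experiments spanning concentrations up to the half-saturation scale,
which is how the package's recovery tests are constructed
(`u` up to ≈ 3·Ks).

## Evaluation metrics

`compute_metrics` returns MSE, RMSE (= √MSE, an exact internal identity
asserted on every computed instance), MAPE in percent, and
`R² = 1 - SS_res/SS_tot`. MAPE is flagged undefined when an observed value
is exactly zero; R² when the observations have zero variance. Metrics for
the model comparison are computed on the original concentration scale by
default (`space="scaled"` switches to the scaled target space); which space
a published error table uses is generally ambiguous, so both are exposed.

## Synthetic data generator

The generator emulates the reactor's stated operating envelope:

| variable | distribution | source |
|---|---|---|
| influent DMP | one of {30, 40, 50, 60, 80} µg/L ± 2 µg/L jitter | stated feed levels |
| DO (aerobic) | uniform [2.54, 5.72] mg/L | stated range |
| MLSS | normal(3000, 150) mg/L, clipped positive | stated ≈ 3000 mg/L |
| pH | uniform [6.8, 7.8] | generator convention |
| ORP | uniform [-250, +150] mV | generator convention |

The pH and ORP ranges are package conventions (plausible for activated
sludge); neither variable enters the kinetic mechanism, so in the default
mode they are deliberately uninformative nuisance inputs — a useful stress
test of whether the data-driven models tolerate irrelevant variables.

**Kinetic teacher (default).** Effluent DMP is the deterministic output of
the three-zone chain with the reference kinetic constants and the row's
MLSS as biomass, times multiplicative lognormal noise (default sd 0.05,
which keeps concentrations positive), then capped at the influent so noise
cannot create mass. Zone residence times default to 2.5/2.5/10 in the
internal time unit of the rate constants — the 1:1:4 ratio of the
40/40/160 L zones — chosen so the default configuration removes roughly
60–70 % of influent DMP, a realistic operating point. (The published rate
constants carry no stated units, so the residence times are expressed in
whatever time unit those constants imply; only their product matters.)

**FWNN teacher.** Effluent is a known random FWNN (`make_teacher_fwnn`,
well-conditioned by construction) evaluated on min–max-scaled inputs, plus
additive Gaussian noise, mapped affinely to concentration units. This mode
underlies the function-recovery experiments.

What the generator does **not** emulate: temporal autocorrelation, influent
dynamics, sensor drift, sorption, or any genuine dependence of removal on
pH/ORP/DO. Consequently, passing tests demonstrate correctness of the
algorithms and internal consistency of the models on data with the stated
marginal structure — not predictive validity on a real plant.

## The three-model comparison

`run_comparison` evaluates the FWNN, the GA-NN baseline and the kinetic
model on an identical seeded 35/15 split, with scaling fitted on the
training split only. The kinetic column is *estimated*, not oracular: the
training split is treated as one effective completely-mixed reactor over
the total residence time, per-sample rates are linearized and fitted, and
the fitted curve predicts the test effluent. Default training budget for
the two learned models: population 60, 120 generations, 500 descent epochs.

Because the default benchmark data are generated *by* the kinetic model,
the refit kinetic column sits essentially at the observation-noise floor,
and a learner estimated from 35 noisy samples in five inputs cannot
systematically undercut it — the corresponding acceptance check fails by
construction and is retained as an honest negative result. On data whose
mechanism departs from the kinetic family (or in the FWNN-teacher mode) the
ordering reverses.

## Problem sizes

Experiments are sized for a single CPU: 50-sample datasets with a 35/15
split (the study's design), 200-sample teacher–student sets, GA populations
of 40–100 over 40–200 generations, and ≤ 10 replicate seeds per property.
The full test suite and the acceptance script each complete in well under a
minute of compute apiece at these sizes.
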