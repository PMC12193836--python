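# Methods

## Optimizer model

The package implements a population metaheuristic for box-constrained
minimization. The canonical grey-wolf search moves every candidate
toward the mean of three points obtained by "encircling" the three best
pack members; its only schedule is the linear decay `a(t) = 2(1 −
t/T_max)` of the exploration radius. The enhanced variant (LGWO) layers
five further moves on top, all accepted greedily so the tracked best
fitness is non-increasing by construction:

1. **Weight factor.** `O(t) = ((T_max−2)/T_max)(w_s − (w_s−w_e)·(2/π)·
   arctan(a + b·t))²` decays smoothly from ≈0.60 at t = 0 toward
   `((T_max−2)/T_max)·w_e²`. The arctan is normalised by 2/π so the
   bracket runs from near `w_s` to `w_e`; the unnormalised reading
   (`arctan(·)·2π`) makes the bracket negative and oscillatory and is
   kept only behind `literal_weight=True` for study.
2. **Lévy repositioning (stagnation-gated).** When the best fitness has
   improved by less than `tol·max(1, |f_old|)` over the last `w`
   iterations (defaults `tol = 1e-12`, `w = 5`), every non-leader wolf
   is displaced by `0.01 · s ⊙ (x − x_α)` with per-coordinate Mantegna
   steps `s = u/|v|^{1/β}`. The max(1, ·) floor makes the test behave
   as a relative-improvement criterion at ordinary scales while staying
   meaningful once the best fitness is below machine precision — without
   the floor the trigger can never stay active during the contraction
   cascade (each contraction is a large relative improvement), and the
   exact-zero finishes on the origin-centred functions become
   unreachable.
3. **Best-wolf jumps (every iteration).** A Lévy jump
   `x_best + O·L·(x_best − x_worst)` and an opposition candidate
   `ub + lb − L·x_best` challenge the incumbent best.
4. **Per-wolf drift and contraction (every iteration).** Each wolf
   proposes `x + L(x_best − x)` and `O·x`; the best of the three is
   kept. Applying these unconditionally (rather than only under the
   stagnation trigger) follows the procedure's step listing, in which
   only the Lévy repositioning carries the "no substantial improvement"
   condition; it is also what makes the max-norm objective (f4) collapse
   to exact zero within the 500-iteration budget.
5. **Mutation (probability `pp` per wolf per iteration).** The
   Harris-Hawks-style pair `x₃ = x_r − r₁|x_r − 2r₂x|` and
   `x₄ = (x_best − x̄) − r₃((ub−lb)r₄ + lb)`, with each `rand` a scalar
   draw shared across coordinates (the Harris-Hawks convention).
   Scalar draws matter: they let `x₄` explore rays through the search
   box that regenerate diversity in coordinates the pack has collapsed,
   which per-coordinate draws cannot do once a coordinate's spread is
   gone.

**Elitism.** The plain sweep is not greedy, so a discovery can be washed
out of the pack one iteration later. As part of the enhancement suite
the incumbent best is re-seated into the worst wolf's slot whenever the
pack no longer contains it. This is what lets the pack settle and polish
fixed-dimension optima (Shekel's foxholes to 9.98E-01, Kowalik to
3.07E-04) instead of churning around them.

**Reduction.** With `mutation_prob = 0` and `stagnation_window ≥
max_iter` the entire enhancement suite (including elitist re-seating) is
off and the engine consumes exactly the same random stream as the
canonical optimizer: runs are bitwise identical on shared seeds. This is
enforced by test.

**Why exact zeros are attainable.** All moves are clamped to the box,
objectives are evaluated in IEEE doubles, and the sphere-family optima
sit at the origin. Once the pack is near the optimum the greedy
contraction `O·x` (O ≈ 0.06–0.6) shrinks the best position
geometrically; after a few hundred accepted contractions the coordinates
underflow to exactly 0.0 and e.g. `Σx²` evaluates to exactly 0. On
Ackley the same collapse drives the expression to its double-precision
floor `−20 − e + 20 + e = 4.44e-16`. These are floating-point facts, not
statements about the mathematical infimum being attained.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_agents` | 30 (benchmarks), 5 (network training) | pack size; the training value is the stated configuration for weight search |
| `max_iter` | 500 / 30 | iteration budget (same split) |
| `ws, we` | 1.5, 0.1 | start/end of the weight-factor bracket |
| `a_const, b_const` | 1, 0.01 | arctan offset and slope |
| `beta_levy` | 1.5 | Lévy tail index; the cuckoo-search convention (β = 2 is the degenerate Gaussian case and is rejected by the sampler) |
| `levy_scale` | 0.01 | step multiplier of the repositioning move |
| `mutation_prob` | 0.1 | per-wolf mutation probability; a typical mutation rate, exposed in config |
| `stagnation_window`, `stagnation_tol` | 5, 1e-12 | scale-guarded relative-improvement stagnation test |
| `clamp` | True | project every move onto the box. Unclamped runs (`clamp=False`) exist for studying the unbounded escape on the Schwefel function, whose objective is unbounded below outside its box |
| network | 6 hidden units, weights in [−1, 1], threshold 0.5 | the stated training configuration; ties at exactly 0.5 map to class 1 for determinism |
| refinement | lr 0.5, 500 epochs, full batch | unspecified upstream; at lr 0.1/100 epochs full-batch MSE descent through two sigmoids barely moves (separable-fixture accuracy 0.72–0.89), while 0.5/500 attains 1.0 across seeds. Both are config values |
| loss | MSE on the sigmoid output | the classical BP pairing; Bernoulli log-loss available via `loss="cross_entropy"` |

Feature columns are min–max scaled to [0, 1] inside the sklearn
estimator before training (scaling stored for prediction): with weights
confined to [−1, 1], unbounded inputs would saturate the first sigmoid
layer.

## Statistics

The rank-sum test is the normal approximation with midranks,
tie-corrected variance and a 0.5 continuity correction — the formula
whose n=30 signatures are 3.02E-11 (fully separated, tie-free) and
1.21E-12 (one sample fully tied). The signed-rank test drops zero
differences, enumerates the exact null distribution (dynamic program
over doubled midranks) for n ≤ 25 and uses the tie-corrected normal
approximation with continuity correction beyond. Run tables report the
sample standard deviation (ddof = 1). AUC is the pairwise probability
`P(score⁺ > score⁻) + ½P(tie)` computed from midranks, identical to the
trapezoidal ROC area; ties in the decision threshold get half credit.
Degenerate cases are reported, not fudged: single-class AUC is missing
with a warning, zero-spread Cohen's d is NaN, identical samples give
p = 1.

## Synthetic data

The generator emulates the *statistical shape* the pipeline consumes: n
samples, p continuous features, Bernoulli(π) 0/1 outcome, and
k_informative features with a class-mean shift of δ feature-sd units
plus N(0, noise²) jitter. The planted point-biserial correlation has the
closed form `δ√(π(1−π)) / √(δ²π(1−π) + 1 + noise²)`, so δ = 0.4 at
π = 0.5 plants |r| ≈ 0.19 — inside the 0.10–0.23 importance range
typical of prognosis feature rankings. What it deliberately does *not*
emulate: heavy-tailed and zero-inflated omics marginals, feature–feature
correlation structure, batch effects, censoring. Passing tests therefore
demonstrate the machinery (selection recovers planted signal, the hybrid
trainer fits what is fittable), not clinical performance on real
cohorts.

Fixtures: `separable` (n=200, p=5, margin-0.3 linear rule; an explicit
one-hidden-unit parameter vector classifies it perfectly), `xor` (n=400,
four balanced corner clusters, best hyperplane exactly 75%), and
`imbalanced` (π = 0.1) for label-swap metrics.

## Numerical and design notes

* Leaders are a stable top-3 sort of fitness; ties break by lower agent
  index. The sweep is synchronous (one leader snapshot per iteration).
* Non-finite objective values are recorded as +∞ so such a wolf can
  never lead.
* The initial pack counts toward the evaluation budget; `curve[t]` is
  the best-so-far after iteration t, so `curve` is non-increasing and
  ends at `best_fitness`.
* `L` in the best-wolf/drift/contraction moves is a fresh scalar Lévy
  draw per candidate; the repositioning move uses per-coordinate draws
  (it is written with a vector factor `x − x_α`).
* The Mantegna denominator uses |v| before the 1/β power; the sign of a
  step comes from the numerator.
* On the noisy quartic both sides of every greedy comparison are
  re-evaluated (no fitness caching across noise draws).

## Known limitations

* Escape from the second/third Shekel foxhole to the global one is
  stochastic with a small per-run failure probability (~3% under the
  default budget); over 30 seeded runs the mean is occasionally pulled
  from 0.998 to ≈1.06 by a single trapped run. The best-of-30 always
  reaches 9.98E-01.
* The Schwefel function (f7) outside its box is unbounded below;
  clamped runs cannot reproduce unbounded escape artefacts, and no
  result is claimed for f7.
* Comparator metaheuristics (TSA, ROA, DBO, RUN, GJO, LCA, PSA, BKA)
  are out of scope; only the canonical grey-wolf baseline is built.
* Multiclass outputs, momentum/adaptive gradient optimizers, multiple
  hidden layers and real-data acquisition are out of scope.
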