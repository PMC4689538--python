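# Methods

## Model

A two-compartment cell lineage: `I` stem cells (SCs) and `J` differentiated
cells. At each update of a discrete stochastic process exactly one of the
following happens, with probabilities evaluated at the current state:

| event                     | probability   | change                  |
|---------------------------|---------------|-------------------------|
| symmetric differentiation | `L·S·P`       | `(I, J) → (I−1, J+2)`   |
| symmetric proliferation   | `L·S·(1−P)`   | `(I, J) → (I+1, J)`     |
| asymmetric division       | `L·(1−S)`     | `(I, J) → (I, J+1)`     |
| death                     | `D`           | `(I, J) → (I, J−1)`     |
| influx (optional)         | `E`           | `(I, J) → (I+1, J)`     |

`L` is the division rate, `S` the probability a division is symmetric, `P` the
probability a symmetric division produces two differentiated daughters, `D`
the death rate of differentiated cells, `E` an exogenous SC source. All are
functions of the scaled populations `x = εI`, `y = εJ`; the feedback-strength
parameter `ε > 0` makes rates depend weakly on counts, so equilibrium
populations scale as `1/ε`. Rates are population-level (per update), not
per-capita: `L` is the probability that *some* SC divides in an update. This
matches homeostatic tissue where division pressure is a property of the niche
rather than proportional to cell number, and it is the regime in which the
moment expansion below closes.

The mean-field (deterministic) limit, in counts per update,

    dI/dt = L·S·(1 − 2P) + E,
    dJ/dt = 2·L·S·P + L·(1 − S) − D,

has two families of steady states for closed systems (`E` absent):

* **mixed divisions**: `P = 1/2` and `L = D` — symmetric differentiations and
  proliferations balance;
* **purely asymmetric**: `S = 0` and `L = D` — a single scalar condition in
  two unknowns, hence generically a one-parameter *curve* of states.
  `solve_asymmetric` detects this via the rank of the residual Jacobian and
  flags the result `underdetermined` rather than silently picking a point.

Neither steady state depends on `S`; only stability and fluctuation size do.
With an influx the SC balance forces `P > 1/2` at stationarity, so the mixed
state does not exist and `solve_mixed` refuses such networks; their operating
point is obtained from the mean-field attractor instead. (The deterministic
influx term is written at the same population-rate scale as the other events —
one arrival raises `I` by one per update — which makes the ODE fixed point
agree with the stochastic stationary mean.)

## Controls and the linear-noise approximation

The *controls* are the four partial derivatives, at equilibrium, of the net
growth rate `L − D` (written `q_x`, `q_y`) and of `P` (written `p_x`, `p_y`)
with respect to the raw counts; each carries one factor of `ε`. Expanding the
master equation around the mixed state and keeping leading orders in `ε`
yields a linear system for the centred moments. The first-moment equations
are homogeneous with determinant `−Δ ≠ 0`, so the mean corrections vanish at
this order and the first-derivative terms of `L`, `D`, `S` drop out of the
second moments (the package's `solve_moment_system` keeps them and the test
suite verifies the cancellation numerically). The variances are

    Var[I] = K_x / (4·B·Δ),      Var[J] = K_y / (4·B·Δ),
    Δ   = q_x·p_y − q_y·p_x,
    B   = 2·L*·S*·(p_x − p_y) − q_y,
    K_x = 2·L*·S*·Δ + q_y² + 8·L*²·S*·p_y²,
    K_y = 2·L*·(2 + S*)·Δ + q_x² + 8·L*²·S*·p_x².

The mixed state is stable iff `Δ > 0` and `B > 0`. `S*` enters only through
`B`, so the stability boundary in the symmetric fraction is the critical value

    S_c = q_y / (2·L*·(p_x − p_y)),

with stable window `S* > S_c` when `p_x > p_y` and `S* < S_c` when
`p_x < p_y`; at `p_x = p_y` the verdict is independent of `S*` and `S_c` is
reported as signed infinity rather than raising.

Differentiating the variances in `S*` gives closed forms

    dVar[I]/dS* = (L*/2)/(B²·Δ) · p_y·q_y·(q_y − q_x − 4·L*·p_y),
    dVar[J]/dS* = (L*/2)/(B²·Δ) · (p_x·q_x − Δ)·(q_y − q_x − 4·L*·p_y).

The prefactor `L*/2` is the exact derivative of `K/(4BΔ)`; these expressions
are sometimes quoted with prefactor `L*²`, which coincides with `L*/2`
exactly when `L* = 1/2` — the value every network with complementary death
`D = 1 − L` takes at equilibrium, including all presets here. Only the
prefactor differs: every sign conclusion is identical. For fixed controls the
dependence of each variance on `S*` is monotone.

## Enumeration of minimal control networks

A *sign pattern* fixes the signs of the four controls. It is *stabilizable*
when strictly positive magnitudes, some `L* > 0` and some `S* ∈ (0, 1]` make
`Δ > 0` and `B > 0`. Because the magnitudes, `L*S*` and the pattern's free
scales enter each condition through independently scalable terms, feasibility
is an exact calculus on signs. Writing `sa = sign(q_x·p_y)`:

* `q_y < 0`: `B > 0` is achievable at small `L*S*`; need `Δ > 0`, i.e.
  `sa = +1` or `p_x > 0` (so that `−q_y·p_x > 0`).
* `q_y = 0`: `B = 2·L*S*·(p_x − p_y)` needs `p_x − p_y > 0` achievable
  (`p_x > 0` or `p_y < 0`), and `Δ = q_x·p_y > 0` needs `sa = +1`.
* `q_y > 0`: `B > 0` forces `p_x − p_y > 0` to dominate `q_y`; if `p_x > 0`
  the term `−q_y·p_x < 0` in `Δ` can only be beaten by `sa = +1`; if
  `p_x ≤ 0` one needs `p_y < 0` for `B` and either `sa = +1` or `p_x < 0`
  (which makes `−q_y·p_x > 0`) for `Δ`.

A 1000-draw log-uniform magnitude sampler cross-checks this decision on all
81 patterns (they agree everywhere). Exactly two stabilizable patterns have
two nonzero controls — `(q_x<0, p_y<0)` and `(p_x>0, q_y<0)` — and exactly
three three-control patterns are irreducible (no single zeroing leaves a
stabilizable pair): `(q_x>0, q_y<0, p_y>0)`, `(q_y>0, p_x<0, p_y<0)` and
`(q_x>0, p_x>0, p_y>0)`. Classification assigns the variance-versus-`S*`
trends from the closed-form sensitivity signs sampled over stable magnitudes
(the `Var[I]` trend is an exact structural zero whenever `p_y·q_y = 0`).

## Presets

* **model3** (`q_x>0, q_y<0, p_y>0`): `L = (1−e^{−x})/(1−e^{−x}+y)`,
  `P = 1−e^{−3y}`, `D = 1−L`. Mixed state `x0 = −ln(1−ln2/3)`, `y0 = ln2/3`.
  Both variances grow with `S*`: asymmetric divisions are optimal.
* **model5** (`q_x>0, p_x>p_y>0`): `L = 2·tanh x/(2·tanh x+0.4)`,
  `P = tanh(x+0.1y)`, `D = 1−L`. Mixed state `x0 = ln1.5/2`,
  `y0 = (ln3−ln1.5)/0.2`. `S_c = 0`; `Var[I]` is independent of `S*` (exact
  cancellation) and `Var[J]` falls with it: symmetric divisions are optimal.
* **follicle**: an epidermal variant of the positive-control wiring with
  `L = 0.9·tanh x/(2·tanh x+0.4)`, `D = h + 0.01y` and an optional SC influx
  `E = 0.02/(1+x)` that stands for hair-follicle contribution; `influx=False`
  models hairless (e.g. footpad) skin. Defaults `h = 0.3`, `ε = 0.05` put the
  operating point at small populations (`i0 ≈ 9`, `j0 ≈ 17–47`), deliberately:
  the interesting effects are relative-fluctuation effects.

`S` is a constant `c ∈ (0, 1]` in all presets; its derivatives never enter
the stability conditions or variances, so nothing is lost by the choice.
Custom networks may supply any expressions (including non-constant `S`).

## Simulator

One "time step" is one update attempt. For closed presets with `D = 1 − L`
the five weights sum to exactly 1 and every update is an event. Otherwise the
per-step scheme treats weights as literal Bernoulli probabilities when their
sum is ≤ 1 (a "none" event absorbs the remainder) and normalizes by the sum
when it exceeds 1, recording the sum whenever an influx is present so event
counts can be converted to process time. An exact event-time scheme
(exponential waiting times, same embedded chain) is available. Death is
suppressed at `J = 0` and divisions at `I = 0`, so counts never go negative;
a zero total weight with no influx terminates the run as "frozen".

Micro-injuries model abrasion of exposed tissue: each update is independently
an injury with probability `update_fraction` (default study condition `10⁻⁴`),
removing `round(removal_fraction·J)` differentiated cells (study condition
10%). Variants — transient death-rate multiplier, SC removal, removal of both
pools — are exposed with user-set parameters; direct SC damage is the less
plausible biology (SCs sit deeper) and is off by default.

Runs stop on extinction of either population by default, following the
convention used for the large-population presets. For the small-population
follicle regime `J = 0` is a recoverable transient (divisions immediately
replenish it), so sweeps there run with `stop_on_extinction=False` and start
from the per-`S` mean-field attractor; genuinely absorbing states still
terminate through the frozen-state rule.

Moment estimates are per-step averages over the realized time course
(population variance, burn-in 0 by default). Two relative-fluctuation
measures are reported for the differentiated pool: `rel_sd_J = Var(J)/E(J)`
(variance-to-mean ratio) and `cv_J = sd(J)/E(J)` (relative standard
deviation). They differ in trend whenever the mean itself shifts with `S` —
which it does under an influx, where the SC source inflates the differentiated
pool at small `S`. The injury comparison is monotone under either measure;
the with/without-influx comparison is a statement about fluctuation size
relative to population size and uses `cv_J`: with the influx present `cv_J`
grows with `S` (asymmetric divisions optimal), without it `cv_J` falls
(symmetric divisions optimal).

Replicate seeds derive from `(base seed, S-grid index, replicate index)`
through numpy's `SeedSequence`, giving independent yet bit-reproducible
cells; identical config and seed reproduce a trajectory bit-exactly.

## Numerical choices

* Controls: central finite differences with step `1e-6·max(1, |coordinate|)`
  (controls are `O(ε)`; absolute steps must not swamp them). Networks with
  analytic derivatives can bypass this by evaluating their own formulas.
* Steady states: damped Newton (step halving, pseudo-inverse step for
  rank-deficient Jacobians) from `(1, 1)` in scaled coordinates, with a 6×6
  log-grid multi-start on `[1e-3, 10]²`; residual tolerance `1e-12`; multiple
  distinct roots warn and return the one from the default guess.
* Mean-field ODE: LSODA, `rtol 1e-9`, `atol 1e-12`; a configurable state
  bound (default `1e9`) converts blow-up into a `DivergenceError`.
* Degenerate linearizations (`Δ = 0` or `B = 0`) raise rather than return
  infinities; `S_c` uses extended reals at `p_x = p_y`.
* JSON floats are serialized to 12 significant digits; trajectory CSVs are
  comma-separated with LF endings.

## Validation against exact results, and known limitations

The closed-form variances were checked three ways: against an independent
brute-force solve of the full moment system (agreement to ~1e-14 relative,
including the cancellation of first-derivative nuisance terms), against
simulation (below), and — for the simulator itself — against the exact
quasi-stationary distribution of the update chain on a truncated lattice
(power iteration on the sub-stochastic matrix killed at `I = 0` or `J = 0`),
which the empirical time-averages reproduce.

The leading-order theory has two visible finite-`ε` limitations, both genuine
properties of the expansion rather than implementation artifacts:

* **Mean offset.** The true stationary mean exceeds `(i0, j0)` by an `O(1)`
  absolute amount (the next order of the expansion, dropped here). Measured:
  the offset is constant in `ε` over a tenfold range — about `+2.2` SCs for
  model3 and `+1.0` for model5 — i.e. a relative deviation of order `ε` (2–4%
  at `ε = 0.005`), and the exact quasi-stationary mean shows the same shift.
  Consequently the empirical mean converges, with enough replicates, to a
  point a few percent away from `(i0, j0)`, and no amount of sampling brings
  it within a shrinking standard-error band of the leading-order value.
* **Breakdown near the extinction boundary.** When the predicted fluctuation
  scale becomes comparable to the mean (model3 at `S = 1`, `ε = 0.005`:
  `sd_I ≈ 19` on `i0 ≈ 52`), trajectories reach the absorbing boundary within
  `2·10⁵` updates, the realized process is censored and skewed, and empirical
  variances exceed the Gaussian prediction by tens of percent. This is the
  destabilization-at-high-symmetry regime the theory itself predicts for that
  network; quantitative variance agreement should only be expected in the
  interior of the stable window (for model3, `S ≲ 0.8` at this `ε`, where
  agreement is within ~14%).

What the presets do and do not emulate: they reproduce homeostatic
fluctuations of an autonomously controlled two-compartment lineage with the
stated feedback wirings. They do not model spatial structure or niche
geometry, wound-healing-scale (far-from-equilibrium) dynamics, intermediate
progenitor compartments, or mechanistic signaling detail beyond the sign
structure of the controls; passing tests therefore validate the stochastic
and analytic machinery, not any particular tissue's parameter values.

## Problem sizes used by the test suite

Simulation-versus-theory checks use `ε = 0.005`, 20 replicates × `2·10⁵`
updates per `(preset, S)` cell over `S ∈ {0.3, 0.5, 0.8, 1.0}`; perturbation
trends use 10 replicates × `2·10⁵` updates over `S ∈ {0.2, …, 1.0}` with the
injury condition (`10⁻⁴`, 10%) at `ε = 0.002` and the follicle comparison at
`ε = 0.05`, `h = 0.3`. The full suite runs in a few minutes on one CPU.
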