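# Methods

## The model

`litmix` implements a discrete-time (daily) model of litter decomposition in
which moisture is the only driver. One litter is described by four constants
— the water content at saturation `LWC_max` (g water g⁻¹ dry matter), the
maximum decomposition rate `k_max` (d⁻¹), the evaporation rate `e` (d⁻¹,
the fraction of currently held water lost per day) and a pair of
Michaelis–Menten constants — and two state variables, the litter water
content `LWC_t` and the remaining mass `M_t` (tracked as a fraction of the
initial dry mass). Each day, in this order:

1. drying:  `LWC_t = LWC_{t−1} (1 − e)`
2. rate:    `k_t = f(LWC_t)` with one of two moisture functions (below)
3. decay:   `M_t = M_{t−1} (1 − k_t)`

Simulations start saturated (`LWC_0 = LWC_max`, `M_0 = 1`), and the day-0
state is included in every trajectory, which makes the closed forms
`LWC_t = LWC_max (1 − e)^t` and (at constant LWC) `M_t = (1 − k)^t` exact
checks. Water dynamics are independent of the remaining mass (decomposition
does not shrink the water pool).

Two double-Michaelis–Menten moisture functions are available. Both encode
the ambivalence of water: microbes need water, but water displaces oxygen.

* **moyano** (oxygen as a substrate; no activity at saturation):
  `k = k_max · LWC/(a + LWC) · O_a/(b + O_a)` with the oxygen-availability
  coefficient `O_a = (LWC_max − LWC)/LWC_max`. `k = 0` both when dry and at
  saturation.
* **bunnell** (gas exchange merely facilitated when dry; activity persists
  at saturation, as in litter with its large air interface):
  `k = k_max · LWC/(c + LWC) · d/(d + LWC)`. `k = 0` only when dry; the
  interior maximum sits at `LWC = √(cd)`.

## Mixtures and the water-transfer rule

A 50:50 two-litter mixture is simulated under two scenarios. Without
interaction, the litters decompose independently and the mixture's
remaining mass is the average of the two curves — the additive expectation.
With interaction, after both litters have evaporated at their own rates,
one transfer event per day moves water from the currently wetter litter to
the drier one:

    τ = min(lwc_max_receiver − lwc_receiver, (lwc_donor − lwc_receiver)/2)

The single `min` rule covers both regimes — full refill of the receiver up
to saturation while the donor stays wettest, equalisation at the average
otherwise — and guarantees that each transfer conserves water and never
overfills the receiver. Which litter is "wettest" is re-evaluated from the
current contents every day, so roles can swap mid-run. Water is booked in
LWC units (per g dry matter), which conserves actual water mass exactly for
the equal-dry-mass 50:50 design; a mass-weighted variant is out of scope.

The nonadditive effect is `delta_t = 100·(M_no-interaction − M_interaction)`
in percentage points of initial mass: positive = synergistic, negative =
antagonistic, near zero (|delta| ≤ 0.01 pp by default) = additive. The
0.01 pp classification margin is far below any mechanistically meaningful
effect and far above accumulated float error.

### A characterized long-horizon property

In the Model Comparison configuration (identical litters except for
evaporation rate), the synergy is transient: the delta peaks near day
36–41 (+1.9 pp moyano, +0.96 pp bunnell) and crosses zero near day 65–70.
The mechanism is structural: each transfer is conservative, but the
transferred water subsequently evaporates at the receiver's fast rate, so
the interacting mixture's total water — and eventually its cumulative mass
loss advantage — falls behind. The packaged experiments therefore assert
the synergy and the donor's day-40 rate penalty at day 40, and separately
pin the day-80 reversal as model behaviour. Rate Combinations simulation 2
shows the mirror image: near-additive at day 40 (+0.33 pp) with the
antagonism (−4.1 pp at day 80) developing later. The default experiment
horizon is 80 days, which covers both phases.

## Calibration

Calibration is two-phase least squares on pooled replicate observations,
matching the model's one-way coupling:

1. `LWC_max` is *set*, not fit: the ceiling of the replicate-mean water
   content at the earliest sampled day (21.56 → 22). It doubles as the
   day-0 water content.
2. `e` minimises `Σ (lwc_obs − LWC_max(1−e)^day)²` over `e ∈ [0, 1]`:
   a 1000-point grid scan followed by bounded scalar minimisation inside
   the bracketing interval (`xatol` 1e-12). Deterministic and global for
   this one-dimensional problem.
3. `(k_max, c, d)` minimise the squared mass residuals of the recursion
   driven by the *fitted* water curve (not the observed water contents),
   using the bunnell function, inside the box `(0, 0.5] × (0, LWC_max]²`.
   The `k_max` ceiling of 0.5 d⁻¹ is a generous physical bound on a daily
   mass-loss fraction; the `c, d` ceiling is the litter's own `LWC_max`.
   A fixed 3×3×3 multistart (quartiles of the box) of bounded trust-region
   least squares, best SSE wins, ties broken lexicographically — fully
   reproducible, no randomness.

Pooling replicates rather than fitting date means changes nothing for
balanced designs and uses all information for unbalanced ones.

**Identifiability.** The bunnell rate can be written
`k_max·d · LWC/((c+LWC)(d+LWC))`: it depends on the parameters only through
the unordered pole pair {c, d} and the amplitude `k_max·d`. Fitted triples
are therefore reported in the canonical `c ≤ d` form (the swap
`(k_max, c, d) → (k_max·d/c, d, c)` preserves the curve and can only lower
`k_max`, so the box is respected). Beyond that exact symmetry, `c` and `d`
are weakly identified whenever the observed trajectory stays on the
moisture-response plateau — real fits routinely push both to their upper
bound, where the reported `bounds_active` flags make this visible — so
`k_max` is the trustworthy kinetic summary, not `c` or `d` individually.

## Validation statistics

`fit_stats` reports `R² = 1 − SSres/SStot` (SStot about the observed mean),
`adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)` and `NRMSE = √(SSres/n) / denom`.
The adjustment parameter count defaults to `p = 0` for validation
comparisons, where nothing is estimated in the comparison itself. The NRMSE
denominator is the observed mean by default, with the observed range as an
option — both conventions are in circulation and the choice is genuinely
ambiguous; with remaining mass near 0.8–1.0 of initial, mean-normalised
values land in the 0.01–0.05 range. Statistics are computed on the observed
sampling days only, with model values taken at those integer days.

The validation study scores the no-interaction prediction against the
additive expectation *computed from the measured singles*, and the
interaction prediction against the measured mixture itself; the per-day
nonadditive effect is reported both as the model predicts it and as the
experiment shows it (`scenario_deltas`, positive = synergistic).

## Synthetic data

The generator emulates a destructive-sampling incubation: seven sampling
dates (default {2, 7, 14, 28, 56, 84, 112} days — the design's first
measurement falls on day 2; the exact real dates are configurable), six
replicates per date, observing whole-sample water content and remaining
mass. Mixture samples are observed as a whole: combined mass
(fraction-weighted mean) and mean LWC. Noise is additive Gaussian,
independent across replicates and variables, sd 0.02 on the mass fraction
and 5% of the day-0 water content on LWC by default (no error model is
available from the real experiment; these magnitudes give signal-to-noise
comparable to careful gravimetric work). Out-of-range draws are truncated
into the physical domain, a documented small bias at extreme noise levels.
Everything is seeded through numpy's `default_rng`; the same `DesignSpec`
yields the same dataset.

What passing synthetic tests show — and what they do not: the generator
shares the forward model with the estimator, so recovery tests certify the
calibration machinery (optimiser, bounds, determinism) and the pipeline's
statistical power under the stated design and noise, not the model's
adequacy for real litter, which only the external laboratory data can test.

## Problem sizes and numerics

Closed-form equivalence is checked over 1,000 daily steps at relative
tolerance 1e-9 (pure arithmetic recursions; error growth is ~n·ε). Transfer
conservation is exercised on 10,000 random calls at 1e-12. Stochastic
properties use 100 seeded repetitions (evaporation-rate recovery: median
relative error; full-pipeline synergy detection: ≥ 90% hit rate); the
acceptance script summarises the noisy pipeline over 50 seeded repetitions
by medians. Degenerate inputs are rejected loudly: water contents outside
`[0, LWC_max]`, rates outside their unit ranges, observation series with a
variable sampled on fewer than two distinct days, and mixtures with
mismatched horizons all raise typed errors rather than propagating NaNs.

## Known limitations

* Water transfer assumes equal dry masses (the 50:50 design); arbitrary
  mixing fractions reweight the mass average but not the water bookkeeping.
* No temperature dependence, substrate-quality dynamics, nutrient or
  carbon transfer between litters — moisture is the only coupling, so the
  model bounds the moisture-mediated share of a mixture effect from below.
* The discrete daily step is part of the model definition, not an ODE
  discretisation; halving the step is not meaningful.
* `c` and `d` estimates at their upper bound should be read as "moisture
  response unresolved by these data", not as physical half-saturation
  constants.
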