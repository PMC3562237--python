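# Methods

## Model

A recruitment process is a continuous-time Markov chain on N landmark states
on a circle. `RecruitmentNetwork` stores the N×N rate matrix λᵢⱼ (diagonal
zero, no absorbing states); `BindingMatrix` the constant binary protein×state
binding map. The master equation dp/dt = Qᵀp, with generator
Q = λ − diag(row sums), governs the population distribution; the ChIP
prediction is the linear readout c_p(t) = Σᵢ P_pi pᵢ(t), a fraction of input
in [0, 1].

Model assumptions worth keeping in mind: transition waiting times are
exponential (Markovian) at the substep level; the binding matrix is constant
in time (no activity-dependent binding); ChIP averages over an effectively
infinite, independent cell population unless the measurement model is applied.

## Propagation regimes

Two regimes are implemented, and which one a question needs is part of the
science:

* **Master regime (m = 1).** `propagate()` integrates dp/dt = Qᵀp. The
  default integrator is stiff-capable BDF with rtol 1e−8 / atol 1e−10 and an
  analytic (constant) Jacobian; `method="expm"` applies the exact
  matrix-exponential propagator interval-by-interval via sparse
  `expm_multiply`, preferable for expanded substep networks and long
  horizons. Outputs are clipped at zero and renormalized; drift beyond 1e−7
  triggers a logged warning. This regime is the ground truth: it mixes
  (lumps diffuse), so steady states exist and are initial-condition
  independent.

* **Clockwork regime (m → ∞).** With many intermediate substeps the landmark
  waiting time, Erlang(m, mλ), concentrates at 1/λ (variance 1/(mλ²) → 0).
  `clockwork_propagate()` implements the limit as a discrete-time chain:
  the distribution advances one landmark per 1/λ and branches at each
  landmark with the embedded jump probabilities λᵢⱼ/Σₖλᵢₖ (a shortcut
  traversal also takes one step). This requires a uniform forward cycle
  rate. It reproduces the non-decaying periodic ChIP signals that motivate
  the large-m regime in the first place. Caveat: a clockwork chain whose
  cycle lengths share a common divisor is Markov-periodic and never settles
  (the probabilistic-clearance promoter below is the prime example:
  loop lengths n and 2n), so steady-state questions must be asked in the
  master regime.

`expand_substeps()` builds the explicit N·m-state network (per-substep rate
mλ; off-cycle transitions attach at landmark substates, since shortcuts
connect landmark events, not invisible intermediates). In tests the expanded
chain is compared against the advection solution with initial mass placed at
each landmark's mid-substate; starting on the first substate would introduce
the half-step renewal bias of the Erlang transit law (E[completed transits]
≈ λt − (m−1)/2m) and is a discretization artifact, not physics.

## Continuum limits

`sr_advection_solution` translates the distribution circularly by λt landmark
units (linear interpolation at fractional shifts preserves mass).
`fokker_planck_coefficients` uses the biased nearest-neighbour-walk limit
v = λ₊ − λ₋, D = (λ₊ + λ₋)/2 per landmark step; both are validated against
ensemble moments of the exact sampler rather than taken on faith.
`broadening(D, t) = √(2Dt)` is the width the population gains over an
observation window; a transition with circular span s and rate λ_s
contributes s²λ_s/2 to D, and `classify_transition_range` calls it
long-range when its own broadening over the observation time exceeds 5% of N
(configurable — the boundary between "merely rescales the frequency" and
"visibly diffuses" is inherently a resolution question).

## Stochastic sampling

`sample_trajectory` is an exact event-driven (Gillespie) simulation:
exponential holding time at the total exit rate, next state by embedded
probabilities. `sample_ensemble` runs many trajectories in vectorized
lockstep and can track signed circular displacement for drift/diffusion
checks. Goodness-of-fit tests against the master equation pool states with
expected counts below 10 before applying Pearson's chi-square (delta-start
distributions leave far states nearly empty, where the statistic is
unreliable).

## Scenarios

Six bundled configurations cover the canonical study conditions on an N=200
cycle at unit rate (the rate only fixes the time unit):

| name | topology |
|---|---|
| `fig3_sr` | pure sequential cycle |
| `fig4_weak` | + 100 weak transitions, rates U[0.01, 0.05], spans ≤ 3 |
| `fig5_one_shortcut` | + one backward shortcut, embedded probability 0.3 |
| `fig6_two_shortcuts` | + one backward and one forward shortcut, 0.3 each |
| `fig7_100shortcuts` | + 100 random long-range shortcuts (rates 0.3–0.6, spans 20–180) |
| `fig8_ps2` | double transcription cycle with probabilistic clearance |

Shortcut strengths are specified as embedded jump probabilities q and
converted to rates by the competing-exponentials inversion λ_s = λ·q/(1−q).
Initial conditions: wrapped Gaussian of width σ = N/40 at the cleared state
(synchronized), a single random draw, the uniform distribution, and the
split-and-mix protocol (equal mixture of randomly phase-shifted copies;
50 sub-populations by default) — the experimental route to a de-synchronized
population.

### The probabilistic-clearance promoter

`build_ps2_scenario(n, q)` is a 2n-state double cycle: an "odd" transcription
cycle (states 0 … n−1) and an "even" one (n … 2n−1). At the end of the odd
cycle the promoter clears completely with probability q (shortcut to state
0); otherwise the even cycle follows, after which clearance is certain.
Binding roles: the persistent factor A binds late in the odd cycle and
remains bound through the even cycle (window [0.9n, 1.9n), length exactly n);
the cycling factor B occupies the same relative window in each cycle; C is an
early-cycle factor in each half.

A's window length is a deliberate structural choice. Under probabilistic
clearance the population settles into two conjugate phase streams with masses
2/3 (odd) and 1/3 (even), so any protein's long-run signal is
c(u) = (2/3)W(u) + (1/3)W(u+n), which is n-periodic unless W(u) − W(u+n) is
constant. A factor whose bound window covers exactly one of the two conjugate
phases at (almost) every cycle position — i.e. a window of length ≈ n — is
the only kind whose dominant ChIP period is the double cycle 2n. That is
precisely what "remains bound through even cycles" means structurally, and it
yields a measured period ratio of 2.00 at q = 0.5 on both short (3-period)
and long (8-period) analysis windows.

## Oscillation detection and the verdict

`detect_oscillations` fits, per protein, offset + trend + damped sinusoid
A·e^(−γt)·cos(2πft + φ) by bounded least squares, seeded from the
zero-padded periodogram peak (several phase/decay starts; frequency confined
to [0.5, 1.8]× the seed). Significance combines the variance fraction
explained by the oscillatory component with a block-permutation score of the
periodogram peak (199 permutations of ≥ 8 detrended blocks) against a
constant-plus-trend null. A series with standard deviation below 1e−7 is
flat by definition.

A report counts as a *sustained* oscillation when all hold:

* amplitude ≥ 0.02 (fraction of input) — set between the residual
  periodicity of a single random-draw initial condition under a pure cycle
  (≈ 0.01, which the field reads as "constant") and the weakest genuine
  shortcut transient in the bundled scenarios (≈ 0.04);
* variance fraction ≥ 0.2 and permutation p ≤ 0.05;
* envelope decay time 1/γ ≥ 0.5 fitted periods — the one/two-shortcut
  transients decay over ≈ 0.5–1 period while the 100-shortcut scenario
  relaxes within ≈ 2% of a period, so 0.5 sits in the wide gap between the
  regimes being distinguished.

`classify_recruitment` then applies the decision table: de-synchronized
condition oscillates → `PR_shortcuts`; de-synchronized flat but synchronized
oscillates → `SR`; everything flat or immediately stationary → `PR_random`;
otherwise `inconclusive` (also returned when only a flat de-synchronized
condition is available, since SR and PR_random cannot then be separated).
When several de-synchronized conditions are present the verdict rests on the
most de-synchronized one (uniform, then split-and-mix, then a single random
draw): only the uniform distribution is exactly stationary for a sequential
cycle, while one random realization retains phase roughness that recurs
periodically under SR and would otherwise masquerade as a shortcut signature.
De-synchronized conditions are analysed over the transient window (first 3
nominal periods by default; synchronized over 8), where the informative
dynamics live.

## Measurement model

`measure()` emulates a real ChIP time course from a noiseless prediction:
subsampling to a coarser grid, binomial counting noise over n_cells
(default 10⁶) cells, additive Gaussian technical noise (noise_sd), clipping
to [0, 1]. It generates synthetic noisy fixtures; it does not model ChIP
biochemistry (crosslinking efficiency, antibody specificity), and real data
may violate its independence assumptions (shared batches, correlated time
points). Passing classifications on synthetic data therefore demonstrate the
logic of the test, not field performance at arbitrary noise levels; the
verdict degrades — by design, towards `SR`/`inconclusive` — as shortcut rates
shrink or spans approach short range.

## Problem sizes and numerical choices

Bundled scenario runs propagate N = 200 states over 40 cycle periods
(clockwork) or 10 periods (master regime) with detection on the windows
above; steady-state checks run the master equation to 60 periods, where the
across-IC spread is < 1e−10. Sampler validations use 10⁵ endpoint draws
(chi-square) and 10⁴ trajectories (drift/diffusion, 4-sigma CLT bands).
Erlang-limit checks integrate the implemented density numerically rather
than trusting closed-form moments. All randomness flows through
`numpy.random.default_rng` seeds recorded in the provenance sidecar; scenario
artifacts are byte-identical across runs at a fixed seed.

Known limitations: the clockwork propagator requires a uniform forward cycle
rate (position-dependent rates need the master regime or substep expansion);
the de-synchronization verdict assumes the compared time courses share the
time unit and were measured densely enough (≥ 8 points, ideally tens per
period); and the short/long-range boundary is reported relative to the
configured broadening threshold rather than asserted as a universal constant.
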