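# Methods

## Model and assumptions

The package treats one elementary motif: a cooperative binding reaction
`n S + R ⇌ RSₙ` (association `k₁`, dissociation `k₂`) driven by a square-wave
signal `[S](t)` of amplitude `A`, period `T` and duty cycle `γ`. The bound
fraction obeys `dP/dt = (1 − P) k₁[S]ⁿ − k₂P`. Standing assumptions:

- the receptor pool is dilute (`[S] ≫ [R]`), so binding does not deplete the
  signal — appropriate for gene promoters, where `[R]` is one or a few copies;
- the Hill step is elementary as written: `n` molecules bind in one kinetic
  event with an `[S]ⁿ` rate law (no partially-liganded intermediates);
- the signal is an ideal square wave; rise/fall times, amplitude noise and
  cycle-to-cycle variability are not modeled;
- the receptor starts unbound (`P(0) = 0`) in all closed-form trajectories.

On-intervals are half-open, `[(i−1)T, (i−1)T + γT)`: the instant a pulse
starts is "on", the instant it ends is "off". The choice only matters on a
measure-zero set but keeps the piecewise solution single-valued where its two
branches meet.

Units are fixed throughout: concentrations nM, times h, `k₁` in nM⁻ⁿ h⁻¹ and
`k₂` in h⁻¹ (so `K_d = K_Aⁿ = k₂/k₁` is in nMⁿ). Rate constants quoted with
these units elsewhere occasionally appear with µM- or M-based prefactors;
this package uses the nM convention consistently.

## Exact solutions

Within each constant-signal segment the ODE is linear, so the trajectory is a
chain of exponential relaxations. Two evaluators are provided and tested
against each other:

- `analytic_binding` — the closed-form per-pulse expression: during pulse `i`
  (phase `ξ = t − (i−1)T`) a rising branch relaxing toward
  `P̄_sus = Aⁿ/(K_Aⁿ+Aⁿ)` at rate `r = k₁Aⁿ + k₂`, after the pulse a falling
  branch decaying at `k₂`, with an `e^{−i(k₁AⁿγT + k₂T)}` start-up transient.
- `integrate_numeric` — the oracle: the exact two-branch exponential update
  applied segment by segment (`P(t₀+h) = P* + (P(t₀)−P*)e^{−rh}`), restarted
  at every pulse edge. An adaptive RK45 per-segment integration
  (rtol 1e-10) is available as a secondary, algorithmically independent
  cross-check. The segment-exact update was preferred as the reference
  because `k₂` spans ~1e-4–1e3 h⁻¹ across the parameter ranges of interest
  and stiffness is then a non-issue by construction.

Numerical policy for the closed form: every exponential is arranged as
`exp(non-positive)`; `expm1` replaces `1 − e^x` wherever the argument can be
small; the start-up transient `e^{−i(a+b)}(e^{a+d}−1)` switches between an
`expm1` product (small exponents) and a difference of two non-positive
exponentials (large), so neither overflow nor catastrophic cancellation
occurs anywhere in `k₂T ∈ [1e-4, 1e3]`. Branch continuity, inter-pulse
continuity and convergence onto the T-periodic limit cycle are asserted to
`1e-10·P̄_sus` over randomized parameter draws.

`mean_pulsed_binding` integrates the limit cycle branch-wise in closed form
(each branch is a single exponential), so the infinite-time average
`P̄_pulsed` carries no quadrature or truncation error. Its slow- and
fast-pulsing limits, `γ·P̄_sus` and `γAⁿ/(K_Aⁿ+γAⁿ)`, are recovered in tests:
the recovery tolerances (0.02 at `x = k₂(1−γ)T ≥ 100`, 0.01 at `x ≤ 0.01`)
are applied to the *difference of the dimensionless ratio* `P̄_pulsed/P̄_sus`,
whose deviation from the limit is bounded by `(1−γ)/x`; the relative
deviation is `(1−γ)/(xγ)` and can exceed any fixed percentage at small duty
cycles, so a relative criterion would be ill-posed.

## Titration curves and the apparent dissociation constant

`titration_curve` sweeps the average signal `γA` at fixed dimensionless
pulsing speed `k₂T` (a reference period of 6 h converts it to rates; the
dimensionless curve is period-independent) and computes the exact cycle
average at each point. The half-saturation point is the **half-maximal**
(EC50) concentration: the mean signal at which the mean binding reaches half
of its large-signal plateau

    lim_{A→∞} P̄_pulsed = γ + (1−γ)(1 − e^{−x})/x,   x = k₂(1−γ)T.

For sustained and fast pulsing the plateau is ≈1 and this coincides with the
`P̄ = 1/2` crossing, but for slow pulsing the plateau drops toward `γ` (the
off-phase always empties the receptor) and a literal `P̄ = 1/2` crossing may
not exist — at `γ = 0.3`, `k₂T = 10` the plateau is 0.40. The half-maximal
definition keeps the apparent dissociation constant meaningful at every
pulsing speed; with it the left-shift `half_saturation < K_A` holds across
`k₂T ∈ {0.1, 1, 10}` (ratios 0.535, 0.459, 0.339 at `γ = 0.3`, `n = 2`,
against the fast-limit closed form `γ^{1/2} = 0.548`). The root is bracketed
on the log grid and polished with Brent's method to machine precision.

## Regime analysis

The classifier is a pure function of `x = k₂(1−γ)T` with a symmetric
factor-of-10 threshold (default): slow (d) for `x ≥ 10`, fast (f) for
`x ≤ 0.1`, competitive (e) between. The factor operationalizes the
qualitative "much greater/less" comparisons and is exposed as a parameter
rather than hidden. Sustained signaling (`γ = 1`) is reported as its own
status, never silently mapped onto a regime. Boundary affinities emitted for
grid overlays (with `k₂ = k₁K_Aⁿ`):

- fast/competitive: `K_A = (k₁(1−γ)T)^{−1/n}` (the `x = 1` locus);
- delay: the `K_A` at which the fast-pulsing rise time
  `τ_pulsed = 1/(k₁(Aⁿγ+K_Aⁿ)) − (T/2)(1−γ)` equals the sustained
  `τ_sus = 1/(k₁Aⁿ+k₂)`. Solving `τ_pulsed = τ_sus` for `K_Aⁿ` gives
  `K_A = A·{[((1−γ)² + 8/(k₁TAⁿ))^{1/2} − (1+γ)]/2}^{1/n}`, which exists
  iff `k₁TAⁿγ < 2`; when it does not, pulsing never significantly delays
  binding. `τ_pulsed` can be negative outside the fast regime and is
  returned as-is with a validity flag rather than clipped.
- graded clocking: `K_Aⁿ = ε(1/(k₁T) − γAⁿ)` with `ε = 0.1` reading "≪",
  existing only when the drive condition `k₁AⁿγT ≤ ε` also holds. This
  condition is strictly stronger than fast pulsing, so the graded boundary
  always lies below the fast one.

`graded_clocking` evaluates the exact per-pulse levels `P_i(T)` and measures
departure from `P_i(T) ≈ i·P₁(T)` over the initial window
`i ≤ 0.1·P̄_pulsed/P₁(T)`; within that window the relative deviation is
≈ `i(a+b)/2 ≤ 5%` by construction, so the 10% linearity assertion probes the
mechanism rather than the window bookkeeping.

Rise times are measured numerically (in tests) as the `(1 − 1/e)` crossing of
the period-averaged trajectory, consistent with the exponential-relaxation
definitions behind the closed forms.

## Dimerization-coupled binding (p53)

The two-step scheme — monomer⇌dimer (`K_Ad`), two dimers binding a promoter
(`K_AR² = k₂R/k₁R`) — is treated with instantaneously equilibrated
dimerization (the usual assumption of fast dimer exchange); slow dimer
kinetics would couple into the pulse response and is out of scope. DNA-bound
protein is excluded from the mass balance `total = [monomer] + 2[dimer]`.
The dimer level is evaluated in the cancellation-free conjugate form
`[dimer] = 2·total²/(4·total + K_Ad + √(K_Ad² + 8K_Ad·total))` and verified
against an independent monomer-side quadratic solve to 1e-10 relative.

The limiting Hill mappings are `n = 2, K_A = K_AR, A = total/2` (strong
dimerization) and `n = 4, K_A⁴ = K_AR²K_Ad², A = total` (weak). The strong
mapping is *accepted* by `effective_hill_map` when `K_Ad ≤ 0.4·total`, a
deliberately permissive gate for regime work; its *accuracy* converges only
as the monomer mass fraction `≈ √(K_Ad/(2·total))` (and the weak branch as
`4·total/K_Ad`), so percent-level agreement requires `K_Ad ≲ 1e-5·total`
(resp. `≳ 10³·total`) and the tests assert branch recovery at those
separations while checking the predicted error scaling at moderate ones.
When the gate refuses, both limiting mappings are attached to the raised
error instead of silently picking one. The measured effective Hill slope
`d logit P̄ / d log total` is verified to approach 2 and 4 in the two limits.

Promoter panels (`promoter_name, K_AR_nM` CSV) assume strong dimerization and
a default dimer-DNA association rate of `k₁R = 0.01 nM⁻² h⁻¹` (the central,
near-diffusion-limited association-rate row of the survey grids) when none is
supplied; the signal amplitude passed in is the peak *total* p53, halved
internally for the dimer-level effective model.

## Scenario grids and problem sizes

`generate_fig3_grid` fills `P(t; K_A)` panels with 64 log-spaced affinities
over 1–64 nM, 200 samples per 6 h period out to 4 periods by default — enough
to resolve every pulse at the smallest duty cycle surveyed (0.1) while
keeping a full 20-panel registry sweep under a second. The registry crosses
`A ∈ {10, 20, 40}` nM and `γ ∈ {1, 0.8, 0.3, 0.1}` at
`k₁ = 10e-3 nM⁻ⁿ h⁻¹`, plus `k₁ ∈ {0.1, 1}e-3` rows at `A = 40` nM; the
latter pairings are flagged `inferred` since only the parameter values, not
their combinations, are pinned down. Randomized test ensembles use 200–1000
draws (`n ∈ {2,4}`, log-uniform `k₁ ∈ [1e-4, 1e-2]`, `K_A ∈ [1, 64]`,
`A ∈ [5, 80]`, uniform `γ`), sized so the full suite runs in about half a
minute; the closed forms make larger ensembles cheap but uninformative.

## Known limitations

- No stochastic chemical kinetics: single-copy promoters fluctuate; `P(t)`
  here is the ensemble/occupancy probability only.
- No downstream kinetics (mRNA, protein): cumulative-product comparisons are
  proxies for downstream output only when production is proportional to
  occupancy.
- Arbitrary waveforms (sinusoids, irregular pulse trains) are not supported;
  the square wave is what admits exact solutions.
- The synthetic parameter ensembles emulate the surveyed ranges of rate
  constants and affinities, not any measured distribution over real
  promoters; passing tests certify the mathematics and its implementation,
  not the biological parameterization of a particular system.
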