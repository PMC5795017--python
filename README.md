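# pulsedhill

Many signaling systems deliver information as concentration *pulses* rather than
steady levels: transcription factor p53 after gamma irradiation, cytosolic
calcium, circadian effectors, yeast Msn2. When the downstream step is a
cooperative (Hill-type) binding reaction — `n` signal molecules S binding a
receptor R such as a gene promoter — pulsing does not simply average out.
`pulsedhill` is a small toolkit for working out exactly what it does instead.

## The model

The signal is a square wave of amplitude `A` (nM), period `T` (h) and duty
cycle `γ` (the signal is on for `Δ = γT` of each period; `γ = 1` is sustained
signaling). The bound fraction `P(t)` of receptors obeys

    dP/dt = (1 − P) k₁ [S]ⁿ − k₂ P,        K_d = K_Aⁿ = k₂/k₁,

with `[S] ≫ [R]` (no signal depletion). Because `[S](t)` is piecewise constant
the equation is exactly solvable: the package evaluates the closed-form
per-pulse trajectory (a rising exponential toward the sustained asymptote
`P̄_sus = Aⁿ/(K_Aⁿ + Aⁿ)` during each pulse, a `k₂`-decay between pulses), its
T-periodic infinite-time limit cycle, and the exact cycle average `P̄_pulsed`.

From these follow the closed-form results the package exposes:

- **Suppression of low-affinity binding.** `P̄_pulsed/P̄_sus → γ` for slow
  pulsing (`k₂(1−γ)T ≫ 1`) and `γ(K_Aⁿ+Aⁿ)/(K_Aⁿ+γAⁿ)` for fast pulsing.
- **Apparent dissociation-constant shift.** Under fast pulsing the system
  responds to the *average* signal with `K′_A/K_A = γ^((n−1)/n)`: brief, high
  pulses activate cooperative binders at lower average dose than a steady
  signal could.
- **Regime classification.** Slow (d), competitive (e) and fast (f) pulsing
  from `x = k₂(1−γ)T`, plus the graded-clocking sub-regime (g) in which the
  bound level steps up by a nearly constant increment on every pulse.
- **Kinetic delay.** Fast pulsing stretches the rise time of high-affinity
  binders by `(Aⁿ+K_Aⁿ)/(Aⁿγ+K_Aⁿ)`; the critical `K_A` below which pulsing
  slows binding is available in closed form.
- **p53 application.** A dimerization-coupled scheme (monomer⇌dimer with
  constant `K_Ad`, two dimers binding a promoter with constant `K_AR`) that
  collapses onto the plain Hill model with `n = 2` (strong dimerization) or
  `n = 4` (weak), so promoter panels differing only in `K_AR` can be placed
  into pulsing regimes.

A segment-exact numerical integrator (and an adaptive RK45 cross-check) backs
every closed form.

## Worked example

```python
from pulsedhill import (HillParameters, SquareWaveSignal, sustained_binding,
                        mean_pulsed_binding, apparent_KA_ratio, classify_regime)

params = HillParameters.from_dissociation_constant(n=2, k1=0.01, K_A=32.0)
signal = SquareWaveSignal(amplitude=40.0, period=6.0, duty_cycle=0.3)

p_sus = sustained_binding(params, signal.amplitude)
p_pulsed = mean_pulsed_binding(params, signal)
report = classify_regime(params, signal)

print(f"sustained occupancy     : {p_sus:.3f}")
print(f"pulsed cycle average    : {p_pulsed:.3f}")
print(f"suppression P_pul/P_sus : {p_pulsed / p_sus:.3f}")
print(f"regime                  : {report.regime} (x = {report.x:.1f})")
print(f"apparent K_A shift      : {apparent_KA_ratio(signal.duty_cycle, params.n):.2f}")
```

prints

```
sustained occupancy     : 0.610
pulsed cycle average    : 0.189
suppression P_pul/P_sus : 0.310
regime                  : slow_d (x = 43.0)
apparent K_A shift      : 0.55
```

A steady 40 nM signal would occupy 61% of this low-affinity (K_A = 32 nM)
promoter, but a 30%-duty-cycle pulse train holds the long-time average at
18.9% — essentially the slow-pulsing limit γ·P̄_sus = 0.3·0.61, as the regime
label (`slow_d`, off-phase 43 unbinding times long) predicts. The last line is
the fast-pulsing titration shift `0.3^(1/2) = 0.55` for n = 2.

The same computations are available from the shell:

```
pulsedhill regimes  --n 2 --k1 0.01 --KA 1 --amplitude 40 --duty-cycle 0.3
pulsedhill simulate --n 2 --k1 0.01 --KA 8 --amplitude 10 --duty-cycle 0.3 --t-end 24
pulsedhill titrate  --n 2 --duty-cycle 0.3 --k2T 0.1
pulsedhill grid     --n 2 --k1 0.01 --amplitude 40 --duty-cycle 0.3
pulsedhill p53      --promoters promoters.csv --p53-total 12 --amplitude 12 --duty-cycle 0.3
```

(`regimes`/`p53` emit JSON reports, the others CSV; `--config file.json`
supplies any flag, with command-line values taking precedence.)

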