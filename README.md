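# dendrokit

A self-contained Python toolkit for building, tuning, reducing, and
validating single-cell multicompartmental biophysical neuron models with
active dendrites.  It is aimed at computational neuroscientists who want to
inspect and rework detailed conductance-based models — morphology,
channels, spatial parameter distributions, synaptic input, and reduction —
without being tied to an external simulator: a small implicit cable solver
is built in.

## What it does

- **Morphology** (`dendrokit.morphology`): reads and writes SWC
  reconstructions as three linked tree graphs — 3D points, unbranched
  *sections* cut at bifurcations and type changes, and *segments*, the
  spatial discretisation units with centers at `(2i−1)/(2·nseg)`.  Includes
  tree edits (insert/remove nodes and subtrees, translate, sort), the
  NEURON-style `d_lambda` discretisation rule at 100 Hz, and morphometry.
- **Channels** (`dendrokit.channels`): parses an HH-formalism subset of the
  NMODL (MOD) format into gating variables `dx/dt = (x∞(V) − x)/τx(V)`,
  and *standardizes* each gate to five transition-state parameters

      x∞(V) = 1/(1 + exp((V − v_half)/σ))
      α(V)  = K·exp( δ·(V − v_half)/σ′),  β(V) = K·exp(−(1−δ)·(V − v_half)/σ′)
      τ(V)  = 1/(α + β) + τ0,             σ′ = −σ

  by a two-stage least-squares fit (joint x∞+τ fit, then an x∞-only refit
  of `v_half, σ`), and regenerates MOD files that round-trip exactly.
- **Distributions** (`dendrokit.distributions`): criterion-based *segment
  groups* (domain + diameter / absolute / relative distance) stacked with
  top-most-group precedence, bound to parametric distance functions
  (constant, linear, exponential, sigmoidal, step, polynomial), serialised
  as a three-section JSON configuration.
- **Simulator** (`dendrokit.simulator`): assembles segments into an RC
  network and integrates the branched cable equation implicitly (backward
  Euler, Crank–Nicolson optional) with an O(N) symmetric tree solve per
  step; exact exponential gating updates; AMPA / NMDA / GABA_A /
  AMPA-NMDA double-exponential synapses with Jahr–Stevens Mg block;
  NetStim-style spike trains; length-weighted random synapse placement.
- **Reduction** (`dendrokit.reduction`): maps any passive inclusive
  subtree to the unique sealed equivalent cylinder preserving its input
  impedance `Z_in` and tip-to-root transfer impedance `Z_tr`
  (`L̂ = arccosh(Z_in/Z_tr)`, `Z_c = Z_tr·sinh L̂`,
  `d = ((2/π)√(Rm·Ra)/Z_c)^{2/3}`), remaps channel densities by
  electrotonic position, and refits compact analytic distributions.
- **Validation** (`dendrokit.validation`): protocol formulas — input
  resistance `(V_off − V_on)/I`, double-exponential membrane time
  constant, spike detection with amplitude and half-width, f–I curve and
  rheobase, voltage attenuation profiles, expected-vs-actual EPSP
  nonlinearity, sag ratio `(V_off − V_min)/(V_on − V_min)`.
- **Fixtures** (`dendrokit.fixtures`): deterministic toy morphologies
  (ball-and-stick, Y, binary trees, three-stem cell), toy MOD channels,
  configurations and protocols, so everything is testable offline.

## Worked example

```python
import dendrokit as dk
from dendrokit import fixtures as fx
from dendrokit.distributions import apply_config
from dendrokit.simulator import IClamp, SimConfig, build_system, integrate
from dendrokit.validation import detect_spikes

# a toy cell: spherical soma + 200 µm dendrite, Na/Kdr/leak everywhere
morph = fx.ball_and_stick(length=200.0, diameter=2.0)
morph.build_segments(d_lambda=0.1)          # 5 dendritic segments at 100 Hz
chans = {n: dk.parse_mod(t) for n, t in fx.make_channels().items()}
table = apply_config(fx.active_config(domains=("soma", "dend")), morph)

cfg = SimConfig(t_stop=300.0, v_init=-70.0, equilibration=300.0)
sys_ = build_system(morph, table, chans,
                    stimuli=[IClamp(0, 0.15, 100.0, 100.0)],
                    recordings=[0], config=cfg)
traces = integrate(sys_, cfg)
spikes = detect_spikes(traces.t, traces.v[0], min_height=-10.0,
                       window=(100.0, 200.0))
print(f"{spikes.n_spikes} spikes at {spikes.rate:.0f} Hz, "
      f"mean half-width {spikes.half_widths.mean():.2f} ms")
```

prints

```
17 spikes at 170 Hz, mean half-width 0.42 ms
```

— the 0.15 nA / 100 ms somatic step drives sustained firing of this small,
high-input-resistance toy cell; each action potential is measured between
its half-amplitude crossings.  Standardizing the fixture sodium channel:

```python
std, report = dk.standardize(chans["na"])
p = report.params["m"]
print(f"m-gate: v_half={p.v_half:.1f} mV, sigma={p.sigma:.1f} mV, "
      f"K={p.K:.2f}/ms, delta={p.delta:.2f}, tau_0={p.tau_0:.2f} ms")
```

```
m-gate: v_half=-35.0 mV, sigma=-7.8 mV, K=1.90/ms, delta=0.55, tau_0=0.04 ms
```

A `dendrokit` console script exposes the same operations
(`dendrokit morpho stats`, `dendrokit channel standardize`,
`dendrokit biophys apply`, `dendrokit simulate`, `dendrokit reduce`,
`dendrokit validate`, `dendrokit fixtures make`).

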