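# Methods

This note records the models, numerical choices, and design decisions
behind dendrokit, in the spirit of a simulator's model documentation.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Morphology representation

A reconstruction is held at three coupled levels.  The *point tree* is the
raw SWC graph (id, type code, xyz, radius, parent), validated for unique
ids, a single root, positive radii, and resolvable parents, and kept in a
canonical parent-before-child order.  *Sections* are derived by cutting the
point tree at every bifurcation and at every type-code change; a contiguous
run of type-1 points forms one soma section.  *Segments* discretise each
section; segment `i` of `nseg` covers arc fraction `[(i−1)/n, i/n]` with
its center at `(2i−1)/(2n)`, so `nseg` is kept odd and a center segment
always exists.

Geometry conventions:

- Lengths are 3D polyline lengths; diameters interpolate linearly in arc
  length; segment areas are frustum lateral surfaces summed over the
  segment's span (checked to 1e−9 relative against the whole-section
  frustum surface).
- A child section of a *non-soma* parent prepends its attachment point to
  its polyline, so a single-point child still has finite extent.  Sections
  rooted on the soma start at their own first point: the soma is modelled
  as a sphere (single-point soma) or a stack of frusta (multi-point), not
  as part of the neurite cable.  Consequently path distances of dendritic
  segments are measured from the soma along the dendrite, with the soma
  itself at distance 0.
- A single-point soma is one spherical segment regardless of the requested
  `nseg`; a sphere has no cable axis worth subdividing, and splitting it
  would create fictitious zero-resistance internal nodes.
- Children of a soma section attach electrically at its center (fraction
  0.5).  A mid-soma axon is therefore supported but its attachment position
  along the soma is deliberately not resolved more finely.

The `d_lambda` rule assigns `nseg = int((L/(d_lambda·λ_f) + 0.9)/2)·2 + 1`
with the AC length constant `λ_f = 1e5·sqrt(d/(4π·f·Ra·cm))` (d in µm, f
in Hz, Ra in Ω·cm, cm in µF/cm²) evaluated at the section's
arc-length-weighted mean diameter, default f = 100 Hz, d_lambda = 0.1.
Refining d_lambda can only increase each section's nseg (asserted as a
property test).

## Channel model and standardization

A channel is a maximal conductance `gbar` (S/cm²), a reversal potential E
(mV), and gating variables `x` with `dx/dt = (x∞(V) − x)/τx(V)` entering
the open probability as `Π x_i^{p_i}`.  The standardized gate has five
parameters — `v_half` (mV), signed inverse slope `σ` (mV, negative for
activation gates), maximum rate `K` (1/ms), skew `δ ∈ (0,1)`, and floor
`τ0` (ms):

    x∞ = 1/(1 + exp((V − v_half)/σ))
    α  = K·exp(δ·(V − v_half)/σ′),   β = K·exp(−(1−δ)·(V − v_half)/σ′)
    τ  = 1/(α + β) + τ0,             σ′ ≡ −σ

The sign convention is chosen so that `α/(α+β)` reduces to `x∞` identically
for every `δ` (a Borg-Graham-style parameterisation); with the exponents
written against `(V − v_half)` and `(v_half − V)` asymmetrically that
identity would fail, so internal consistency was preferred and is enforced
by a property test at machine precision.  Useful identities: `x∞(v_half) =
1/2` and `τ(v_half) = 1/(2K) + τ0` exactly; `τ → τ0` far from `v_half`;
`τ` is symmetric about `v_half` iff `δ = 1/2`.

**Fitting.**  Kinetics are sampled on 201 uniform points over
[−100, 100] mV at the channel's reference temperature.  Stage 1 fits all
five parameters with trust-region least squares (`scipy.optimize.
least_squares`, bounds `K > 0`, `δ ∈ (0,1)`, `τ0 ≥ 0`, `σ` sign-locked to
the curve's direction) on the concatenated residuals of `x∞` and `τ`, each
normalised by its curve maximum.  Initial values: `v_half` at the sample
closest to `x∞ = 0.5`; `σ` from the 25–75% crossing span
(`(V_25 − V_75)/(2·ln 3)`); `τ0 = 0.9·min τ`; `K = 1/(2·(max τ − τ0))`;
`δ = 0.5`.  Stage 2 refits `(v_half, σ)` on `x∞` alone with `(K, δ, τ0)`
frozen — steady-state accuracy governs resting potential and threshold, so
it is restored at the cost of some `τ` accuracy; freezing the other three
keeps the τ curve's scale from drifting.  Both stages' RMS errors are
reported.  Non-convergence raises with the initial values and residual
norm rather than returning silently.  On noise-free self-generated data the
five parameters are recovered to better than 1% (asserted; in practice
machine precision).

**MOD subset.**  The parser handles NEURON / UNITS / PARAMETER / CONSTANT /
ASSIGNED / STATE / BREAKPOINT / INITIAL / DERIVATIVE / PROCEDURE / FUNCTION
blocks.  Expressions are parsed with sympy (unknown identifiers become
plain symbols, so NMODL names never collide with sympy built-ins); each
state derivative must be *linear in the state*, which covers both
`x' = (xinf − x)/xtau` and `x' = α·(1−x) − β·x`: writing
`x' = c1·x + c0`, `τ = −1/c1` and `x∞ = −c0/c1`.  PROCEDURE bodies are
inlined symbolically in statement order; FUNCTION blocks become
substitutable lambdas.  Gate exponents are read off as the polynomial
degree of each state in the BREAKPOINT current expression.  KINETIC
schemes, VERBATIM, and POINT_PROCESS mechanisms are rejected by name as
outside the subset.  Generated MOD files use full-precision float
formatting so that parse∘generate is a kinetics identity within 1e−10 on
the evaluation grid (tested).  Temperature enters only through an optional
Q10 factor dividing τ; `celsius` appearing inside expressions is fixed at
the file's parameter value.

## Spatial parameter distributions

*Where* a parameter applies is an ordered stack of segment groups; a group
is a domain set plus one criterion (diameter, absolute path distance from
the root, or relative distance within the segment's domain, computed as
position between the domain's most proximal and most distal segment edges,
in [0,1]).  "Distance" is path distance, not Euclidean.  *How much* is a
distribution function of path distance: constant `c`; linear `a + b·d`;
exponential `a + b·exp(d/c)`; sigmoidal `a + b/(1+exp(−(d−d0)/s))`; step
(breakpoints + values); polynomial (numpy coefficient order).  When groups
overlap, the last-listed (top-most) matching group that carries a
distribution for the parameter wins; uncovered segments keep the mechanism
default and are logged, not errored, matching an incremental editing
workflow.  Precedence is verified against brute-force evaluation over
random group stacks.  The whole configuration serialises to JSON in three
sections (domain → mechanisms, group definitions, parameter → group →
distribution); unknown keys and undefined group references are rejected
with the offending name.

## Simulator

Units: mV, ms, nA, µS, nF, µm — chosen so `C[nF]·dV/dt[mV/ms]` and
`g[µS]·(V−E)[mV]` are both nA without further factors.  Per segment,
`C = cm·area·1e−5` nF and `g = gbar·area·1e−2` µS.  Axial conductance
between neighbouring segment centers is the series sum of half-segment
resistances `Ra·(ℓ/2)/(π d²/4)`; the spherical soma contributes zero
internal resistance, and any zero-resistance link is replaced by a large
finite coupling (1e9 µS) to keep the matrix definite.

Each step advances gates first by the exact exponential relaxation
`x ← x∞ + (x − x∞)·exp(−dt/τ)` at the frozen voltage (cnexp-style), then
solves the linearised voltage system implicitly: diagonal
`C/h + Σg_chan + Σg_syn + Σg_ax`, off-diagonal `−g_ax`, right-hand side
`C/h·V + Σg·E + I_ext`.  Backward Euler uses `h = dt`; Crank–Nicolson
solves a half step and extrapolates `V ← 2V_½ − V`.  The matrix is
symmetric positive definite on a tree, so one Hines elimination
(children-into-parents, then back-substitution) solves it in O(N); the
loop is JIT-compiled with numba when available and falls back to pure
Python.  Tree and dense solves agree to 1e−10 on random trees, and the
per-step charge balance closes to solver tolerance (both tested).  The
NMDA voltage dependence is evaluated at the previous step's voltage
(linearised), which is stable at the default dt = 0.025 ms.  Simulations
are preceded by a 300 ms unrecorded equilibration with stimuli and
synapses silent.

Synapses are conductance-based double exponentials normalised to peak
`g_max` at `t_p = τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)`, integrated by two
exponential state variables incremented at spike arrivals (events snap to
the next grid point).  Defaults (τ_rise, τ_decay, e): AMPA (0.2, 2.5, 0),
NMDA (2, 30, 0), GABA_A (0.2, 8, −70) ms/mV — standard cortical values.
NMDA carries the Jahr–Stevens magnesium block
`s(V) = 1/(1 + ([Mg]/3.57 mM)·exp(−0.062·V))`, [Mg] = 1 mM.  AMPA_NMDA is
sugar for one AMPA plus one NMDA synapse sharing spike times, with
`g_max(NMDA) = nmda_ratio·g_max` (default ratio 1; the two components do
not share a literal conductance because their kinetics differ).

Spike trains are NetStim-style: each interval is
`(1−noise)/rate + noise·Exp(1/rate)`, so noise 0 gives a regular train
starting at onset and noise 1 a homogeneous Poisson process; this is one
concrete reading of a "randomness" knob between synchrony and Poisson, and
is documented as such.  Population placement draws target segments with
probability proportional to segment length (uniform per unit length);
per-segment uniform weighting is available.  All stochastic outputs are
reproducible under a seed.

## Reduction

Only passive properties (Rm, Cm, Ra) enter the reduction; active channels
are ignored during impedance measurement and remapped afterwards.  Each
section is a chain of two-ports (one per inter-point frustum, treated as a
uniform cylinder at the mean of its end diameters).  A post-order pass
folds input admittances from the sealed tips toward the subtree root
(`Z_in = Z_c·(1 + Z_c Y_L tanh x)/(Z_c Y_L + tanh x)`, `x = ℓ/λ`); a
pre-order pass accumulates voltage attenuations
(`1/(cosh x + Z_c Y_L sinh x)`), giving the transfer impedance to any
point as `Z_in(root)·Π(attenuations)`.  The "electrotonically most distal
tip" is the tip with the smallest |Z_tr|.  The equivalent cylinder solves

    L̂ = arccosh(Z_in/Z_tr),  Z_c = Z_tr·sinh(L̂),
    d = ((2/π)·√(Rm·Ra)/Z_c)^(2/3),  L = L̂·λ(d)

The matching frequency is configurable and defaults to DC (0 Hz), where
the solution is analytic and exactly testable; at ω > 0 magnitudes are
matched with `|Z_c(ω)| = Z_c/|q|` and `|λ(ω)| = λ/|q|`,
`q = sqrt(1 + iωτ_m)` — other conventions (complex matching, a nonzero
default ω) exist, and the choice is recorded here deliberately.  The
degenerate isopotential case `Z_in ≈ Z_tr` becomes a unit-aspect stub of
matched membrane area.  Reducing an unbranched cylinder is the identity to
1e−6 relative; the cylinder reproduces the measured pair by construction;
whole-cell somatic input resistance moves by well under 2% when a subtree
is replaced (all tested).

After surgery the cylinder is re-discretised at 0.1·λ_DC (odd nseg) and
the rest of the cell keeps its segment counts.  Channel densities are
remapped by assigning each original segment to the reduced segment with
the nearest |Z_tr| to the subtree root — electrotonic position, the
natural reading of "segments that map" — with a path-distance-fraction
fallback available; reduced values are contributor means, so a uniform
density is preserved exactly and the contributor-count-weighted mean is
conserved.  Empty reduced segments inherit the nearest assigned
neighbour's value.  Synapses are deliberately *not* remapped: populations
are placed afresh on the reduced morphology, which keeps the workflow
"reduce first, then instrument".  Remapped profiles are compressed by
fitting {constant, linear, polynomial ≤ 3, step ≤ 3 breaks, exponential,
sigmoidal} and keeping the minimum-MSE candidate, with near-ties (within
1e−12 + 1e−9·var) broken toward fewer coefficients; if every parametric
fit fails, a lossless step function through the data is returned and
flagged.

## Validation protocols

All protocols are pure functions of traces plus stimulus metadata.  Steady
windows are the last 10% of the pre-stimulus and stimulus epochs,
half-open so a sample on a step edge belongs to the following epoch; a
final-window slope above 1e−3 mV/ms triggers a warning.  Rin is
`(V_off − V_on)/I_ext` (mV/nA = MΩ).  The membrane time constant fits
`V∞ + A₁e^{−t/τ₁} + A₂e^{−t/τ₂}` to the onset transient and returns the
slow component (intended with h-current zeroed).  Spike detection uses
scipy peak finding with a minimum height and inter-peak distance;
amplitude is peak minus the preceding local minimum (threshold-to-peak is
the documented alternative), half-width interpolates the half-amplitude
crossings linearly, and peak times are refined by parabolic interpolation.
The f–I protocol counts spikes within the stimulus window only and refines
rheobase by bisection to step/8.  The nonlinearity protocol defines
expected(k) = k·unitary and reports expected and actual peak EPSPs plus
waveforms.  Sag ratio is `(V_off − V_min)/(V_on − V_min)`.

## Fixtures and what the tests do (and do not) show

Fixture channels use simple closed-form kinetics invented for this
package: Na (m³h, sigmoid steady states, Gaussian-bell τ), Kdr (n⁴ from
exponential α/β rates), an HCN-like gate opening with hyperpolarization,
a leak, and a channel generated from known five-parameter ground truth
(the recovery oracle).  Densities (Na 0.12, Kdr 0.05, leak 1e−4 S/cm²,
cm 1 µF/cm², Ra 100 Ω·cm) give tonic, roughly monotone f–I behaviour over
the first few suprathreshold steps on the toy trees.  The qualitative
benchmarks use: 20 synchronous AMPA-NMDA synapses (0.5 nS) on one terminal
branch for the NMDA-plateau contrast; 40 Poisson AMPA-NMDA inputs at
25 Hz for 200 ms, clustered in 5 terminal branches vs distributed over
all 16, on a depth-4 active tree; and a somatic 0.2 nA step on a Y-cell
with sodium zeroed in one branch for the backpropagation contrast.

Toy morphologies are electrotonically compact and their channel kinetics
are smooth closed forms, so passing tests demonstrate the correctness of
the algorithms (solver, fitting, reduction, protocols) — they do not
demonstrate that any particular published cortical model is reproduced.
Published SWC/MOD files can be dropped into the model-folder layout
(`morphology/`, `biophys/` with `biophys/mod/`, `stimuli/`) to the extent
their MOD files stay within the supported subset.

## Benchmark problem sizes

The acceptance benchmarks run on deliberately small systems — single
compartments, a 51-segment cable, trees of 28–93 segments, three trials of
the clustering contrast — chosen as the smallest systems on which each
property is meaningfully exercised; every closed-form comparison is
resolution-checked by its stated tolerance rather than by size.
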