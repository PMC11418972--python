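"""Implicit branched-cable simulation of a compartmental neuron model.

Each segment is an RC node: its membrane capacitance (from cm and area) and
ionic/synaptic/external currents balance the axial currents to its tree
neighbours.  The voltage update is implicit (backward Euler by default,
Crank–Nicolson optional) with one symmetric tree-structured linear solve per
step (Hines elimination, O(N)); gating variables advance by the exact
exponential relaxation toward x_inf(V) at the frozen voltage.

Units: mV, ms, nA, µS, nF, µm — so that C[nF]·dV/dt[mV/ms] = I[nA] and
g[µS]·(V-E)[mV] = I[nA].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # optional JIT for the per-step tree solve
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

MG_BLOCK_CONC = 3.57  # mM, Jahr–Stevens magnesium half-block concentration
MG_BLOCK_SLOPE = 0.062  # 1/mV

SYNAPSE_DEFAULTS = {
    # tau_rise (ms), tau_decay (ms), reversal (mV)
    "AMPA": (0.2, 2.5, 0.0),
    "NMDA": (2.0, 30.0, 0.0),
    "GABA_A": (0.2, 8.0, -70.0),
}


@dataclass
class SimConfig:
    dt: float = 0.025          # ms
    t_stop: float = 300.0      # ms
    v_init: float = -70.0      # mV
    temperature: float = 37.0  # °C, enters only via channel Q10 factors
    equilibration: float = 300.0  # ms of unrecorded settling before t = 0
    seed: int = 0
    method: str = "backward_euler"  # or "crank_nicolson"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class IClamp:
    """Step current: I(t) = amplitude for t in [delay, delay+duration)."""

    segment: object  # Segment or integer index
    amplitude: float  # nA
    delay: float      # ms
    duration: float   # ms

    def current(self, t: float) -> float:
        return self.amplitude if self.delay <= t < self.delay + self.duration else 0.0


@dataclass
class Synapse:
    """A conductance-based synapse with double-exponential kinetics.

    ``g(t) = g_max·N_f·Σ_s [exp(-(t-t_s)/τ_d) - exp(-(t-t_s)/τ_r)]`` with
    N_f normalising the unitary peak to g_max.  NMDA conductance is scaled
    by the Jahr–Stevens magnesium block ``1/(1 + [Mg]/3.57·exp(-0.062·V))``.
    ``kind == "AMPA_NMDA"`` is a shorthand expanded into one AMPA and one
    NMDA synapse sharing spike times, with g_max(NMDA) = nmda_ratio·g_max.
    """

    kind: str
    segment: object
    g_max: float = 1e-3  # µS
    e: float | None = None  # mV; None -> kind default
    tau_rise: float | None = None
    tau_decay: float | None = None
    mg: float = 1.0  # mM
    nmda_ratio: float = 1.0
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        base = self.kind if self.kind != "AMPA_NMDA" else "AMPA"
        if base not in SYNAPSE_DEFAULTS:
            raise ValueError(f"unknown synapse kind '{self.kind}'")
        tr, td, e = SYNAPSE_DEFAULTS[base]
        if self.tau_rise is None:
            self.tau_rise = tr
        if self.tau_decay is None:
            self.tau_decay = td
        if self.e is None:
            self.e = e
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be < tau_decay")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))

    @property
    def peak_time_offset(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm_factor(self) -> float:
        tp = self.peak_time_offset
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))

    def conductance(self, t) -> np.ndarray:
        """g(t) in µS by direct summation over spikes (reference form)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        g = np.zeros_like(t)
        for ts in self.spike_times:
            dtp = t - ts
            m = dtp >= 0
            g[m] += np.exp(-dtp[m] / self.tau_decay) - np.exp(-dtp[m] / self.tau_rise)
        return self.g_max * self.norm_factor * g

    def block_factor(self, V) -> np.ndarray:
        if self.kind != "NMDA":
            return np.ones_like(np.asarray(V, dtype=float))
        return 1.0 / (1.0 + (self.mg / MG_BLOCK_CONC) * np.exp(-MG_BLOCK_SLOPE * np.asarray(V)))


def mg_block(V, mg: float = 1.0) -> np.ndarray:
    """Jahr–Stevens NMDA magnesium unblock factor at voltage V (mV)."""
    return 1.0 / (1.0 + (mg / MG_BLOCK_CONC) * np.exp(-MG_BLOCK_SLOPE * np.asarray(V, dtype=float)))


def synapse_current(synapse: Synapse, V, t, spike_times=None) -> np.ndarray:
    """Synaptic current (nA): g(t)·s(V)·(V − e), s the NMDA block (else 1)."""
    if spike_times is not None:
        synapse = Synapse(kind=synapse.kind, segment=synapse.segment,
                          g_max=synapse.g_max, e=synapse.e,
                          tau_rise=synapse.tau_rise, tau_decay=synapse.tau_decay,
                          mg=synapse.mg, spike_times=spike_times)
    g = synapse.conductance(t)
    return g * synapse.block_factor(V) * (np.asarray(V, dtype=float) - synapse.e)


@dataclass
class Population:
    """N like-kind synapses placed randomly over a target segment set."""

    kind: str
    n: int
    targets: list  # Segment refs
    rate: float = 10.0   # Hz per input
    noise: float = 1.0   # 0 regular .. 1 Poisson
    onset: float = 0.0   # ms
    duration: float = 100.0  # ms
    g_max: float = 1e-3  # µS
    nmda_ratio: float = 1.0
    weighting: str = "length"  # or "segment": uniform per segment

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("population needs n >= 1 synapses")
        if not self.targets:
            raise ValueError("population needs a non-empty target set")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must lie in [0, 1]")


def spike_train(rate: float, noise: float, onset: float, duration: float,
                seed=None) -> np.ndarray:
    """NetStim-style spike times over [onset, onset+duration).

    noise = 0: regular intervals 1/rate starting at onset.  noise = 1:
    homogeneous Poisson at ``rate``.  In between, each interval is
    (1-noise)/rate + noise·Exponential(1/rate).
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration == 0:
        return np.array([])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = 1000.0 / rate  # ms
    times = []
    t = onset
    while t < onset + duration:
        times.append(t)
        t += (1.0 - noise) * mean + noise * rng.exponential(mean)
    return np.asarray(times)


def place_population(pop: Population, seed=None) -> list:
    """Draw synapse placements and spike trains for a population.

    Placement is uniform per unit length over the target segments by
    default (``weighting="segment"`` gives equal probability per segment).
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pop.weighting == "length":
        w = np.array([s.length for s in pop.targets], dtype=float)
    else:
        w = np.ones(len(pop.targets))
    w = w / w.sum()
    picks = rng.choice(len(pop.targets), size=pop.n, p=w)
    out = []
    for k in range(pop.n):
        st = spike_train(pop.rate, pop.noise, pop.onset, pop.duration, rng)
        out.append(Synapse(kind=pop.kind, segment=pop.targets[picks[k]],
                           g_max=pop.g_max, nmda_ratio=pop.nmda_ratio,
                           spike_times=st))
    return out


# --------------------------------------------------------------- the system

class _ChannelInstance:
    """One mechanism inserted on a subset of segments, with gate state."""

    def __init__(self, channel, idx: np.ndarray, gbar_abs: np.ndarray,
                 temperature: float):
        self.channel = channel
        self.idx = idx          # segment indices where inserted
        self.g_abs = gbar_abs   # µS per segment (gbar * area)
        self.E = channel.E
        if self.E is None:
            raise ValueError(f"channel '{channel.name}' has no reversal potential E")
        self.tau_factor = channel.tau_temperature_factor(temperature)
        self.gates = list(channel.gates)
        self.x = [np.zeros_like(gbar_abs) for _ in self.gates]

    def init_states(self, V: np.ndarray) -> None:
        v = V[self.idx]
        for i, g in enumerate(self.gates):
            self.x[i] = np.asarray(g.x_inf(v), dtype=float) * np.ones_like(v)

    def advance_gates(self, V: np.ndarray, dt: float) -> None:
        v = V[self.idx]
        for i, g in enumerate(self.gates):
            xi = np.asarray(g.x_inf(v), dtype=float)
            tau = np.asarray(g.tau(v), dtype=float) / self.tau_factor
            self.x[i] = xi + (self.x[i] - xi) * np.exp(-dt / tau)

    def conductance(self) -> np.ndarray:
        g = self.g_abs.copy()
        for xi, gate in zip(self.x, self.gates):
            if gate.p_exp:
                g *= xi ** gate.p_exp
        return g


class CompartmentalSystem:
    """Assembled state: compartments, channels, synapses, stimuli, recordings."""

    def __init__(self, morph, C: np.ndarray, g_ax: np.ndarray,
                 parent: np.ndarray, channels: list, synapses: list,
                 stimuli: list, recordings: list, temperature: float):
        self.morph = morph
        self.N = len(C)
        self.C = C              # nF
        self.g_ax = g_ax        # µS coupling of node i to its parent (0 for root)
        self.parent = parent    # parent index per node (-1 for root)
        self.channels = channels
        self.synapses = synapses
        self.stimuli = stimuli
        self.recordings = recordings
        self.temperature = temperature
        ax = np.zeros(self.N)
        if self.N > 1:
            np.add.at(ax, np.arange(1, self.N), g_ax[1:])
            np.add.at(ax, parent[1:], g_ax[1:])
        self.axial_diag = ax  # constant part of the step matrix diagonal

    def laplacian(self) -> np.ndarray:
        """Dense axial-conductance Laplacian (µS), for small-system checks."""
        L = np.zeros((self.N, self.N))
        for i in range(1, self.N):
            p = self.parent[i]
            g = self.g_ax[i]
            L[i, i] += g
            L[p, p] += g
            L[i, p] -= g
            L[p, i] -= g
        return L

    def membrane_terms(self, V: np.ndarray):
        """(g_diag, ge_rhs) of all ionic conductances at current gate states."""
        g_diag = np.zeros(self.N)
        ge = np.zeros(self.N)
        for ch in self.channels:
            g = ch.conductance()
            np.add.at(g_diag, ch.idx, g)
            np.add.at(ge, ch.idx, g * ch.E)
        return g_diag, ge


def segment_index(morph, seg) -> int:
    return seg if isinstance(seg, (int, np.integer)) else seg.idx


def build_system(morph, param_table: pd.DataFrame, channels: dict,
                 synapses=(), stimuli=(), recordings=None,
                 config: SimConfig | None = None) -> CompartmentalSystem:
    """Assemble the solvable system from geometry and the parameter table.

    ``param_table`` rows follow ``morph.segments`` order and must provide
    ``cm`` (µF/cm²) and ``Ra`` (Ω·cm); a channel named *mech* reads its
    density from column ``gbar_<mech>`` (S/cm², NaN/0 = not inserted there).
    """
    config = config or SimConfig()
    segs = morph.segments
    N = len(segs)
    if N == 0:
        raise ValueError("morphology has no segments; call build_segments first")
    area = np.array([s.area for s in segs])  # µm²
    if np.any(area <= 0):
        raise ValueError("zero-area segment in the morphology")
    for col in ("cm", "Ra"):
        if col not in param_table.columns:
            raise ValueError(f"param table lacks required column '{col}'")
    cm = param_table["cm"].to_numpy(dtype=float)
    Ra = param_table["Ra"].to_numpy(dtype=float)
    C = cm * area * 1e-5  # µF/cm² · µm² -> nF

    parent = np.full(N, -1, dtype=np.int64)
    g_ax = np.zeros(N)
    for i, s in enumerate(segs):
        if s.idx != i:
            raise ValueError("segment indices out of sync; rebuild segments")
        if s.parent is None:
            if i != 0:
                raise ValueError(f"segment {i} is disconnected from the tree")
            continue
        p = s.parent.idx
        parent[i] = p
        r = _half_resistance(s, Ra[i]) + _half_resistance(segs[p], Ra[p])
        # r = 0 between isopotential (spherical-soma) nodes: couple tightly
        g_ax[i] = 1e6 / r if r > 1e-3 else 1e9  # Ω -> µS
    if N > 1 and np.any(parent[1:] < 0):
        raise ValueError("multiple roots in the segment tree")

    instances = []
    for mech, ch in channels.items():
        col = f"gbar_{mech}"
        if col not in param_table.columns:
            continue
        gbar = param_table[col].to_numpy(dtype=float)
        idx = np.where(np.nan_to_num(gbar) > 0)[0]
        if len(idx) == 0:
            continue
        g_abs = gbar[idx] * area[idx] * 1e-2  # S/cm² · µm² -> µS
        instances.append(_ChannelInstance(ch, idx, g_abs, config.temperature))

    syn_expanded = []
    for s in synapses:
        if s.kind == "AMPA_NMDA":
            syn_expanded.append(Synapse("AMPA", s.segment, s.g_max, None, None, None,
                                        s.mg, spike_times=s.spike_times))
            syn_expanded.append(Synapse("NMDA", s.segment,
                                        s.g_max * s.nmda_ratio, None, None, None,
                                        s.mg, spike_times=s.spike_times))
        else:
            syn_expanded.append(s)

    if recordings is None:
        recordings = [0]
    rec_idx = [segment_index(morph, r) for r in recordings]
    return CompartmentalSystem(morph, C, g_ax, parent, instances, syn_expanded,
                               list(stimuli), rec_idx, config.temperature)


def _half_resistance(seg, Ra: float) -> float:
    """Axial resistance (Ω) from a segment's center to its section-side end."""
    if seg.section.is_spherical_soma:
        return 0.0  # the soma sphere is treated as isopotential
    d = seg.diameter
    return Ra * seg.length * 2e4 / (math.pi * d * d)


# ----------------------------------------------------------------- the solve

@_njit(cache=True)
def _hines(parent, d, a, b):  # pragma: no cover - exercised via integrate
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        f = a[i] / d[i]
        d[parent[i]] -= f * a[i]
        b[parent[i]] -= f * b[i]
    v = np.empty(n)
    v[0] = b[0] / d[0]
    for i in range(1, n):
        v[i] = (b[i] - a[i] * v[parent[i]]) / d[i]
    return v


def hines_solve(parent: np.ndarray, diag: np.ndarray, g_ax: np.ndarray,
                rhs: np.ndarray) -> np.ndarray:
    """Solve the symmetric tree system (diag, off-diagonal −g_ax) in O(N)."""
    d = diag.copy()
    a = -g_ax.copy()
    b = rhs.copy()
    return _hines(parent, d, a, b)


@dataclass
class Traces:
    """Recorded simulation output on the dt grid."""

    t: np.ndarray
    v: dict           # recording segment index -> voltage array (mV)
    spikes_in: dict   # synapse order index -> presynaptic spike times
    config: SimConfig

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        for k, tr in self.v.items():
            df[f"v_seg{k}"] = tr
        return df


class SimulationDiverged(RuntimeError):
    pass


def integrate(system: CompartmentalSystem, config: SimConfig) -> Traces:
    """Advance the system from v_init to t_stop and return the recordings.

    An ``equilibration`` period (stimuli and synapses silent) precedes t = 0
    so channels settle to their resting state; recordings start at t = 0.
    """
    dt = config.dt
    nsteps = int(round(config.t_stop / dt))
    N = system.N
    V = np.full(N, config.v_init, dtype=float)
    for ch in system.channels:
        ch.init_states(V)

    # synapse working arrays
    syns = system.synapses
    ns = len(syns)
    s_seg = np.array([segment_index(system.morph, s.segment) for s in syns], dtype=int) \
        if ns else np.zeros(0, dtype=int)
    s_gnf = np.array([s.g_max * s.norm_factor for s in syns])
    s_e = np.array([s.e for s in syns])
    s_is_nmda = np.array([s.kind == "NMDA" for s in syns])
    s_mg = np.array([s.mg for s in syns]) if ns else np.zeros(0)
    dec_r = np.array([math.exp(-dt / s.tau_rise) for s in syns]) if ns else np.zeros(0)
    dec_d = np.array([math.exp(-dt / s.tau_decay) for s in syns]) if ns else np.zeros(0)
    A = np.zeros(ns)
    B = np.zeros(ns)
    events = []  # (time, synapse index), sorted
    for j, s in enumerate(syns):
        for ts in s.spike_times:
            events.append((ts, j))
    events.sort()
    ev_ptr = 0

    rec = {k: np.empty(nsteps + 1) for k in system.recordings}
    t_grid = np.arange(nsteps + 1) * dt

    # ---- equilibration: no stimuli, no synapses
    n_eq = int(round(config.equilibration / dt))
    zero_i = np.zeros(N)
    none_syn = (np.zeros(0), np.zeros(0), np.zeros(0, dtype=int))
    for _ in range(n_eq):
        V = _step(system, V, dt, config.method, zero_i, *none_syn)

    for k in system.recordings:
        rec[k][0] = V[k]

    for step in range(1, nsteps + 1):
        t_new = step * dt
        # spikes arriving in (t_old, t_new]
        while ev_ptr < len(events) and events[ev_ptr][0] <= t_new:
            A[events[ev_ptr][1]] += 1.0
            B[events[ev_ptr][1]] += 1.0
            ev_ptr += 1
        if ns:
            A *= dec_r
            B *= dec_d
            g_syn = s_gnf * (B - A)
            s = np.ones(ns)
            if s_is_nmda.any():
                vv = V[s_seg[s_is_nmda]]
                s[s_is_nmda] = 1.0 / (1.0 + (s_mg[s_is_nmda] / MG_BLOCK_CONC)
                                      * np.exp(-MG_BLOCK_SLOPE * vv))
            gs = g_syn * s
        else:
            gs = np.zeros(0)
        i_ext = np.zeros(N)
        for stim in system.stimuli:
            amp = stim.current(t_new)
            if amp:
                i_ext[segment_index(system.morph, stim.segment)] += amp
        V = _step(system, V, dt, config.method, i_ext, gs,
                  s_e[: len(gs)], s_seg[: len(gs)])
        if not np.all(np.isfinite(V)) or np.max(np.abs(V)) > 1e3:
            raise SimulationDiverged(f"voltage diverged at step {step} (t = {t_new} ms)")
        for k in system.recordings:
            rec[k][step] = V[k]

    spikes_in = {j: s.spike_times for j, s in enumerate(syns)}
    return Traces(t=t_grid, v=rec, spikes_in=spikes_in, config=config)


def _step(system, V, dt, method, i_ext, g_syn, e_syn, seg_syn):
    """One implicit voltage update (gates advanced first at frozen V)."""
    for ch in system.channels:
        ch.advance_gates(V, dt)
    g_diag, ge = system.membrane_terms(V)
    if len(g_syn):
        np.add.at(g_diag, seg_syn, g_syn)
        np.add.at(ge, seg_syn, g_syn * e_syn)
    h = dt / 2.0 if method == "crank_nicolson" else dt
    diag = system.C / h + g_diag + system.axial_diag
    rhs = system.C / h * V + ge + i_ext
    V_solve = hines_solve(system.parent, diag, system.g_ax, rhs)
    if method == "crank_nicolson":
        return 2.0 * V_solve - V
    return V_solve
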