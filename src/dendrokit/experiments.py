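"""Canonical benchmark experiments on the built-in fixture models.

Each function runs one self-contained study — closed-form cable checks,
five-parameter fit recovery, reduction fidelity, discretisation rules,
protocol-formula exactness, and the qualitative synaptic-integration
contrasts — and returns a flat dict of measured numbers.  The test suite
asserts on these dicts; the acceptance script serialises them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import fixtures as fx
from .channels import parse_mod, standard_rates, standardize
from .distributions import apply_config
from .morphology import Morphology, PointNode
from .reduction import measure_impedances, reduce_subtree, solve_cylinder
from .simulator import (IClamp, Population, SimConfig, Synapse, build_system,
                        integrate, place_population)
from .validation import (detect_spikes, f_i_curve, input_resistance,
                         membrane_time_constant, sag_ratio)

RM, CM, RA = 1e4, 1.0, 100.0  # passive constants implied by gbar_leak = 1e-4


def _chans(names=("leak",)):
    mods = fx.make_channels()
    return {n: parse_mod(mods[n]) for n in names}


def _passive_table(morph, g_leak=1e-4):
    n = len(morph.segments)
    return pd.DataFrame({"cm": [CM] * n, "Ra": [RA] * n, "gbar_leak": [g_leak] * n})


def _single_compartment():
    m = Morphology([PointNode(1, 1, 0.0, 0.0, 0.0, 10.0, -1)])
    m.build_segments(1)
    return m


def _cable(length=500.0, diameter=2.0, nseg=51):
    m = Morphology([PointNode(1, 3, 0.0, 0.0, 0.0, diameter / 2.0, -1),
                    PointNode(2, 3, length, 0.0, 0.0, diameter / 2.0, 1)])
    m.build_segments(nseg)
    return m


# ----------------------------------------------------------- cable benchmarks

def rc_step_accuracy() -> dict:
    """Passive single compartment vs the RC charging closed form."""
    m = _single_compartment()
    chans = _chans()
    cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=50.0)
    sys_ = build_system(m, _passive_table(m), chans,
                        stimuli=[IClamp(0, 0.1, 20.0, 100.0)],
                        recordings=[0], config=cfg)
    tr = integrate(sys_, cfg)
    area_cm2 = m.segments[0].area * 1e-8
    r_mohm = RM / area_cm2 / 1e6
    tau = RM * CM * 1e-3  # ms
    mask = (tr.t >= 20.0) & (tr.t <= 119.0)
    closed = -70.0 + 0.1 * r_mohm * (1.0 - np.exp(-(tr.t[mask] - 20.0) / tau))
    err = float(np.max(np.abs(tr.v[0][mask] - closed)) / (0.1 * r_mohm))
    return {"max_rel_error_pct": 100.0 * err, "R_MOhm": r_mohm, "tau_ms": tau,
            "n": int(mask.sum())}


def cable_attenuation_accuracy(nseg: int = 51) -> dict:
    """Sealed-cable DC attenuation vs cosh((L-x)/λ)/cosh(L/λ)."""
    L, d = 500.0, 2.0
    m = _cable(L, d, nseg)
    chans = _chans()
    cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=100.0)
    n = len(m.segments)
    sys_ = build_system(m, _passive_table(m), chans,
                        stimuli=[IClamp(0, 0.05, 0.0, 200.0)],
                        recordings=list(range(n)), config=cfg)
    tr = integrate(sys_, cfg)
    lam = math.sqrt(RM * d * 1e-4 / (4.0 * RA)) * 1e4
    x = np.array([s.path_distance for s in m.segments])
    dv = np.array([tr.v[i][-1] for i in range(n)]) + 70.0
    ratio = dv / dv[0]
    pred = np.cosh((L - x) / lam) / np.cosh((L - x[0]) / lam)
    return {"max_abs_error_pct": 100.0 * float(np.max(np.abs(ratio - pred))),
            "lambda_um": lam, "n": n}


# -------------------------------------------------- standardization recovery

def standardization_recovery() -> dict:
    """Refit a channel generated from known five-parameter ground truth."""
    truth = fx.STD_GATE_TRUTH
    ch = fx.standard_channel_fixture()
    _, report = standardize(ch)
    got = report.params["m"]
    rel = [abs(a - b) / abs(b) for a, b in zip(got.as_tuple(), truth.as_tuple())]
    _, _, x_half, tau_half = standard_rates(got, truth.v_half)
    return {"max_param_error_pct": 100.0 * float(max(rel)),
            "x_inf_at_v_half": float(standard_rates(truth, truth.v_half)[2]),
            "tau_at_v_half_ms": float(standard_rates(truth, truth.v_half)[3]),
            "tau_at_v_half_expected_ms": 1.0 / (2.0 * truth.K) + truth.tau_0,
            "n": 201}


# ------------------------------------------------------- reduction benchmarks

def reduction_fidelity() -> dict:
    """Identity on a bare cylinder, impedance preservation, somatic Rin drift."""
    # identity
    m = Morphology([PointNode(1, 1, 0, 0, 0, 8.0, -1),
                    PointNode(2, 3, 8.0, 0, 0, 1.0, 1),
                    PointNode(3, 3, 508.0, 0, 0, 1.0, 2)])
    m.build_segments(5)
    sec = next(s for s in m.sections if s.domain == "dend")
    pair = measure_impedances(m, sec, RM, CM, RA, 0.0)
    cyl = solve_cylinder(pair, RM, CM, RA, 0.0)
    id_err = max(abs(cyl.diameter - 2.0) / 2.0, abs(cyl.length - 500.0) / 500.0)

    # impedance preservation on a branched fixture subtree
    tree = fx.binary_tree(depth=3)
    tree.build_segments(3)
    stem = next(s for s in tree.sections
                if s.domain == "dend" and s.parent.domain == "soma")
    pair0 = measure_impedances(tree, stem, RM, CM, RA, 0.0)
    red, _, _ = reduce_subtree(tree, stem, RM, CM, RA)
    new_sec = next(s for s in red.sections if s.domain == "dend")
    pair1 = measure_impedances(red, new_sec, RM, CM, RA, 0.0)
    z_err = max(abs(pair1.Z_in - pair0.Z_in) / pair0.Z_in,
                abs(pair1.Z_tr - pair0.Z_tr) / pair0.Z_tr)

    # whole-cell somatic input resistance before/after
    chans = _chans()

    def rin_of(morph):
        cfg = SimConfig(t_stop=100.0, v_init=-70.0, equilibration=200.0)
        sys_ = build_system(morph, _passive_table(morph), chans,
                            stimuli=[IClamp(0, -0.05, 10.0, 95.0)],
                            recordings=[0], config=cfg)
        tr = integrate(sys_, cfg)
        return input_resistance(tr.t, tr.v[0], -0.05, 10.0, 85.0)

    tree2 = fx.binary_tree(depth=3)
    tree2.build_segments(3)
    stem2 = next(s for s in tree2.sections
                 if s.domain == "dend" and s.parent.domain == "soma")
    r0 = rin_of(tree2)
    red2, _, _ = reduce_subtree(tree2, stem2, RM, CM, RA)
    r1 = rin_of(red2)
    return {"identity_error_rel": float(id_err),
            "impedance_error_rel": float(z_err),
            "rin_change_pct": 100.0 * abs(r1 - r0) / r0,
            "rin_original_MOhm": float(r0), "rin_reduced_MOhm": float(r1),
            "n": len(tree.segments)}


# ---------------------------------------------------- segmentation benchmarks

def segmentation_rules() -> dict:
    """Segment-center formula exactness and d_lambda refinement monotonicity."""
    m = fx.binary_tree(depth=3)
    center_err = 0.0
    for n in (1, 3, 7):
        m.build_segments(n)
        for sec in m.sections:
            k = len(sec.segments)
            for i, seg in enumerate(sec.segments, start=1):
                center_err = max(center_err,
                                 abs(seg.center_fraction - (2 * i - 1) / (2 * k)))
    m.build_segments(d_lambda=0.2, frequency=100.0)
    coarse = {s.id: len(s.segments) for s in m.sections}
    total_02 = sum(coarse.values())
    m.build_segments(d_lambda=0.1, frequency=100.0)
    fine = {s.id: len(s.segments) for s in m.sections}
    monotone = all(fine[k] >= coarse[k] for k in coarse)
    return {"max_center_error": float(center_err),
            "monotone_refinement": float(monotone),
            "total_nseg_dlambda_0p2": float(total_02),
            "total_nseg_dlambda_0p1": float(sum(fine.values())),
            "n": len(m.segments)}


# ------------------------------------------------------- validation formulas

def validation_formulas() -> dict:
    """Protocol formulas on constructed traces: Rin, sag, Gaussian half-width."""
    dt = 0.025
    t = np.arange(0.0, 400.0, dt)
    v = np.where((t >= 100.0) & (t < 300.0), -75.0, -70.0)
    rin = input_resistance(t, v, -0.05, delay=100.0, duration=200.0)

    v2 = np.full_like(t, -70.0)
    v2[(t >= 100.0) & (t < 300.0)] = -75.0
    v2[(t >= 100.0) & (t < 110.0)] = -80.0
    sag = sag_ratio(t, v2, delay=100.0, duration=195.0)

    sigma = 0.5
    t3 = np.arange(0.0, 60.0, dt)
    v3 = -70.0 + 40.0 * (np.exp(-((t3 - 20.0) ** 2) / (2 * sigma ** 2))
                         + np.exp(-((t3 - 40.0) ** 2) / (2 * sigma ** 2)))
    sm = detect_spikes(t3, v3, min_height=-50.0, min_distance=5.0)
    fwhm = 2.0 * sigma * math.sqrt(2.0 * math.log(2.0))
    fwhm_err = float(np.max(np.abs(sm.half_widths - fwhm)) / fwhm)
    return {"rin_MOhm": float(rin), "sag_ratio": float(sag),
            "n_detected_spikes": float(sm.n_spikes),
            "half_width_error_pct": 100.0 * fwhm_err, "n": len(t)}


# ------------------------------------------- qualitative synaptic integration

def nmda_block_contrast(seed: int = 1) -> dict:
    """20 synchronous AMPA-NMDA inputs on one branch, NMDA intact vs blocked."""
    m = fx.binary_tree(depth=2)
    m.build_segments(5)
    chans = _chans()
    table = _passive_table(m)
    leaf = [s for s in m.sections if not s.children][0]
    probe = leaf.segments[len(leaf.segments) // 2].idx
    rng = np.random.default_rng(seed)
    picks = rng.choice(leaf.segments, size=20)
    out = {}
    for label, ratio in (("nmda", 1.0), ("blocked", 0.0)):
        syns = [Synapse("AMPA_NMDA", seg, g_max=5e-4, nmda_ratio=ratio,
                        spike_times=[20.0]) for seg in picks]
        cfg = SimConfig(t_stop=120.0, v_init=-70.0, equilibration=100.0)
        sys_ = build_system(m, table, chans, synapses=syns,
                            recordings=[probe], config=cfg)
        v = integrate(sys_, cfg).v[probe]
        out[f"peak_{label}_mV"] = float(v.max())
        out[f"plateau_{label}_ms"] = float((v > -40.0).sum() * cfg.dt)
    out["n"] = 20
    return out


def clustering_contrast(seed: int = 1, n_trials: int = 3) -> dict:
    """40 AMPA-NMDA inputs, clustered in 5 branches vs distributed over all."""
    m = fx.binary_tree(depth=4)
    m.build_segments(3)
    chans = _chans(("leak", "na", "kdr"))
    table = apply_config(fx.active_config(domains=tuple(sorted(m.domains()))), m)
    leaves = [s for s in m.sections if not s.children]
    counts = {"clustered": 0, "distributed": 0}
    ss = np.random.SeedSequence(seed)
    for sub in ss.spawn(n_trials):
        trial_seed = int(sub.generate_state(1)[0] % (2 ** 31))
        for label in counts:
            rng = np.random.default_rng(trial_seed)
            if label == "clustered":
                secs = [leaves[i] for i in rng.choice(len(leaves), 5, replace=False)]
            else:
                secs = leaves
            targets = [seg for s in secs for seg in s.segments]
            pop = Population(kind="AMPA_NMDA", n=40, targets=targets, rate=25.0,
                             noise=1.0, onset=20.0, duration=200.0, g_max=2e-4)
            syns = place_population(pop, rng)
            cfg = SimConfig(t_stop=250.0, v_init=-70.0, equilibration=150.0)
            sys_ = build_system(m, table, chans, synapses=syns,
                                recordings=[0], config=cfg)
            tr = integrate(sys_, cfg)
            counts[label] += detect_spikes(tr.t, tr.v[0], min_height=-10.0).n_spikes
    return {"clustered_spikes": float(counts["clustered"]),
            "distributed_spikes": float(counts["distributed"]),
            "n": 40 * n_trials}


def bap_na_removal_contrast() -> dict:
    """Somatic spikes back-propagate; zeroing Na in one branch kills its spike."""
    m = fx.y_tree(stem=150.0, branch=300.0)
    m.build_segments(9)
    chans = _chans(("leak", "na", "kdr"))
    table = apply_config(fx.active_config(domains=tuple(sorted(m.domains()))), m)
    stem = next(s for s in m.sections if s.domain == "dend" and s.children)
    br_full, br_cut = stem.children
    table.loc[[s.idx for s in br_cut.segments], "gbar_na"] = 0.0
    tip_full, tip_cut = br_full.segments[-1].idx, br_cut.segments[-1].idx
    cfg = SimConfig(t_stop=100.0, v_init=-70.0, equilibration=150.0)
    sys_ = build_system(m, table, chans, stimuli=[IClamp(0, 0.2, 20.0, 60.0)],
                        recordings=[0, tip_full, tip_cut], config=cfg)
    tr = integrate(sys_, cfg)
    return {"soma_spikes": float(detect_spikes(tr.t, tr.v[0], min_height=-10.0).n_spikes),
            "intact_branch_peak_mV": float(tr.v[tip_full].max()),
            "na_free_branch_peak_mV": float(tr.v[tip_cut].max()),
            "n": len(m.segments)}


# ------------------------------------------------------ fixture-cell readouts

def fixture_cell_readouts(seed: int = 1) -> dict:
    """Standard electrophysiology panel on the active ball-and-stick fixture."""
    m = fx.ball_and_stick()
    m.build_segments(d_lambda=0.1)
    mods = fx.make_channels()
    chans = {n: parse_mod(mods[n]) for n in ("leak", "na", "kdr", "hcn")}
    table = apply_config(fx.active_config(domains=("soma", "dend")), m)
    table["gbar_hcn"] = 2e-4

    def run(amp, hcn=True, active=True, t_stop=400.0, delay=50.0, duration=300.0):
        tab = table.copy()
        if not hcn:
            tab["gbar_hcn"] = 0.0
        if not active:
            tab["gbar_na"] = 0.0
            tab["gbar_kdr"] = 0.0
        cfg = SimConfig(t_stop=t_stop, v_init=-70.0, equilibration=300.0)
        sys_ = build_system(m, tab, chans,
                            stimuli=[IClamp(0, amp, delay, duration)],
                            recordings=[0], config=cfg)
        tr = integrate(sys_, cfg)
        return tr.t, tr.v[0]

    t, v = run(-0.05, hcn=False, active=False)
    rin = input_resistance(t, v, -0.05, 50.0, 295.0)
    tau = membrane_time_constant(t, v, delay=50.0, fit_duration=150.0)
    t, v = run(-0.05, hcn=True, active=False)
    sag = sag_ratio(t, v, 50.0, 290.0)
    rin_ss = input_resistance(t, v, -0.05, 50.0, 295.0)

    def sim(amp):
        return run(amp, hcn=False, active=True, t_stop=250.0, delay=50.0,
                   duration=180.0)

    fi = f_i_curve(sim, start=0.0, stop=0.5, step=0.1, delay=50.0,
                   duration=180.0, min_height=-10.0)
    supra = fi.rates[fi.amplitudes >= (fi.rheobase or np.inf) - 1e-9]
    return {"rin_MOhm": float(rin), "tau_m_ms": float(tau),
            "sag_ratio": float(sag), "steady_state_rin_MOhm": float(rin_ss),
            "rheobase_nA": float(fi.rheobase) if fi.rheobase else float("nan"),
            "max_rate_Hz": float(np.max(fi.rates)),
            "n": len(m.segments)}
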