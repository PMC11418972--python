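"""Deterministic toy morphologies, channels, configs, and protocols.

Everything every other module needs for testing is generated here in code:
ball-and-stick and branched SWC morphologies, a minimal set of MOD channel
files with simple closed-form kinetics (invented for this package, not
copied from any published model), a passive/active biophys configuration,
and canonical stimulation protocols.  Generation is deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import math
import os

import numpy as np

from . import channels as ch
from .distributions import BiophysConfig, Distribution, SegmentGroup
from .morphology import Morphology, PointNode

# --------------------------------------------------------------- morphologies


def ball_and_stick(length: float = 200.0, diameter: float = 2.0,
                   soma_radius: float = 10.0, n_points: int = 3,
                   stick_type: int = 3) -> Morphology:
    """A spherical soma with one uniform dendritic cylinder."""
    if length <= 0 or diameter <= 0 or soma_radius <= 0:
        raise ValueError("dimensions must be positive")
    pts = [PointNode(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
    xs = np.linspace(soma_radius, soma_radius + length, max(2, n_points))
    parent = 1
    for i, x in enumerate(xs):
        pid = 2 + i
        pts.append(PointNode(pid, stick_type, float(x), 0.0, 0.0, diameter / 2.0, parent))
        parent = pid
    return Morphology(pts)


def y_tree(stem: float = 100.0, branch: float = 120.0, diameter: float = 2.0,
           soma_radius: float = 8.0, rall: bool = False) -> Morphology:
    """Soma + one stem splitting into two daughters (three dendritic sections).

    With ``rall=True`` the daughters obey the 3/2-power rule
    (d_child = d_stem / 2^(2/3)) so the Y is equivalent to a single cable.
    """
    d_child = diameter / 2.0 ** (2.0 / 3.0) if rall else diameter * 0.7
    r0, rc = diameter / 2.0, d_child / 2.0
    x0 = soma_radius
    pts = [
        PointNode(1, 1, 0.0, 0.0, 0.0, soma_radius, -1),
        PointNode(2, 3, x0, 0.0, 0.0, r0, 1),
        PointNode(3, 3, x0 + stem, 0.0, 0.0, r0, 2),
        PointNode(4, 3, x0 + stem + branch / math.sqrt(2), branch / math.sqrt(2), 0.0, rc, 3),
        PointNode(5, 3, x0 + stem + branch / math.sqrt(2), -branch / math.sqrt(2), 0.0, rc, 3),
    ]
    return Morphology(pts)


def binary_tree(depth: int = 2, branch_length: float = 80.0,
                diameter: float = 2.0, soma_radius: float = 8.0,
                rall: bool = True, domain_type: int = 3) -> Morphology:
    """A full binary dendritic tree of the given depth (2^depth leaves).

    ``rall=True`` shrinks daughter diameters by 2^(2/3) per level, making
    the whole tree collapsible to a single equivalent cylinder.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pts = [PointNode(1, 1, 0.0, 0.0, 0.0, soma_radius, -1),
           PointNode(2, domain_type, soma_radius, 0.0, 0.0, diameter / 2.0, 1),
           PointNode(3, domain_type, soma_radius + branch_length, 0.0, 0.0,
                     diameter / 2.0, 2)]
    counter = [3]

    def grow(parent_id, x, y, level, diam, spread):
        """Spawn the two daughters of a branch point; leaves sit at ``depth``."""
        d_next = diam / 2.0 ** (2.0 / 3.0) if rall else diam
        for sgn in (1.0, -1.0):
            counter[0] += 1
            pid = counter[0]
            pts.append(PointNode(pid, domain_type, x + branch_length,
                                 y + sgn * spread, 0.0, d_next / 2.0, parent_id))
            if level < depth:
                grow(pid, x + branch_length, y + sgn * spread, level + 1,
                     d_next, spread / 2.0)

    grow(3, soma_radius + branch_length, 0.0, 1, diameter, 60.0)
    return Morphology(pts)


def three_stem_cell(stem: float = 90.0, branch: float = 110.0,
                    diameter: float = 2.0, soma_radius: float = 10.0) -> Morphology:
    """Three stem dendrites off the soma, each splitting once (full-reduction toy)."""
    pts = [PointNode(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
    pid = 1
    for k, (ux, uy) in enumerate([(1.0, 0.0), (-0.5, 0.8660254), (-0.5, -0.8660254)]):
        tcode = 4 if k == 0 else 3  # one apical-like, two basal stems
        base = pid
        for j, s in enumerate((soma_radius, soma_radius + stem)):
            pid += 1
            pts.append(PointNode(pid, tcode, ux * s, uy * s, 0.0, diameter / 2.0,
                                 1 if j == 0 else pid - 1))
        fork = pid
        for sgn in (1.0, -1.0):
            pid += 1
            px = ux * (soma_radius + stem) - uy * sgn * branch * 0.6
            py = uy * (soma_radius + stem) + ux * sgn * branch * 0.6
            dd = math.hypot(px - ux * (soma_radius + stem), py - uy * (soma_radius + stem))
            ex = ux * (soma_radius + stem) + (px - ux * (soma_radius + stem)) * branch / dd
            ey = uy * (soma_radius + stem) + (py - uy * (soma_radius + stem)) * branch / dd
            pts.append(PointNode(pid, tcode, ex, ey, 0.0, diameter * 0.35, fork))
    return Morphology(pts)


def make_morphology(kind: str, path=None, **kw) -> Morphology:
    """Generate a fixture morphology by name; optionally write it as SWC."""
    makers = {"ball_and_stick": ball_and_stick, "y_tree": y_tree,
              "binary_tree": binary_tree, "three_stem_cell": three_stem_cell}
    if kind not in makers:
        raise ValueError(f"unknown fixture kind '{kind}' (have {sorted(makers)})")
    m = makers[kind](**kw)
    if path is not None:
        from .morphology import write_swc
        write_swc(m, path)
    return m


# ------------------------------------------------------------------ channels

LEAK_MOD = """\
NEURON {
    SUFFIX leak
    NONSPECIFIC_CURRENT i
    RANGE gbar, e
}

PARAMETER {
    gbar = 0.0001 (S/cm2)
    e = -70 (mV)
}

BREAKPOINT {
    i = gbar*(v - e)
}
"""

NA_MOD = """\
: toy transient sodium channel, m^3 h gating with closed-form kinetics
NEURON {
    SUFFIX na
    USEION na READ ena WRITE ina
    RANGE gbar
}

PARAMETER {
    gbar = 0.05 (S/cm2)
    ena = 60 (mV)
}

STATE { m h }

BREAKPOINT {
    SOLVE states METHOD cnexp
    ina = gbar*m^3*h*(v - ena)
}

INITIAL {
    rates(v)
    m = minf
    h = hinf
}

DERIVATIVE states {
    rates(v)
    m' = (minf - m)/mtau
    h' = (hinf - h)/htau
}

PROCEDURE rates(v (mV)) {
    minf = 1/(1 + exp(-(v + 35)/7.8))
    mtau = 0.05 + 0.25*exp(-((v + 38)/25)^2)
    hinf = 1/(1 + exp((v + 58)/7))
    htau = 0.3 + 4*exp(-((v + 62)/22)^2)
}
"""

KDR_MOD = """\
: toy delayed-rectifier potassium channel, n^4, alpha/beta rate form
NEURON {
    SUFFIX kdr
    USEION k READ ek WRITE ik
    RANGE gbar
}

PARAMETER {
    gbar = 0.02 (S/cm2)
    ek = -80 (mV)
}

STATE { n }

BREAKPOINT {
    SOLVE states METHOD cnexp
    ik = gbar*n^4*(v - ek)
}

INITIAL {
    rates(v)
    n = alpha/(alpha + beta)
}

DERIVATIVE states {
    rates(v)
    n' = alpha*(1 - n) - beta*n
}

PROCEDURE rates(v (mV)) {
    alpha = 0.35*exp(0.055*(v + 42))
    beta = 0.35*exp(-0.065*(v + 42))
}
"""

HCN_MOD = """\
: toy hyperpolarization-activated (h-like) cation channel -> voltage sag
NEURON {
    SUFFIX hcn
    NONSPECIFIC_CURRENT i
    RANGE gbar, e
}

PARAMETER {
    gbar = 0.0002 (S/cm2)
    e = -30 (mV)
}

STATE { l }

BREAKPOINT {
    SOLVE states METHOD cnexp
    i = gbar*l*(v - e)
}

INITIAL {
    rates(v)
    l = linf
}

DERIVATIVE states {
    rates(v)
    l' = (linf - l)/ltau
}

PROCEDURE rates(v (mV)) {
    linf = 1/(1 + exp((v + 80)/8))
    ltau = 40 + 60/(1 + exp(-(v + 70)/10))
}
"""

STD_GATE_TRUTH = ch.StandardGateParams(v_half=-42.0, sigma=-5.5, K=0.8,
                                       delta=0.35, tau_0=1.2)


def standard_channel_fixture() -> ch.GatedChannel:
    """A channel generated from known five-parameter ground truth."""
    gate = ch.GatingVariable.from_standard("m", 1, STD_GATE_TRUTH)
    return ch.GatedChannel(name="stdk", ion="k", gbar=0.01, E=-80.0,
                           gates=[gate], temp_ref=23.0)


def make_channels(outdir=None) -> dict:
    """All fixture MOD sources keyed by mechanism name; optionally written."""
    std_text = ch.generate_mod(standard_channel_fixture())
    mods = {"leak": LEAK_MOD, "na": NA_MOD, "kdr": KDR_MOD, "hcn": HCN_MOD,
            "stdk": std_text}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for name, text in mods.items():
            with open(os.path.join(outdir, f"{name}.mod"), "w") as fh:
                fh.write(text)
    return mods


# ------------------------------------------------------------ biophys config


def passive_config(domains=("soma", "dend"), g_leak: float = 1e-4,
                   e_leak: float = -70.0) -> BiophysConfig:
    """Uniform passive membrane: leak everywhere, cm = 1, Ra = 100."""
    return BiophysConfig(
        mechanisms={d: ["leak"] for d in domains},
        groups=[SegmentGroup(name="everywhere", domains=["all"])],
        parameters={
            "cm": {"everywhere": Distribution("constant", [1.0])},
            "Ra": {"everywhere": Distribution("constant", [100.0])},
            "gbar_leak": {"everywhere": Distribution("constant", [g_leak])},
        },
    )


def active_config(domains=("soma", "dend"), g_na: float = 0.12,
                  g_kdr: float = 0.05, g_leak: float = 1e-4,
                  g_hcn: float = 0.0) -> BiophysConfig:
    """Spiking membrane: Na + Kdr + leak everywhere (HCN optional)."""
    mechs = ["leak", "na", "kdr"] + (["hcn"] if g_hcn else [])
    params = {
        "cm": {"everywhere": Distribution("constant", [1.0])},
        "Ra": {"everywhere": Distribution("constant", [100.0])},
        "gbar_leak": {"everywhere": Distribution("constant", [g_leak])},
        "gbar_na": {"everywhere": Distribution("constant", [g_na])},
        "gbar_kdr": {"everywhere": Distribution("constant", [g_kdr])},
    }
    if g_hcn:
        params["gbar_hcn"] = {"everywhere": Distribution("constant", [g_hcn])}
    return BiophysConfig(
        mechanisms={d: list(mechs) for d in domains},
        groups=[SegmentGroup(name="everywhere", domains=["all"])],
        parameters=params,
    )


# ----------------------------------------------------------------- protocols

STEP_PROTOCOL = {
    "type": "iclamp",
    "amplitude": 0.15,  # nA
    "delay": 100.0,     # ms
    "duration": 100.0,  # ms
    "temperature": 37.0,
    "t_stop": 300.0,
    "record": "soma",
}

FI_PROTOCOL = {
    "type": "fi",
    "start": 0.0, "stop": 1.0, "step": 0.1,  # nA sweep
    "delay": 50.0, "duration": 200.0,
    "t_stop": 300.0,
    "record": "soma",
}


def synaptic_protocol(n_synapses: int = 20, clustered: bool = False,
                      n_branches: int = 5, rate: float = 25.0,
                      noise: float = 1.0, onset: float = 20.0,
                      duration: float = 200.0) -> dict:
    """Population protocol: N AMPA-NMDA inputs, single-branch / clustered /
    distributed placement."""
    return {
        "type": "population", "kind": "AMPA_NMDA", "n": n_synapses,
        "placement": "clustered" if clustered else "distributed",
        "n_branches": n_branches if clustered else None,
        "rate": rate, "noise": noise, "onset": onset, "duration": duration,
        "t_stop": onset + duration + 80.0,
    }


def make_protocols(outdir=None) -> dict:
    protos = {
        "step": dict(STEP_PROTOCOL),
        "fi": dict(FI_PROTOCOL),
        "syn_branch": synaptic_protocol(20),
        "syn_distributed": synaptic_protocol(40, clustered=False),
        "syn_clustered": synaptic_protocol(40, clustered=True, n_branches=5),
        "empty": {"type": "iclamp", "amplitude": 0.0, "delay": 0.0,
                  "duration": 0.0, "t_stop": 100.0, "record": "soma"},
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for name, p in protos.items():
            with open(os.path.join(outdir, f"{name}.json"), "w") as fh:
                json.dump(p, fh, indent=2)
                fh.write("\n")
    return protos


# ------------------------------------------------------------- model folders


def make_model_folder(path, kind: str = "ball_and_stick", active: bool = True,
                      **morph_kw) -> str:
    """Write the standard model layout: morphology/, biophys/ (+mod/), stimuli/."""
    from .distributions import write_config
    from .morphology import write_swc

    os.makedirs(os.path.join(path, "morphology"), exist_ok=True)
    os.makedirs(os.path.join(path, "biophys"), exist_ok=True)
    os.makedirs(os.path.join(path, "stimuli"), exist_ok=True)
    m = make_morphology(kind, **morph_kw)
    write_swc(m, os.path.join(path, "morphology", "cell.swc"))
    make_channels(os.path.join(path, "biophys", "mod"))
    domains = tuple(sorted(m.domains()))
    cfg = active_config(domains) if active else passive_config(domains)
    write_config(cfg, os.path.join(path, "biophys", "biophys.json"))
    make_protocols(os.path.join(path, "stimuli"))
    return path
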