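"""Hodgkin–Huxley-formalism ion channels and their standardization.

A channel carries gating variables x with first-order kinetics
dx/dt = (x_inf(V) - x)/tau_x(V) and open probability p = prod x_i^p_i, giving
the membrane current I = gbar * p * (V - E).

The *standardized* form expresses each gate by five parameters grounded in
transition-state theory:

    x_inf(V) = 1 / (1 + exp((V - v_half)/sigma))
    alpha(V) = K * exp( delta      * (V - v_half)/sigma')
    beta(V)  = K * exp(-(1 - delta)* (V - v_half)/sigma')
    tau(V)   = 1/(alpha + beta) + tau_0        with sigma' = -sigma

so that alpha/(alpha+beta) equals x_inf identically for every delta.  v_half
(mV) is the half-(in)activation voltage, sigma (mV) the signed inverse
slope, K (1/ms) the maximum transition rate, delta in (0,1) skews the tau
curve, and tau_0 (ms) is the rate-limiting minimum time constant.

A restricted NMODL (MOD) dialect is parsed into this representation:
NEURON / UNITS / PARAMETER / ASSIGNED / STATE / BREAKPOINT / DERIVATIVE /
INITIAL / PROCEDURE / FUNCTION blocks, with gate dynamics reducible to a
form linear in the state variable.  KINETIC schemes and VERBATIM are
rejected as outside the supported subset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.optimize import least_squares

V_RANGE_MV = (-100.0, 100.0)
V_GRID_POINTS = 201


class ModParseError(ValueError):
    """MOD content outside the supported subset, with location when known."""


# --------------------------------------------------------- standardized form

@dataclass
class StandardGateParams:
    """Five-parameter transition-state description of one gating variable."""

    v_half: float  # mV
    sigma: float   # mV, signed inverse slope (negative for activation gates)
    K: float       # 1/ms, maximum transition rate
    delta: float   # unitless skew, in (0, 1)
    tau_0: float   # ms, rate-limiting minimum time constant

    def __post_init__(self):
        if self.sigma == 0:
            raise ValueError("sigma must be nonzero")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.tau_0 < 0:
            raise ValueError("tau_0 must be >= 0")

    def as_tuple(self):
        return (self.v_half, self.sigma, self.K, self.delta, self.tau_0)


def standard_rates(params: StandardGateParams, V):
    """Evaluate (alpha, beta, x_inf, tau) of a standardized gate at V (mV).

    Guarantees alpha/(alpha+beta) == x_inf to machine precision.
    """
    V = np.asarray(V, dtype=float)
    s_prime = -params.sigma
    u = (V - params.v_half) / s_prime
    alpha = params.K * np.exp(params.delta * u)
    beta = params.K * np.exp(-(1.0 - params.delta) * u)
    x_inf = alpha / (alpha + beta)
    tau = 1.0 / (alpha + beta) + params.tau_0
    return alpha, beta, x_inf, tau


# ------------------------------------------------------------- channel model

@dataclass
class GatingVariable:
    """One gating state variable: exponent + (x_inf, tau) voltage functions."""

    name: str
    p_exp: int
    x_inf: "callable"  # V (mV) -> unitless in [0, 1]
    tau: "callable"    # V (mV) -> ms, > 0
    std: StandardGateParams | None = None  # set when generated/standardized

    @classmethod
    def from_rates(cls, name, p_exp, alpha, beta):
        """Build from alpha/beta rate functions (1/ms)."""
        def x_inf(V):
            a, b = alpha(V), beta(V)
            denom = a + b
            if np.any(denom == 0):
                bad = np.asarray(V)[np.asarray(denom) == 0]
                raise ZeroDivisionError(f"alpha+beta = 0 at V = {bad} mV")
            return a / denom

        def tau(V):
            a, b = alpha(V), beta(V)
            denom = a + b
            if np.any(denom == 0):
                bad = np.asarray(V)[np.asarray(denom) == 0]
                raise ZeroDivisionError(f"alpha+beta = 0 at V = {bad} mV")
            return 1.0 / denom

        return cls(name=name, p_exp=p_exp, x_inf=x_inf, tau=tau)

    @classmethod
    def from_standard(cls, name, p_exp, params: StandardGateParams):
        return cls(
            name=name, p_exp=p_exp,
            x_inf=lambda V, p=params: standard_rates(p, V)[2],
            tau=lambda V, p=params: standard_rates(p, V)[3],
            std=params,
        )


@dataclass
class GatedChannel:
    """A voltage-gated (or passive, if gateless) membrane conductance."""

    name: str
    ion: str  # 'na', 'k', 'ca', or 'nonspecific'
    gbar: float  # S/cm²
    E: float | None  # mV; None if taken from the ion at build time
    gates: list = field(default_factory=list)
    temp_ref: float = 23.0  # °C at which the kinetics were characterised
    q10: float | None = None  # tau scaling per 10 °C, if declared
    params: dict = field(default_factory=dict)  # raw PARAMETER values

    @property
    def is_standard(self) -> bool:
        return bool(self.gates) and all(g.std is not None for g in self.gates)

    def tau_temperature_factor(self, temperature: float | None) -> float:
        """Divide tau by this factor; identity unless a Q10 is declared."""
        if self.q10 is None or temperature is None:
            return 1.0
        return self.q10 ** ((temperature - self.temp_ref) / 10.0)

    def open_probability(self, states: dict) -> float:
        p = 1.0
        for g in self.gates:
            p *= states[g.name] ** g.p_exp
        return p


def eval_kinetics(channel: GatedChannel, V_grid, temperature: float | None = None) -> dict:
    """Steady states and time constants of every gate on a voltage grid.

    Returns ``{gate_name: {"x_inf": array, "tau": array}}``; tau is divided
    by the channel's Q10 factor at ``temperature`` (if declared).
    """
    V = np.asarray(V_grid, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V grid must be finite")
    factor = channel.tau_temperature_factor(temperature)
    out = {}
    for g in channel.gates:
        xi = np.asarray(g.x_inf(V), dtype=float) * np.ones_like(V)
        tau = np.asarray(g.tau(V), dtype=float) * np.ones_like(V) / factor
        out[g.name] = {"x_inf": xi, "tau": tau}
    return out


# ------------------------------------------------------------ standardization

@dataclass
class StandardizationReport:
    """Fit diagnostics for one channel's standardization."""

    params: dict  # gate name -> StandardGateParams
    rms_x_inf: dict  # gate -> RMS error of the steady-state fit (final stage)
    rms_tau: dict    # gate -> RMS error of the tau fit (stage-1 params kept)
    rms_x_inf_stage1: dict
    rms_tau_stage1: dict
    v_grid: np.ndarray = None
    stage: str = "steady-state-refit"


def _initial_guess(V, xi, tau) -> np.ndarray:
    """Heuristic start for (v_half, sigma, K, delta, tau_0)."""
    v_half = float(V[np.argmin(np.abs(xi - 0.5))])
    # sigma from the 25–75% crossing span of the sigmoid
    order = np.argsort(xi)
    xs, vs = xi[order], V[order]
    xs, iu = np.unique(xs, return_index=True)
    vs = vs[iu]
    if xs[0] < 0.25 < xs[-1] and xs[0] < 0.75 < xs[-1]:
        v25 = float(np.interp(0.25, xs, vs))
        v75 = float(np.interp(0.75, xs, vs))
        sigma = (v25 - v75) / (2.0 * math.log(3.0))
    else:
        sigma = -5.0
    if abs(sigma) < 1e-3:
        sigma = math.copysign(1e-3, sigma or -1.0)
    increasing = xi[-1] >= xi[0]
    if increasing and sigma > 0:
        sigma = -sigma
    if not increasing and sigma < 0:
        sigma = -sigma
    tau_0 = max(float(np.min(tau)) * 0.9, 0.0)
    spread = float(np.max(tau)) - tau_0
    K = 1.0 / (2.0 * spread) if spread > 1e-9 else 100.0
    return np.array([v_half, sigma, K, 0.5, tau_0])


def standardize(channel: GatedChannel, V_range=V_RANGE_MV,
                temperature: float | None = None,
                n_points: int = V_GRID_POINTS):
    """Fit the five-parameter model to every gate of a channel.

    Two stages: (1) a joint trust-region least-squares fit of all five
    parameters to the steady-state and time-constant curves together, with
    per-curve normalisation; (2) a refit of (v_half, sigma) on the steady
    state alone, holding (K, delta, tau_0) — trading tau accuracy for exact
    voltage dynamics.  Kinetics are sampled at the channel's reference
    temperature unless ``temperature`` overrides it.

    Returns ``(standard_channel, StandardizationReport)``.  Raises
    ``RuntimeError`` with residual diagnostics if a fit fails to converge.
    """
    V = np.linspace(V_range[0], V_range[1], n_points)
    temp = channel.temp_ref if temperature is None else temperature
    kin = eval_kinetics(channel, V, temperature=temp)

    fitted = {}
    rms_x, rms_t, rms_x1, rms_t1 = {}, {}, {}, {}
    new_gates = []
    for g in channel.gates:
        xi, tau = kin[g.name]["x_inf"], kin[g.name]["tau"]
        sx = max(float(np.max(np.abs(xi))), 1e-12)
        st = max(float(np.max(np.abs(tau))), 1e-12)
        p0 = _initial_guess(V, xi, tau)
        lo = [-200.0, -200.0, 1e-9, 1e-6, 0.0]
        hi = [200.0, 200.0, 1e9, 1.0 - 1e-6, 1e6]
        if p0[1] > 0:
            lo[1], hi[1] = 1e-6, 200.0
        else:
            lo[1], hi[1] = -200.0, -1e-6

        def joint_resid(th):
            p = StandardGateParams(*th)
            _, _, xm, tm = standard_rates(p, V)
            return np.concatenate([(xm - xi) / sx, (tm - tau) / st])

        sol = least_squares(joint_resid, np.clip(p0, lo, hi), bounds=(lo, hi),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(
                f"stage-1 fit for gate '{g.name}' did not converge: {sol.message}; "
                f"initial guess {p0}, final residual norm {np.linalg.norm(sol.fun):.3g}")
        vh, sg, K, dl, t0 = sol.x
        p1 = StandardGateParams(vh, sg, K, dl, t0)
        _, _, xm1, tm1 = standard_rates(p1, V)
        rms_x1[g.name] = float(np.sqrt(np.mean((xm1 - xi) ** 2)))
        rms_t1[g.name] = float(np.sqrt(np.mean((tm1 - tau) ** 2)))

        # stage 2: steady state alone, (K, delta, tau_0) frozen
        def ss_resid(th):
            p = StandardGateParams(th[0], th[1], K, dl, t0)
            return standard_rates(p, V)[2] - xi

        sol2 = least_squares(ss_resid, [vh, sg], bounds=([lo[0], lo[1]], [hi[0], hi[1]]),
                             method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol2.success:
            raise RuntimeError(
                f"stage-2 fit for gate '{g.name}' did not converge: {sol2.message}")
        p2 = StandardGateParams(sol2.x[0], sol2.x[1], K, dl, t0)
        _, _, xm2, tm2 = standard_rates(p2, V)
        rms_x[g.name] = float(np.sqrt(np.mean((xm2 - xi) ** 2)))
        rms_t[g.name] = float(np.sqrt(np.mean((tm2 - tau) ** 2)))
        fitted[g.name] = p2
        new_gates.append(GatingVariable.from_standard(g.name, g.p_exp, p2))

    std = GatedChannel(name=f"{channel.name}_std", ion=channel.ion,
                       gbar=channel.gbar, E=channel.E, gates=new_gates,
                       temp_ref=temp, q10=None)
    report = StandardizationReport(params=fitted, rms_x_inf=rms_x, rms_tau=rms_t,
                                   rms_x_inf_stage1=rms_x1, rms_tau_stage1=rms_t1,
                                   v_grid=V)
    return std, report


# ------------------------------------------------------------ MOD file parser

_BLOCK_RE = re.compile(
    r"^\s*(NEURON|UNITS|PARAMETER|ASSIGNED|STATE|BREAKPOINT|DERIVATIVE|"
    r"INITIAL|PROCEDURE|FUNCTION|KINETIC|CONSTANT)\b\s*([A-Za-z_]\w*)?"
    r"([^{\n]*)\{", re.M)


def _strip_comments(text: str) -> str:
    text = re.sub(r"COMMENT.*?ENDCOMMENT", "", text, flags=re.S)
    text = re.sub(r"\bUNITSON\b|\bUNITSOFF\b|\bTHREADSAFE\b", "", text)
    # ':' and '?' start line comments in NMODL
    return "\n".join(re.split(r"[:?]", ln, maxsplit=1)[0] for ln in text.splitlines())


def _split_blocks(text: str):
    """Yield (kind, name, args, body) for each top-level block."""
    for m in _BLOCK_RE.finditer(text):
        depth = 1
        i = m.end()
        while depth and i < len(text):
            if text[i] == "{":
                depth += 1
            elif text[i] == "}":
                depth -= 1
            i += 1
        if depth:
            raise ModParseError(f"unbalanced braces in {m.group(1)} block")
        yield m.group(1), m.group(2), m.group(3), text[m.end():i - 1]


_sym_v = sp.Symbol("v")


def _sympify(expr_text: str, local_syms: dict):
    expr_text = expr_text.replace("^", "**")
    # any identifier we don't know becomes a plain symbol, so that NMODL
    # variable names never collide with sympy built-ins (beta, gamma, ...)
    local_syms = dict(local_syms)
    for ident in set(re.findall(r"[A-Za-z_]\w*", expr_text)):
        local_syms.setdefault(ident, sp.Symbol(ident))
    try:
        return sp.sympify(expr_text, locals=local_syms, evaluate=True)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModParseError(f"unparseable expression '{expr_text.strip()}': {exc}") from None


_ASSIGN_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*'?\s*=\s*(.+)$")


def _arg_names(argtext: str | None) -> list:
    """First identifier of each comma-separated formal argument.

    Handles unit annotations: ``(v (mV), x)`` -> ['v', 'x'].
    """
    if not argtext:
        return []
    inner = argtext.strip()
    if inner.startswith("("):
        inner = inner[1:]
    if inner.endswith(")"):
        inner = inner[:-1]
    names = []
    for part in inner.split(","):
        m = re.match(r"\s*([A-Za-z_]\w*)", part)
        if m:
            names.append(m.group(1))
    return names


def _statements(body: str):
    """Assignment statements of a block body, statement-per-line or ';'-split."""
    for raw in re.split(r"[;\n]", body):
        line = raw.strip()
        if not line or line.startswith(("SOLVE", "LOCAL", "TABLE", "FROM", "IF", "}")):
            continue
        yield line


def parse_mod(source) -> GatedChannel:
    """Parse a MOD file (path or text) in the supported HH-formalism subset.

    The DERIVATIVE block must express each state derivative in a form linear
    in the state, covering both ``x' = (xinf - x)/xtau`` and
    ``x' = alpha*(1-x) - beta*x``.  PROCEDURE bodies (e.g. ``rates(v)``) are
    inlined symbolically; FUNCTIONs become substitutable lambdas.
    """
    import os
    if isinstance(source, str) and ("\n" in source or "{" in source):
        text = source
        label = "<string>"
    elif hasattr(source, "read"):
        text = source.read()
        label = "<stream>"
    else:
        label = str(source)
        if not os.path.exists(label):
            raise FileNotFoundError(label)
        with open(label) as fh:
            text = fh.read()

    if re.search(r"\bVERBATIM\b", text):
        raise ModParseError(f"{label}: VERBATIM block is outside the supported subset")
    clean = _strip_comments(text)
    blocks = list(_split_blocks(clean))
    kinds = {k for k, *_ in blocks}
    if "KINETIC" in kinds:
        raise ModParseError(f"{label}: KINETIC block is outside the supported subset")

    name, ion, current_var, e_var = None, "nonspecific", None, None
    params: dict[str, float] = {"celsius": 23.0}
    states: list[str] = []
    functions: dict[str, object] = {}
    proc_bodies: dict[str, tuple] = {}

    for kind, bname, bargs, body in blocks:
        if kind == "NEURON":
            m = re.search(r"\bSUFFIX\s+(\w+)", body)
            if m:
                name = m.group(1)
            m = re.search(r"\bPOINT_PROCESS\s+(\w+)", body)
            if m:
                raise ModParseError(f"{label}: POINT_PROCESS mechanisms are outside "
                                    "the supported subset (built-in synapses cover them)")
            m = re.search(r"\bUSEION\s+(\w+)\s+READ\s+([\w, ]+?)(?:\s+WRITE\s+([\w, ]+))?\s*$",
                          body, re.M)
            if m:
                ion = m.group(1)
                e_var = f"e{ion}"
                current_var = f"i{ion}"
            m = re.search(r"\bNONSPECIFIC_CURRENT\s+(\w+)", body)
            if m:
                current_var = m.group(1)
        elif kind in ("PARAMETER", "CONSTANT"):
            for line in _statements(body):
                pm = re.match(r"([A-Za-z_]\w*)\s*=\s*([-+0-9.eE]+)", line)
                if pm:
                    params[pm.group(1)] = float(pm.group(2))
        elif kind == "STATE":
            states = re.findall(r"[A-Za-z_]\w*", body)
        elif kind == "FUNCTION":
            functions[bname] = (bargs, body)
        elif kind == "PROCEDURE":
            proc_bodies[bname] = (bargs, body)

    if name is None:
        raise ModParseError(f"{label}: no SUFFIX found in NEURON block")

    # symbol table: v, parameters, states
    syms = {"v": _sym_v, "exp": sp.exp, "log": sp.log, "log10": lambda x: sp.log(x, 10),
            "fabs": sp.Abs, "sqrt": sp.sqrt, "pow": lambda a, b: a ** b, "tanh": sp.tanh}
    for p in params:
        syms[p] = sp.Symbol(p)
    for s in states:
        syms[s] = sp.Symbol(s)

    # FUNCTION fname(args) { ... fname = expr ... } -> sympy Lambda
    for fname, (fargs, fbody) in functions.items():
        argnames = _arg_names(fargs)
        argsyms = [sp.Symbol(a) for a in argnames]
        local = dict(syms)
        local.update({a: s for a, s in zip(argnames, argsyms)})
        ret = None
        for line in _statements(fbody):
            am = _ASSIGN_RE.match(line)
            if am and am.group(1) == fname:
                ret = _sympify(am.group(2), local)
        if ret is None:
            raise ModParseError(f"{label}: FUNCTION {fname} has no return assignment")
        syms[fname] = sp.Lambda(tuple(argsyms), ret)

    def run_assignments(body, env):
        """Execute a block's assignments symbolically into env (name -> expr)."""
        for line in _statements(body):
            if re.match(r"^\s*[A-Za-z_]\w*\s*'", line):
                continue  # state derivatives are handled separately
            cm = re.match(r"([A-Za-z_]\w*)\s*\(([^)]*)\)\s*$", line)
            if cm and cm.group(1) in proc_bodies:
                run_assignments(proc_bodies[cm.group(1)][1], env)
                continue
            am = _ASSIGN_RE.match(line)
            if not am:
                continue
            lhs, rhs = am.group(1), am.group(2)
            expr = _sympify(rhs, syms)
            expr = expr.subs(env, simultaneous=False)
            env[sp.Symbol(lhs)] = sp.simplify(expr) if expr.free_symbols else expr
        return env

    # DERIVATIVE: recover (x_inf, tau) per state from the linear-in-x form
    deriv = next((b for k, n, a, b in blocks if k == "DERIVATIVE"), None)
    gate_kinetics: dict[str, tuple] = {}
    if states and deriv is None:
        raise ModParseError(f"{label}: STATE variables but no DERIVATIVE block")
    if deriv is not None:
        env = run_assignments(deriv, {})
        prime_re = re.compile(r"^\s*([A-Za-z_]\w*)\s*'\s*=\s*(.+)$")
        for line in _statements(deriv):
            pm = prime_re.match(line)
            if not pm:
                continue
            sname, rhs = pm.group(1), pm.group(2)
            if sname not in states:
                raise ModParseError(f"{label}: derivative of non-state '{sname}'")
            x = syms[sname]
            expr = _sympify(rhs, syms).subs(env)
            poly = sp.expand(expr)
            c1 = poly.coeff(x, 1)
            c0 = poly.coeff(x, 0)
            if sp.expand(poly - c1 * x - c0) != 0:
                raise ModParseError(
                    f"{label}: derivative of '{sname}' is not linear in the state "
                    "(outside supported subset)")
            tau_expr = sp.simplify(-1 / c1)
            xinf_expr = sp.simplify(-c0 / c1)
            gate_kinetics[sname] = (xinf_expr, tau_expr)

    # BREAKPOINT: the current expression gives the gate exponents
    bp = next((b for k, n, a, b in blocks if k == "BREAKPOINT"), None)
    if bp is None:
        raise ModParseError(f"{label}: no BREAKPOINT block")
    env = run_assignments(bp, {})
    cur_sym = sp.Symbol(current_var) if current_var else None
    if cur_sym is None or cur_sym not in env:
        raise ModParseError(f"{label}: BREAKPOINT does not assign the current "
                            f"'{current_var}'")
    current_expr = env[cur_sym]
    exponents = {}
    for s in states:
        try:
            deg = sp.degree(sp.expand(current_expr), syms[s])
        except sp.PolynomialError:
            raise ModParseError(f"{label}: current is not polynomial in state '{s}'")
        exponents[s] = int(deg)

    # reversal potential: PARAMETER e<ion>/e if present
    E = None
    for cand in ([e_var] if e_var else []) + ["e", "el", f"e_{name}", "erev"]:
        if cand and cand in params:
            E = params[cand]
            break

    gbar = None
    for cand in ("gbar", "gmax", f"g{ion}bar", "gl", "g"):
        if cand in params:
            gbar = params[cand]
            break
    if gbar is None:
        gbar = 0.0

    temp_ref = params.get("temp", params.get("celsius", 23.0))
    q10 = params.get("q10")

    # numeric substitutions for everything but v and the states
    subs = {sp.Symbol(k): v for k, v in params.items()}

    gates = []
    for s in states:
        if s not in gate_kinetics:
            raise ModParseError(f"{label}: state '{s}' has no derivative equation")
        xinf_expr, tau_expr = gate_kinetics[s]
        xi_fun = sp.lambdify(_sym_v, xinf_expr.subs(subs), modules="numpy")
        tau_fun = sp.lambdify(_sym_v, tau_expr.subs(subs), modules="numpy")
        gates.append(GatingVariable(name=s, p_exp=exponents.get(s, 1),
                                    x_inf=_vector(xi_fun), tau=_vector(tau_fun)))

    return GatedChannel(name=name, ion=ion, gbar=gbar, E=E, gates=gates,
                        temp_ref=float(temp_ref), q10=q10, params=params)


def _vector(f):
    def g(V):
        return np.asarray(f(np.asarray(V, dtype=float)), dtype=float)
    return g


# -------------------------------------------------------- MOD file generation

STANDARD_MOD_TEMPLATE = """\
NEURON {{
    SUFFIX {suffix}
    {ion_clause}
    RANGE gbar
}}

UNITS {{
    (mV) = (millivolt)
    (mA) = (milliamp)
    (S) = (siemens)
}}

PARAMETER {{
    gbar = {gbar} (S/cm2)
{param_lines}
{e_line}
}}

STATE {{ {state_names} }}

BREAKPOINT {{
    SOLVE states METHOD cnexp
    {current_assign}
}}

INITIAL {{
    rates(v)
{init_lines}
}}

DERIVATIVE states {{
    rates(v)
{deriv_lines}
}}

PROCEDURE rates(v (mV)) {{
{rate_lines}
}}
"""


def generate_mod(channel: GatedChannel, template: str | None = None,
                 path=None) -> str:
    """Emit MOD source for a channel; standardized channels use the
    five-parameter closed forms so that ``parse_mod`` round-trips exactly.

    A custom ``template`` (str.format style, same field names as the default)
    may be supplied; a missing template variable raises ``KeyError``.
    """
    names = [g.name for g in channel.gates]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate gate names in channel '{channel.name}': {names}")
    if not channel.is_standard:
        raise ValueError(
            "generate_mod requires standardized gates (five-parameter form); "
            "run standardize() first")
    tmpl = template if template is not None else STANDARD_MOD_TEMPLATE

    if channel.ion in ("na", "k", "ca"):
        ion_clause = f"USEION {channel.ion} READ e{channel.ion} WRITE i{channel.ion}"
        cur = f"i{channel.ion}"
        e_name = f"e{channel.ion}"
    else:
        ion_clause = "NONSPECIFIC_CURRENT i"
        cur = "i"
        e_name = "e"
    e_line = f"    {e_name} = {_fmt(channel.E if channel.E is not None else 0.0)} (mV)"

    param_lines, rate_lines, deriv_lines, init_lines = [], [], [], []
    prob = []
    for g in channel.gates:
        p = g.std
        for pname, val in zip(("vhalf", "sigma", "k", "delta", "tau0"), p.as_tuple()):
            param_lines.append(f"    {pname}_{g.name} = {_fmt(val)}")
        rate_lines += [
            f"    {g.name}inf = 1/(1 + exp((v - vhalf_{g.name})/sigma_{g.name}))",
            f"    {g.name}tau = 1/(k_{g.name}*exp(delta_{g.name}*(v - vhalf_{g.name})"
            f"/(-sigma_{g.name})) + k_{g.name}*exp(-(1 - delta_{g.name})*(v - "
            f"vhalf_{g.name})/(-sigma_{g.name}))) + tau0_{g.name}",
        ]
        deriv_lines.append(f"    {g.name}' = ({g.name}inf - {g.name})/{g.name}tau")
        init_lines.append(f"    {g.name} = {g.name}inf")
        prob.append(g.name if g.p_exp == 1 else f"{g.name}^{g.p_exp}")
    current_assign = f"{cur} = gbar*{'*'.join(prob)}*(v - {e_name})"

    assigned = [f"{g.name}inf" for g in channel.gates] + [f"{g.name}tau" for g in channel.gates]
    text = tmpl.format(
        suffix=channel.name, ion_clause=ion_clause, gbar=_fmt(channel.gbar),
        param_lines="\n".join(param_lines), e_line=e_line,
        state_names=" ".join(names), current_assign=current_assign,
        deriv_lines="\n".join(deriv_lines), init_lines="\n".join(init_lines),
        rate_lines="\n".join(rate_lines), assigned_names=" ".join(assigned),
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _fmt(x: float) -> str:
    return repr(float(x))
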