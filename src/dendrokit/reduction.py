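"""Impedance-preserving reduction of passive dendritic subtrees.

Any inclusive subtree (a section plus everything distal to it) of a passive
cable model is mapped to the unique sealed cylinder that preserves, at a
chosen frequency, the input impedance at the subtree's root end (measured
disconnected from the cell) and the transfer impedance from the
electrotonically most distal tip to that root.  The cylinder shares the
subtree's specific membrane resistivity Rm, capacitance Cm, and axial
resistivity Ra; only its diameter d and length L are solved for:

    L_hat = arccosh(Z_in / Z_tr)          (electrotonic length)
    Z_c   = Z_tr * sinh(L_hat)            (characteristic impedance)
    d     = ((2/pi) * sqrt(Rm*Ra) / Z_c)^(2/3),   L = L_hat * lambda(d)

Active channel densities are remapped post hoc: each original segment is
assigned to the reduced segment with the closest transfer impedance to the
subtree root (electrotonic position), and the reduced value is the mean of
its contributors.  Remapped profiles are finally compressed to a compact
analytic distribution (minimum MSE, complexity as tie-break).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .distributions import Distribution
from .morphology import Morphology, PointNode

MOHM = 1e6  # Ω per MΩ


@dataclass
class ImpedancePair:
    """Input and transfer impedance magnitudes of a subtree (MΩ)."""

    Z_in: float
    Z_tr: float
    frequency: float = 0.0

    def __post_init__(self):
        if not (self.Z_in >= self.Z_tr > 0):
            raise ValueError(f"need Z_in >= Z_tr > 0, got {self.Z_in}, {self.Z_tr}")


@dataclass
class EquivalentCylinder:
    """Sealed cylinder preserving a subtree's impedance pair."""

    diameter: float  # µm
    length: float    # µm
    Rm: float        # Ω·cm²
    Cm: float        # µF/cm²
    Ra: float        # Ω·cm
    frequency: float = 0.0

    @property
    def lambda_dc(self) -> float:
        """DC length constant in µm."""
        return math.sqrt(self.Rm * (self.diameter * 1e-4) / (4.0 * self.Ra)) * 1e4

    def impedances(self) -> ImpedancePair:
        zin, ztr = _cylinder_impedances(self.diameter, self.length, self.Rm,
                                        self.Cm, self.Ra, self.frequency)
        return ImpedancePair(zin, ztr, self.frequency)


@dataclass
class SegmentMapping:
    """Original-to-reduced segment assignment with per-target contributors."""

    assignment: dict   # original Segment -> reduced segment index
    contributors: dict  # reduced segment index -> list of original Segments


# ------------------------------------------------- two-port cable primitives

def _gamma_zc(d_um: float, Rm: float, Cm: float, Ra: float, freq: float):
    """Per-cable (1/λ, Z_c) at a frequency; complex for f > 0.

    d in µm; Rm Ω·cm²; Cm µF/cm²; Ra Ω·cm.  λ returned in µm, Z_c in Ω.
    """
    d_cm = d_um * 1e-4
    tau_s = Rm * Cm * 1e-6  # s
    q = np.sqrt(1.0 + 1j * 2.0 * math.pi * freq * tau_s) if freq else 1.0
    lam_um = math.sqrt(Rm * d_cm / (4.0 * Ra)) * 1e4 / q
    z_c = (2.0 / math.pi) * math.sqrt(Rm * Ra) * d_cm ** -1.5 / q
    return lam_um, z_c


def _fold_piece(length_um, lam_um, z_c, y_load):
    """Input admittance at the proximal end of one uniform piece."""
    x = length_um / lam_um
    t = np.tanh(x)
    z_in = z_c * (1.0 + z_c * y_load * t) / (z_c * y_load + t) if abs(t) > 0 \
        else 1.0 / y_load if y_load != 0 else np.inf
    return 1.0 / z_in


def _piece_attenuation(length_um, lam_um, z_c, y_load):
    """V(distal)/V(proximal) of one piece terminated by y_load."""
    x = length_um / lam_um
    return 1.0 / (np.cosh(x) + z_c * y_load * np.sinh(x))


def _cylinder_impedances(d_um, L_um, Rm, Cm, Ra, freq):
    lam, z_c = _gamma_zc(d_um, Rm, Cm, Ra, freq)
    x = L_um / lam
    z_in = z_c / np.tanh(x)
    z_tr = z_c / np.sinh(x)
    return abs(z_in) / MOHM, abs(z_tr) / MOHM


class _SubtreeCable:
    """Passive two-port view of an inclusive section subtree."""

    def __init__(self, morph: Morphology, section, Rm, Cm, Ra, frequency):
        self.morph = morph
        self.root = section
        self.Rm, self.Cm, self.Ra, self.freq = Rm, Cm, Ra, frequency
        self._pieces: dict = {}   # section -> list of (length, diameter)
        self._y_in: dict = {}     # section -> admittance at proximal end
        self._y_at: dict = {}     # section -> per-piece distal-side admittance
        self._att: dict = {}      # section -> attenuation root->distal end
        self._build()

    def _section_pieces(self, sec):
        if any(d <= 0 for d in (2 * r for r in sec._radii)):
            raise ValueError(f"zero-diameter section {sec.id}")
        arc, radii = sec._arc, sec._radii
        pieces = []
        for i in range(len(arc) - 1):
            ln = arc[i + 1] - arc[i]
            if ln <= 0:
                continue
            pieces.append((float(ln), float(radii[i] + radii[i + 1])))  # (len, mean diam)
        if not pieces:
            pieces = [(max(sec.length, 1e-6), 2.0 * float(radii[0]))]
        return pieces

    def _build(self):
        post = self.morph.subtree_sections(self.root)[::-1]  # children first
        for sec in post:
            pieces = self._section_pieces(sec)
            y = sum(self._y_in[ch] for ch in sec.children) if sec.children else 0.0
            y_at = []
            for ln, dd in reversed(pieces):
                y_at.append(y)  # admittance loading this piece's distal end
                lam, z_c = _gamma_zc(dd, self.Rm, self.Cm, self.Ra, self.freq)
                y = _fold_piece(ln, lam, z_c, y)
            self._pieces[sec] = pieces
            self._y_at[sec] = list(reversed(y_at))
            self._y_in[sec] = y
        # pre-order: attenuation from subtree root to each section's distal end
        for sec in self.morph.subtree_sections(self.root):
            a = 1.0 if sec is self.root else self._att[sec.parent]
            for (ln, dd), yl in zip(self._pieces[sec], self._y_at[sec]):
                lam, z_c = _gamma_zc(dd, self.Rm, self.Cm, self.Ra, self.freq)
                a = a * _piece_attenuation(ln, lam, z_c, yl)
            self._att[sec] = a

    @property
    def z_in(self) -> complex:
        return 1.0 / self._y_in[self.root]

    def attenuation_at(self, sec, frac: float) -> complex:
        """Attenuation from the subtree root to arc fraction ``frac`` of sec."""
        a = 1.0 if sec is self.root else self._att[sec.parent]
        s_target = frac * sec.length
        s = 0.0
        for (ln, dd), yl in zip(self._pieces[sec], self._y_at[sec]):
            lam, z_c = _gamma_zc(dd, self.Rm, self.Cm, self.Ra, self.freq)
            if s + ln <= s_target:
                a = a * _piece_attenuation(ln, lam, z_c, yl)
                s += ln
            else:
                part = s_target - s
                if part > 0:
                    # load seen at the cut = remaining piece folded onto yl
                    y_cut = _fold_piece(ln - part, lam, z_c, yl)
                    a = a * _piece_attenuation(part, lam, z_c, y_cut)
                return a
        return a

    def tips(self):
        return [s for s in self.morph.subtree_sections(self.root) if not s.children]


def measure_impedances(morph: Morphology, section, Rm: float, Cm: float,
                       Ra: float, frequency: float = 0.0) -> ImpedancePair:
    """Z_in at the subtree root end and Z_tr to the electrotonically most
    distal tip (the tip minimising |Z_tr|), in MΩ, at ``frequency`` Hz.

    The subtree is treated as disconnected from the rest of the cell and
    purely passive (only Rm, Cm, Ra enter).
    """
    cab = _SubtreeCable(morph, section, Rm, Cm, Ra, frequency)
    z_in = cab.z_in
    z_tr = min((abs(z_in * cab._att[tip]) for tip in cab.tips()))
    return ImpedancePair(abs(z_in) / MOHM, z_tr / MOHM, frequency)


def transfer_impedance_profile(morph: Morphology, section, Rm, Cm, Ra,
                               frequency: float = 0.0) -> dict:
    """|Z_tr| (MΩ) from the subtree root to every segment center."""
    cab = _SubtreeCable(morph, section, Rm, Cm, Ra, frequency)
    z_in = cab.z_in
    out = {}
    for sec in morph.subtree_sections(section):
        for seg in sec.segments:
            out[seg] = abs(z_in * cab.attenuation_at(sec, seg.center_fraction)) / MOHM
    return out


# --------------------------------------------------------- cylinder solving

def solve_cylinder(pair: ImpedancePair, Rm: float, Cm: float, Ra: float,
                   frequency: float = 0.0) -> EquivalentCylinder:
    """Recover the unique sealed cylinder (d, L) from an impedance pair.

    For f > 0 magnitudes are matched using |Z_c(ω)| = Z_c/|q| and
    |λ(ω)| = λ/|q| with q = sqrt(1 + iωτ_m).  The isopotential limit
    Z_in ≈ Z_tr degenerates to L_hat = 0 and is replaced by a unit-aspect
    stub with the matched membrane area.
    """
    z_in, z_tr = pair.Z_in * MOHM, pair.Z_tr * MOHM
    ratio = z_in / z_tr
    tau_s = Rm * Cm * 1e-6
    qmag = abs(np.sqrt(1.0 + 1j * 2 * math.pi * frequency * tau_s)) if frequency else 1.0
    if ratio <= 1.0 + 1e-9:
        # isopotential stub of matched membrane area, aspect ratio 1
        area_cm2 = Rm / z_in
        d_cm = math.sqrt(area_cm2 / math.pi)
        return EquivalentCylinder(d_cm * 1e4, d_cm * 1e4, Rm, Cm, Ra, frequency)
    L_hat = math.acosh(ratio)
    z_c_mag = z_tr * math.sinh(L_hat)
    z_c_dc = z_c_mag * qmag
    d_cm = ((2.0 / math.pi) * math.sqrt(Rm * Ra) / z_c_dc) ** (2.0 / 3.0)
    lam_dc_um = math.sqrt(Rm * d_cm / (4.0 * Ra)) * 1e4
    L_um = L_hat * lam_dc_um / qmag
    if not (np.isfinite(d_cm) and np.isfinite(L_um)):
        raise ValueError("non-finite cylinder solution")
    return EquivalentCylinder(d_cm * 1e4, L_um, Rm, Cm, Ra, frequency)


# ------------------------------------------------------------ tree surgery

def reduce_subtree(morph: Morphology, section, Rm: float, Cm: float, Ra: float,
                   frequency: float = 0.0, d_lambda: float = 0.1):
    """Replace a section's inclusive subtree by its equivalent cylinder.

    Returns ``(reduced_morph, mapping, cylinder)``.  The cylinder is
    reattached at the original parent position and re-discretised at
    ``d_lambda`` of its DC length constant; the rest of the cell keeps its
    per-section segment counts.  The soma cannot be reduced.
    """
    if section.parent is None or section.domain == "soma":
        raise ValueError("cannot reduce the soma/root section")
    pair = measure_impedances(morph, section, Rm, Cm, Ra, frequency)
    cyl = solve_cylinder(pair, Rm, Cm, Ra, frequency)

    # electrotonic positions of the original segments, for channel mapping
    z_orig = transfer_impedance_profile(morph, section, Rm, Cm, Ra, frequency)

    # --- build the reduced point list
    first_pt = section.points[0]
    attach = section._attach_point
    doomed = {p.id for p in morph.subtree_points(first_pt.id)}
    keep = [PointNode(p.id, p.type_code, p.x, p.y, p.z, p.radius, p.parent_id)
            for p in morph.points if p.id not in doomed]
    next_id = max(p.id for p in keep) + 1
    base = attach.xyz() if attach is not None else np.zeros(3)
    direction = first_pt.xyz() - base
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    r = cyl.diameter / 2.0
    tc = first_pt.type_code
    p0 = PointNode(next_id, tc, *base, r, attach.id)
    p1 = PointNode(next_id + 1, tc, *(base + direction * cyl.length), r, next_id)
    reduced = Morphology(keep + [p0, p1])

    # locate the new cylinder section and re-discretise it at d_lambda * λ_DC
    new_sec = next(s for s in reduced.sections if p1 in s.points)
    nseg_map = {}
    old_counts = {}
    for s in morph.sections:
        if s not in morph.subtree_sections(section):
            key = tuple(p.id for p in s.points)
            old_counts[key] = max(1, len(s.segments))
    for s in reduced.sections:
        key = tuple(p.id for p in s.points)
        if s is new_sec:
            n = int(math.ceil(new_sec.length / (d_lambda * cyl.lambda_dc)))
            nseg_map[s.id] = n + 1 if n % 2 == 0 else n
        else:
            nseg_map[s.id] = old_counts.get(key, 1)
    reduced.build_segments(nseg_map)
    new_sec = next(s for s in reduced.sections if p1 in s.points)

    z_red = transfer_impedance_profile(reduced, new_sec, Rm, Cm, Ra, frequency)
    mapping = _assign_by_impedance(z_orig, {s: z for s, z in z_red.items()})
    return reduced, mapping, cyl


def reduce_all_stems(morph: Morphology, Rm, Cm, Ra, frequency: float = 0.0,
                     d_lambda: float = 0.1):
    """Iteratively reduce every stem dendrite (soma child), yielding the
    fully reduced soma-plus-cylinders model."""
    reduced = morph
    mappings = []
    while True:
        stem = next((s for s in reduced.root_section.children
                     if len(s.points) > 2 or s.children), None)
        if stem is None:
            break
        reduced, mp, _ = reduce_subtree(reduced, stem, Rm, Cm, Ra, frequency, d_lambda)
        mappings.append(mp)
    return reduced, mappings


def _assign_by_impedance(z_orig: dict, z_red: dict) -> SegmentMapping:
    red_segs = list(z_red.keys())
    red_z = np.array([z_red[s] for s in red_segs])
    assignment, contributors = {}, {s.idx: [] for s in red_segs}
    for seg, z in z_orig.items():
        j = int(np.argmin(np.abs(red_z - z)))
        assignment[seg] = red_segs[j].idx
        contributors[red_segs[j].idx].append(seg)
    return SegmentMapping(assignment, contributors)


# ---------------------------------------------------------- channel mapping

def map_channels(values: dict, mapping: SegmentMapping, rule: str = "impedance") -> dict:
    """Per-reduced-segment parameter values by averaging contributors.

    ``values`` maps original segments to their parameter value.  Reduced
    segments with no contributor inherit the nearest (by index) assigned
    neighbour's value.  A uniform original density is therefore preserved
    exactly.
    """
    out = {}
    for ridx, contribs in mapping.contributors.items():
        vals = [values[s] for s in contribs if s in values]
        if vals:
            out[ridx] = float(np.mean(vals))
    if not out:
        return {ridx: 0.0 for ridx in mapping.contributors}
    filled = sorted(out)
    for ridx in mapping.contributors:
        if ridx not in out:
            j = min(filled, key=lambda k: abs(k - ridx))
            out[ridx] = out[j]
    return out


# ------------------------------------------------------- distribution refit

def _step_fit(d, v, max_breaks=3):
    """Best piecewise-constant fit with up to ``max_breaks`` breakpoints."""
    order = np.argsort(d)
    ds, vs = np.asarray(d)[order], np.asarray(v)[order]
    n = len(ds)
    cands = np.unique((ds[:-1] + ds[1:]) / 2.0)
    pre = np.concatenate([[0.0], np.cumsum(vs)])
    pre2 = np.concatenate([[0.0], np.cumsum(vs ** 2)])

    def sse(i, j):  # [i, j)
        if j <= i:
            return 0.0
        s, s2 = pre[j] - pre[i], pre2[j] - pre2[i]
        return s2 - s * s / (j - i)

    best = (sse(0, n), [], [float(np.mean(vs))])
    idx_of = np.searchsorted(ds, cands, side="right")
    m = len(cands)
    for k in range(1, max_breaks + 1):
        if m < k:
            break
        for combo in itertools.combinations(range(m), k):
            cuts = [0] + [idx_of[c] for c in combo] + [n]
            if any(cuts[i] >= cuts[i + 1] for i in range(len(cuts) - 1)):
                continue
            tot = sum(sse(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))
            if tot < best[0] - 1e-15:
                breaks = [float(cands[c]) for c in combo]
                vals = [float(np.mean(vs[cuts[i]:cuts[i + 1]]))
                        for i in range(len(cuts) - 1)]
                best = (tot, breaks, vals)
    mse = best[0] / n
    return Distribution("step", [best[1], best[2]]), mse


def refit_distribution(distances, values, max_poly_degree: int = 3):
    """Compress (distance, value) samples to a compact analytic distribution.

    Candidates: constant, linear, polynomial (deg <= 3), step (<= 3
    breakpoints), exponential ``a + b·exp(d/c)``, sigmoidal.  The winner
    minimises MSE; near-ties go to the form with fewer coefficients.  If
    every parametric fit fails, a lossless step function through the data is
    returned (flagged in the report).
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 samples to refit a distribution")
    scale = max(float(np.var(v)), 1e-30)
    candidates = []  # (mse, n_coeff, Distribution)

    def add(dist):
        mse = float(np.mean((dist(d) - v) ** 2))
        if np.isfinite(mse):
            ncoef = (len(dist.coefficients[0]) + len(dist.coefficients[1])
                     if dist.kind == "step" else len(dist.coefficients))
            candidates.append((mse, ncoef, dist))

    add(Distribution("constant", [float(np.mean(v))]))
    try:
        for deg in range(1, max_poly_degree + 1):
            coeffs = np.polyfit(d, v, deg)
            kind = "linear" if deg == 1 else "polynomial"
            cl = [float(coeffs[1]), float(coeffs[0])] if deg == 1 \
                else [float(c) for c in coeffs]
            add(Distribution(kind, cl))
    except (np.linalg.LinAlgError, ValueError):
        pass
    try:
        sd, mse = _step_fit(d, v)
        candidates.append((mse, len(sd.coefficients[0]) + len(sd.coefficients[1]), sd))
    except ValueError:
        pass
    span = float(np.ptp(d)) or 1.0
    try:
        p, _ = curve_fit(lambda x, a, b, c: a + b * np.exp(x / c), d, v,
                         p0=[float(v.min()), max(float(v[-1] - v[0]), 1e-6), span],
                         maxfev=5000)
        add(Distribution("exponential", [float(x) for x in p]))
    except (RuntimeError, ValueError, TypeError):
        pass
    try:
        p, _ = curve_fit(lambda x, a, b, d0, s: a + b / (1 + np.exp(-(x - d0) / s)),
                         d, v, p0=[float(v[0]), float(v[-1] - v[0]),
                                   float(np.median(d)), span / 10.0], maxfev=5000)
        add(Distribution("sigmoidal", [float(x) for x in p]))
    except (RuntimeError, ValueError, TypeError):
        pass

    if not candidates:
        order = np.argsort(d)
        breaks = [float(x) for x in (d[order][:-1] + d[order][1:]) / 2.0]
        dist = Distribution("step", [breaks, [float(x) for x in v[order]]])
        return dist, {"mse": 0.0, "fallback": True, "candidates": 0}

    tol = 1e-12 + 1e-9 * scale
    best_mse = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_mse + tol]
    tied.sort(key=lambda c: (c[1], c[0]))
    mse, ncoef, dist = tied[0]
    return dist, {"mse": mse, "fallback": False, "candidates": len(candidates),
                  "kind": dist.kind}
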