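"""Neuronal morphologies as three linked tree graphs: points, sections, segments.

A reconstruction is a tree of 3D points (SWC rows).  Points are grouped into
*sections* — the unbranched stretches between bifurcations and type-code
changes — and each section is spatially discretised into *segments*, the
nodes of the cable-equation system.  Segment centers sit at (2i-1)/(2*nseg)
of the section arc length, i = 1..nseg.

All lengths are in micrometres; diameters are interpolated linearly in arc
length; section length is the 3D polyline length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# SWC type codes -> domain labels (>=5 become "custom<N>")
SWC_DOMAINS = {1: "soma", 2: "axon", 3: "dend", 4: "apic"}
DOMAIN_CODES = {v: k for k, v in SWC_DOMAINS.items()}


class SWCError(ValueError):
    """Malformed SWC content; message carries the offending line number."""


def domain_of(type_code: int) -> str:
    return SWC_DOMAINS.get(type_code, f"custom{type_code}")


def code_of(domain: str) -> int:
    if domain in DOMAIN_CODES:
        return DOMAIN_CODES[domain]
    if domain.startswith("custom"):
        return int(domain[6:])
    # user relabels (trunk/oblique/tuft ...) export as apical unless known
    return DOMAIN_CODES.get(domain, 5)


@dataclass
class PointNode:
    """One SWC row: a 3D sample with radius, linked to its parent."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def dist_to(self, other: "PointNode") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass
class Segment:
    """A spatial-discretisation unit of a section; one cable-equation node."""

    section: "Section"
    index: int  # 1-based, matching the (2i-1)/(2*nseg) convention
    center_fraction: float
    length: float  # µm of section arc covered by this segment
    diameter: float  # µm at the segment center
    area: float  # µm², frustum lateral surface over its span (sphere for a 1-pt soma)
    path_distance: float  # µm from the tree root to the segment center
    parent: "Segment | None" = None
    children: list = field(default_factory=list, repr=False)

    @property
    def domain(self) -> str:
        return self.section.domain

    @property
    def idx(self) -> int:
        """Global index in the segment tree's traversal order."""
        return self._idx

    def __hash__(self):
        return id(self)

    def __eq__(self, other):
        return self is other


@dataclass
class Section:
    """An unbranched run of points sharing one domain label."""

    id: int
    domain: str
    points: list  # PointNode refs, shared with the point tree
    parent: "Section | None" = None
    attachment: float = 1.0  # arc fraction on the parent where this section connects
    children: list = field(default_factory=list, repr=False)
    segments: list = field(default_factory=list, repr=False)

    # geometry caches, filled by _build_geometry
    _arc: np.ndarray | None = None
    _radii: np.ndarray | None = None
    _start_dist: float = 0.0  # path distance from root to the section's proximal end

    def __hash__(self):
        return id(self)

    def __eq__(self, other):
        return self is other

    @property
    def is_spherical_soma(self) -> bool:
        return self.domain == "soma" and len(self.points) == 1

    def _build_geometry(self) -> None:
        """Polyline arc lengths and radii, prepending the parent attachment point.

        A child section's polyline starts at its parent point's coordinates so
        that a single-point child still has finite length.  A spherical
        (single-point) soma is special-cased.
        """
        pts = self.points
        if self.is_spherical_soma:
            r = pts[0].radius
            self._arc = np.array([0.0, 2.0 * r])  # equivalent-cylinder span
            self._radii = np.array([r, r])
            self._own_arc = np.array([r])  # the point sits at the sphere center
            return
        coords = [p.xyz() for p in pts]
        radii = [p.radius for p in pts]
        prepended = False
        # sections rooted on the soma start at their own first point (the
        # soma sphere/stack is not part of the neurite polyline)
        if self.parent is not None and self.parent.domain != "soma":
            pp = self._attach_point
            if pp is not None and not np.allclose(pp.xyz(), coords[0]):
                coords.insert(0, pp.xyz())
                radii.insert(0, radii[0])  # do not taper into the parent's radius
                prepended = True
        coords = np.asarray(coords, dtype=float)
        seglens = np.linalg.norm(np.diff(coords, axis=0), axis=1) if len(coords) > 1 else np.array([])
        arc = np.concatenate([[0.0], np.cumsum(seglens)])
        if arc[-1] <= 0:
            arc = np.array([0.0] + [1e-6] * (len(coords) - 1))
            if len(arc) == 1:
                arc = np.array([0.0, 1e-6])
                radii = [radii[0], radii[-1]]
        self._arc = arc
        self._radii = np.asarray(radii, dtype=float)
        self._own_arc = arc[1:] if prepended else arc

    def arc_fraction_of(self, point: PointNode) -> float:
        """Arc-length fraction of one of this section's own points."""
        i = self.points.index(point)
        return float(self._own_arc[i] / self.length)

    @property
    def _attach_point(self) -> PointNode | None:
        if self.parent is None:
            return None
        pid = self.points[0].parent_id
        for p in self.parent.points:
            if p.id == pid:
                return p
        return self.parent.points[-1]

    @property
    def length(self) -> float:
        return float(self._arc[-1])

    def radius_at(self, frac: float) -> float:
        s = frac * self.length
        return float(np.interp(s, self._arc, self._radii))

    def diameter_at(self, frac: float) -> float:
        return 2.0 * self.radius_at(frac)

    def frustum_area(self, f0: float = 0.0, f1: float = 1.0) -> float:
        """Lateral frustum surface (µm²) between arc fractions f0 and f1."""
        if self.is_spherical_soma and f0 == 0.0 and f1 == 1.0:
            r = self.points[0].radius
            return 4.0 * math.pi * r * r
        s0, s1 = f0 * self.length, f1 * self.length
        cuts = np.unique(np.concatenate([[s0, s1], self._arc[(self._arc > s0) & (self._arc < s1)]]))
        r = np.interp(cuts, self._arc, self._radii)
        ds = np.diff(cuts)
        dr = np.diff(r)
        slant = np.sqrt(ds * ds + dr * dr)
        if self.is_spherical_soma:
            # sphere: partial surface proportional to the axial span
            rr = self.points[0].radius
            return 4.0 * math.pi * rr * rr * (s1 - s0) / self.length
        return float(np.sum(math.pi * (r[:-1] + r[1:]) * slant))

    def mean_diameter(self) -> float:
        """Arc-length-weighted mean diameter along the polyline."""
        if len(self._arc) < 2:
            return 2.0 * float(self._radii[0])
        ds = np.diff(self._arc)
        dmid = self._radii[:-1] + self._radii[1:]  # 2 * mean radius per piece
        return float(np.sum(dmid * ds) / np.sum(ds))


class Morphology:
    """Linked point / section / segment trees of one reconstruction."""

    def __init__(self, points: list):
        self.points: list[PointNode] = points
        self.sections: list[Section] = []
        self.segments: list[Segment] = []
        self._rebuild()

    # ------------------------------------------------------------------ build

    def _rebuild(self) -> None:
        self._validate_points()
        self._sort_points()
        self._derive_sections()
        nseg_keep = {}
        for sec in self.sections:
            nseg_keep[sec.id] = max(1, len(sec.segments)) if sec.segments else 1
        self.build_segments({sid: n for sid, n in nseg_keep.items()})

    def _validate_points(self) -> None:
        seen = set()
        roots = 0
        ids = {p.id for p in self.points}
        if not self.points:
            raise SWCError("empty morphology: no points")
        for p in self.points:
            if p.id in seen:
                raise SWCError(f"duplicate point id {p.id}")
            seen.add(p.id)
            if p.radius <= 0:
                raise SWCError(f"non-positive radius at point id {p.id}")
            if p.parent_id == -1:
                roots += 1
            elif p.parent_id not in ids:
                raise SWCError(f"parent id {p.parent_id} of point {p.id} is not defined")
        if roots == 0:
            raise SWCError("no root point (parent_id == -1)")
        if roots > 1:
            raise SWCError(f"multiple roots: {roots} points with parent_id == -1")

    def _sort_points(self) -> None:
        """Topological order (parent before child), stable in id within level."""
        by_parent: dict[int, list[PointNode]] = {}
        for p in self.points:
            by_parent.setdefault(p.parent_id, []).append(p)
        for lst in by_parent.values():
            lst.sort(key=lambda p: p.id)
        ordered: list[PointNode] = []
        stack = list(reversed(by_parent.get(-1, [])))
        while stack:
            p = stack.pop()
            ordered.append(p)
            stack.extend(reversed(by_parent.get(p.id, [])))
        if len(ordered) != len(self.points):
            raise SWCError("point graph is not a tree (cycle or disconnected points)")
        self.points = ordered

    def _derive_sections(self) -> None:
        """Cut at every bifurcation and every type-code change."""
        by_id = {p.id: p for p in self.points}
        children: dict[int, list[PointNode]] = {}
        for p in self.points:
            if p.parent_id != -1:
                children.setdefault(p.parent_id, []).append(p)
        for lst in children.values():
            lst.sort(key=lambda q: q.id)
        self._children_of_point = children
        self._point_by_id = by_id

        root = next(p for p in self.points if p.parent_id == -1)
        sections: list[Section] = []
        sec_of_point: dict[int, Section] = {}

        def new_section(first: PointNode, parent_sec: Section | None) -> Section:
            sec = Section(id=len(sections), domain=domain_of(first.type_code),
                          points=[first], parent=parent_sec)
            sections.append(sec)
            if parent_sec is not None:
                parent_sec.children.append(sec)
            return sec

        # iterative DFS carrying the section a run belongs to
        stack: list[tuple[PointNode, Section | None]] = [(root, None)]
        while stack:
            p, parent_sec = stack.pop()
            sec = new_section(p, parent_sec)
            sec_of_point[p.id] = sec
            # extend the run while: single child, same type code
            cur = p
            while True:
                kids = children.get(cur.id, [])
                if len(kids) == 1 and kids[0].type_code == cur.type_code:
                    cur = kids[0]
                    sec.points.append(cur)
                    sec_of_point[cur.id] = sec
                else:
                    break
            for k in reversed(children.get(cur.id, [])):
                if len(children.get(cur.id, [])) == 1 and k.type_code == cur.type_code:
                    continue  # consumed above
                stack.append((k, sec))

        self.sections = sections
        self._section_of_point = sec_of_point
        for sec in sections:
            sec._build_geometry()
        # attachment fractions + path distance of the proximal end
        for sec in sections:
            if sec.parent is None:
                sec.attachment = 0.0
                sec._start_dist = 0.0
        for sec in self._sections_topo():
            for ch in sec.children:
                ap = ch._attach_point
                try:
                    frac = 1.0 if ap is None else sec.arc_fraction_of(ap)
                except ValueError:
                    frac = 1.0
                # soma children attach at the soma center by convention
                ch.attachment = 0.5 if sec.domain == "soma" else frac
                ch._start_dist = sec._start_dist + (0.0 if sec.domain == "soma"
                                                   else ch.attachment * sec.length)

    def _sections_topo(self):
        out = []
        stack = [s for s in self.sections if s.parent is None]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(reversed(s.children))
        return out

    # -------------------------------------------------------------- segments

    def build_segments(self, nseg: "int | dict | None" = None, *,
                       d_lambda: float | None = None, frequency: float = 100.0,
                       cm: float = 1.0, Ra: float = 100.0) -> list:
        """Discretise every section and rebuild the segment tree.

        Either pass ``nseg`` (an int applied to all sections, or a map
        section-id -> nseg), or a ``d_lambda`` policy: nseg is the smallest
        odd integer such that each segment spans at most ``d_lambda`` of the
        AC length constant at ``frequency`` Hz given ``cm`` (µF/cm²) and
        ``Ra`` (Ω·cm).
        """
        if d_lambda is not None:
            if d_lambda <= 0:
                raise ValueError("d_lambda must be > 0")
            if frequency <= 0:
                raise ValueError("frequency must be > 0")
            if cm <= 0 or Ra <= 0:
                raise ValueError("cm and Ra must be > 0")
        self.segments = []
        for sec in self._sections_topo():
            if d_lambda is not None:
                n = self._nseg_d_lambda(sec, d_lambda, frequency, cm, Ra)
            elif isinstance(nseg, dict):
                n = nseg.get(sec.id, 1)
            else:
                n = int(nseg) if nseg else 1
            self._segment_section(sec, n)
        self._link_segment_tree()
        return self.segments

    @staticmethod
    def lambda_f(diam_um: float, frequency: float, Ra: float, cm: float) -> float:
        """AC length constant in µm: 1e5·sqrt(d/(4π·f·Ra·cm))."""
        return 1e5 * math.sqrt(diam_um / (4.0 * math.pi * frequency * Ra * cm))

    def _nseg_d_lambda(self, sec: Section, d_lambda, frequency, cm, Ra) -> int:
        lam = self.lambda_f(sec.mean_diameter(), frequency, Ra, cm)
        return int((sec.length / (d_lambda * lam) + 0.9) / 2.0) * 2 + 1

    def _segment_section(self, sec: Section, n: int) -> None:
        if n < 1:
            raise ValueError("nseg must be >= 1")
        if sec.is_spherical_soma:
            n = 1  # a sphere has no cable axis to subdivide
        sec.segments = []
        L = sec.length
        for i in range(1, n + 1):
            cf = (2 * i - 1) / (2.0 * n)
            f0, f1 = (i - 1) / n, i / n
            seg = Segment(
                section=sec, index=i, center_fraction=cf,
                length=L / n, diameter=sec.diameter_at(cf),
                area=sec.frustum_area(f0, f1),
                path_distance=sec._start_dist + (0.0 if sec.domain == "soma" else cf * L),
            )
            sec.segments.append(seg)
        self.segments.extend(sec.segments)

    def _link_segment_tree(self) -> None:
        for idx, seg in enumerate(self.segments):
            seg._idx = idx
            seg.children = []
            seg.parent = None
        for sec in self._sections_topo():
            prev = None
            if sec.parent is not None:
                prev = sec.parent.segment_at(sec.attachment)
            for seg in sec.segments:
                if prev is not None:
                    seg.parent = prev
                    prev.children.append(seg)
                prev = seg

    # ------------------------------------------------------------- accessors

    @property
    def root_section(self) -> Section:
        return next(s for s in self.sections if s.parent is None)

    def section(self, sec_id: int) -> Section:
        for s in self.sections:
            if s.id == sec_id:
                return s
        raise KeyError(f"no section with id {sec_id}")

    def domains(self) -> set:
        return {s.domain for s in self.sections}

    def subtree_sections(self, sec: Section) -> list:
        out = []
        stack = [sec]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(reversed(s.children))
        return out

    def subtree_points(self, point_id: int) -> list:
        out = []
        stack = [self._point_by_id[point_id]]
        while stack:
            p = stack.pop()
            out.append(p)
            stack.extend(self._children_of_point.get(p.id, []))
        return out

    # ----------------------------------------------------------------- edits

    def insert_node(self, parent_id: int, child_id: int, *, fraction: float = 0.5) -> PointNode:
        """Insert a point on the edge parent->child at the given fraction."""
        par = self._point_by_id[parent_id]
        ch = self._point_by_id.get(child_id)
        if ch is None or ch.parent_id != parent_id:
            raise ValueError(f"point {child_id} is not a child of {parent_id}")
        new_id = max(p.id for p in self.points) + 1
        xyz = par.xyz() + fraction * (ch.xyz() - par.xyz())
        node = PointNode(new_id, ch.type_code, *xyz,
                         radius=par.radius + fraction * (ch.radius - par.radius),
                         parent_id=parent_id)
        ch.parent_id = new_id
        self.points.append(node)
        self._rebuild()
        return node

    def remove_node(self, point_id: int) -> None:
        """Remove one point, splicing its children onto its parent."""
        p = self._point_by_id.get(point_id)
        if p is None:
            raise KeyError(f"no point with id {point_id}")
        if p.parent_id == -1:
            raise ValueError("cannot remove the root point")
        for ch in self._children_of_point.get(point_id, []):
            ch.parent_id = p.parent_id
        self.points = [q for q in self.points if q.id != point_id]
        self._rebuild()

    def remove_subtree(self, point_id: int) -> int:
        """Remove a point and all its descendants; returns the count removed."""
        doomed = {q.id for q in self.subtree_points(point_id)}
        if self._point_by_id[point_id].parent_id == -1:
            raise ValueError("cannot remove the root subtree (would empty the tree)")
        self.points = [q for q in self.points if q.id not in doomed]
        self._rebuild()
        return len(doomed)

    def translate_subtree(self, point_id: int, dx: float, dy: float, dz: float) -> None:
        for q in self.subtree_points(point_id):
            q.x += dx
            q.y += dy
            q.z += dz
        self._rebuild()

    def sort(self) -> None:
        """Renumber points 1..N in the canonical traversal order."""
        mapping = {}
        for new_id, p in enumerate(self.points, start=1):
            mapping[p.id] = new_id
        for p in self.points:
            p.id = mapping[p.id]
            if p.parent_id != -1:
                p.parent_id = mapping[p.parent_id]
        self._rebuild()


# (Section.segment_at defined here to keep the dataclass body short)
def _segment_at(self: Section, frac: float) -> Segment:
    for seg in self.segments:
        i = seg.index
        n = len(self.segments)
        if (i - 1) / n <= frac <= i / n:
            return seg
    return self.segments[-1]


Section.segment_at = _segment_at


# ------------------------------------------------------------------ file I/O

def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into linked point/section trees.

    Raises :class:`SWCError` naming the offending line for duplicate ids,
    missing parents, multiple roots, or non-positive radii.
    """
    points = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                pid, tc = int(cols[0]), int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                par = int(cols[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if r <= 0:
                raise SWCError(f"line {lineno}: non-positive radius {r} at point {pid}")
            points.append(PointNode(pid, tc, x, y, z, r, par))
    try:
        return Morphology(points)
    except SWCError as exc:
        raise SWCError(f"{path}: {exc}") from None


def write_swc(morph: Morphology, path) -> None:
    """Write canonical 7-column SWC (points renumbered 1..N in tree order)."""
    if not morph.points:
        raise SWCError("cannot write an empty morphology")
    mapping = {p.id: i for i, p in enumerate(morph.points, start=1)}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for p in morph.points:
            par = -1 if p.parent_id == -1 else mapping[p.parent_id]
            fh.write(f"{mapping[p.id]} {p.type_code} {p.x:.6f} {p.y:.6f} {p.z:.6f} "
                     f"{p.radius:.6f} {par}\n")


# --------------------------------------------------------------- morphometry

def morphometry(segments) -> dict:
    """Counts and summary statistics over a selection of segments.

    Returns section/segment/bifurcation/root/leaf counts, mean diameter,
    mean and total length, mean and total area.  Raises on an empty
    selection.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("empty segment selection")
    secs = {s.section for s in segments}
    n_bif = sum(1 for s in secs if len(s.children) >= 2)
    n_leaves = sum(1 for s in secs if not s.children)
    n_roots = sum(1 for s in secs if s.parent is None)
    diam = np.array([s.diameter for s in segments])
    length = np.array([s.length for s in segments])
    area = np.array([s.area for s in segments])
    return {
        "n_sections": len(secs),
        "n_segments": len(segments),
        "n_bifurcations": n_bif,
        "n_roots": n_roots,
        "n_leaves": n_leaves,
        "mean_diameter": float(diam.mean()),
        "mean_length": float(length.mean()),
        "total_length": float(length.sum()),
        "mean_area": float(area.mean()),
        "total_area": float(area.sum()),
    }


def histogram(segments, attribute: str, bins: int = 10):
    """Histogram of a segment attribute (diameter, length, area, path_distance)."""
    vals = np.array([getattr(s, attribute) for s in segments])
    return np.histogram(vals, bins=bins)
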