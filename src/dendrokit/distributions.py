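"""Segment groups, distance-parameterized distributions, and the biophys config.

Where a parameter applies is decided by *segment groups* — ordered,
criterion-based selections of segments (by domain plus diameter, absolute
path distance, or relative distance within a domain).  How much of it each
segment gets is decided by a *distribution function* of the segment's path
distance from the soma.  When groups overlap, the top-most group in the
stack wins; segments covered by no group keep the mechanism default.

The whole biophysical configuration serializes to a three-section JSON
document: (1) domain -> inserted mechanisms, (2) segment-group definitions
(listed order = stack order, last listed is top-most), (3) parameter ->
{group -> distribution} maps.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dendrokit.distributions")

CRITERIA = ("diameter", "absolute_distance", "relative_distance")
DISTRIBUTION_KINDS = ("constant", "linear", "exponential", "sigmoidal", "step", "polynomial")


@dataclass
class Distribution:
    """A parametric map from path distance (µm) to a parameter value.

    Forms: constant ``c``; linear ``a + b·d``; exponential ``a + b·exp(d/c)``;
    sigmoidal ``a + b/(1 + exp(-(d - d0)/s))``; step (breakpoints + values,
    values has one more entry); polynomial (coefficients, highest degree
    first, numpy convention).
    """

    kind: str
    coefficients: list

    def __post_init__(self):
        if self.kind not in DISTRIBUTION_KINDS:
            raise ValueError(f"unknown distribution kind '{self.kind}'")
        if self.kind == "step":
            breaks, values = self.coefficients
            if len(values) != len(breaks) + 1:
                raise ValueError("step distribution needs len(values) == len(breaks)+1")

    def __call__(self, distance):
        d = np.asarray(distance, dtype=float)
        c = self.coefficients
        if self.kind == "constant":
            out = np.full_like(d, float(c[0]))
        elif self.kind == "linear":
            out = c[0] + c[1] * d
        elif self.kind == "exponential":
            out = c[0] + c[1] * np.exp(d / c[2])
        elif self.kind == "sigmoidal":
            out = c[0] + c[1] / (1.0 + np.exp(-(d - c[2]) / c[3]))
        elif self.kind == "step":
            breaks, values = c
            out = np.asarray(values, dtype=float)[np.searchsorted(breaks, d, side="right")]
        else:  # polynomial
            out = np.polyval(c, d)
        return float(out) if np.isscalar(distance) else out

    def to_dict(self) -> dict:
        return {"kind": self.kind, "coefficients": self.coefficients}

    @classmethod
    def from_dict(cls, data: dict) -> "Distribution":
        extra = set(data) - {"kind", "coefficients"}
        if extra:
            raise ValueError(f"unknown distribution keys {sorted(extra)}")
        return cls(kind=data["kind"], coefficients=data["coefficients"])


@dataclass
class SegmentGroup:
    """An ordered, criterion-based selection of segments."""

    name: str
    domains: list  # domain labels; ["all"] matches every domain
    criterion: str = "absolute_distance"
    min_value: float = 0.0
    max_value: float = math.inf

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion '{self.criterion}'")
        if self.min_value > self.max_value:
            raise ValueError("group bounds must satisfy min <= max")

    def matches(self, segment, morph=None) -> bool:
        if "all" not in self.domains and segment.domain not in self.domains:
            return False
        val = criterion_value(segment, self.criterion, morph)
        return self.min_value <= val <= self.max_value

    def select(self, segments, morph=None) -> list:
        return [s for s in segments if self.matches(s, morph)]

    def to_dict(self) -> dict:
        d = {"name": self.name, "domains": list(self.domains),
             "criterion": self.criterion}
        if self.min_value != 0.0:
            d["min"] = self.min_value
        if self.max_value != math.inf:
            d["max"] = self.max_value
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SegmentGroup":
        extra = set(data) - {"name", "domains", "criterion", "min", "max"}
        if extra:
            raise ValueError(f"group '{data.get('name')}': unknown keys {sorted(extra)}")
        return cls(name=data["name"], domains=data["domains"],
                   criterion=data.get("criterion", "absolute_distance"),
                   min_value=data.get("min", 0.0), max_value=data.get("max", math.inf))


def criterion_value(segment, criterion: str, morph=None) -> float:
    if criterion == "diameter":
        return segment.diameter
    if criterion == "absolute_distance":
        return segment.path_distance
    # relative distance within the segment's domain: position between the
    # domain's most proximal point and its most distal point, in [0, 1]
    if morph is None:
        raise ValueError("relative_distance needs the morphology for domain extents")
    dom_seg = [s for s in morph.segments if s.domain == segment.domain]
    dmin = min(s.path_distance - s.length / 2.0 for s in dom_seg)
    dmax = max(s.path_distance + s.length / 2.0 for s in dom_seg)
    if dmax <= dmin:
        return 0.0
    return (segment.path_distance - dmin) / (dmax - dmin)


def match_segments(group: SegmentGroup, morph) -> list:
    """All segments of the morphology matching a group's domain + criterion."""
    known = morph.domains()
    for d in group.domains:
        if d != "all" and d not in known:
            raise ValueError(f"group '{group.name}': unknown domain '{d}' "
                             f"(have {sorted(known)})")
    return group.select(morph.segments, morph)


@dataclass
class BiophysConfig:
    """Three-section biophysical configuration of a cell.

    ``mechanisms``: domain -> list of inserted mechanism names.
    ``groups``: the ordered group stack (last listed is top-most).
    ``parameters``: parameter name -> ordered {group name -> Distribution}.
    Parameter names follow the ``<param>_<mechanism>`` convention (plus the
    passive cable properties ``cm`` and ``Ra``).
    """

    mechanisms: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in the stack")
        for pname, per_group in self.parameters.items():
            for gname in per_group:
                if gname not in names:
                    raise ValueError(
                        f"parameter '{pname}' references undefined group '{gname}'")

    def group(self, name: str) -> SegmentGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def mechanism_of(self, parameter: str) -> str | None:
        if "_" in parameter:
            return parameter.rsplit("_", 1)[1]
        return None


def effective_value(parameter: str, segment, config: BiophysConfig, morph,
                    default: float | None = None):
    """Value of a parameter at one segment under top-most-group precedence.

    Scans the group stack from the top; the first matching group that
    carries a distribution for this parameter decides the value.  Segments
    covered by no group keep the mechanism ``default`` (logged, not an
    error).
    """
    per_group = config.parameters.get(parameter, {})
    for g in reversed(config.groups):  # last listed = top-most
        if g.name in per_group and g.matches(segment, morph):
            return per_group[g.name](segment.path_distance)
    logger.debug("segment %s not covered for '%s'; keeping default %s",
                 segment, parameter, default)
    return default


def apply_config(config: BiophysConfig, morph, defaults: dict | None = None) -> pd.DataFrame:
    """Evaluate every distributed parameter at every segment.

    Returns a DataFrame indexed by segment order with one column per
    parameter plus ``domain`` and ``distance``.  Raises if a parameter's
    mechanism is not inserted in a domain where the parameter would be
    assigned.  Idempotent, and portable across morphologies sharing the
    same domain labels.
    """
    defaults = defaults or {}
    known = morph.domains()
    for g in config.groups:
        for d in g.domains:
            if d != "all" and d not in known:
                raise ValueError(f"group '{g.name}': unknown domain '{d}'")
    rows = {}
    rows["domain"] = [s.domain for s in morph.segments]
    rows["distance"] = [s.path_distance for s in morph.segments]
    for pname, per_group in config.parameters.items():
        mech = config.mechanism_of(pname)
        vals = []
        for seg in morph.segments:
            v = effective_value(pname, seg, config, morph, default=defaults.get(pname))
            if v is not None and mech is not None:
                inserted = config.mechanisms.get(seg.domain, [])
                if mech not in inserted:
                    raise ValueError(
                        f"parameter '{pname}' assigned in domain '{seg.domain}' "
                        f"but mechanism '{mech}' is not inserted there")
            vals.append(np.nan if v is None else v)
        rows[pname] = vals
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- JSON I/O

_TOP_KEYS = {"domains", "groups", "params"}


def write_config(config: BiophysConfig, path) -> None:
    doc = {
        "domains": {d: sorted(m) for d, m in sorted(config.mechanisms.items())},
        "groups": [g.to_dict() for g in config.groups],
        "params": {p: {g: dist.to_dict() for g, dist in per.items()}
                   for p, per in config.parameters.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path) -> BiophysConfig:
    with open(path) as fh:
        doc = json.load(fh)
    extra = set(doc) - _TOP_KEYS
    if extra:
        raise ValueError(f"{path}: unknown top-level keys {sorted(extra)}")
    groups = [SegmentGroup.from_dict(g) for g in doc.get("groups", [])]
    names = {g.name for g in groups}
    params = {}
    for pname, per in doc.get("params", {}).items():
        params[pname] = {}
        for gname, dd in per.items():
            if gname not in names:
                raise ValueError(
                    f"{path}: params.{pname} references undefined group '{gname}'")
            params[pname][gname] = Distribution.from_dict(dd)
    return BiophysConfig(mechanisms={d: list(m) for d, m in doc.get("domains", {}).items()},
                         groups=groups, parameters=params)
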