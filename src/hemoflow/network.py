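"""Vessel-network container: a geometric graph of cylindrical segments.

Positions are in micrometres inside a slab-shaped field of view; every
segment is a straight cylinder between two nodes, so its length is the
Euclidean distance between the endpoint positions.  Curved vessels are
represented as chains of straight segments.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

VESSEL_CLASSES = ("arteriole_1", "arteriole_2", "capillary", "venule_1", "venule_2")
ARTERIOLE_INLET = "arteriole_inlet"
VENULE_OUTLET = "venule_outlet"

#: capillary lumen diameter never exceeds this (µm)
MAX_CAPILLARY_DIAMETER_UM = 7.0
#: classification threshold: diameter <= this is a capillary (µm)
DEFAULT_CAPILLARY_THRESHOLD_UM = 8.0


class NetworkError(ValueError):
    """Raised when a vessel network violates its structural invariants."""


@dataclass(frozen=True)
class Segment:
    """A straight cylindrical vessel segment between two nodes."""

    id: int
    a: int
    b: int
    radius: float  # µm
    vessel_class: str = "capillary"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise NetworkError(f"segment {self.id}: radius must be > 0")
        if self.vessel_class not in VESSEL_CLASSES:
            raise NetworkError(
                f"segment {self.id}: unknown vessel class {self.vessel_class!r}"
            )


# note: the capillary-diameter cap is enforced by validate(), not by the
# Segment constructor, so that graphs extracted from images (whose radius
# estimates carry voxel-scale error) can be built and then checked with a
# caller-chosen bound.


@dataclass
class VesselNetwork:
    """Geometric vessel graph.

    Parameters
    ----------
    positions:
        Mapping node id -> (x, y, z) position in µm.
    segments:
        List of :class:`Segment`.  Segment ids must be unique.
    roots:
        Mapping terminal-node id -> ``"arteriole_inlet"`` or ``"venule_outlet"``.
    extents:
        Optional (Lx, Ly, Lz) slab extents in µm used for validation.
    """

    positions: dict[int, tuple[float, float, float]]
    segments: list[Segment]
    roots: dict[int, str] = field(default_factory=dict)
    extents: tuple[float, float, float] | None = None

    # -- basic geometry -------------------------------------------------
    def length(self, seg: Segment) -> float:
        pa = self.positions[seg.a]
        pb = self.positions[seg.b]
        return math.dist(pa, pb)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def inlets(self) -> list[int]:
        return [n for n, tag in self.roots.items() if tag == ARTERIOLE_INLET]

    def outlets(self) -> list[int]:
        return [n for n, tag in self.roots.items() if tag == VENULE_OUTLET]

    def arrays(self):
        """Vectorised view: (node_ids, index_of, a_idx, b_idx, radius_um, length_um)."""
        node_ids = sorted(self.positions)
        index_of = {n: i for i, n in enumerate(node_ids)}
        a_idx = np.array([index_of[s.a] for s in self.segments], dtype=np.intp)
        b_idx = np.array([index_of[s.b] for s in self.segments], dtype=np.intp)
        radius = np.array([s.radius for s in self.segments], dtype=float)
        length = np.array([self.length(s) for s in self.segments], dtype=float)
        return node_ids, index_of, a_idx, b_idx, radius, length

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n, p in self.positions.items():
            g.add_node(n, position=p, root=self.roots.get(n))
        for s in self.segments:
            g.add_edge(s.a, s.b, key=s.id, segment=s)
        return g

    # -- validation -----------------------------------------------------
    def validate(self, max_capillary_diameter_um: float = MAX_CAPILLARY_DIAMETER_UM) -> None:
        """Check all structural invariants; raise :class:`NetworkError` on failure."""
        seen_ids: set[int] = set()
        for s in self.segments:
            if s.id in seen_ids:
                raise NetworkError(f"duplicate segment id {s.id}")
            seen_ids.add(s.id)
            if s.a not in self.positions or s.b not in self.positions:
                raise NetworkError(f"segment {s.id} references missing node")
            if self.length(s) <= 0:
                raise NetworkError(f"segment {s.id} has zero length")
            if s.vessel_class == "capillary" and 2 * s.radius > max_capillary_diameter_um + 1e-9:
                raise NetworkError(
                    f"capillary segment {s.id} diameter {2 * s.radius:.2f} µm exceeds "
                    f"{max_capillary_diameter_um} µm"
                )
        if self.extents is not None:
            ext = np.asarray(self.extents, dtype=float)
            for n, p in self.positions.items():
                q = np.asarray(p, dtype=float)
                if np.any(q < -1e-9) or np.any(q > ext + 1e-9):
                    raise NetworkError(f"node {n} at {p} lies outside slab extents {self.extents}")
        for n, tag in self.roots.items():
            if tag not in (ARTERIOLE_INLET, VENULE_OUTLET):
                raise NetworkError(f"unknown root tag {tag!r} on node {n}")
            if n not in self.positions:
                raise NetworkError(f"root node {n} has no position")
        if not self.inlets():
            raise NetworkError("network has no arteriole inlet")
        if not self.outlets():
            raise NetworkError("network has no venule outlet")
        g = self.to_networkx()
        if self.n_segments and not nx.is_connected(g):
            raise NetworkError("network graph is not connected")
        if not self.has_inlet_outlet_path():
            raise NetworkError("no path joins an arteriole inlet to a venule outlet")

    def has_inlet_outlet_path(self) -> bool:
        adj: dict[int, list[int]] = {}
        for s in self.segments:
            adj.setdefault(s.a, []).append(s.b)
            adj.setdefault(s.b, []).append(s.a)
        outlets = set(self.outlets())
        stack = [n for n in self.inlets() if n in adj]
        seen = set(stack)
        while stack:
            n = stack.pop()
            if n in outlets:
                return True
            for m in adj.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return False

    # -- derived quantities ---------------------------------------------
    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            positions=dict(self.positions),
            segments=list(self.segments),
            roots=dict(self.roots),
            extents=self.extents,
        )

    def subdivided(self) -> tuple["VesselNetwork", dict[int, tuple[int, int]]]:
        """Split every segment into two colinear halves at its midpoint.

        Returns the refined network and a map parent segment id -> (child_id_a,
        child_id_b).  Used for discretization-independence checks.
        """
        positions = dict(self.positions)
        next_node = max(positions) + 1 if positions else 0
        next_seg = max((s.id for s in self.segments), default=-1) + 1
        segments: list[Segment] = []
        children: dict[int, tuple[int, int]] = {}
        for s in self.segments:
            pa = np.asarray(positions[s.a], dtype=float)
            pb = np.asarray(positions[s.b], dtype=float)
            mid = tuple(0.5 * (pa + pb))
            m = next_node
            next_node += 1
            positions[m] = mid
            c1 = Segment(next_seg, s.a, m, s.radius, s.vessel_class)
            c2 = Segment(next_seg + 1, m, s.b, s.radius, s.vessel_class)
            next_seg += 2
            segments.extend([c1, c2])
            children[s.id] = (c1.id, c2.id)
        return (
            VesselNetwork(positions=positions, segments=segments, roots=dict(self.roots), extents=self.extents),
            children,
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n, "position": [float(v) for v in self.positions[n]]}
                for n in sorted(self.positions)
            ],
            "segments": [
                {
                    "id": s.id,
                    "a": s.a,
                    "b": s.b,
                    "radius_um": s.radius,
                    "vessel_class": s.vessel_class,
                }
                for s in self.segments
            ],
            "roots": {str(n): tag for n, tag in sorted(self.roots.items())},
            "extents_um": list(self.extents) if self.extents is not None else None,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "VesselNetwork":
        try:
            positions = {int(n["id"]): tuple(float(v) for v in n["position"]) for n in d["nodes"]}
            segments = [
                Segment(
                    id=int(s["id"]),
                    a=int(s["a"]),
                    b=int(s["b"]),
                    radius=float(s["radius_um"]),
                    vessel_class=str(s["vessel_class"]),
                )
                for s in d["segments"]
            ]
            roots = {int(n): str(tag) for n, tag in d.get("roots", {}).items()}
            extents = d.get("extents_um")
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkError(f"malformed network record: {exc}") from exc
        return cls(
            positions=positions,
            segments=segments,
            roots=roots,
            extents=tuple(extents) if extents is not None else None,
        )

    @classmethod
    def from_json(cls, text: str) -> "VesselNetwork":
        return cls.from_dict(json.loads(text))


def network_volume(network: VesselNetwork) -> float:
    """Total vessel volume Σ πR²L in µm³."""
    return float(sum(math.pi * s.radius**2 * network.length(s) for s in network.segments))


def classify_vessels(
    network: VesselNetwork,
    capillary_threshold_um: float = DEFAULT_CAPILLARY_THRESHOLD_UM,
) -> VesselNetwork:
    """Assign a vessel class to every segment.

    A segment whose diameter is at or below ``capillary_threshold_um`` is a
    capillary (ties go to capillary).  Larger segments are arterioles or
    venules depending on which tagged root they are reachable from through
    other large segments; the branching order (1 vs 2) counts junction nodes
    of degree >= 3 passed on the way from the root, capped at 2.
    """
    if not network.roots:
        raise NetworkError("classify_vessels requires tagged roots")

    large = [s for s in network.segments if 2 * s.radius > capillary_threshold_um]
    adj: dict[int, list[Segment]] = {}
    degree: dict[int, int] = {}
    for s in network.segments:
        degree[s.a] = degree.get(s.a, 0) + 1
        degree[s.b] = degree.get(s.b, 0) + 1
    for s in large:
        adj.setdefault(s.a, []).append(s)
        adj.setdefault(s.b, []).append(s)

    # BFS over large segments from each root type; order bumps at junctions
    side_of: dict[int, str] = {}
    order_of: dict[int, int] = {}
    for tag, side in ((ARTERIOLE_INLET, "arteriole"), (VENULE_OUTLET, "venule")):
        frontier = [(n, 1) for n, t in network.roots.items() if t == tag]
        seen_nodes = {n for n, _ in frontier}
        while frontier:
            node, order = frontier.pop(0)
            for s in adj.get(node, ()):
                if s.id in side_of:
                    continue
                side_of[s.id] = side
                order_of[s.id] = order
                other = s.b if s.a == node else s.a
                if other not in seen_nodes:
                    seen_nodes.add(other)
                    nxt = order + 1 if degree.get(other, 0) >= 3 else order
                    frontier.append((other, min(nxt, 2)))

    segments = []
    for s in network.segments:
        if 2 * s.radius <= capillary_threshold_um:
            cls = "capillary"
        elif s.id in side_of:
            cls = f"{side_of[s.id]}_{min(order_of[s.id], 2)}"
        else:
            # large vessel not reachable from any root through large vessels:
            # keep its existing non-capillary class if any, else treat as capillary-adjacent
            cls = s.vessel_class if s.vessel_class != "capillary" else "capillary"
        segments.append(replace(s, vessel_class=cls))
    out = network.copy()
    out.segments = segments
    return out
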