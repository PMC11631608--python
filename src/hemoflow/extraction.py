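"""Vessel-graph extraction from binary volumes.

The mask is thinned to a 1-voxel-wide centerline; skeleton voxels with one
26-neighbor become terminals and those with three or more become junctions,
and the chains between them become polyline vessel segments.  The local
radius is read from the Euclidean distance transform of the mask (mean along
each chain — robust against inflation at junctions), and short terminal
spurs, a standard thinning artifact, are pruned.

Physical positions follow the voxel convention used throughout: position =
index * spacing + origin, with the z axis of the stack the
anterior-posterior direction.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .network import NetworkError, Segment, VesselNetwork
from .synthetic import LabelVolume

__all__ = ["skeletonize_and_graph", "graph_summary"]

_NEIGHBORS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def skeletonize_and_graph(
    mask: LabelVolume,
    prune_spurs: bool = True,
    spur_factor: float = 2.0,
    junction_merge_um: float = 20.0,
    min_radius_um: float | None = None,
) -> VesselNetwork:
    """Convert a binary vessel mask into a :class:`VesselNetwork`.

    Parameters
    ----------
    mask:
        Binary volume (z, y, x) with voxel spacing in µm.
    prune_spurs:
        Remove terminal chains shorter than ``spur_factor`` times their mean
        local radius (skeletonization artifacts at vessel walls).
    junction_merge_um:
        Junction clusters joined by a centerline chain shorter than this (or
        than twice the local radius, whichever is larger) are one anatomical
        bifurcation and are merged; set below the true inter-branch spacing.
    min_radius_um:
        Optional floor applied to estimated radii (sub-voxel estimates on
        thin vessels are noisy).

    Raises ``NetworkError`` on an empty mask.  Warns when no vessel of
    arteriole/venule calibre (diameter > 8 µm) is present.
    """
    data = mask.data.astype(bool)
    if not data.any():
        raise NetworkError("cannot extract a network from an empty mask")
    dx, dy, dz = mask.spacing
    skel = skeletonize(data)
    if not skel.any():
        raise NetworkError("skeletonization produced an empty centerline")
    edt = ndimage.distance_transform_edt(data, sampling=(dz, dy, dx))

    coords = {tuple(c) for c in np.argwhere(skel)}
    degree = {c: sum(((c[0] + o[0], c[1] + o[1], c[2] + o[2]) in coords) for o in _NEIGHBORS) for c in coords}

    # one anatomical bifurcation thins to a small cluster of adjacent
    # degree>=3 voxels; contract each cluster to a single junction node
    cluster_of: dict[tuple[int, int, int], int] = {}
    n_clusters = 0
    for c in sorted(coords):
        if degree[c] < 3 or c in cluster_of:
            continue
        cid = n_clusters
        n_clusters += 1
        stack = [c]
        cluster_of[c] = cid
        while stack:
            cur = stack.pop()
            for o in _NEIGHBORS:
                nb = (cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                if nb in coords and degree[nb] >= 3 and nb not in cluster_of:
                    cluster_of[nb] = cid
                    stack.append(nb)

    # trace chains between nodes (degree != 2); isolated loops get an anchor
    nodes = {c for c, d in degree.items() if d != 2}
    visited_edges: set[frozenset] = set()
    chains: list[list[tuple[int, int, int]]] = []

    def neighbors(c):
        for o in _NEIGHBORS:
            n = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            if n in coords:
                yield n

    for start in sorted(nodes):
        for nb in sorted(neighbors(start)):
            if frozenset((start, nb)) in visited_edges:
                continue
            chain = [start, nb]
            visited_edges.add(frozenset((start, nb)))
            prev, cur = start, nb
            while cur not in nodes:
                nxts = [n for n in neighbors(cur) if n != prev and frozenset((cur, n)) not in visited_edges]
                if not nxts:
                    break
                nxt = nxts[0]
                visited_edges.add(frozenset((cur, nxt)))
                chain.append(nxt)
                prev, cur = cur, nxt
            chains.append(chain)
    # isolated cycles (no degree!=2 voxel): anchor at the smallest coordinate
    remaining = coords - {c for ch in chains for c in ch}
    while remaining:
        start = min(remaining)
        chain = [start]
        prev, cur = None, start
        while True:
            nxts = [n for n in neighbors(cur) if n != prev and frozenset((cur, n)) not in visited_edges]
            if not nxts:
                break
            nxt = nxts[0]
            visited_edges.add(frozenset((cur, nxt)))
            chain.append(nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
        chains.append(chain)
        remaining -= set(chain)

    def chain_radius(chain) -> float:
        vals = [edt[c] for c in chain]
        r = float(np.mean(vals))
        if min_radius_um is not None:
            r = max(r, min_radius_um)
        return max(r, 0.25 * min(dx, dy, dz))

    def chain_length(chain) -> float:
        p = np.array(chain, dtype=float) * np.array([dz, dy, dx])
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))

    if prune_spurs:
        chains = _prune_spur_chains(chains, degree, chain_radius, chain_length, spur_factor)

    # build the geometric graph: chain interior voxels become polyline nodes
    positions: dict[int, tuple[float, float, float]] = {}
    index_of: dict[tuple[int, int, int], int] = {}
    segments: list[Segment] = []
    ox, oy, oz = mask.origin

    def node_id(c) -> int:
        if c not in index_of:
            index_of[c] = len(index_of)
            z, y, x = c
            positions[index_of[c]] = (x * dx + ox, y * dy + oy, z * dz + oz)
        return index_of[c]

    # a bifurcation on a thick vessel often thins to two nearby triads; merge
    # junction clusters joined by a chain shorter than the local radius
    parent = list(range(n_clusters))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for chain in chains:
        ca = cluster_of.get(chain[0])
        cb = cluster_of.get(chain[-1])
        if ca is None or cb is None or find(ca) == find(cb):
            continue
        if chain_length(chain) < max(2.0 * chain_radius(chain), junction_merge_um):
            parent[find(ca)] = find(cb)

    # junction clusters collapse onto a representative voxel so that each
    # bifurcation is one graph node
    rep_of_cluster: dict[int, tuple[int, int, int]] = {}
    for c in sorted(cluster_of):
        rep_of_cluster.setdefault(find(cluster_of[c]), c)

    def canonical(c):
        return rep_of_cluster[find(cluster_of[c])] if c in cluster_of else c

    sid = 0
    for chain in chains:
        if len(chain) >= 2 and canonical(chain[0]) == canonical(chain[-1]):
            # chain collapsed within one junction cluster
            interior = [c for c in chain[1:-1] if c not in cluster_of]
            if not interior:
                continue
        r = chain_radius(chain)
        simplified = _simplify_polyline(chain, tol_vox=0.5)
        simplified = [canonical(simplified[0])] + simplified[1:-1] + [canonical(simplified[-1])]
        for a, b in zip(simplified[:-1], simplified[1:]):
            ia, ib = node_id(a), node_id(b)
            if ia == ib:
                continue
            segments.append(Segment(sid, ia, ib, r, "capillary"))
            sid += 1

    if segments and max(2 * s.radius for s in segments) <= 8.0:
        warnings.warn(
            "extracted network contains no vessel of arteriole/venule calibre (> 8 µm diameter)",
            stacklevel=2,
        )
    return VesselNetwork(positions=positions, segments=segments, roots={}, extents=None)


def _prune_spur_chains(chains, degree, chain_radius, chain_length, spur_factor):
    """Drop terminal chains shorter than spur_factor x local radius."""
    kept = []
    for chain in chains:
        end_degrees = (degree.get(chain[0], 1), degree.get(chain[-1], 1))
        is_spur = (1 in end_degrees) and (3 <= max(end_degrees))
        if is_spur and chain_length(chain) < spur_factor * 2.0 * chain_radius(chain):
            continue
        kept.append(chain)
    return kept


def _simplify_polyline(chain, tol_vox: float = 0.5):
    """Ramer-Douglas-Peucker on voxel coordinates; endpoints always kept.

    Each emitted sub-segment is straight between its endpoint nodes, so the
    straight-segment length invariant of the network container holds by
    construction.
    """
    pts = np.array(chain, dtype=float)
    if len(pts) <= 2:
        return chain

    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = pts[j] - pts[i]
        nrm = np.linalg.norm(seg)
        if nrm == 0:
            d = np.linalg.norm(pts[i + 1 : j] - pts[i], axis=1)
        else:
            d = np.linalg.norm(np.cross(pts[i + 1 : j] - pts[i], seg / nrm), axis=1)
        k = int(np.argmax(d))
        if d[k] > tol_vox:
            m = i + 1 + k
            keep[m] = True
            stack.extend([(i, m), (m, j)])
    return [chain[i] for i in range(len(chain)) if keep[i]]


def graph_summary(network: VesselNetwork) -> dict:
    """Terminal/junction/chain counts of an extracted (or generated) graph."""
    degree: dict[int, int] = {}
    for s in network.segments:
        degree[s.a] = degree.get(s.a, 0) + 1
        degree[s.b] = degree.get(s.b, 0) + 1
    n_term = sum(1 for d in degree.values() if d == 1)
    n_junc = sum(1 for d in degree.values() if d >= 3)
    # chains = maximal paths between non-degree-2 nodes
    n_chain = 0
    seen: set[int] = set()
    adj: dict[int, list[Segment]] = {}
    for s in network.segments:
        adj.setdefault(s.a, []).append(s)
        adj.setdefault(s.b, []).append(s)
    for s in network.segments:
        if s.id in seen:
            continue
        # walk both directions through degree-2 nodes
        comp = {s.id}
        for start, first in ((s.a, s), (s.b, s)):
            node, seg = start, first
            while degree.get(node, 0) == 2:
                nxt = [t for t in adj[node] if t.id != seg.id][0]
                if nxt.id in comp:
                    break
                comp.add(nxt.id)
                node = nxt.b if nxt.a == node else nxt.a
                seg = nxt
        seen |= comp
        n_chain += 1
    return {"n_terminals": n_term, "n_junctions": n_junc, "n_chains": n_chain}
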