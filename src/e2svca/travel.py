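"""Origin–destination travel times on a road graph.

Real deployments precompute OD matrices with a routing engine and import
them through :mod:`e2svca.io`; this module provides the desk-scale path —
snap block centroids to the nearest road node and run Dijkstra shortest
paths, pruned at the largest catchment threshold.  Edge weights are minutes
directly; no speed-limit or length conversion is performed.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import networkx as nx

from .model import Block, DataError, RoadGraph, TravelTimeMatrix


def od_pair_count(n_blocks: int) -> int:
    """Number of OD records for a full cross-product over ``n_blocks``
    (every block is both an origin and a destination)."""
    if n_blocks < 0:
        raise DataError("block count must be >= 0")
    return n_blocks * n_blocks


def snap_to_graph(
    blocks: Iterable[Block], graph: RoadGraph
) -> dict[str, str]:
    """Map each block to its nearest graph node by Euclidean distance.

    Ties are broken deterministically by the smallest node id.
    """
    if not graph.nodes:
        raise DataError("cannot snap to an empty road graph")
    # sorted once so the tie-break is the lexicographically smallest id
    node_items = sorted(graph.nodes.items())
    mapping: dict[str, str] = {}
    for b in blocks:
        best_id, best_d = None, math.inf
        for node_id, (nx_, ny_) in node_items:
            d = math.hypot(b.x - nx_, b.y - ny_)
            if d < best_d:
                best_id, best_d = node_id, d
        mapping[b.block_id] = best_id
    return mapping


def od_matrix(
    graph: RoadGraph,
    origins: Mapping[str, str],
    destinations: Mapping[str, str],
    cutoff: float | None = None,
) -> TravelTimeMatrix:
    """Shortest-path travel times from every origin block to every
    destination block.

    Pairs with no path, or whose time exceeds ``cutoff`` when one is given,
    are absent from the result (unreachable).  Self pairs are present with
    the node-to-node shortest time (0 when both blocks snap to the same
    node).  Dijkstra runs once per distinct origin node.
    """
    g = graph.to_networkx()
    for name, mapping in (("origin", origins), ("destination", destinations)):
        for blk, node in mapping.items():
            if node not in g:
                raise DataError(f"{name} block {blk} maps to unknown node {node}")

    dest_by_node: dict[str, list[str]] = {}
    for blk, node in destinations.items():
        dest_by_node.setdefault(node, []).append(blk)

    od = TravelTimeMatrix()
    lengths_cache: dict[str, dict[str, float]] = {}
    for o_blk, o_node in origins.items():
        if o_node not in lengths_cache:
            lengths_cache[o_node] = nx.single_source_dijkstra_path_length(
                g, o_node, cutoff=cutoff, weight="minutes"
            )
        lengths = lengths_cache[o_node]
        for d_node, d_blks in dest_by_node.items():
            t = lengths.get(d_node)
            if t is None:
                continue
            for d_blk in d_blks:
                od.set(o_blk, d_blk, t)
    return od
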