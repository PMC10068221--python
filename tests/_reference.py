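"""Independent reference implementations used as test oracles.

Everything here is written brute-force and shares no code with the package:
modal sets by count-and-filter, step weights by explicit if-chains, the
two-step accessibility model as a literal triple loop over blocks, and
shortest paths by exhaustive simple-path enumeration.
"""

from __future__ import annotations

import itertools


def ref_modal_set(values):
    counts = {v: sum(1 for u in values if u == v) for v in values}
    top = max(counts.values())
    return sorted(v for v in counts if counts[v] == top)


def ref_table1_weight(x):
    if x < 0.6:
        return 0.0
    if x < 1.2:
        return 0.33
    if x < 3.0:
        return 0.66
    return 1.0


def ref_block_speeds(records, block_id, direction):
    return [
        (r.download_mbps if direction == "down" else r.upload_mbps)
        for r in records
        if r.block_id == block_id
    ]


def ref_aggregate(speeds, metric):
    if metric == "avg":
        return sum(speeds) / len(speeds)
    if metric == "min_a":
        return min(speeds)
    modes = ref_modal_set(speeds)
    return modes[0] if metric == "min_f" else modes[-1]


def ref_has_internet(records, block_id):
    return any(
        r.block_id == block_id and r.download_mbps > 0 and r.upload_mbps > 0
        for r in records
    )


def ref_pair_weight(method, metric, records, demand_id, supply_id):
    """Broadband pair weight recomputed from raw provider records."""
    if method == "2sfca":
        return 1.0
    if method == "2svca":
        both = ref_has_internet(records, demand_id) and ref_has_internet(
            records, supply_id
        )
        return 1.0 if both else 0.0
    speeds = []
    for blk in (demand_id, supply_id):
        for direction in ("down", "up"):
            s = ref_block_speeds(records, blk, direction)
            if not s:
                return 0.0
            speeds.append(ref_aggregate(s, metric))
    return ref_table1_weight(min(speeds))


def ref_accessibility(blocks, od, d0, method, metric=None, records=None):
    """Literal triple-loop two-step model: for each demand block i, sum over
    reachable supply blocks j of S_j * w(i,j) / (weighted demand on j)."""

    def w(k_id, j_id):
        return ref_pair_weight(method, metric, records, k_id, j_id)

    def reachable(a_id, b_id):
        t = od.get(a_id, b_id)
        return t is not None and t <= d0

    scores = {}
    for i in blocks:
        total = 0.0
        for j in blocks:
            if j.supply <= 0 or not reachable(i.block_id, j.block_id):
                continue
            denom = 0.0
            for k in blocks:
                if reachable(k.block_id, j.block_id):
                    denom += k.population * w(k.block_id, j.block_id)
            if denom > 0:
                total += (j.supply / denom) * w(i.block_id, j.block_id)
        scores[i.block_id] = total
    return scores


def ref_shortest_time(nodes, arcs, src, dst):
    """Minimum over all simple paths; None when disconnected.  Only viable
    on tiny graphs."""
    if src == dst:
        return 0.0
    best = None
    arc_time = {}
    for u, v, t in arcs:
        if (u, v) not in arc_time or t < arc_time[(u, v)]:
            arc_time[(u, v)] = t
    others = [n for n in nodes if n not in (src, dst)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (src, *mid, dst)
            total = 0.0
            ok = True
            for u, v in zip(path, path[1:]):
                if (u, v) not in arc_time:
                    ok = False
                    break
                total += arc_time[(u, v)]
            if ok and (best is None or total < best):
                best = total
    return best
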