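"""Two-step floating/virtual catchment area accessibility engines.

All three methods share the same two-step skeleton over a sparse pairwise
weight map W[(demand k, supply j)]:

1. For each supply block j, the supply–demand ratio
   R_j = S_j / sum_k D_k * W[k, j] over demand blocks inside the travel-time
   catchment (R_j = 0 when no weighted demand can reach j).
2. For each demand block i, accessibility
   A_i = sum_j R_j * W[i, j] over supply blocks inside the catchment.

The methods differ only in the weight:

* ``2sfca``  — distance weight f(d) inside the catchment (indicator by
  default, optionally Gaussian decay).
* ``2svca``  — binary broadband joint function: 1 iff both blocks have at
  least one Internet provider.
* ``e2svca`` — step-wise broadband joint function on the minimum of the
  four speeds (demand up/down, supply up/down) aggregated per block under
  a chosen speed metric.

Catchment membership is always by travel time d_kj <= d0; the virtual
methods carry no distance decay inside the catchment.  Because both steps
use the same weights, the engines satisfy the conservation identity
sum_i D_i * A_i = sum over supplies with positive weighted demand of S_j,
which the test suite verifies.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

from .broadband import (
    ZOOM_SCHEDULE,
    aggregate_all,
    binary_weight,
    internet_flags,
    joint_weight,
)
from .model import (
    AccessibilityResult,
    Block,
    BlockBroadband,
    CatchmentSpec,
    DataError,
    DecayFunction,
    ProviderSpeedRecord,
    SpeedMetric,
    StepWeightSchedule,
    TravelTimeMatrix,
)

WeightMode = Literal["distance_only", "binary_broadband", "stepwise_broadband"]

_INDICATOR = DecayFunction("indicator")


def pair_weights(
    blocks: Sequence[Block],
    od: TravelTimeMatrix,
    catchment: CatchmentSpec,
    mode: WeightMode,
    bb: Iterable[BlockBroadband] | None = None,
    schedule: StepWeightSchedule | None = None,
    decay: DecayFunction = _INDICATOR,
    has_internet: dict[str, bool] | None = None,
) -> dict[tuple[str, str], float]:
    """Sparse pairwise weight map over in-catchment (demand, supply) pairs.

    An entry exists only for pairs whose OD travel time is present and
    <= d0; absent OD pairs are unreachable and get no entry.  Within the
    catchment the weight depends on ``mode``; blocks lacking a broadband
    aggregate (or Internet flag) get weight 0 in the broadband modes rather
    than raising — FCC-style extracts have gaps.
    """
    if mode == "stepwise_broadband":
        if bb is None:
            raise DataError("stepwise_broadband mode requires broadband aggregates")
        if schedule is None:
            raise DataError("stepwise_broadband mode requires a weight schedule")
    if mode == "binary_broadband" and has_internet is None:
        raise DataError("binary_broadband mode requires Internet presence flags")

    bb_by_block = {rec.block_id: rec for rec in bb} if bb is not None else {}
    ids = {b.block_id for b in blocks}

    w: dict[tuple[str, str], float] = {}
    for (k, j), minutes in od.items():
        if minutes > catchment.d0 or k not in ids or j not in ids:
            continue
        if mode == "distance_only":
            w[(k, j)] = decay(minutes, catchment.d0)
        elif mode == "binary_broadband":
            w[(k, j)] = float(
                binary_weight(
                    has_internet.get(k, False), has_internet.get(j, False)
                )
            )
        else:
            bk, bj = bb_by_block.get(k), bb_by_block.get(j)
            w[(k, j)] = 0.0 if bk is None or bj is None else joint_weight(bk, bj, schedule)
    return w


def supply_demand_ratios(
    blocks: Sequence[Block], w: dict[tuple[str, str], float]
) -> dict[str, float]:
    """Step 1: ratio R_j = S_j / weighted in-catchment demand, for every
    block with positive supply.  Supplies no weighted demand can reach get
    R_j = 0 — an unreachable clinic provides no accessibility."""
    pop = {b.block_id: b.population for b in blocks}
    denom: dict[str, float] = {}
    for (k, j), weight in w.items():
        denom[j] = denom.get(j, 0.0) + pop.get(k, 0.0) * weight

    ratios: dict[str, float] = {}
    for b in blocks:
        if b.supply > 0:
            d = denom.get(b.block_id, 0.0)
            ratios[b.block_id] = b.supply / d if d > 0 else 0.0
    return ratios


def accessibility_step(
    blocks: Sequence[Block],
    w: dict[tuple[str, str], float],
    ratios: dict[str, float],
) -> dict[str, float]:
    """Step 2: A_i = sum_j R_j * W[i, j] over in-catchment supply blocks.
    Demand blocks with no reachable supply score 0."""
    scores = {b.block_id: 0.0 for b in blocks}
    for (i, j), weight in w.items():
        r = ratios.get(j)
        if r is not None and i in scores:
            scores[i] += r * weight
    return scores


def compute(
    blocks: Sequence[Block],
    od: TravelTimeMatrix,
    catchment: CatchmentSpec,
    method: Literal["2sfca", "2svca", "e2svca"],
    metric: SpeedMetric | str | None = None,
    schedule: StepWeightSchedule | None = None,
    records: Iterable[ProviderSpeedRecord] | None = None,
    decay: DecayFunction = _INDICATOR,
) -> AccessibilityResult:
    """Run the full two-step computation for one method.

    ``2sfca`` uses the distance weight only (indicator unless ``decay`` is
    given); ``2svca`` needs ``records`` to derive Internet presence flags;
    ``e2svca`` needs ``records`` plus a speed ``metric`` (and uses the
    1-to-1 video-call schedule when ``schedule`` is None).
    """
    if method == "2sfca":
        w = pair_weights(blocks, od, catchment, "distance_only", decay=decay)
        metric_out = None
    elif method == "2svca":
        if records is None:
            raise DataError("2svca requires broadband provider records")
        w = pair_weights(
            blocks, od, catchment, "binary_broadband",
            has_internet=internet_flags(records),
        )
        metric_out = None
    elif method == "e2svca":
        if records is None:
            raise DataError("e2svca requires broadband provider records")
        if metric is None:
            raise DataError("e2svca requires a speed metric")
        metric_out = SpeedMetric(metric)
        schedule = schedule if schedule is not None else ZOOM_SCHEDULE
        bb = aggregate_all(records, metric_out)
        w = pair_weights(
            blocks, od, catchment, "stepwise_broadband", bb=bb, schedule=schedule
        )
    else:
        raise DataError(f"unknown method: {method!r}")

    ratios = supply_demand_ratios(blocks, w)
    scores = accessibility_step(blocks, w, ratios)
    return AccessibilityResult(
        method=method,
        metric=metric_out,
        d0=catchment.d0,
        scores=scores,
        ratios=ratios,
        per_capita_factor=None,
    )
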