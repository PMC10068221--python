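"""Block-level broadband speed aggregation and broadband weight functions.

FCC-style deployment data reports one maximum advertised speed per provider
per census block; accessibility modelling needs one number per block.  Four
aggregation metrics are supported:

* ``avg``   — arithmetic mean of all offered speeds (the baseline earlier
  virtual-catchment work used; sensitive to gigabit outliers).
* ``min_a`` — minimum of all offered speeds: the worst-case scenario.
* ``min_f`` — minimum of the *modal set* (the speeds attaining maximal
  provider count): a common-case scenario.
* ``max_f`` — maximum of the modal set: the optimal scenario.

Two pairwise weight functions connect a demand block to a supply block:
the binary joint function (1 iff both sides have any Internet service) and
the step-wise joint function, which bins the minimum of the four speeds
(demand up/down, supply up/down) against video-conferencing bandwidth
requirements.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .model import (
    BlockBroadband,
    DataError,
    ProviderSpeedRecord,
    SpeedMetric,
    StepWeightSchedule,
)

#: Default step-weight schedule from 1-to-1 Zoom video-call bandwidth
#: requirements: below 0.6 Mbps no video call is possible (weight 0);
#: 0.6 Mbps sustains high-quality video (0.33); 1.2 Mbps sustains 720p
#: (0.66); 3.0 Mbps and above sustains 1080p (1.0).  Upload and download
#: requirements are taken as equal at the 1080p tier.
ZOOM_SCHEDULE = StepWeightSchedule(breaks=(0.6, 1.2, 3.0), weights=(0.0, 0.33, 0.66, 1.0))


def modal_set(values: Sequence[float]) -> list[float]:
    """Values attaining the maximal count in ``values``, sorted ascending.

    When every value occurs equally often the modal set is the whole set of
    distinct values.  Equality is exact on the parsed decimal values: FCC
    speeds are coarse decimals, so no epsilon is applied.
    """
    if not values:
        raise DataError("modal set of an empty collection is undefined")
    counts = Counter(values)
    top = max(counts.values())
    return sorted(v for v, c in counts.items() if c == top)


def aggregate_block_speed(speeds: Sequence[float], metric: SpeedMetric) -> float:
    """Aggregate one block's per-provider speeds (one direction) to a single
    Mbps value under ``metric``.

    Raises
    ------
    DataError
        If ``speeds`` is empty.
    """
    if len(speeds) == 0:
        raise DataError("no broadband records for block")
    metric = SpeedMetric(metric)
    if metric is SpeedMetric.AVG:
        return float(sum(speeds) / len(speeds))
    if metric is SpeedMetric.MIN_A:
        return float(min(speeds))
    modes = modal_set(speeds)
    if metric is SpeedMetric.MIN_F:
        return float(modes[0])
    return float(modes[-1])  # MAX_F


def aggregate_all(
    records: Iterable[ProviderSpeedRecord], metric: SpeedMetric
) -> list[BlockBroadband]:
    """Aggregate provider records to one :class:`BlockBroadband` per block.

    Download and upload speeds are aggregated independently.  Blocks with
    no records simply do not appear in the output; downstream stages treat
    them as having zero broadband weight.
    """
    metric = SpeedMetric(metric)
    downs: dict[str, list[float]] = defaultdict(list)
    ups: dict[str, list[float]] = defaultdict(list)
    order: list[str] = []
    for rec in records:
        if rec.block_id not in downs:
            order.append(rec.block_id)
        downs[rec.block_id].append(rec.download_mbps)
        ups[rec.block_id].append(rec.upload_mbps)
    return [
        BlockBroadband(
            block_id=blk,
            download_mbps=aggregate_block_speed(downs[blk], metric),
            upload_mbps=aggregate_block_speed(ups[blk], metric),
            metric=metric,
        )
        for blk in order
    ]


def stepwise_weight(x: float, schedule: StepWeightSchedule = ZOOM_SCHEDULE) -> float:
    """Weight for speed ``x`` (Mbps) under a step schedule.

    Bins are closed on the left and open on the right: weight ``w_i``
    applies on [x_i, x_{i+1}), with ``w_0`` on [0, x_1) and the top weight
    on [x_n, inf).
    """
    if x < 0:
        raise DataError("speed must be >= 0")
    return schedule.weights[bisect_right(schedule.breaks, x)]


def joint_weight(
    demand_bb: BlockBroadband,
    supply_bb: BlockBroadband,
    schedule: StepWeightSchedule = ZOOM_SCHEDULE,
) -> float:
    """Step-wise broadband joint weight for a demand/supply block pair.

    Video conferencing is two-way, so the binding constraint is the minimum
    of the four speeds: demand upload/download and supply upload/download.
    """
    x = min(
        demand_bb.upload_mbps,
        demand_bb.download_mbps,
        supply_bb.upload_mbps,
        supply_bb.download_mbps,
    )
    return stepwise_weight(x, schedule)


def binary_weight(demand_has_internet: bool, supply_has_internet: bool) -> int:
    """Binary broadband joint function: 1 iff both sides have Internet
    access, regardless of whether the speed suffices for video calls."""
    return 1 if (demand_has_internet and supply_has_internet) else 0


def internet_flags(records: Iterable[ProviderSpeedRecord]) -> dict[str, bool]:
    """Which blocks have Internet access: at least one provider record with
    strictly positive download and upload speed."""
    flags: dict[str, bool] = {}
    for rec in records:
        has = rec.download_mbps > 0 and rec.upload_mbps > 0
        flags[rec.block_id] = flags.get(rec.block_id, False) or has
    return flags
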