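"""Domain types for virtual catchment area accessibility modelling.

The objects here carry the study area: census-block-like areal units with
population (demand) and doctor counts (supply), per-provider broadband speed
records, per-block aggregated broadband speeds, the step-wise broadband
weight schedule, travel-time catchment specification, and the sparse
origin–destination travel-time matrix.  No accessibility computation lives
here — only construction-time validation and a study-area consistency check.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class DataError(ValueError):
    """Raised when input data violates a structural requirement."""


class SpeedMetric(str, enum.Enum):
    """Per-block broadband aggregation metric.

    ``avg`` is the arithmetic-mean baseline used by earlier 2SVCA work;
    ``min_a`` is the minimum of all offered speeds (worst case);
    ``min_f`` / ``max_f`` are the minimum / maximum of the modal set
    (the speeds attaining maximal provider count).
    """

    AVG = "avg"
    MIN_A = "min_a"
    MIN_F = "min_f"
    MAX_F = "max_f"

    def __str__(self) -> str:  # serialized as lowercase token
        return self.value


@dataclass(frozen=True)
class Block:
    """One areal unit: demand (population), supply (doctors), centroid.

    ``block_id`` is an opaque string — FIPS-style codes have leading zeros
    and must never be coerced to integers.  ``in_report_region`` is False
    for buffer-only blocks that participate in computation but are excluded
    from reporting and normalization.
    """

    block_id: str
    x: float
    y: float
    population: float
    supply: float = 0.0
    in_report_region: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.block_id, str) or not self.block_id:
            raise DataError("block_id must be a non-empty string")
        if self.population < 0:
            raise DataError(f"block {self.block_id}: population must be >= 0")
        if self.supply < 0:
            raise DataError(f"block {self.block_id}: supply must be >= 0")


@dataclass(frozen=True)
class ProviderSpeedRecord:
    """One ISP offering in one block: max advertised down/up speed in Mbps."""

    block_id: str
    provider_id: str
    download_mbps: float
    upload_mbps: float

    def __post_init__(self) -> None:
        if self.download_mbps < 0 or self.upload_mbps < 0:
            raise DataError(
                f"block {self.block_id} provider {self.provider_id}: "
                "speeds must be >= 0"
            )


@dataclass(frozen=True)
class BlockBroadband:
    """Aggregated per-block broadband speeds under one metric."""

    block_id: str
    download_mbps: float
    upload_mbps: float
    metric: SpeedMetric

    def __post_init__(self) -> None:
        if self.download_mbps < 0 or self.upload_mbps < 0:
            raise DataError(f"block {self.block_id}: aggregated speeds must be >= 0")


@dataclass(frozen=True)
class StepWeightSchedule:
    """Step-wise broadband weight function: weight ``weights[i]`` applies on
    the half-open bin [breaks[i-1], breaks[i]), with ``weights[0]`` on
    [0, breaks[0]) and ``weights[-1]`` on [breaks[-1], inf).

    Bins are closed on the left and open on the right; the top bin extends
    to infinity (published schedules print a large sentinel such as 9999.0
    for the upper bound).
    """

    breaks: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        breaks = tuple(float(b) for b in self.breaks)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "weights", weights)
        if len(weights) != len(breaks) + 1:
            raise DataError("schedule needs exactly one more weight than breaks")
        if not breaks:
            raise DataError("schedule needs at least one break")
        if breaks[0] <= 0:
            raise DataError("breaks must be > 0")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise DataError("breaks must be strictly increasing")
        if any(not (0.0 <= w <= 1.0) for w in weights):
            raise DataError("weights must lie in [0, 1]")


@dataclass(frozen=True)
class CatchmentSpec:
    """Travel-time catchment threshold d0 in minutes."""

    d0: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise DataError("catchment threshold d0 must be > 0")


@dataclass(frozen=True)
class DecayFunction:
    """Distance-decay weight on travel time, evaluated within a catchment.

    ``indicator`` is 1 for d <= d0, 0 beyond (the classic 2SFCA weight);
    ``gaussian`` is exp(-d^2 / (2 * bandwidth^2)) within the catchment.
    Values always lie in [0, 1].
    """

    kind: str = "indicator"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("indicator", "gaussian"):
            raise DataError(f"unknown decay kind: {self.kind!r}")
        if self.kind == "gaussian" and (self.bandwidth is None or self.bandwidth <= 0):
            raise DataError("gaussian decay requires bandwidth > 0")

    def __call__(self, minutes: float, d0: float) -> float:
        if minutes < 0:
            raise DataError("travel time must be >= 0")
        if minutes > d0:
            return 0.0
        if self.kind == "indicator":
            return 1.0
        return math.exp(-(minutes * minutes) / (2.0 * self.bandwidth * self.bandwidth))


class TravelTimeMatrix:
    """Sparse OD travel times in minutes, keyed (origin, destination).

    An absent pair means *unreachable* — it lies outside every catchment —
    and is distinguishable from a stored time of 0.
    """

    __slots__ = ("_times",)

    def __init__(
        self, times: Mapping[tuple[str, str], float] | None = None
    ) -> None:
        self._times: dict[tuple[str, str], float] = {}
        if times:
            for (o, d), t in times.items():
                self.set(o, d, t)

    def set(self, origin: str, destination: str, minutes: float) -> None:
        if minutes < 0:
            raise DataError(f"negative travel time for ({origin}, {destination})")
        if origin == destination and minutes != 0:
            raise DataError(f"self-pair ({origin}) must have time 0")
        self._times[(origin, destination)] = float(minutes)

    def get(self, origin: str, destination: str) -> float | None:
        """Return the time in minutes, or None when the pair is unreachable."""
        return self._times.get((origin, destination))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._times

    def __len__(self) -> int:
        return len(self._times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TravelTimeMatrix):
            return NotImplemented
        return self._times == other._times

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._times.items())


@dataclass
class RoadGraph:
    """Directed road graph: node coordinates and positive traversal minutes.

    Undirected edge lists are expanded to two arcs at construction.  The
    graph may be disconnected; unreachable pairs simply never enter the OD
    matrix.
    """

    nodes: dict[str, tuple[float, float]] = field(default_factory=dict)
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def add_node(self, node_id: str, x: float, y: float) -> None:
        self.nodes[node_id] = (float(x), float(y))

    def add_edge(
        self, u: str, v: str, minutes: float, oneway: bool = False
    ) -> None:
        if minutes <= 0:
            raise DataError(f"edge ({u}, {v}): traversal minutes must be > 0")
        self.edges.append((u, v, float(minutes)))
        if not oneway:
            self.edges.append((v, u, float(minutes)))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for node_id, (x, y) in self.nodes.items():
            g.add_node(node_id, x=x, y=y)
        for u, v, minutes in self.edges:
            # keep the cheapest arc when duplicates occur
            if g.has_edge(u, v):
                if minutes < g[u][v]["minutes"]:
                    g[u][v]["minutes"] = minutes
            else:
                g.add_edge(u, v, minutes=minutes)
        return g


@dataclass
class AccessibilityResult:
    """Per-block accessibility scores plus the intermediate supply ratios.

    ``scores`` maps demand block id to A_i (or VA_i for the virtual
    methods); ``ratios`` maps supply block id to R_j, retained for testing
    the conservation identity.  ``per_capita_factor`` records any scaling
    applied after computation (None means raw ratios of doctors per person).
    """

    method: str
    metric: SpeedMetric | None
    d0: float
    scores: dict[str, float]
    ratios: dict[str, float]
    per_capita_factor: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("2sfca", "2svca", "e2svca"):
            raise DataError(f"unknown method: {self.method!r}")
        if any(s < 0 for s in self.scores.values()):
            raise DataError("accessibility scores must be >= 0")
        if any(r < 0 for r in self.ratios.values()):
            raise DataError("supply-demand ratios must be >= 0")


@dataclass
class DifferenceResult:
    """Block-wise score difference between two methods.

    ``deltas`` holds score_A - score_B; ``classes`` labels each block
    under / equal / over by the sign of its delta; ``counts`` and
    ``populations`` aggregate block counts and population totals per class.
    """

    deltas: dict[str, float]
    classes: dict[str, str]
    counts: dict[str, int]
    populations: dict[str, float]


def validate_study_area(
    blocks: Iterable[Block],
    broadband: Iterable[ProviderSpeedRecord],
    od: TravelTimeMatrix,
) -> list[str]:
    """Check cross-references between blocks, broadband records and the OD
    matrix.  Returns a list of human-readable issues; empty means valid.
    """
    blocks = list(blocks)
    issues: list[str] = []
    seen: set[str] = set()
    for b in blocks:
        if b.block_id in seen:
            issues.append(f"duplicate id: block {b.block_id} appears more than once")
        seen.add(b.block_id)
    if not any(b.in_report_region for b in blocks):
        issues.append("no block has in_report_region = true")

    bb_blocks: set[str] = set()
    for rec in broadband:
        bb_blocks.add(rec.block_id)
        if rec.block_id not in seen:
            issues.append(
                f"orphan broadband record: provider {rec.provider_id} "
                f"references unknown block {rec.block_id}"
            )
    for blk in sorted(seen - bb_blocks):
        issues.append(f"block {blk} has no broadband record")

    for (o, d), _ in od.items():
        if o not in seen:
            issues.append(f"OD entry references unknown origin block {o}")
        if d not in seen:
            issues.append(f"OD entry references unknown destination block {d}")
    return issues
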