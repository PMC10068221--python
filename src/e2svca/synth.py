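"""Deterministic synthetic study areas for desk-scale runs.

Real inputs for this kind of analysis are census block geometries and
populations, doctor locations aggregated to blocks, FCC-style per-provider
broadband records, and a routed OD matrix — none of which can be bundled.
The generator emulates their structure on a lattice:

* a rows x cols grid of square blocks, the outer ``buffer_width`` ring
  flagged as buffer (in_report_region = False), mirroring the buffer zone
  a real study draws around its county to absorb edge effects;
* log-normal block populations (census block populations are strongly
  right-skewed);
* doctors clustered around a small number of centers with exponential
  spatial decay, emulating a downtown concentration of providers;
* per-block multi-provider speed mixtures spanning DSL through gigabit
  tiers, including a digital-divide component whose blocks have every
  offered speed below 0.6 Mbps — too slow for any video call;
* a lattice road graph with per-edge traversal minutes drawn uniformly
  from a configured range.

Everything is driven by one integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model import Block, DataError, ProviderSpeedRecord, RoadGraph

#: (download Mbps, upload Mbps, probability) tiers for ordinary providers,
#: spanning legacy DSL to gigabit fiber.  Probabilities sum to 1.
SPEED_TIERS: tuple[tuple[float, float, float], ...] = (
    (1.5, 0.6, 0.10),    # legacy ADSL
    (10.0, 1.0, 0.15),   # basic DSL/fixed wireless
    (25.0, 3.0, 0.25),   # entry cable
    (100.0, 10.0, 0.30), # mid cable
    (500.0, 35.0, 0.10), # high cable
    (1000.0, 1000.0, 0.10),  # fiber
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study area.

    Defaults give an 8x8 grid (block side ~1 travel-minute scale) with a
    one-block buffer ring, two doctor clusters, and a 5% digital-divide
    mixing probability.
    """

    rows: int = 8
    cols: int = 8
    seed: int = 0
    buffer_width: int = 1
    pop_log_mean: float = math.log(40.0)  # median ~40 people per block
    pop_log_sd: float = 1.0
    n_supply_clusters: int = 2
    cluster_intensity: float = 6.0  # expected doctors at a cluster center
    cluster_decay: float = 2.0      # e-folding distance in block widths
    providers_min: int = 1
    providers_max: int = 8
    divide_probability: float = 0.05  # P(block's best speed < 0.6 Mbps)
    edge_minutes_min: float = 1.0
    edge_minutes_max: float = 4.0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise DataError("grid must be at least 2x2")
        if not (0.0 <= self.divide_probability <= 1.0):
            raise DataError("divide_probability must lie in [0, 1]")
        if self.buffer_width < 0 or 2 * self.buffer_width >= min(self.rows, self.cols):
            raise DataError("buffer_width leaves no report region")
        if self.providers_min < 1 or self.providers_max < self.providers_min:
            raise DataError("invalid provider count range")
        if not (0 < self.edge_minutes_min <= self.edge_minutes_max):
            raise DataError("invalid edge-minutes range")
        if self.pop_log_sd < 0 or self.cluster_intensity < 0 or self.cluster_decay <= 0:
            raise DataError("invalid population/supply model parameters")


class StudyArea(NamedTuple):
    blocks: list[Block]
    records: list[ProviderSpeedRecord]
    graph: RoadGraph
    notes: dict


def _block_id(r: int, c: int) -> str:
    # fixed-width, zero-padded: exercises the leading-zero contract
    return f"{r:03d}{c:03d}"


def generate(config: ScenarioConfig = ScenarioConfig()) -> StudyArea:
    """Generate one reproducible study area from ``config``.

    When ``divide_probability`` is positive, at least one report-region
    block is guaranteed to come from the digital-divide mixture so that
    the step-wise weight's zero bin is always exercised.
    """
    rng = np.random.default_rng(config.seed)
    R, C, bw = config.rows, config.cols, config.buffer_width

    def in_region(r: int, c: int) -> bool:
        return bw <= r < R - bw and bw <= c < C - bw

    # doctor cluster centers: report-region cells, drawn once
    region_cells = [(r, c) for r in range(R) for c in range(C) if in_region(r, c)]
    k = min(config.n_supply_clusters, len(region_cells))
    centers = [region_cells[i] for i in rng.choice(len(region_cells), size=k, replace=False)]

    blocks: list[Block] = []
    for r in range(R):
        for c in range(C):
            pop = int(round(float(rng.lognormal(config.pop_log_mean, config.pop_log_sd))))
            lam = sum(
                config.cluster_intensity
                * math.exp(-math.hypot(r - cr, c - cc) / config.cluster_decay)
                for cr, cc in centers
            )
            supply = int(rng.poisson(lam)) if lam > 0 else 0
            blocks.append(
                Block(
                    block_id=_block_id(r, c),
                    x=float(c),
                    y=float(r),
                    population=pop,
                    supply=supply,
                    in_report_region=in_region(r, c),
                )
            )

    # broadband: block-level digital-divide event, else per-provider tiers
    tier_p = np.array([t[2] for t in SPEED_TIERS])
    records: list[ProviderSpeedRecord] = []
    divide_blocks: list[str] = []
    for b in blocks:
        n_prov = int(rng.integers(config.providers_min, config.providers_max + 1))
        is_divide = bool(rng.random() < config.divide_probability)
        if is_divide:
            divide_blocks.append(b.block_id)
        for p in range(n_prov):
            if is_divide:
                down = float(rng.uniform(0.05, 0.55))
                up = float(rng.uniform(0.05, min(down, 0.55)))
            else:
                tier = SPEED_TIERS[int(rng.choice(len(SPEED_TIERS), p=tier_p))]
                down, up = tier[0], tier[1]
            records.append(
                ProviderSpeedRecord(
                    block_id=b.block_id,
                    provider_id=f"isp{p:02d}",
                    download_mbps=down,
                    upload_mbps=up,
                )
            )
    if config.divide_probability > 0 and not divide_blocks:
        # guarantee the zero bin is exercised: rewrite one report block
        target = region_cells[int(rng.integers(len(region_cells)))]
        tid = _block_id(*target)
        records = [rec for rec in records if rec.block_id != tid]
        down = float(rng.uniform(0.05, 0.55))
        records.append(
            ProviderSpeedRecord(
                block_id=tid, provider_id="isp00",
                download_mbps=down, upload_mbps=float(rng.uniform(0.05, min(down, 0.55))),
            )
        )
        divide_blocks.append(tid)

    # lattice road graph: one node per centroid, 4-neighbour links
    graph = RoadGraph()
    for b in blocks:
        graph.add_node(f"n{b.block_id}", b.x, b.y)
    for r in range(R):
        for c in range(C):
            if c + 1 < C:
                graph.add_edge(
                    f"n{_block_id(r, c)}", f"n{_block_id(r, c + 1)}",
                    float(rng.uniform(config.edge_minutes_min, config.edge_minutes_max)),
                )
            if r + 1 < R:
                graph.add_edge(
                    f"n{_block_id(r, c)}", f"n{_block_id(r + 1, c)}",
                    float(rng.uniform(config.edge_minutes_min, config.edge_minutes_max)),
                )

    notes = {
        "cluster_centers": [_block_id(*c) for c in centers],
        "digital_divide_blocks": sorted(divide_blocks),
        "n_report_blocks": sum(1 for b in blocks if b.in_report_region),
        "n_buffer_blocks": sum(1 for b in blocks if not b.in_report_region),
        "total_population": sum(b.population for b in blocks),
        "total_supply": sum(b.supply for b in blocks),
    }
    return StudyArea(blocks=blocks, records=records, graph=graph, notes=notes)


#: The two per-block speed lists used by the worked micro-examples: ten
#: download offerings whose modal set is {25, 1000}, and ten upload
#: offerings whose mean is 126.78 Mbps.
EXAMPLE_DOWNLOADS = (2.0, 3.0, 18.0, 25.0, 25.0, 35.0, 100.0, 500.0, 1000.0, 1000.0)
EXAMPLE_UPLOADS = (0.5, 1.3, 2.0, 3.0, 3.0, 3.0, 20.0, 35.0, 200.0, 1000.0)


def worked_example_fixture() -> StudyArea:
    """Two-block study area carrying the worked micro-example speed lists.

    Block 170310102011004 carries the ten-value download list (modal set
    {25, 1000}); block 170318391002021 carries the ten-value upload list
    (mean 126.78).  The opposite direction of each record mirrors the
    listed value so that per-direction aggregation is well defined.
    """
    b1, b2 = "170310102011004", "170318391002021"
    blocks = [
        Block(block_id=b1, x=0.0, y=0.0, population=100, supply=1),
        Block(block_id=b2, x=1.0, y=0.0, population=100, supply=0),
    ]
    records = [
        ProviderSpeedRecord(b1, f"isp{i:02d}", v, v)
        for i, v in enumerate(EXAMPLE_DOWNLOADS)
    ] + [
        ProviderSpeedRecord(b2, f"isp{i:02d}", v, v)
        for i, v in enumerate(EXAMPLE_UPLOADS)
    ]
    graph = RoadGraph()
    graph.add_node("a", 0.0, 0.0)
    graph.add_node("b", 1.0, 0.0)
    graph.add_edge("a", "b", 5.0)
    notes = {"example_blocks": [b1, b2]}
    return StudyArea(blocks=blocks, records=records, graph=graph, notes=notes)
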