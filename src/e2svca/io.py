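"""Readers and writers for the file dialects the pipeline touches.

All files are UTF-8 CSV with a mandatory header row, except the schedule
and scenario configs (JSON) and the results export (GeoJSON points).
Block ids are always read as strings so leading zeros survive round trips.
Readers reject malformed required fields rather than coercing them.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AccessibilityResult,
    Block,
    DataError,
    DifferenceResult,
    ProviderSpeedRecord,
    RoadGraph,
    SpeedMetric,
    StepWeightSchedule,
    TravelTimeMatrix,
)

_FCC477_COLUMNS = {
    "BlockCode": "block_id",
    "Provider_Id": "provider_id",
    "MaxAdDown": "download_mbps",
    "MaxAdUp": "upload_mbps",
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing column: {col}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    parsed = pd.to_numeric(df[col], errors="coerce")
    bad = parsed.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        row = int(bad.idxmax())
        raise DataError(f"{path}: non-numeric {col} in row {row}")
    return parsed


def read_blocks(path) -> list[Block]:
    """Read a block table: block_id, x, y, population, supply, and an
    optional in_report_region column (default true)."""
    df = pd.read_csv(path, dtype={"block_id": str})
    _require_columns(df, ["block_id", "x", "y", "population", "supply"], path)
    pop = _numeric(df, "population", path)
    sup = _numeric(df, "supply", path)
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    if "in_report_region" in df.columns:
        region = df["in_report_region"].astype(str).str.strip().str.lower().isin(
            ("true", "1", "yes", "t")
        )
    else:
        region = pd.Series(True, index=df.index)
    blocks = []
    for i in range(len(df)):
        blocks.append(
            Block(
                block_id=str(df["block_id"].iloc[i]),
                x=float(x.iloc[i]),
                y=float(y.iloc[i]),
                population=float(pop.iloc[i]),
                supply=float(sup.iloc[i]),
                in_report_region=bool(region.iloc[i]),
            )
        )
    return blocks


def write_blocks(blocks: Iterable[Block], path) -> None:
    pd.DataFrame([asdict(b) for b in blocks]).to_csv(path, index=False)


def read_broadband(path, dialect: str = "generic") -> list[ProviderSpeedRecord]:
    """Read per-provider speed records.

    ``generic`` expects columns block_id, provider_id, download_mbps,
    upload_mbps; ``fcc477`` maps the Form 477 fixed-broadband deployment
    headers (BlockCode, Provider_Id, MaxAdDown, MaxAdUp) onto them.
    """
    if dialect not in ("generic", "fcc477"):
        raise DataError(f"unknown broadband dialect: {dialect!r}")
    id_col = "BlockCode" if dialect == "fcc477" else "block_id"
    df = pd.read_csv(path, dtype={id_col: str})
    if dialect == "fcc477":
        _require_columns(df, list(_FCC477_COLUMNS), path)
        df = df.rename(columns=_FCC477_COLUMNS)
    _require_columns(df, ["block_id", "provider_id", "download_mbps", "upload_mbps"], path)
    down = _numeric(df, "download_mbps", path)
    up = _numeric(df, "upload_mbps", path)
    records = []
    for i in range(len(df)):
        if down.iloc[i] < 0 or up.iloc[i] < 0:
            raise DataError(f"{path}: negative speed in row {i}")
        records.append(
            ProviderSpeedRecord(
                block_id=str(df["block_id"].iloc[i]),
                provider_id=str(df["provider_id"].iloc[i]),
                download_mbps=float(down.iloc[i]),
                upload_mbps=float(up.iloc[i]),
            )
        )
    return records


def write_broadband(records: Iterable[ProviderSpeedRecord], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_od(path) -> TravelTimeMatrix:
    """Read a long-format sparse OD file (origin, destination, minutes).
    Absent pairs mean unreachable; duplicates are an error."""
    df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    _require_columns(df, ["origin", "destination", "minutes"], path)
    minutes = _numeric(df, "minutes", path)
    od = TravelTimeMatrix()
    for i in range(len(df)):
        o, d = str(df["origin"].iloc[i]), str(df["destination"].iloc[i])
        if (o, d) in od:
            raise DataError(f"{path}: duplicate OD pair ({o}, {d}) in row {i}")
        t = float(minutes.iloc[i])
        if t < 0:
            raise DataError(f"{path}: negative minutes in row {i}")
        od.set(o, d, t)
    return od


def write_od(od: TravelTimeMatrix, path) -> None:
    rows = [
        {"origin": o, "destination": d, "minutes": t} for (o, d), t in od.items()
    ]
    pd.DataFrame(rows, columns=["origin", "destination", "minutes"]).to_csv(
        path, index=False
    )


def read_road_graph(nodes_path, edges_path) -> RoadGraph:
    """Read a road graph from node (node_id, x, y) and edge
    (from_node, to_node, minutes[, oneway]) CSVs."""
    nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
    _require_columns(nodes, ["node_id", "x", "y"], nodes_path)
    edges = pd.read_csv(edges_path, dtype={"from_node": str, "to_node": str})
    _require_columns(edges, ["from_node", "to_node", "minutes"], edges_path)
    g = RoadGraph()
    for i in range(len(nodes)):
        g.add_node(
            str(nodes["node_id"].iloc[i]),
            float(nodes["x"].iloc[i]),
            float(nodes["y"].iloc[i]),
        )
    minutes = _numeric(edges, "minutes", edges_path)
    oneway = (
        edges["oneway"].astype(str).str.strip().str.lower().isin(("true", "1", "yes", "t"))
        if "oneway" in edges.columns
        else pd.Series(False, index=edges.index)
    )
    for i in range(len(edges)):
        g.add_edge(
            str(edges["from_node"].iloc[i]),
            str(edges["to_node"].iloc[i]),
            float(minutes.iloc[i]),
            oneway=bool(oneway.iloc[i]),
        )
    return g


def write_road_graph(graph: RoadGraph, nodes_path, edges_path) -> None:
    pd.DataFrame(
        [{"node_id": n, "x": x, "y": y} for n, (x, y) in graph.nodes.items()]
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [
            {"from_node": u, "to_node": v, "minutes": t, "oneway": True}
            for u, v, t in graph.edges
        ],
        columns=["from_node", "to_node", "minutes", "oneway"],
    ).to_csv(edges_path, index=False)


def read_schedule(path) -> StepWeightSchedule:
    """Read a step-weight schedule config: {"breaks": [...], "weights": [...]}."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if "breaks" not in cfg or "weights" not in cfg:
        raise DataError(f"{path}: schedule config needs 'breaks' and 'weights'")
    return StepWeightSchedule(breaks=tuple(cfg["breaks"]), weights=tuple(cfg["weights"]))


def write_schedule(schedule: StepWeightSchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"breaks": list(schedule.breaks), "weights": list(schedule.weights)}, fh)


def write_results(
    result: AccessibilityResult,
    path,
    normalized: dict[str, float] | None = None,
    classes: dict[str, str] | None = None,
) -> None:
    """Write per-block scores with the result's method metadata as constant
    columns, so comparisons between result files stay checkable."""
    rows = []
    for blk in sorted(result.scores):
        rows.append(
            {
                "block_id": blk,
                "score": repr(result.scores[blk]),
                "normalized_score": (
                    repr(normalized[blk]) if normalized and blk in normalized else ""
                ),
                "class_label": classes.get(blk, "") if classes else "",
                "method": result.method,
                "metric": str(result.metric) if result.metric else "",
                "d0": result.d0,
                "per_capita_factor": (
                    result.per_capita_factor if result.per_capita_factor is not None else ""
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "block_id", "score", "normalized_score", "class_label",
            "method", "metric", "d0", "per_capita_factor",
        ],
    ).to_csv(path, index=False)


def read_results(path) -> AccessibilityResult:
    """Reconstruct an :class:`AccessibilityResult` (scores and metadata
    only; intermediate ratios are not serialized)."""
    df = pd.read_csv(path, dtype={"block_id": str}, float_precision="round_trip")
    _require_columns(df, ["block_id", "score", "method", "d0"], path)
    scores = {
        str(df["block_id"].iloc[i]): float(df["score"].iloc[i]) for i in range(len(df))
    }
    metric = df["metric"].iloc[0] if "metric" in df.columns and len(df) else None
    pcf = None
    if "per_capita_factor" in df.columns and len(df):
        raw = df["per_capita_factor"].iloc[0]
        pcf = float(raw) if pd.notna(raw) else None
    return AccessibilityResult(
        method=str(df["method"].iloc[0]),
        metric=SpeedMetric(metric) if isinstance(metric, str) and metric else None,
        d0=float(df["d0"].iloc[0]),
        scores=scores,
        ratios={},
        per_capita_factor=pcf,
    )


def write_difference(diff: DifferenceResult, path) -> None:
    rows = [
        {"block_id": blk, "delta": repr(diff.deltas[blk]), "diff_class": diff.classes[blk]}
        for blk in sorted(diff.deltas)
    ]
    pd.DataFrame(rows, columns=["block_id", "delta", "diff_class"]).to_csv(
        path, index=False
    )


def write_summary(rows: list[dict], path) -> None:
    """Write one summary row per method/metric (mean, std, min, max, count)."""
    pd.DataFrame(
        rows, columns=["method", "metric", "mean", "std", "min", "max", "count"]
    ).to_csv(path, index=False)


def write_geojson(
    result: AccessibilityResult,
    blocks: Iterable[Block],
    path,
    normalized: dict[str, float] | None = None,
) -> None:
    """Export scores as a GeoJSON FeatureCollection of centroid points."""
    features = []
    for b in sorted(blocks, key=lambda b: b.block_id):
        if b.block_id not in result.scores:
            continue
        props = {
            "block_id": b.block_id,
            "score": result.scores[b.block_id],
            "population": b.population,
            "supply": b.supply,
            "in_report_region": b.in_report_region,
        }
        if normalized and b.block_id in normalized:
            props["normalized_score"] = normalized[b.block_id]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [b.x, b.y]},
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
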