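"""Two-step accessibility engines against hand computations and the
independent triple-loop reference implementation."""

from __future__ import annotations

import numpy as np
import pytest

from e2svca.broadband import ZOOM_SCHEDULE, aggregate_all
from e2svca.fca import (
    accessibility_step,
    compute,
    pair_weights,
    supply_demand_ratios,
)
from e2svca.model import (
    Block,
    CatchmentSpec,
    DataError,
    ProviderSpeedRecord,
    SpeedMetric,
    TravelTimeMatrix,
)

from ._reference import ref_accessibility
from .conftest import random_fixture

METHODS = ("2sfca", "2svca", "e2svca")
METRICS = ("avg", "min_a", "min_f", "max_f")


def _fast_records(block_ids, mbps=100.0):
    return [ProviderSpeedRecord(b, "p1", mbps, mbps) for b in block_ids]


class TestPairWeights:
    def _setup(self):
        blocks = [Block("d1", 0, 0, 100, supply=0), Block("s1", 1, 0, 0, supply=1)]
        od = TravelTimeMatrix({("d1", "s1"): 10.0, ("s1", "d1"): 10.0,
                               ("d1", "d1"): 0.0, ("s1", "s1"): 0.0})
        return blocks, od

    def test_pair_outside_catchment_absent(self):
        blocks, _ = self._setup()
        od = TravelTimeMatrix({("d1", "s1"): 31.0})
        w = pair_weights(blocks, od, CatchmentSpec(30), "distance_only")
        assert ("d1", "s1") not in w

    def test_fast_pair_gets_full_weight(self):
        blocks, od = self._setup()
        bb = aggregate_all(_fast_records(["d1", "s1"], 3.0), SpeedMetric.MIN_F)
        w = pair_weights(blocks, od, CatchmentSpec(30), "stepwise_broadband",
                         bb=bb, schedule=ZOOM_SCHEDULE)
        assert w[("d1", "s1")] == 1.0

    def test_sub_minimum_speed_present_but_zero(self):
        blocks, od = self._setup()
        bb = aggregate_all(
            _fast_records(["s1"], 100.0) + _fast_records(["d1"], 0.4),
            SpeedMetric.MIN_F,
        )
        w = pair_weights(blocks, od, CatchmentSpec(30), "stepwise_broadband",
                         bb=bb, schedule=ZOOM_SCHEDULE)
        assert w[("d1", "s1")] == 0.0

    def test_block_without_aggregate_gets_zero(self):
        blocks, od = self._setup()
        bb = aggregate_all(_fast_records(["s1"]), SpeedMetric.MIN_F)
        w = pair_weights(blocks, od, CatchmentSpec(30), "stepwise_broadband",
                         bb=bb, schedule=ZOOM_SCHEDULE)
        assert w[("d1", "s1")] == 0.0

    def test_missing_schedule_rejected(self):
        blocks, od = self._setup()
        with pytest.raises(DataError, match="schedule"):
            pair_weights(blocks, od, CatchmentSpec(30), "stepwise_broadband",
                         bb=[])


class TestTwoSteps:
    def test_single_demand_ratio(self):
        blocks = [Block("d", 0, 0, 1000), Block("s", 1, 0, 0, supply=2)]
        r = supply_demand_ratios(blocks, {("d", "s"): 1.0})
        assert r == {"s": 0.002}

    def test_weighted_two_demand_fixture(self):
        """S=1 against demands 100 (w=1) and 100 (w=0.33): R = 1/133, and
        each demand scores R times its own weight."""
        blocks = [
            Block("d1", 0, 0, 100),
            Block("d2", 1, 0, 100),
            Block("s", 2, 0, 0, supply=1),
        ]
        w = {("d1", "s"): 1.0, ("d2", "s"): 0.33}
        r = supply_demand_ratios(blocks, w)
        assert r["s"] == pytest.approx(1 / 133, rel=1e-12)
        scores = accessibility_step(blocks, w, r)
        assert scores["d1"] == pytest.approx(0.0075188, abs=5e-8)
        assert scores["d2"] == pytest.approx(0.0024812, abs=5e-8)

    def test_unreachable_supply_ratio_zero(self):
        blocks = [Block("d", 0, 0, 100), Block("s", 1, 0, 0, supply=3)]
        assert supply_demand_ratios(blocks, {}) == {"s": 0.0}

    def test_demand_with_no_supply_scores_zero(self):
        blocks = [Block("d", 0, 0, 100), Block("s", 1, 0, 0, supply=1)]
        scores = accessibility_step(blocks, {}, {"s": 0.0})
        assert scores["d"] == 0.0


class TestCompute:
    def test_colocated_supply_and_demand(self):
        blocks = [Block("b", 0, 0, 1000, supply=2)]
        od = TravelTimeMatrix({("b", "b"): 0.0})
        res = compute(blocks, od, CatchmentSpec(30), "2sfca")
        assert res.scores["b"] == pytest.approx(0.002, rel=1e-12)

    def test_saturated_speeds_collapse_to_2sfca(self):
        """When every block's four speeds are at the top tier the step-wise
        and binary weights are all 1, so all three methods coincide."""
        rng = np.random.default_rng(5)
        blocks, _, od = random_fixture(rng, n_blocks=10)
        records = _fast_records([b.block_id for b in blocks], 50.0)
        cs = CatchmentSpec(30)
        base = compute(blocks, od, cs, "2sfca")
        for method, metric in (("2svca", None), ("e2svca", "min_f"),
                               ("e2svca", "min_a"), ("e2svca", "max_f")):
            res = compute(blocks, od, cs, method, metric=metric, records=records)
            assert res.scores == base.scores

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_reference(self, method, seed):
        rng = np.random.default_rng(seed)
        blocks, records, od = random_fixture(rng, n_blocks=int(rng.integers(5, 21)))
        metric = "min_f" if method == "e2svca" else None
        res = compute(blocks, od, CatchmentSpec(30), method, metric=metric,
                      records=records)
        expected = ref_accessibility(blocks, od, 30, method, metric=metric,
                                     records=records)
        for blk, a in expected.items():
            assert res.scores[blk] == pytest.approx(a, abs=1e-12)

    def test_missing_inputs_rejected(self):
        blocks = [Block("b", 0, 0, 10, supply=1)]
        od = TravelTimeMatrix()
        with pytest.raises(DataError):
            compute(blocks, od, CatchmentSpec(30), "e2svca", metric="min_f")
        with pytest.raises(DataError):
            compute(blocks, od, CatchmentSpec(30), "e2svca", records=[])
        with pytest.raises(DataError):
            compute(blocks, od, CatchmentSpec(30), "2svca")


class TestEngineInvariants:
    @pytest.mark.parametrize("method,metric",
                             [("2sfca", None), ("2svca", None)]
                             + [("e2svca", m) for m in METRICS])
    def test_conservation(self, method, metric):
        """Total population-weighted accessibility equals total supply at
        blocks with positive weighted demand — both steps share weights."""
        for seed in range(5):
            blocks, records, od = random_fixture(
                np.random.default_rng(seed), n_blocks=15
            )
            res = compute(blocks, od, CatchmentSpec(30), method, metric=metric,
                          records=records)
            lhs = sum(b.population * res.scores[b.block_id] for b in blocks)
            rhs = sum(b.supply for b in blocks if res.ratios.get(b.block_id, 0) > 0)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_supply_and_demand_linearity(self, small_fixture):
        blocks, records, od = small_fixture
        cs = CatchmentSpec(30)
        base = compute(blocks, od, cs, "e2svca", metric="min_f", records=records)
        scaled_supply = [
            Block(b.block_id, b.x, b.y, b.population, b.supply * 3.0,
                  b.in_report_region)
            for b in blocks
        ]
        res_s = compute(scaled_supply, od, cs, "e2svca", metric="min_f",
                        records=records)
        scaled_demand = [
            Block(b.block_id, b.x, b.y, b.population * 2.0, b.supply,
                  b.in_report_region)
            for b in blocks
        ]
        res_d = compute(scaled_demand, od, cs, "e2svca", metric="min_f",
                        records=records)
        for blk in base.scores:
            assert res_s.scores[blk] == pytest.approx(3.0 * base.scores[blk], rel=1e-12)
            assert res_d.scores[blk] == pytest.approx(0.5 * base.scores[blk], rel=1e-12)

    def test_zero_population_blocks_change_nothing(self, small_fixture):
        blocks, records, od = small_fixture
        cs = CatchmentSpec(30)
        base = compute(blocks, od, cs, "2sfca")
        extra = blocks + [Block("zzz", 5, 5, 0)]
        od2 = TravelTimeMatrix(dict(od.items()))
        for b in blocks:
            od2.set("zzz", b.block_id, 1.0)
            od2.set(b.block_id, "zzz", 1.0)
        od2.set("zzz", "zzz", 0.0)
        res = compute(extra, od2, cs, "2sfca")
        for blk in base.scores:
            assert res.scores[blk] == base.scores[blk]

    def test_zero_broadband_demand_changes_nothing(self, small_fixture):
        """A demand block whose best speed is below the lowest video tier
        exerts no competition in the step-wise model."""
        blocks, records, od = small_fixture
        cs = CatchmentSpec(30)
        base = compute(blocks, od, cs, "e2svca", metric="min_f", records=records)
        extra = blocks + [Block("zzz", 5, 5, 500)]
        records2 = records + [ProviderSpeedRecord("zzz", "p1", 0.3, 0.2)]
        od2 = TravelTimeMatrix(dict(od.items()))
        for b in blocks:
            od2.set("zzz", b.block_id, 1.0)
            od2.set(b.block_id, "zzz", 1.0)
        od2.set("zzz", "zzz", 0.0)
        res = compute(extra, od2, cs, "e2svca", metric="min_f", records=records2)
        for blk in base.scores:
            assert res.scores[blk] == base.scores[blk]

    def test_metric_dominance_on_totals(self):
        """Supplies reachable by weighted demand under min_a are a subset of
        those under max_f, so the conserved totals are ordered."""
        for seed in range(5):
            blocks, records, od = random_fixture(
                np.random.default_rng(100 + seed), n_blocks=15
            )
            totals = {}
            for metric in ("min_a", "max_f"):
                res = compute(blocks, od, CatchmentSpec(30), "e2svca",
                              metric=metric, records=records)
                totals[metric] = sum(
                    b.population * res.scores[b.block_id] for b in blocks
                )
            assert totals["min_a"] <= totals["max_f"] + 1e-9
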