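from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from e2svca.model import Block, ProviderSpeedRecord, TravelTimeMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_fixture(rng: np.random.Generator, n_blocks: int = 15):
    """Random study area built directly (no road graph): blocks with skewed
    populations and sparse supply, multi-provider speed records spanning
    the digital-divide through gigabit range, and a random sparse OD matrix
    with ~30% unreachable pairs."""
    blocks = []
    for i in range(n_blocks):
        blocks.append(
            Block(
                block_id=f"{i:05d}",
                x=float(rng.uniform(0, 10)),
                y=float(rng.uniform(0, 10)),
                population=int(rng.integers(0, 500)),
                supply=int(rng.integers(0, 4)) if rng.random() < 0.4 else 0,
                in_report_region=bool(rng.random() < 0.8),
            )
        )
    records = []
    for b in blocks:
        for p in range(int(rng.integers(1, 5))):
            down = float(rng.choice([0.3, 0.9, 1.5, 5.0, 25.0, 100.0, 1000.0]))
            up = float(rng.choice([0.1, 0.7, 1.3, 3.0, 10.0, 35.0, 1000.0]))
            records.append(
                ProviderSpeedRecord(b.block_id, f"p{p}", down, up)
            )
    od = TravelTimeMatrix()
    for a in blocks:
        for b in blocks:
            if a.block_id == b.block_id:
                od.set(a.block_id, b.block_id, 0.0)
            elif rng.random() < 0.7:
                od.set(a.block_id, b.block_id, float(rng.uniform(0, 60)))
    return blocks, records, od


@pytest.fixture
def small_fixture():
    return random_fixture(np.random.default_rng(42), n_blocks=12)
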