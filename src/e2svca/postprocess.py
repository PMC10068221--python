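"""Scaling, normalization, classification and comparison of accessibility
results.

All reporting operations restrict to ``in_report_region`` blocks by
default: buffer blocks exist to absorb edge effects during computation and
would distort minima, maxima and summary statistics if reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Sequence

from .model import (
    AccessibilityResult,
    Block,
    DataError,
    DifferenceResult,
)

#: Raw-score class boundaries (doctors per 1,000 population): very poor,
#: low, middle, better, high.
RAW_BREAKS = (0.0, 2.00, 3.00, 4.00, 5.00, 8.00)
#: Quintile boundaries for min-max normalized scores.
NORMALIZED_BREAKS = (0.0, 0.20, 0.40, 0.60, 0.80, 1.00)

DIFF_CLASSES = ("under", "equal", "over")


def per_capita_scale(
    result: AccessibilityResult, factor: float = 1000.0
) -> AccessibilityResult:
    """Scale every score by ``factor`` (default: per 1,000 population).

    Successive applications compose multiplicatively and the combined
    factor is recorded on the result.
    """
    if factor <= 0:
        raise DataError("per-capita factor must be > 0")
    prev = result.per_capita_factor if result.per_capita_factor is not None else 1.0
    return replace(
        result,
        scores={blk: s * factor for blk, s in result.scores.items()},
        per_capita_factor=prev * factor,
    )


def _in_scope(
    result: AccessibilityResult, blocks: Sequence[Block], region_only: bool
) -> list[str]:
    region = {b.block_id for b in blocks if b.in_report_region or not region_only}
    return [blk for blk in result.scores if blk in region]


def min_max_normalize(
    result: AccessibilityResult,
    blocks: Sequence[Block],
    region_only: bool = True,
) -> dict[str, float]:
    """Min-max normalize scores to [0, 1] over the reporting scope.

    The minimum and maximum are taken over report-region blocks when
    ``region_only`` (the default) and the transform is applied to those
    blocks only.  A degenerate scope where max equals min yields all zeros
    with a warning.
    """
    scope = _in_scope(result, blocks, region_only)
    if not scope:
        raise DataError("no blocks in normalization scope")
    vals = [result.scores[blk] for blk in scope]
    lo, hi = min(vals), max(vals)
    if hi == lo:
        warnings.warn("all scores equal; normalized scores set to 0", stacklevel=2)
        return {blk: 0.0 for blk in scope}
    span = hi - lo
    return {blk: (result.scores[blk] - lo) / span for blk in scope}


def class_labels(breaks: Sequence[float]) -> list[str]:
    """Human-readable labels, one per class interval."""
    return [f"{lo:g}–{hi:g}" for lo, hi in zip(breaks, breaks[1:])]


def classify(
    scores: dict[str, float], breaks: Sequence[float] = RAW_BREAKS
) -> dict[str, str]:
    """Assign each score to a half-open class [b_i, b_{i+1}); the top class
    is closed at its upper bound.  A score outside the covered range raises
    an error naming the offending block."""
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise DataError("class breaks must be strictly increasing")
    labels = class_labels(breaks)
    out: dict[str, str] = {}
    for blk, s in scores.items():
        if s < breaks[0] or s > breaks[-1]:
            raise DataError(
                f"score {s} of block {blk} lies outside the class range "
                f"[{breaks[0]}, {breaks[-1]}]"
            )
        if s == breaks[-1]:  # top class closed above
            out[blk] = labels[-1]
            continue
        for lo, hi, lab in zip(breaks, breaks[1:], labels):
            if lo <= s < hi:
                out[blk] = lab
                break
    return out


def difference(
    result_a: AccessibilityResult,
    result_b: AccessibilityResult,
    blocks: Sequence[Block],
    zero_tol: float = 0.0,
    region_only: bool = True,
) -> DifferenceResult:
    """Block-wise difference ``result_a - result_b`` with sign classes.

    Both results must cover the same block set at the same catchment size
    and per-capita scaling.  Each compared block is classed ``under``
    (delta < -zero_tol), ``equal`` (|delta| <= zero_tol) or ``over``
    (delta > zero_tol); counts and population totals are aggregated per
    class.  Identical pipelines produce bit-identical scores, hence the
    exact-zero default tolerance.
    """
    if set(result_a.scores) != set(result_b.scores):
        raise DataError("results cover different block sets")
    if result_a.d0 != result_b.d0:
        raise DataError("results use different catchment sizes")
    if result_a.per_capita_factor != result_b.per_capita_factor:
        raise DataError("results use different per-capita scaling")

    scope = set(_in_scope(result_a, blocks, region_only))
    pop = {b.block_id: b.population for b in blocks}
    deltas: dict[str, float] = {}
    classes: dict[str, str] = {}
    counts = {c: 0 for c in DIFF_CLASSES}
    pops = {c: 0.0 for c in DIFF_CLASSES}
    for blk in result_a.scores:
        if blk not in scope:
            continue
        d = result_a.scores[blk] - result_b.scores[blk]
        if abs(d) <= zero_tol:
            cls = "equal"
        elif d < 0:
            cls = "under"
        else:
            cls = "over"
        deltas[blk] = d
        classes[blk] = cls
        counts[cls] += 1
        pops[cls] += pop.get(blk, 0.0)
    return DifferenceResult(deltas=deltas, classes=classes, counts=counts, populations=pops)


def summarize(
    result: AccessibilityResult,
    blocks: Sequence[Block],
    region_only: bool = True,
    sample_std: bool = False,
) -> dict[str, float]:
    """Summary statistics {mean, std, min, max, count} over the reporting
    scope.  ``std`` is the population standard deviation unless
    ``sample_std`` is set."""
    scope = _in_scope(result, blocks, region_only)
    if not scope:
        raise DataError("no blocks in summary scope")
    vals = [result.scores[blk] for blk in scope]
    n = len(vals)
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    if sample_std:
        std = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    else:
        std = math.sqrt(ss / n)
    return {
        "mean": mean,
        "std": std,
        "min": min(vals),
        "max": max(vals),
        "count": float(n),
    }
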