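"""Benchmarking called origins against planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .mapping import OriginCall
from .simulate import OriginSpec


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float        # fraction of planted firing origins recovered
    false_call_rate: float    # fraction of calls with no planted origin nearby
    class_accuracy: float     # class agreement among matched planted origins
    n_truth_firing: int
    n_calls: int
    n_matched: int


def match_origins(
    calls: Sequence[OriginCall],
    truth: Sequence[OriginSpec],
    tolerance: int = 2_000,
) -> RecoveryReport:
    """Score retained origin calls against the planted origin set.

    Sensitivity counts planted firing (early/late) origins with a call
    within ``tolerance`` bp. A call is false when no planted origin of any
    class lies within the tolerance. Class accuracy is measured over all
    planted origins matched by at least one call, using the nearest call's
    class.
    """
    def nearest(chrom: str, pos: int):
        best, dist = None, None
        for c in calls:
            if c.chrom != chrom:
                continue
            d = abs(c.pos - pos)
            if dist is None or d < dist:
                best, dist = c, d
        return best, dist

    firing = [o for o in truth if o.cls in ("early", "late")]
    hit_firing = 0
    for o in firing:
        _, d = nearest(o.chrom, o.pos)
        if d is not None and d <= tolerance:
            hit_firing += 1

    false_calls = 0
    for c in calls:
        if not any(o.chrom == c.chrom and abs(o.pos - c.pos) <= tolerance for o in truth):
            false_calls += 1

    matched = 0
    agree = 0
    for o in truth:
        call, d = nearest(o.chrom, o.pos)
        if d is not None and d <= tolerance:
            matched += 1
            if call.cls == o.cls:
                agree += 1

    return RecoveryReport(
        sensitivity=hit_firing / len(firing) if firing else 0.0,
        false_call_rate=false_calls / len(calls) if calls else 0.0,
        class_accuracy=agree / matched if matched else 0.0,
        n_truth_firing=len(firing),
        n_calls=len(calls),
        n_matched=matched,
    )
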