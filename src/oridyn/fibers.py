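"""DNA-combing quantification: fork speed, symmetry, and restart statistics.

Combed DNA molecules carry stretches of CldU and IdU incorporation whose
lengths report on replication fork movement during the two labeling
pulses. The speed protocol (HU sync, CldU, IdU) yields origin-centered
structures — a central CldU segment flanked by bidirectional IdU tracks —
from which per-flank fork speeds and fork (a)symmetry are measured. The
restart protocol (CldU, HU, IdU) yields single forks whose IdU length
reports on the ability to restart after HU-induced arrest.

Lengths are in kb after conversion from micrometers (combing stretches
DNA at a constant factor; the conventional dual scale bar equates 10 um
with 20 kb, i.e. 2 kb/um).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

KB_PER_UM = 2.0


@dataclass(frozen=True)
class Fiber:
    """A combed DNA molecule: labeled segments (label, start, end) on one axis."""

    fiber_id: str
    segments: tuple[tuple[str, float, float], ...]
    units: Literal["um", "kb"] = "kb"

    def __init__(self, fiber_id: str, segments, units: str = "kb") -> None:
        object.__setattr__(self, "fiber_id", fiber_id)
        object.__setattr__(self, "segments", tuple((str(l), float(a), float(b)) for l, a, b in segments))
        object.__setattr__(self, "units", units)
        for label, a, b in self.segments:
            if b <= a:
                raise ValueError(f"{fiber_id}: segment ({label}, {a}, {b}) has start >= end")
        ordered = sorted(self.segments, key=lambda s: s[1])
        for (_, _, e1), (_, s2, _) in zip(ordered, ordered[1:]):
            if s2 < e1 - 1e-9:
                raise ValueError(f"{fiber_id}: overlapping segments")

    def of_label(self, label: str) -> list[tuple[float, float]]:
        return sorted((a, b) for l, a, b in self.segments if l == label)


@dataclass(frozen=True)
class ForkMeasurement:
    """Origin-centered measurement: central CldU and its two IdU flanks (kb)."""

    fiber_id: str
    cldu_kb: float
    left_idu_kb: float | None
    right_idu_kb: float | None

    @property
    def paired(self) -> bool:
        return self.left_idu_kb is not None and self.right_idu_kb is not None

    @property
    def flanks(self) -> list[float]:
        return [x for x in (self.left_idu_kb, self.right_idu_kb) if x is not None]


def to_kb(fiber: Fiber, factor: float = KB_PER_UM) -> Fiber:
    """Convert a fiber measured in micrometers to kb (factor kb per um)."""
    if fiber.units == "kb":
        warnings.warn(f"{fiber.fiber_id}: already in kb; returning unchanged", stacklevel=2)
        return fiber
    return Fiber(
        fiber.fiber_id,
        [(l, a * factor, b * factor) for l, a, b in fiber.segments],
        units="kb",
    )


def measure_origin_forks(fiber: Fiber, gap_tolerance: float = 1.0) -> ForkMeasurement | None:
    """Measure the origin-centered CldU/IdU structure of one fiber.

    The central CldU segment is the longest CldU stretch; an IdU segment
    counts as a flank if the gap between it and the CldU segment is at
    most ``gap_tolerance`` kb. One-sided structures are returned with the
    missing flank as None (to be reported as unpaired); fibers without
    CldU are skipped (None).
    """
    if fiber.units != "kb":
        raise ValueError("fiber must be converted to kb first")
    cldu = fiber.of_label("CldU")
    if not cldu:
        return None
    central = max(cldu, key=lambda ab: ab[1] - ab[0])
    left = right = None
    for a, b in fiber.of_label("IdU"):
        if -1e-9 <= central[0] - b <= gap_tolerance:
            left = b - a
        elif -1e-9 <= a - central[1] <= gap_tolerance:
            right = b - a
    return ForkMeasurement(fiber.fiber_id, central[1] - central[0], left, right)


def measure_fibers(fibers: Sequence[Fiber], gap_tolerance: float = 1.0) -> list[ForkMeasurement]:
    out = []
    for f in fibers:
        m = measure_origin_forks(f, gap_tolerance)
        if m is not None:
            out.append(m)
    return out


def estimate_fork_speed(
    measurements: Sequence[ForkMeasurement], idu_pulse: float = 20.0
) -> tuple[np.ndarray, float, float]:
    """Per-flank fork speeds (flank length / IdU pulse) and their mean/sd.

    Every available flank contributes one speed; zero-length flanks are
    retained (they are real, stalled forks). Returns (speeds, mean, sd);
    an empty input yields (empty, nan, nan).
    """
    if idu_pulse <= 0:
        raise ValueError("idu_pulse must be > 0")
    speeds = np.array([x / idu_pulse for m in measurements for x in m.flanks])
    if len(speeds) == 0:
        return speeds, math.nan, math.nan
    return speeds, float(speeds.mean()), float(speeds.std(ddof=1)) if len(speeds) > 1 else 0.0


def classify_symmetry(
    measurement: ForkMeasurement, ratio_cut: float = 1.5, clamp_kb: float = 0.5
) -> Literal["symmetric", "asymmetric", "unpaired"]:
    """Classify bidirectional fork symmetry by the flank-length ratio.

    A fork pair is asymmetric when max/min exceeds ``ratio_cut``; the
    shorter flank is clamped to ``clamp_kb`` to keep the ratio finite for
    fully stalled forks. One-sided measurements are unpaired.
    """
    if not measurement.paired:
        return "unpaired"
    lo = max(min(measurement.flanks), clamp_kb)
    hi = max(measurement.flanks)
    return "asymmetric" if hi / lo > ratio_cut else "symmetric"


def asymmetric_fraction(
    measurements: Sequence[ForkMeasurement], ratio_cut: float = 1.5, clamp_kb: float = 0.5
) -> tuple[int, int]:
    """(number asymmetric, number of paired forks)."""
    labels = [classify_symmetry(m, ratio_cut, clamp_kb) for m in measurements]
    paired = [l for l in labels if l != "unpaired"]
    return sum(l == "asymmetric" for l in paired), len(paired)


def restart_stats(
    fibers: Sequence[Fiber], gap_tolerance: float = 1.0
) -> tuple[np.ndarray, float, float]:
    """IdU track lengths after HU arrest, one per CldU-labeled fork.

    A fork that failed to restart contributes length 0 (no adjacent IdU).
    Returns (lengths, mean, sd).
    """
    lengths = []
    for fiber in fibers:
        cldu = fiber.of_label("CldU")
        if not cldu:
            continue
        central = max(cldu, key=lambda ab: ab[1] - ab[0])
        idu = 0.0
        for a, b in fiber.of_label("IdU"):
            if -1e-9 <= a - central[1] <= gap_tolerance:
                idu = b - a
                break
        lengths.append(idu)
    arr = np.array(lengths)
    if len(arr) == 0:
        return arr, math.nan, math.nan
    return arr, float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float], welch: bool = True
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test: returns (t, df, p).

    Welch's unequal-variance form by default; the pooled-variance Student
    form behind ``welch=False``. Two zero-variance samples with equal
    means give (0, df, 1); with unequal means the test is degenerate and
    raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate test: zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["fiber_id", "label", "start", "end", "units"]


def write_fiber_table(fibers: Sequence[Fiber], path: str | Path) -> None:
    rows = [
        {"fiber_id": f.fiber_id, "label": l, "start": a, "end": b, "units": f.units}
        for f in fibers
        for l, a, b in f.segments
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fiber_table(path: str | Path) -> list[Fiber]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fiber table missing columns: {sorted(missing)}")
    fibers = []
    for fid, grp in df.groupby("fiber_id", sort=False):
        units = grp["units"].iloc[0]
        segments = [(r.label, r.start, r.end) for r in grp.itertuples()]
        fibers.append(Fiber(str(fid), segments, units=units))
    return fibers


def measurements_frame(
    measurements: Sequence[ForkMeasurement], idu_pulse: float = 20.0
) -> pd.DataFrame:
    """Tidy per-fiber measurement table with speeds and symmetry calls."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "fiber_id": m.fiber_id,
                "cldu_kb": m.cldu_kb,
                "left_idu_kb": m.left_idu_kb,
                "right_idu_kb": m.right_idu_kb,
                "left_speed_kb_min": None if m.left_idu_kb is None else m.left_idu_kb / idu_pulse,
                "right_speed_kb_min": None if m.right_idu_kb is None else m.right_idu_kb / idu_pulse,
                "symmetry": classify_symmetry(m),
            }
        )
    return pd.DataFrame(rows)
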