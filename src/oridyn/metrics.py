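"""Quantitative origin descriptors and whole-genome replication estimators.

Includes the peak width at half height over background, peak enrichment
versus random positions in a surrounding window, fixed-window overlap
between origin lists, genic annotation, and the back-of-the-envelope
origin-count estimator

    N = G / (2 * T * v)

with G the genome size (kb), T the time to replicate the genome (min) and
v the fork speed (kb/min) — each fired origin contributes two forks, so
N origins replicate 2*N*v*T kb in time T. T itself is estimated from an
EdU-incorporation time course as the time between the first observed
incorporation and the plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import GenomeSpec
from .tracks import SignalTrack

UNDEFINED = math.nan


@dataclass(frozen=True)
class OriginEstimateInputs:
    """Inputs to the origin-count formula: G (kb), T (min), v (kb/min)."""

    genome_size_kb: float
    replication_time_min: float
    fork_speed_kb_min: float

    def __post_init__(self) -> None:
        if min(self.genome_size_kb, self.replication_time_min, self.fork_speed_kb_min) <= 0:
            raise ValueError("all estimator inputs must be > 0")


def estimate_origin_number(inputs: OriginEstimateInputs) -> tuple[float, int]:
    """N = G / (2*T*v); returns (real value, rounded count)."""
    n = inputs.genome_size_kb / (2.0 * inputs.replication_time_min * inputs.fork_speed_kb_min)
    return n, round(n)


def width_at_half_height(
    track: SignalTrack,
    chrom: str,
    pos: int,
    background: float = 0.0,
    search_window: int = 25_000,
) -> float:
    """Peak width (kb) at half height over background.

    The peak height is the maximum signal within ``search_window`` of the
    position, minus ``background``. The width is the distance between the
    two crossings of background + height/2 nearest the summit, linearly
    interpolated between bin centers. Returns NaN when the peak does not
    rise above background or a crossing is not found inside the window.
    """
    if not track.genome.contains(chrom, pos):
        raise ValueError(f"({chrom}, {pos}) outside genome")
    bs = track.bin_size
    vec = track.data[chrom]
    lo = max(0, (pos - search_window) // bs)
    hi = min(len(vec), (pos + search_window) // bs + 1)
    seg = vec[lo:hi]
    if len(seg) == 0:
        return UNDEFINED
    i_max = int(np.argmax(seg))
    height = float(seg[i_max]) - background
    if height <= 0:
        return UNDEFINED
    level = background + height / 2.0

    def cross(direction: int) -> float | None:
        i = i_max
        while 0 <= i + direction < len(seg):
            j = i + direction
            if seg[j] < level <= seg[i]:
                # linear interpolation between bin centers i and j
                frac = (seg[i] - level) / (seg[i] - seg[j])
                return i + direction * frac
            i = j
        return None

    left = cross(-1)
    right = cross(+1)
    if left is None or right is None:
        return UNDEFINED
    return (right - left) * bs / 1000.0


def enrichment_vs_random(
    track: SignalTrack,
    chrom: str,
    pos: int,
    half_window: int = 25_000,
    n_random: int = 100,
    seed: int = 0,
) -> float:
    """Signal at the peak minus the mean at random positions around it.

    Random positions are drawn uniformly within +/- half_window (clipped
    to the chromosome), excluding the summit bin itself.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if not track.genome.contains(chrom, pos):
        raise ValueError(f"({chrom}, {pos}) outside genome")
    bs = track.bin_size
    length = track.genome.lengths[chrom]
    lo = max(0, pos - half_window)
    hi = min(length - 1, pos + half_window)
    rng = np.random.default_rng(seed)
    summit_bin = pos // bs
    draws = []
    while len(draws) < n_random:
        p = int(rng.integers(lo, hi + 1))
        if p // bs != summit_bin:
            draws.append(track.value_at(chrom, p))
    return track.value_at(chrom, pos) - float(np.mean(draws))


def window_mean_enrichment(
    track: SignalTrack, chrom: str, pos: int, half_window: int = 25_000
) -> float:
    """Deterministic limit of :func:`enrichment_vs_random`: peak value minus
    the mean over every bin in the window except the summit bin."""
    bs = track.bin_size
    vec = track.data[chrom]
    lo = max(0, (pos - half_window) // bs)
    hi = min(len(vec), (pos + half_window) // bs + 1)
    summit_bin = pos // bs
    others = [float(vec[k]) for k in range(lo, hi) if k != summit_bin]
    return track.value_at(chrom, pos) - float(np.mean(others))


@dataclass(frozen=True)
class OverlapReport:
    count: int
    fraction_a: float
    fraction_b: float


def overlap_lists(
    a: Sequence[tuple[str, int]],
    b: Sequence[tuple[str, int]],
    window: int = 5_000,
    mode: str = "tile",
) -> OverlapReport:
    """Overlap between two origin position lists.

    In the default ``tile`` mode the genome is tiled into consecutive
    ``window``-bp windows and two positions overlap when they share a tile
    (floor(pos / window)). ``distance`` mode instead counts positions
    within ``window`` bp of each other.
    """
    if mode == "tile":
        tiles_b = {(c, p // window) for c, p in b}
        tiles_a = {(c, p // window) for c, p in a}
        count = len(tiles_a & tiles_b)
        hits_a = sum(1 for c, p in a if (c, p // window) in tiles_b)
        hits_b = sum(1 for c, p in b if (c, p // window) in tiles_a)
    elif mode == "distance":
        by_chrom_b: dict[str, list[int]] = {}
        for c, p in b:
            by_chrom_b.setdefault(c, []).append(p)
        by_chrom_a: dict[str, list[int]] = {}
        for c, p in a:
            by_chrom_a.setdefault(c, []).append(p)
        hits_a = sum(
            1 for c, p in a if any(abs(p - q) <= window for q in by_chrom_b.get(c, []))
        )
        hits_b = sum(
            1 for c, p in b if any(abs(p - q) <= window for q in by_chrom_a.get(c, []))
        )
        count = hits_a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OverlapReport(
        count,
        hits_a / len(a) if a else 0.0,
        hits_b / len(b) if b else 0.0,
    )


def annotate_genic(
    origins: Sequence[tuple[str, int]], genome: GenomeSpec
) -> list[str]:
    """'intragenic' or 'extragenic' per origin against the genome's gene
    intervals (0-based half-open; a position at a gene end is extragenic)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in genome.genes:
        by_chrom.setdefault(chrom, []).append((start, end))
    out = []
    for chrom, pos in origins:
        genic = any(s <= pos < e for s, e in by_chrom.get(chrom, []))
        out.append("intragenic" if genic else "extragenic")
    return out


def genic_fractions(
    origins: Sequence[tuple[str, int]], classes: Sequence[str], genome: GenomeSpec
) -> dict[str, float]:
    """Per-class intragenic fraction."""
    ann = annotate_genic(origins, genome)
    out: dict[str, float] = {}
    for cls in sorted(set(classes)):
        members = [a for a, c in zip(ann, classes) if c == cls]
        out[cls] = sum(a == "intragenic" for a in members) / len(members) if members else 0.0
    return out


def estimate_replication_time(
    timecourse: Sequence[tuple[float, float]], plateau_fraction: float = 0.95
) -> float:
    """Genome replication time T from an EdU-incorporation time course.

    The plateau is the mean of the two largest intensities; T is the first
    sampled time whose intensity reaches ``plateau_fraction`` of the
    plateau, minus the first sampled time with any incorporation. Returns
    NaN for an all-zero series.
    """
    if len(timecourse) < 3:
        raise ValueError("need at least 3 timepoints")
    times = [t for t, _ in timecourse]
    values = [y for _, y in timecourse]
    if max(values) <= 0:
        return UNDEFINED
    plateau = float(np.mean(sorted(values)[-2:]))
    threshold = plateau_fraction * plateau
    t_plateau = next(t for t, y in timecourse if y >= threshold)
    t_first = next(t for t, y in timecourse if y > 0)
    return t_plateau - t_first
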