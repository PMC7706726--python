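"""Binned signal tracks and the standard processing steps applied to them.

Sequencing coverage is represented as a :class:`SignalTrack`: one float
vector per chromosome at a fixed bin size (1-kb bins for ChEC-seq and
EdU-seq, 10-kb bins for Repli-seq). The processing pipeline mirrors the
standard treatment of such tracks: library-size normalization to a common
read count, per-bin subtraction of a matched control, and smoothing with a
five-bin sliding average. Coordinates are 0-based and half-open
throughout; bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``.

All operations here are deterministic and return new tracks; processing
flags (``library_normalized``, ``control_subtracted``, ``smoothed``) are
carried forward and never unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import GenomeSpec

MISSING = np.nan


@dataclass
class TrackFlags:
    library_normalized: bool = False
    control_subtracted: bool = False
    smoothed: bool = False

    def merged(self, other: "TrackFlags") -> "TrackFlags":
        return TrackFlags(
            self.library_normalized or other.library_normalized,
            self.control_subtracted or other.control_subtracted,
            self.smoothed or other.smoothed,
        )


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage vectors over a shared genome."""

    genome: GenomeSpec
    bin_size: int
    data: dict[str, np.ndarray]
    flags: TrackFlags = field(default_factory=TrackFlags)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        expected = self.genome.n_bins(self.bin_size)
        for chrom, vec in self.data.items():
            if chrom not in expected:
                raise ValueError(f"track has unknown chromosome {chrom!r}")
            if len(vec) != expected[chrom]:
                raise ValueError(
                    f"{chrom}: expected {expected[chrom]} bins, got {len(vec)}"
                )
        for chrom in expected:
            if chrom not in self.data:
                raise ValueError(f"track missing chromosome {chrom!r}")

    @classmethod
    def zeros(cls, genome: GenomeSpec, bin_size: int) -> "SignalTrack":
        return cls(
            genome,
            bin_size,
            {c: np.zeros(n) for c, n in genome.n_bins(bin_size).items()},
        )

    @property
    def total_reads(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def values(self) -> np.ndarray:
        """All bins concatenated in chromosome order."""
        return np.concatenate([self.data[c] for c in self.genome.names])

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.genome,
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            replace(self.flags),
        )

    def value_at(self, chrom: str, pos: int) -> float:
        if not self.genome.contains(chrom, pos):
            raise ValueError(f"position ({chrom}, {pos}) outside genome")
        return float(self.data[chrom][pos // self.bin_size])

    def __eq__(self, other: object) -> bool:  # bitwise comparison, used for determinism checks
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.genome.chroms == other.genome.chroms
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.genome.names)
        )


def bin_counts(
    positions: list[tuple[str, int]], genome: GenomeSpec, bin_size: int
) -> SignalTrack:
    """Count read positions into fixed bins: position p lands in bin floor(p/bin_size)."""
    track = SignalTrack.zeros(genome, bin_size)
    for chrom, pos in positions:
        if not genome.contains(chrom, pos):
            raise ValueError(f"position ({chrom}, {pos}) outside genome")
        track.data[chrom][pos // bin_size] += 1
    return track


def normalize_total(
    tracks: list[SignalTrack], target: float | str = "min"
) -> list[SignalTrack]:
    """Scale each track to the same total read count (default: the smallest input total)."""
    totals = [t.total_reads for t in tracks]
    for t, tot in zip(tracks, totals):
        if tot <= 0:
            raise ValueError("cannot normalize a track with non-positive total reads")
    tgt = min(totals) if target == "min" else float(target)
    out = []
    for t, tot in zip(tracks, totals):
        scaled = t.copy()
        factor = tgt / tot
        for c in scaled.data:
            scaled.data[c] *= factor
        scaled.flags.library_normalized = True
        out.append(scaled)
    return out


def subtract_control(sample: SignalTrack, control: SignalTrack) -> SignalTrack:
    """Per-bin control subtraction; negative values are retained."""
    if sample.bin_size != control.bin_size:
        raise ValueError("bin_size mismatch between sample and control")
    if sample.genome.chroms != control.genome.chroms:
        raise ValueError("genome mismatch between sample and control")
    out = sample.copy()
    for c in out.data:
        out.data[c] = out.data[c] - control.data[c]
    out.flags = sample.flags.merged(control.flags)
    out.flags.control_subtracted = True
    return out


def smooth(track: SignalTrack, window: int = 5) -> SignalTrack:
    """Centered sliding-window mean over ``window`` consecutive bins.

    At chromosome edges the window shrinks to the available bins (the mean
    is over however many bins fall inside the chromosome); smoothing never
    crosses a chromosome boundary.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    out = track.copy()
    half = window // 2
    for c, vec in track.data.items():
        n = len(vec)
        if n == 0:
            continue
        csum = np.concatenate(([0.0], np.cumsum(vec)))
        i = np.arange(n)
        lo = np.maximum(0, i - half)
        hi = np.minimum(n, i + half + 1)
        out.data[c] = (csum[hi] - csum[lo]) / (hi - lo)
    out.flags.smoothed = True
    return out


def extract_matrix(
    track: SignalTrack,
    anchors: list[tuple[str, int]],
    half_window: int = 25_000,
    res: int = 1_000,
) -> np.ndarray:
    """Signal matrix around anchor positions (one row per anchor).

    Row ``i`` is the track resampled at ``res``-bp columns covering
    ``[anchor - half_window, anchor + half_window)``. Column values are
    overlap-weighted means of the underlying bins; columns extending past
    a chromosome end are NaN and are to be excluded from column means
    (metaplots), not zero-filled.
    """
    if half_window % res != 0:
        raise ValueError("half_window must be a multiple of res")
    if res % track.bin_size != 0 and track.bin_size % res != 0:
        raise ValueError("res must be a multiple of bin_size or vice versa")
    n_cols = 2 * half_window // res
    mat = np.full((len(anchors), n_cols), MISSING)
    lengths = track.genome.lengths
    for i, (chrom, pos) in enumerate(anchors):
        if not track.genome.contains(chrom, pos):
            raise ValueError(f"anchor ({chrom}, {pos}) outside genome")
        vec = track.data[chrom]
        length = lengths[chrom]
        for j in range(n_cols):
            a = pos - half_window + j * res
            b = a + res
            if a < 0 or b > length:
                continue
            mat[i, j] = _interval_mean(vec, track.bin_size, a, b)
    return mat


def _interval_mean(vec: np.ndarray, bin_size: int, a: int, b: int) -> float:
    """Overlap-weighted mean of binned values over the bp interval [a, b)."""
    first, last = a // bin_size, (b - 1) // bin_size
    if first == last:
        return float(vec[first])
    total = 0.0
    for k in range(first, last + 1):
        lo = max(a, k * bin_size)
        hi = min(b, (k + 1) * bin_size, len(vec) * bin_size)
        total += vec[k] * (hi - lo)
    return total / (b - a)


def metaplot(matrix: np.ndarray) -> np.ndarray:
    """Column means of an anchor matrix, ignoring missing values."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix, axis=0)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, one line per non-zero bin, aligned to the bin grid."""
    lengths = track.genome.lengths
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            vec = track.data[chrom]
            nz = np.nonzero(vec)[0]
            for i in nz:
                start = int(i) * track.bin_size
                end = min(start + track.bin_size, lengths[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:.10g}\n")


def read_bedgraph(path: str | Path, genome: GenomeSpec, bin_size: int) -> SignalTrack:
    """Read a bedGraph into a binned track.

    Grid-aligned intervals round-trip losslessly. Intervals not aligned to
    the bin grid deposit their value into each overlapped bin weighted by
    the fraction of the interval's length falling in that bin. Overlapping
    intervals and unknown chromosomes are rejected.
    """
    track = SignalTrack.zeros(genome, bin_size)
    lengths = genome.lengths
    seen: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, s, e, v = line.split()[:4]
        start, end, value = int(s), int(e), float(v)
        if chrom not in lengths:
            raise ValueError(f"line {ln}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= lengths[chrom]):
            raise ValueError(f"line {ln}: interval out of bounds")
        seen.setdefault(chrom, []).append((start, end))
        vec = track.data[chrom]
        span = end - start
        first, last = start // bin_size, (end - 1) // bin_size
        for k in range(first, last + 1):
            lo, hi = max(start, k * bin_size), min(end, (k + 1) * bin_size)
            vec[k] += value * (hi - lo) / span
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping intervals on {chrom} at {s2}")
    return track
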