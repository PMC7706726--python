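"""Stochastic forward simulator of embryonic S phase with planted ground truth.

The model
---------
A cell enters S phase with a set of licensed origins. Each origin fires at
most once per cell: a Bernoulli draw at its efficiency decides whether it
is competent in that cell, and a truncated-Normal clock (per-origin mean
and sd, truncated at zero) decides when. A fired origin launches two forks
that move outward at constant speed ``v`` (kb/min). Converging forks
terminate where they meet; an origin whose locus is reached by a fork
before its own clock is passively replicated and never fires. Forks may
stall (per-fork Bernoulli draw), in which case they arrest after
travelling the HU-arrest distance ``delta``.

Hydroxyurea (HU) is modelled as fire-then-arrest: origins fire on
schedule, but their forks arrest after at most ``delta`` kb of travel.
This mirrors the observation that nucleotide depletion permits only short
fork movements away from origins, producing the characteristic double
peak of EdU incorporation flanking early origins.

Three read-out layers sit on top of the fork kinematics:

* ChEC-seq emission: Gaussian peak mass at origin positions (CDT-1 at all
  licensed origins; TRES-1 at firing origins, plus reduced mass at
  stress-activated dormant origins under temperature stress).
* EdU-seq: the synchronize/release/pulse protocol (HU block, release,
  EdU+HU pulse at a chosen release time); bases replicated during the
  pulse are labeled.
* Repli-seq: an asynchronous population is gated early/mid/late by noisy
  DNA content, and each gate's track counts bases replicated in a short
  pulse at each cell's S-phase time.

The H3.3-null genotype elevates the fork stall and restart-failure
probabilities. Because stress-activated (dormant) origins sit near early
origins, restart failure of the early forks leaves them unsilenced, so
they fire late and EdU label accumulates at their centers at late release
times — the qualitative mutant signature.

All randomness flows from ``SimConfig.seed`` through per-cell
``numpy.random.SeedSequence`` substreams, so identical configurations
reproduce tracks and fibers bit for bit.
"""

from __future__ import annotations

import math
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import norm, truncnorm

from .fibers import Fiber
from .genome import GenomeSpec, default_genome
from .tracks import SignalTrack

OriginClass = Literal["early", "late", "dormant"]

# Per-class firing-clock defaults (minutes from S-phase entry / HU release)
# and efficiencies. Early origins fire essentially at S-phase onset; late
# origins fire well after the first EdU pulse window; dormant origins are
# backup origins with late, broad clocks that matter only under stress.
CLASS_DEFAULTS: dict[str, dict[str, float]] = {
    "early": {"firing_time_mean": 0.0, "firing_time_sd": 2.0, "efficiency": 0.98},
    "late": {"firing_time_mean": 20.0, "firing_time_sd": 5.0, "efficiency": 0.90},
    "dormant": {"firing_time_mean": 50.0, "firing_time_sd": 20.0, "efficiency": 0.90},
}


@dataclass(frozen=True)
class OriginSpec:
    """A planted replication origin with class and firing-time parameters."""

    chrom: str
    pos: int
    cls: OriginClass
    firing_time_mean: float
    firing_time_sd: float
    efficiency: float
    stress_activated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if self.firing_time_sd < 0:
            raise ValueError("firing_time_sd must be >= 0")
        if self.cls not in ("early", "late", "dormant"):
            raise ValueError(f"unknown origin class {self.cls!r}")

    @classmethod
    def with_class_defaults(
        cls, chrom: str, pos: int, origin_class: OriginClass, stress_activated: bool = False
    ) -> "OriginSpec":
        d = CLASS_DEFAULTS[origin_class]
        return cls(
            chrom,
            pos,
            origin_class,
            d["firing_time_mean"],
            d["firing_time_sd"],
            d["efficiency"],
            stress_activated,
        )


@dataclass
class SimConfig:
    """Simulation parameters. Units: kb and minutes unless noted.

    ``stall_prob`` and ``restart_fail_prob`` default to genotype-specific
    values when left as None: near zero for WT, elevated for the
    H3.3-null mode (impaired fork progression and restart).
    """

    fork_speed: float = 1.5          # v, kb/min
    hu_arrest_distance: float = 2.0  # delta, kb a fork travels under HU before arrest
    stall_prob: float | None = None
    restart_fail_prob: float | None = None
    n_cells: int = 50
    read_depth: float = 50.0         # expected reads per fully-labeled bin
    background_rate: float = 4.0     # expected background reads per bin
    bin_size: int = 1000             # bp (ChEC-seq / EdU-seq)
    repliseq_bin_size: int = 10_000  # bp
    condition: Literal["baseline20", "stress25"] = "baseline20"
    genotype: Literal["WT", "H3.3null"] = "WT"
    edu_pulse: float = 10.0          # min
    cldu_pulse: float = 20.0         # min
    idu_pulse: float = 20.0          # min
    hu_duration: float = 60.0        # min, length of the synchronizing HU block
    repliseq_pulse: float = 5.0      # min, EdU pulse for Repli-seq gating
    content_noise_sd: float = 0.05   # DNA-content measurement noise, fraction of 2C
    chec_kernel_sd: float = 2.0      # kb, ChEC peak width
    chec_reads_per_origin: float = 250.0
    tres1_dormant_factor: float = 0.3  # TRES-1 amplitude at stress-activated dormant origins
    fiber_noise_sd: float = 0.8      # kb, combing measurement noise per segment
    restart_delay: float = 0.0       # min, delay before a restarting fork resumes (fibers)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be > 0")
        if self.hu_arrest_distance < 0:
            raise ValueError("hu_arrest_distance must be >= 0")
        if self.stall_prob is None:
            self.stall_prob = 0.30 if self.genotype == "H3.3null" else 0.02
        if self.restart_fail_prob is None:
            self.restart_fail_prob = 0.70 if self.genotype == "H3.3null" else 0.02
        for p in (self.stall_prob, self.restart_fail_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def v_bp(self) -> float:
        return self.fork_speed * 1000.0

    @property
    def delta_bp(self) -> float:
        return self.hu_arrest_distance * 1000.0


def effective_efficiency(origin: OriginSpec, config: SimConfig) -> float:
    """Firing efficiency under the configured condition.

    Dormant origins are silent at baseline; stress-activated dormant
    origins fire (at their nominal efficiency) only under temperature
    stress.
    """
    if origin.cls == "dormant":
        if origin.stress_activated and config.condition == "stress25":
            return origin.efficiency
        return 0.0
    return origin.efficiency


@dataclass(frozen=True)
class ForkTrajectory:
    """One fork of a fired origin: direction, firing time, arrest cap, extent."""

    chrom: str
    origin_index: int
    direction: int            # +1 right, -1 left
    fired_at: float           # min
    cap_bp: float             # max travel before arrest (inf = no stall)
    extent_bp: float          # bases replicated by this fork

    def __post_init__(self) -> None:
        if self.extent_bp < -1e-9:
            raise ValueError("extent must be >= 0")


@dataclass(frozen=True)
class LabeledSegment:
    chrom: str
    start: float
    end: float
    label: Literal["EdU", "CldU", "IdU"]


@dataclass
class LabeledIntervalSet:
    """Per-cell labeled (analog-incorporated) genomic intervals."""

    cells: list[list[LabeledSegment]]

    def all_segments(self) -> list[LabeledSegment]:
        return [seg for cell in self.cells for seg in cell]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-element Normal(mean, sd) truncated at zero (exact, renormalized)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.maximum(mean, 0.0).copy()
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], size=int(pos.sum()), random_state=rng
        )
    return out


class CellRealization:
    """Closed-form S-phase kinematics for one cell (no protocol phases).

    Firing decisions, clocks and stall caps are drawn at construction;
    fork extents, replicated intervals, replicated fraction and completion
    time are then exact deterministic functions of time. Between two
    consecutive fired origins the facing forks race: with equal speeds the
    boundary claimed by the left origin's right fork is

        X = clip(max(x*, d - reach_right), 0, reach_left),

    where ``x*`` is the free meeting offset and the reaches encode time,
    stall caps and the chromosome ends. Claims are non-decreasing in time,
    so labeled windows are differences of claims at two times.
    """

    def __init__(
        self,
        genome: GenomeSpec,
        origins: Sequence[OriginSpec],
        config: SimConfig,
        rng: np.random.Generator,
    ) -> None:
        self.genome = genome
        self.config = config
        self.v = config.v_bp
        self._fired: dict[str, dict[str, np.ndarray]] = {}
        for origin in origins:
            if not genome.contains(origin.chrom, origin.pos):
                raise ValueError(f"origin at ({origin.chrom}, {origin.pos}) outside genome")
        for chrom in genome.names:
            idx = sorted(
                (i for i, o in enumerate(origins) if o.chrom == chrom),
                key=lambda i: origins[i].pos,
            )
            n = len(idx)
            if n == 0:
                self._fired[chrom] = {k: np.empty(0) for k in ("pos", "t", "capL", "capR", "idx")}
                continue
            eff = np.array([effective_efficiency(origins[i], config) for i in idx])
            competent = rng.random(n) < eff
            clocks = _truncated_normal(
                rng,
                np.array([origins[i].firing_time_mean for i in idx]),
                np.array([origins[i].firing_time_sd for i in idx]),
            )
            stall_l = rng.random(n) < config.stall_prob
            stall_r = rng.random(n) < config.stall_prob
            cap_l = np.where(stall_l, config.delta_bp, np.inf)
            cap_r = np.where(stall_r, config.delta_bp, np.inf)
            pos = np.array([origins[i].pos for i in idx], dtype=float)

            fired = self._resolve_passive_silencing(pos, clocks, cap_l, cap_r, competent)
            sel = np.array(sorted(fired), dtype=int) if fired else np.empty(0, dtype=int)
            self._fired[chrom] = {
                "pos": pos[sel],
                "t": clocks[sel],
                "capL": cap_l[sel],
                "capR": cap_r[sel],
                "idx": np.array([idx[i] for i in sel], dtype=int),
            }

    def _resolve_passive_silencing(self, pos, clocks, cap_l, cap_r, competent) -> set[int]:
        """Process competent origins in firing order; drop those whose locus
        is replicated by a neighboring fired origin before their clock."""
        from bisect import bisect_left

        order = sorted(np.nonzero(competent)[0], key=lambda i: clocks[i])
        fired_positions: list[tuple[float, int]] = []  # sorted by position
        fired: set[int] = set()
        for j in order:
            silenced = False
            k = bisect_left(fired_positions, (pos[j], -1))
            if k > 0:  # nearest fired origin to the left
                p_i, i = fired_positions[k - 1]
                d = pos[j] - p_i
                if d <= cap_r[i] and clocks[i] + d / self.v < clocks[j]:
                    silenced = True
            if not silenced and k < len(fired_positions):  # nearest to the right
                p_i, i = fired_positions[k]
                d = p_i - pos[j]
                if d <= cap_l[i] and clocks[i] + d / self.v < clocks[j]:
                    silenced = True
            if not silenced:
                insort(fired_positions, (pos[j], int(j)))
                fired.add(int(j))
        return fired

    # -- kinematics ---------------------------------------------------------

    def _claims(self, chrom: str, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Left/right extents (bp) claimed by each fired origin's forks at time t."""
        f = self._fired[chrom]
        pos, tf, cap_l, cap_r = f["pos"], f["t"], f["capL"], f["capR"]
        n = len(pos)
        length = self.genome.lengths[chrom]
        xl = np.zeros(n)
        xr = np.zeros(n)
        if n == 0:
            return xl, xr
        reach_l = np.clip(self.v * (t - tf), 0.0, None)
        reach_l = np.minimum(reach_l, cap_l)
        reach_r = np.clip(self.v * (t - tf), 0.0, None)
        reach_r = np.minimum(reach_r, cap_r)
        # chromosome edges
        xl[0] = min(reach_l[0], pos[0])
        xr[-1] = min(reach_r[-1], length - pos[-1])
        # interior gaps: facing forks of consecutive fired origins compete
        for i in range(n - 1):
            j = i + 1
            d = pos[j] - pos[i]
            x_star = (d + self.v * (tf[j] - tf[i])) / 2.0
            xr[i] = float(np.clip(max(x_star, d - reach_l[j]), 0.0, reach_r[i]))
            xl[j] = float(np.clip(max(d - x_star, d - reach_r[i]), 0.0, reach_l[j]))
        return xl, xr

    def fork_trajectories(self, t: float) -> list[ForkTrajectory]:
        out = []
        for chrom in self.genome.names:
            f = self._fired[chrom]
            xl, xr = self._claims(chrom, t)
            for k in range(len(f["pos"])):
                out.append(
                    ForkTrajectory(chrom, int(f["idx"][k]), -1, float(f["t"][k]), float(f["capL"][k]), float(xl[k]))
                )
                out.append(
                    ForkTrajectory(chrom, int(f["idx"][k]), +1, float(f["t"][k]), float(f["capR"][k]), float(xr[k]))
                )
        return out

    def replicated_intervals(self, t: float) -> list[tuple[str, float, float]]:
        """Disjoint replicated intervals at time t (merged where forks met)."""
        out: list[tuple[str, float, float]] = []
        for chrom in self.genome.names:
            f = self._fired[chrom]
            xl, xr = self._claims(chrom, t)
            cur: tuple[float, float] | None = None
            for k in range(len(f["pos"])):
                a, b = f["pos"][k] - xl[k], f["pos"][k] + xr[k]
                if b <= a:
                    continue
                if cur is not None and a <= cur[1] + 1e-9:
                    cur = (cur[0], max(cur[1], b))
                else:
                    if cur is not None:
                        out.append((chrom, cur[0], cur[1]))
                    cur = (a, b)
            if cur is not None:
                out.append((chrom, cur[0], cur[1]))
        return out

    def replicated_fraction(self, t: float) -> float:
        total = 0.0
        for chrom in self.genome.names:
            xl, xr = self._claims(chrom, t)
            total += float(xl.sum() + xr.sum())
        return total / self.genome.size_bp

    def labeled_window(self, t0: float, t1: float) -> list[LabeledSegment]:
        """Bases replicated during [t0, t1], as disjoint labeled segments."""
        segs: list[LabeledSegment] = []
        for chrom in self.genome.names:
            f = self._fired[chrom]
            xl0, xr0 = self._claims(chrom, t0)
            xl1, xr1 = self._claims(chrom, t1)
            for k in range(len(f["pos"])):
                p = f["pos"][k]
                if xl1[k] > xl0[k] + 1e-9:
                    segs.append(LabeledSegment(chrom, p - xl1[k], p - xl0[k], "EdU"))
                if xr1[k] > xr0[k] + 1e-9:
                    segs.append(LabeledSegment(chrom, p + xr0[k], p + xr1[k], "EdU"))
        return segs

    def completion_time(self, finite_only: bool = False) -> float:
        """Time at which the last base is replicated (inf if arrested forks
        leave an unclosable gap; with ``finite_only`` the latest closure
        among closable regions is returned instead)."""
        closures: list[float] = []
        unclosable = False
        for chrom in self.genome.names:
            f = self._fired[chrom]
            pos, tf, cap_l, cap_r = f["pos"], f["t"], f["capL"], f["capR"]
            n = len(pos)
            length = self.genome.lengths[chrom]
            if n == 0:
                if length > 0:
                    unclosable = True
                continue
            if cap_l[0] >= pos[0]:
                closures.append(tf[0] + pos[0] / self.v)
            else:
                unclosable = True
            if cap_r[-1] >= length - pos[-1]:
                closures.append(tf[-1] + (length - pos[-1]) / self.v)
            else:
                unclosable = True
            for i in range(n - 1):
                j = i + 1
                d = pos[j] - pos[i]
                if cap_r[i] + cap_l[j] < d:
                    unclosable = True
                    continue
                x_star = (d + self.v * (tf[j] - tf[i])) / 2.0
                if 0.0 <= x_star <= d and x_star <= cap_r[i] and d - x_star <= cap_l[j]:
                    closures.append(tf[i] + x_star / self.v)
                elif x_star > cap_r[i]:
                    closures.append(tf[j] + (d - cap_r[i]) / self.v)
                else:
                    closures.append(tf[i] + (d - cap_l[j]) / self.v)
        if unclosable and not finite_only:
            return math.inf
        return max(closures) if closures else 0.0


@dataclass
class SPhaseResult:
    """Per-cell S-phase realizations evaluated at a common end time."""

    cells: list[CellRealization]
    t_end: float

    def trajectories(self, cell: int, t: float | None = None) -> list[ForkTrajectory]:
        return self.cells[cell].fork_trajectories(self.t_end if t is None else t)

    def intervals(self, cell: int, t: float | None = None) -> list[tuple[str, float, float]]:
        return self.cells[cell].replicated_intervals(self.t_end if t is None else t)


def _cell_rngs(config: SimConfig, n: int, stream: int = 0) -> list[np.random.Generator]:
    """Independent per-cell substreams from the single configured seed."""
    root = np.random.SeedSequence(config.seed + 1_000_003 * stream)
    return [np.random.default_rng(s) for s in root.spawn(n)]


def simulate_sphase(
    genome: GenomeSpec,
    origins: Sequence[OriginSpec],
    config: SimConfig,
    t_end: float,
) -> SPhaseResult:
    """Simulate free-running S phase for ``config.n_cells`` cells."""
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    cells = [CellRealization(genome, origins, config, rng) for rng in _cell_rngs(config, config.n_cells)]
    return SPhaseResult(cells, t_end)


# ---------------------------------------------------------------------------
# HU-synchronize / release / EdU-pulse protocol (event-driven, exact)
# ---------------------------------------------------------------------------


class _Fork:
    __slots__ = ("budget", "dead", "was_arrested")

    def __init__(self, budget: float) -> None:
        self.budget = budget
        self.dead = False
        self.was_arrested = False

    @property
    def active(self) -> bool:
        return not self.dead and self.budget > 0


class _Interval:
    __slots__ = ("oid", "l", "r", "fl", "fr")

    def __init__(self, oid: int, pos: float, budget_l: float, budget_r: float) -> None:
        self.oid = oid
        self.l = pos
        self.r = pos
        self.fl = _Fork(budget_l)
        self.fr = _Fork(budget_r)


def _advance(intervals: list[_Interval], dt: float, v: float, length: float) -> None:
    """Advance all forks by dt, resolving arrests, edges and convergences exactly."""
    if dt <= 0 or not intervals:
        return
    step = v * dt

    def allowance(fork: _Fork) -> float:
        return min(step, fork.budget) if fork.active else 0.0

    # left chromosome edge
    first = intervals[0]
    a = allowance(first.fl)
    if a >= first.l:
        travel = first.l
        first.l = 0.0
        first.fl.dead = True
    else:
        travel = a
        first.l -= a
    first.fl.budget -= travel
    if first.fl.budget <= 0 and not first.fl.dead:
        first.fl.was_arrested = True
    # interior gaps
    for left, right in zip(intervals, intervals[1:]):
        g = max(0.0, right.l - left.r)
        a_l = allowance(left.fr)
        a_r = allowance(right.fl)
        if a_l + a_r < g:
            left.r += a_l
            right.l -= a_r
            x_l, x_r = a_l, a_r
        else:
            x_l = min(a_l, max(g / 2.0, g - a_r))
            x_r = g - x_l
            left.r += x_l
            right.l -= x_r
            left.fr.dead = True
            right.fl.dead = True
        left.fr.budget -= x_l
        right.fl.budget -= x_r
        for fork in (left.fr, right.fl):
            if fork.budget <= 0 and not fork.dead:
                fork.was_arrested = True
    # right chromosome edge
    last = intervals[-1]
    a = allowance(last.fr)
    if a >= length - last.r:
        travel = length - last.r
        last.r = length
        last.fr.dead = True
    else:
        travel = a
        last.r += a
    last.fr.budget -= travel
    if last.fr.budget <= 0 and not last.fr.dead:
        last.fr.was_arrested = True


def run_edu_protocol(
    genome: GenomeSpec,
    origins: Sequence[OriginSpec],
    config: SimConfig,
    release_time: float,
) -> LabeledIntervalSet:
    """HU synchronization, release, and an EdU+HU pulse at ``release_time``.

    Phase 1 (HU block, ``config.hu_duration`` min): origins whose clocks
    put them at S-phase onset (the early class) fire; their forks travel
    at most ``delta`` and arrest. Phase 2 (release at t=0): each arrested
    fork fails permanently with probability ``restart_fail_prob``;
    surviving and newly-created forks stall (arrest after a further
    ``delta``) with probability ``stall_prob``; later origins fire on
    their clocks, measured from release. Phase 3 (EdU + HU pulse of
    ``edu_pulse`` min starting at ``release_time``): every base replicated
    during the pulse is EdU-labeled, and forks re-arrest after at most
    ``delta`` of travel within the pulse.
    """
    if release_time < 0:
        raise ValueError("release_time must be >= 0")
    for o in origins:
        if not genome.contains(o.chrom, o.pos):
            raise ValueError(f"origin at ({o.chrom}, {o.pos}) outside genome")
    v = config.v_bp
    delta = config.delta_bp
    t_pulse = float(release_time)
    t_end = t_pulse + config.edu_pulse
    cells: list[list[LabeledSegment]] = []
    for rng in _cell_rngs(config, config.n_cells, stream=1):
        cell_segments: list[LabeledSegment] = []
        for chrom in genome.names:
            idx = sorted(
                (i for i, o in enumerate(origins) if o.chrom == chrom),
                key=lambda i: origins[i].pos,
            )
            n = len(idx)
            if n == 0:
                continue
            length = float(genome.lengths[chrom])
            eff = np.array([effective_efficiency(origins[i], config) for i in idx])
            competent = rng.random(n) < eff
            clocks = _truncated_normal(
                rng,
                np.array([origins[i].firing_time_mean for i in idx]),
                np.array([origins[i].firing_time_sd for i in idx]),
            )
            # Early origins enter S phase at the start of the block; all
            # others measure their clocks from the release.
            t_fire = np.where(
                np.array([origins[i].cls == "early" for i in idx]),
                clocks - config.hu_duration,
                clocks,
            )
            events: list[tuple[float, int, int]] = [
                (float(t_fire[k]), 1, k) for k in range(n) if competent[k]
            ]
            events += [(0.0, 0, -1), (t_pulse, 2, -1), (t_end, 3, -1)]
            events.sort(key=lambda e: (e[0], e[1]))

            intervals: list[_Interval] = []
            snapshot: dict[int, tuple[float, float]] = {}
            t_now = -config.hu_duration
            for t_ev, kind, payload in events:
                if t_ev < t_now - 1e-12:
                    continue  # origin clocked before the block starts: treat as block start
                _advance(intervals, t_ev - t_now, v, length)
                t_now = t_ev
                if kind == 3:  # end of the pulse: cells are fixed
                    break
                if kind == 1:  # firing attempt
                    pos = float(origins[idx[payload]].pos)
                    if any(iv.l <= pos <= iv.r for iv in intervals):
                        continue  # passively replicated: the origin never fires
                    if t_now < 0:
                        bl = br = delta
                    elif t_now < t_pulse:
                        bl = delta if rng.random() < config.stall_prob else math.inf
                        br = delta if rng.random() < config.stall_prob else math.inf
                    else:
                        bl = br = delta
                    iv = _Interval(payload, pos, bl, br)
                    k = 0
                    while k < len(intervals) and intervals[k].l < pos:
                        k += 1
                    intervals.insert(k, iv)
                elif kind == 0:  # HU release
                    for iv in intervals:
                        for fork in (iv.fl, iv.fr):
                            if fork.dead:
                                continue
                            if fork.budget <= 0:  # arrested: restart or fail
                                if rng.random() < config.restart_fail_prob:
                                    fork.dead = True
                                    continue
                            fork.budget = delta if rng.random() < config.stall_prob else math.inf
                elif kind == 2:  # pulse start: EdU + HU
                    snapshot = {id(iv): (iv.l, iv.r) for iv in intervals}
                    for iv in intervals:
                        for fork in (iv.fl, iv.fr):
                            if fork.active:
                                fork.budget = min(fork.budget, delta)
            for iv in intervals:
                l0, r0 = snapshot.get(id(iv), (None, None))
                if l0 is None:
                    if iv.r > iv.l + 1e-9:
                        cell_segments.append(LabeledSegment(chrom, iv.l, iv.r, "EdU"))
                else:
                    if iv.l < l0 - 1e-9:
                        cell_segments.append(LabeledSegment(chrom, iv.l, l0, "EdU"))
                    if iv.r > r0 + 1e-9:
                        cell_segments.append(LabeledSegment(chrom, r0, iv.r, "EdU"))
        cells.append(cell_segments)
    return LabeledIntervalSet(cells)


# ---------------------------------------------------------------------------
# Read sampling and assay tracks
# ---------------------------------------------------------------------------


def sample_track(
    labels: LabeledIntervalSet | Iterable[LabeledSegment],
    genome: GenomeSpec,
    config: SimConfig,
    bin_size: int | None = None,
    n_cells: int | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> SignalTrack:
    """Poisson read sampling from labeled intervals.

    The per-bin expectation is ``read_depth * share + background_rate``,
    where ``share`` is the per-cell mean fraction of the bin's bases that
    are labeled. With ``noise=False`` the expectation itself is returned.
    """
    if genome.size_bp == 0:
        raise ValueError("zero-length genome")
    bin_size = bin_size or config.bin_size
    if isinstance(labels, LabeledIntervalSet):
        segments = labels.all_segments()
        n_cells = labels.n_cells if n_cells is None else n_cells
    else:
        segments = list(labels)
        n_cells = 1 if n_cells is None else n_cells
    track = SignalTrack.zeros(genome, bin_size)
    lengths = genome.lengths
    for seg in segments:
        if seg.chrom not in lengths:
            raise ValueError(f"labeled segment on unknown chromosome {seg.chrom!r}")
        start = max(0.0, min(seg.start, seg.end))
        end = min(float(lengths[seg.chrom]), max(seg.start, seg.end))
        if end <= start:
            continue
        vec = track.data[seg.chrom]
        first, last = int(start // bin_size), int(math.ceil(end / bin_size)) - 1
        for k in range(first, last + 1):
            lo, hi = max(start, k * bin_size), min(end, (k + 1) * bin_size)
            vec[k] += hi - lo
    denom = max(n_cells, 1) * bin_size
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed + 777))
    for chrom in track.data:
        share = track.data[chrom] / denom
        mean = config.read_depth * share + config.background_rate
        track.data[chrom] = rng.poisson(mean).astype(float) if noise else mean
    return track


def simulate_chec_track(
    origins: Sequence[OriginSpec],
    assay: Literal["CDT1", "TRES1"],
    genome: GenomeSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> SignalTrack:
    """ChEC-seq coverage: Gaussian peak mass at origins over Poisson background.

    CDT-1 (licensing) marks every origin; TRES-1 (firing) marks early and
    late origins, and — under temperature stress — stress-activated
    dormant origins at reduced amplitude.
    """
    if assay not in ("CDT1", "TRES1"):
        raise ValueError(f"unknown assay {assay!r}")
    bin_size = config.bin_size
    sd_bp = config.chec_kernel_sd * 1000.0
    track = SignalTrack.zeros(genome, bin_size)
    for o in origins:
        if not genome.contains(o.chrom, o.pos):
            raise ValueError(f"origin at ({o.chrom}, {o.pos}) outside genome")
        if assay == "CDT1":
            mass = config.chec_reads_per_origin
        elif o.cls in ("early", "late"):
            mass = config.chec_reads_per_origin
        elif o.stress_activated and config.condition == "stress25":
            mass = config.chec_reads_per_origin * config.tres1_dormant_factor
        else:
            continue
        vec = track.data[o.chrom]
        lo = max(0, int((o.pos - 6 * sd_bp) // bin_size))
        hi = min(len(vec) - 1, int((o.pos + 6 * sd_bp) // bin_size))
        edges = np.arange(lo, hi + 2) * bin_size
        weights = np.diff(norm.cdf(edges, loc=o.pos, scale=sd_bp))
        vec[lo : hi + 1] += mass * weights
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed + 888))
    for chrom in track.data:
        mean = track.data[chrom] + config.background_rate
        track.data[chrom] = rng.poisson(mean).astype(float) if noise else mean
    return track


def simulate_control_track(
    genome: GenomeSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> SignalTrack:
    """Genomic-DNA / free-MNase control: flat Poisson background."""
    track = SignalTrack.zeros(genome, config.bin_size)
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed + 999))
    for chrom in track.data:
        mean = np.full_like(track.data[chrom], config.background_rate)
        track.data[chrom] = rng.poisson(mean).astype(float) if noise else mean
    return track


@dataclass
class RepliSeqResult:
    early: SignalTrack
    mid: SignalTrack
    late: SignalTrack
    gates: list[str]           # per-cell gate assignment
    fractions: list[float]     # per-cell replicated fraction at sampling time


def simulate_repliseq(
    genome: GenomeSpec,
    origins: Sequence[OriginSpec],
    config: SimConfig,
) -> RepliSeqResult:
    """Repli-seq from an asynchronous population gated by DNA content.

    Each cell is assigned a uniform elapsed S-phase time; its replicated
    fraction f gives a noisy DNA content 2C(1+f)+eps, which gates it into
    exactly one of early (f nominally < 1/3), mid, or late. Each gate's
    track counts bases replicated within a ``repliseq_pulse`` window at
    the cell's time.
    """
    if not any(effective_efficiency(o, config) > 0 for o in origins):
        raise ValueError("at least one origin must be able to fire")
    rngs = _cell_rngs(config, config.n_cells, stream=2)
    gate_labels: dict[str, list[LabeledSegment]] = {"early": [], "mid": [], "late": []}
    gate_counts = {"early": 0, "mid": 0, "late": 0}
    gates: list[str] = []
    fractions: list[float] = []
    c1, c2 = 2.0 * (1 + 1 / 3), 2.0 * (1 + 2 / 3)
    for rng in rngs:
        cell = CellRealization(genome, origins, config, rng)
        horizon = cell.completion_time(finite_only=True)
        tau = rng.uniform(0.0, horizon) if horizon > 0 else 0.0
        f = cell.replicated_fraction(tau)
        content = 2.0 * (1.0 + f) + rng.normal(0.0, config.content_noise_sd * 2.0)
        gate = "early" if content < c1 else ("mid" if content < c2 else "late")
        gates.append(gate)
        fractions.append(f)
        gate_counts[gate] += 1
        gate_labels[gate].extend(cell.labeled_window(tau, tau + config.repliseq_pulse))
    track_rng = np.random.default_rng(np.random.SeedSequence(config.seed + 2222))
    tracks = {}
    for gate in ("early", "mid", "late"):
        tracks[gate] = sample_track(
            gate_labels[gate],
            genome,
            config,
            bin_size=config.repliseq_bin_size,
            n_cells=max(gate_counts[gate], 1),
            rng=track_rng,
        )
    return RepliSeqResult(tracks["early"], tracks["mid"], tracks["late"], gates, fractions)


def edu_intensity_timecourse(
    genome: GenomeSpec,
    origins: Sequence[OriginSpec],
    config: SimConfig,
    times: Sequence[float],
) -> list[tuple[float, float]]:
    """Mean cumulative EdU incorporation (replicated fraction) at each time.

    Emulates the flow-cytometry readout of cells released from HU in the
    continuous presence of EdU and harvested over a time course.
    """
    cells = [CellRealization(genome, origins, config, rng) for rng in _cell_rngs(config, config.n_cells, stream=3)]
    return [(float(t), float(np.mean([c.replicated_fraction(t) for c in cells]))) for t in times]


# ---------------------------------------------------------------------------
# DNA combing fibers
# ---------------------------------------------------------------------------


def simulate_fibers(
    config: SimConfig,
    protocol: Literal["speed", "restart"],
    n_fibers: int,
    rng: np.random.Generator | None = None,
    stall_fraction: float | None = None,
) -> list[Fiber]:
    """Simulate combed DNA fibers (coordinates in kb).

    ``speed`` protocol (HU sync, CldU 20 min, IdU 20 min): origin-centered
    fibers with a central CldU segment of 2*v*cldu_pulse flanked by IdU
    segments of v*idu_pulse per side; a per-side stall draw truncates a
    flank to a fraction of its full length (uniform by default, or the
    fixed ``stall_fraction``; a truncation to zero omits the segment).

    ``restart`` protocol (CldU 20 min, HU 1 h, IdU 20 min): single-fork
    fibers with a CldU segment followed by an IdU segment of v*idu_pulse
    if the fork restarts after the block, absent if restart fails, and
    shortened by ``restart_delay`` if restart is delayed.
    """
    if n_fibers <= 0:
        raise ValueError("n_fibers must be > 0")
    if protocol not in ("speed", "restart"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed + 3333))
    v = config.fork_speed
    fibers: list[Fiber] = []

    def jitter(length: float) -> float:
        if length <= 0:
            return 0.0
        if config.fiber_noise_sd <= 0:
            return length
        return max(0.05, length + rng.normal(0.0, config.fiber_noise_sd))

    for i in range(n_fibers):
        segments: list[tuple[str, float, float]] = []
        if protocol == "speed":
            cldu_len = jitter(2.0 * v * config.cldu_pulse)
            flanks = []
            for _ in ("left", "right"):
                full = v * config.idu_pulse
                if rng.random() < config.stall_prob:
                    frac = stall_fraction if stall_fraction is not None else rng.uniform()
                    full *= frac
                flanks.append(jitter(full))
            left, right = flanks
            x = 10.0
            if left > 0:
                segments.append(("IdU", x, x + left))
            x += left
            segments.append(("CldU", x, x + cldu_len))
            x += cldu_len
            if right > 0:
                segments.append(("IdU", x, x + right))
        else:
            cldu_len = jitter(v * config.cldu_pulse)
            x = 10.0
            segments.append(("CldU", x, x + cldu_len))
            x += cldu_len
            if rng.random() >= config.restart_fail_prob:
                idu_len = jitter(v * max(0.0, config.idu_pulse - config.restart_delay))
                if idu_len > 0:
                    segments.append(("IdU", x, x + idu_len))
        fibers.append(Fiber(fiber_id=f"f{i:05d}", segments=segments, units="kb"))
    return fibers


# ---------------------------------------------------------------------------
# Ground truth I/O and default scenario
# ---------------------------------------------------------------------------


def write_origins_bed(origins: Sequence[OriginSpec], path: str | Path) -> None:
    """BED6 truth file: 0-based half-open point intervals, class in the name
    field (':stress' suffix for stress-activated), efficiency*1000 as score."""
    with open(path, "w") as fh:
        for o in origins:
            name = o.cls + (":stress" if o.stress_activated else "")
            fh.write(f"{o.chrom}\t{o.pos}\t{o.pos + 1}\t{name}\t{round(o.efficiency * 1000)}\t.\n")


def read_origins_bed(path: str | Path) -> list[OriginSpec]:
    """Read a truth BED back into OriginSpecs.

    Firing-time parameters are not representable in BED; they are
    restored from the per-class defaults, so origin sets built with those
    defaults round-trip exactly.
    """
    origins = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, _end, name, score, _strand = line.split("\t")[:6]
        cls, _, flag = name.partition(":")
        d = CLASS_DEFAULTS[cls]
        origins.append(
            OriginSpec(
                chrom,
                int(start),
                cls,  # type: ignore[arg-type]
                d["firing_time_mean"],
                d["firing_time_sd"],
                int(score) / 1000.0,
                stress_activated=(flag == "stress"),
            )
        )
    return origins


def write_domains_bed(domains: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.timing}\n")


def write_truth(origins: Sequence[OriginSpec], domains: Sequence | None, out_dir: str | Path) -> None:
    """Write origin (and optionally domain) ground truth as BED files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_origins_bed(origins, out / "origins_truth.bed")
    if domains is not None:
        write_domains_bed(domains, out / "domains_truth.bed")


def _distribute(n: int, k: int, phase: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if (i + phase) % k < rem else 0) for i in range(k)]


def default_origin_set(
    genome: GenomeSpec | None = None,
    n_early: int = 20,
    n_late: int = 20,
    n_dormant: int = 20,
    dormant_offset: int = 40_000,
) -> list[OriginSpec]:
    """The default planted origin map for the toy genome.

    Firing (early/late) origins are laid out evenly along each chromosome,
    alternating early and late. Dormant origins are backups parked near an
    early origin (``dormant_offset`` downstream) so that, in an
    unperturbed S phase, the early origin's fork passively replicates them
    before their late clocks ring; extra dormant origins (when there are
    more dormant than early origins on a chromosome) sit mid-way between
    firing origins.
    """
    genome = genome or default_genome()
    k = len(genome.chroms)
    ne, nl, nd = _distribute(n_early, k, 0), _distribute(n_late, k, 1), _distribute(n_dormant, k, 2)
    origins: list[OriginSpec] = []
    for c, (chrom, length) in enumerate(genome.chroms):
        n_firing = ne[c] + nl[c]
        positions = [(i + 1) * length // (n_firing + 1) for i in range(n_firing)]
        classes: list[str] = []
        e_left, l_left = ne[c], nl[c]
        for i in range(n_firing):
            if (i % 2 == 0 and e_left > 0) or l_left == 0:
                classes.append("early")
                e_left -= 1
            else:
                classes.append("late")
                l_left -= 1
        for pos, cls in zip(positions, classes):
            origins.append(OriginSpec.with_class_defaults(chrom, pos, cls))  # type: ignore[arg-type]
        early_pos = [p for p, cl in zip(positions, classes) if cl == "early"]
        placed = 0
        for p in early_pos:
            if placed >= nd[c]:
                break
            origins.append(OriginSpec.with_class_defaults(chrom, p + dormant_offset, "dormant", True))
            placed += 1
        gap_i = 0
        while placed < nd[c] and gap_i < n_firing - 1:
            mid = (positions[gap_i] + positions[gap_i + 1]) // 2 + 7_000
            origins.append(OriginSpec.with_class_defaults(chrom, mid, "dormant", True))
            placed += 1
            gap_i += 1
    return origins
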