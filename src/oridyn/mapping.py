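"""Origin calling: per-assay peaks, merged origin list, classes, and domains.

The mapping strategy combines three genome-wide signals: CDT-1 ChEC-seq
(origin licensing), TRES-1 ChEC-seq (origin firing), and EdU-seq at the
moment of release from an HU block (nucleotide incorporation at origins
that fire at S-phase onset). Peaks are called per assay on normalized,
control-subtracted, smoothed tracks; summits are pooled and collapsed
within a merge window; candidates matching a control peak are removed;
signal matrices around the surviving candidates are clustered (k-means,
k=15 by default) and each cluster is assigned a class from its mean
central enrichment per assay:

* enrichment in all three assays        -> early firing
* CDT-1 and TRES-1 only                 -> late firing
* CDT-1 only                            -> dormant (licensed, non-firing)
* EdU only, or nothing above background -> discarded

Replication-timing domains are maximal constant-sign runs of the
early-minus-late Repli-seq score, subject to a minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .tracks import SignalTrack, extract_matrix, metaplot

Assay = Literal["CDT1", "TRES1", "EDU", "CONTROL"]
ASSAYS: tuple[str, ...] = ("CDT1", "TRES1", "EDU")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int           # bp, half-open
    end: int
    summit: int          # bp
    height: float
    assay: Assay

    def __post_init__(self) -> None:
        if not (self.start < self.end and self.start <= self.summit < self.end):
            raise ValueError("require start <= summit < end and start < end")
        if self.height <= 0:
            raise ValueError("peak height must be > 0")


@dataclass
class OriginCall:
    chrom: str
    pos: int                              # merged summit
    enrichment: dict[str, float] = field(default_factory=dict)
    cluster_id: int | None = None
    cls: Literal["early", "late", "dormant", "discarded"] | None = None


@dataclass(frozen=True)
class ReplicationDomain:
    chrom: str
    start: int
    end: int
    timing: Literal["early", "late"]

    @property
    def length(self) -> int:
        return self.end - self.start


def call_peaks(
    track: SignalTrack,
    z: float = 3.0,
    min_width: int = 2,
    merge_gap: int = 2,
    assay: Assay = "CDT1",
    threshold: float | None = None,
) -> list[Peak]:
    """Threshold-and-run peak calling on a processed track.

    The threshold defaults to mean + z*sd of the positive bins genome-wide
    (the positive-bin restriction keeps the noise scale meaningful on
    control-subtracted tracks, whose baseline can sit below zero). Peaks
    are maximal runs of bins above threshold; runs separated by at most
    ``merge_gap`` sub-threshold bins are joined, and joined runs shorter
    than ``min_width`` bins are dropped. The summit is the leftmost
    maximum bin (reported at the bin center).
    """
    if threshold is None:
        values = track.values()
        pos = values[values > 0]
        if len(pos) == 0:
            return []
        threshold = float(pos.mean() + z * pos.std())
    peaks: list[Peak] = []
    bs = track.bin_size
    for chrom in track.genome.names:
        vec = track.data[chrom]
        above = vec > threshold
        if not above.any():
            continue
        idx = np.nonzero(above)[0]
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        for a, b in runs:
            if b - a + 1 < min_width:
                continue
            seg = vec[a : b + 1]
            summit_bin = a + int(np.argmax(seg))
            peaks.append(
                Peak(
                    chrom,
                    a * bs,
                    (b + 1) * bs,
                    summit_bin * bs + bs // 2,
                    float(seg.max()),
                    assay,
                )
            )
    return peaks


def central_enrichment(
    track: SignalTrack, chrom: str, pos: int, half_window: int = 5_000
) -> float:
    """Mean signal over the central +/- half_window around a position."""
    bs = track.bin_size
    vec = track.data[chrom]
    lo = max(0, (pos - half_window) // bs)
    hi = min(len(vec), (pos + half_window) // bs + 1)
    return float(vec[lo:hi].mean())


def merge_peak_lists(
    peak_lists: dict[str, list[Peak]],
    control_peaks: Sequence[Peak] = (),
    window: int = 5_000,
    tracks: dict[str, SignalTrack] | None = None,
) -> list[OriginCall]:
    """Pool per-assay summits into a unified candidate origin list.

    Summits within ``window`` bp of each other collapse to one candidate
    positioned at the summit of the highest contributing peak; candidates
    within ``window`` of any control peak are removed (MNase/genomic-DNA
    artifacts). When ``tracks`` are given, per-assay central enrichment at
    each candidate is recorded. The operation is idempotent: merging its
    own output changes nothing.
    """
    pooled = sorted(
        (p for peaks in peak_lists.values() for p in peaks),
        key=lambda p: -p.height,
    )
    candidates: list[tuple[str, int]] = []
    for p in pooled:
        if any(c == p.chrom and abs(s - p.summit) <= window for c, s in candidates):
            continue
        candidates.append((p.chrom, p.summit))
    candidates = [
        (c, s)
        for c, s in candidates
        if not any(cp.chrom == c and abs(cp.summit - s) <= window for cp in control_peaks)
    ]
    candidates.sort()
    calls = []
    for chrom, pos in candidates:
        enr = {}
        if tracks:
            enr = {a: central_enrichment(t, chrom, pos) for a, t in tracks.items()}
        calls.append(OriginCall(chrom, pos, enr))
    return calls


def cluster_origins(
    matrices: dict[str, np.ndarray], k: int = 15, seed: int = 0
) -> np.ndarray:
    """k-means clustering of per-origin signal profiles across assays.

    Each assay's matrix is z-scored per column across origins (so every
    position offset contributes comparably and assays with different
    dynamic ranges mix fairly), missing values are set to 0 after scaling,
    and the per-assay blocks are concatenated into one feature row per
    origin. k-means++ initialization with a fixed random state makes the
    labeling reproducible.
    """
    mats = list(matrices.values())
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("assay matrices must be row-aligned to the same origin list")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of origins ({n})")
    blocks = []
    for m in mats:
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(m, axis=0)
            sd = np.nanstd(m, axis=0)
        sd[~(sd > 0)] = 1.0
        zb = (m - mu) / sd
        blocks.append(np.nan_to_num(zb, nan=0.0))
    features = np.hstack(blocks)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(features)


def cluster_mean_enrichments(
    matrices: dict[str, np.ndarray],
    labels: np.ndarray,
    res: int = 1_000,
    central_half: int = 5_000,
) -> dict[int, dict[str, float]]:
    """Per-cluster, per-assay mean signal over the central +/- central_half
    of the (unscaled) profiles."""
    out: dict[int, dict[str, float]] = {}
    for assay, m in matrices.items():
        n_cols = m.shape[1]
        mid = n_cols // 2
        w = max(1, central_half // res)
        central = m[:, mid - w : mid + w]
        for cid in np.unique(labels):
            rows = central[labels == cid]
            with np.errstate(invalid="ignore"):
                val = float(np.nanmean(rows)) if rows.size else 0.0
            out.setdefault(int(cid), {})[assay] = 0.0 if np.isnan(val) else val
    return out


def assign_classes(
    labels: np.ndarray,
    cluster_enrichments: dict[int, dict[str, float]],
    background_cutoff: float | dict[str, float],
) -> list[str]:
    """Map clusters to origin classes by which assays exceed background.

    CDT-1 & TRES-1 & EdU -> early; CDT-1 & TRES-1 -> late; CDT-1 only ->
    dormant; anything else (EdU-only clusters — incorporation without an
    origin factor footprint — and all-background clusters) -> discarded.
    """
    def cut(assay: str) -> float:
        if isinstance(background_cutoff, dict):
            return background_cutoff[assay]
        return background_cutoff

    cluster_cls: dict[int, str] = {}
    for cid, enr in cluster_enrichments.items():
        c = enr.get("CDT1", 0.0) > cut("CDT1")
        t = enr.get("TRES1", 0.0) > cut("TRES1")
        e = enr.get("EDU", 0.0) > cut("EDU")
        if c and t and e:
            cluster_cls[cid] = "early"
        elif c and t:
            cluster_cls[cid] = "late"
        elif c and not t and not e:
            cluster_cls[cid] = "dormant"
        else:
            cluster_cls[cid] = "discarded"
    return [cluster_cls[int(l)] for l in labels]


def call_domains(
    early_track: SignalTrack, late_track: SignalTrack, min_length: int = 50_000
) -> list[ReplicationDomain]:
    """Early/late replication-timing domains from Repli-seq fraction tracks.

    Per bin, score = early - late; domains are maximal constant-sign runs
    spanning at least ``min_length`` bp (zero-score bins break runs).
    Domains never overlap, so early and late domains partition disjoint
    base-pair sets.
    """
    if early_track.bin_size != late_track.bin_size:
        raise ValueError("bin-size mismatch between early and late tracks")
    if early_track.genome.chroms != late_track.genome.chroms:
        raise ValueError("genome mismatch between early and late tracks")
    bs = early_track.bin_size
    domains: list[ReplicationDomain] = []
    lengths = early_track.genome.lengths
    for chrom in early_track.genome.names:
        score = early_track.data[chrom] - late_track.data[chrom]
        sign = np.sign(score)
        i = 0
        while i < len(sign):
            s = sign[i]
            j = i
            while j < len(sign) and sign[j] == s:
                j += 1
            if s != 0:
                start = i * bs
                end = min(j * bs, lengths[chrom])
                if end - start >= min_length:
                    domains.append(
                        ReplicationDomain(chrom, start, end, "early" if s > 0 else "late")
                    )
            i = j
    return domains


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class MappingResult:
    calls: list[OriginCall]                  # all candidates, classified
    peaks: dict[str, list[Peak]]
    matrices: dict[str, np.ndarray]
    cutoffs: dict[str, float]

    @property
    def origins(self) -> list[OriginCall]:
        """Candidates retained as origins (early/late/dormant)."""
        return [c for c in self.calls if c.cls != "discarded"]


def robust_noise_cutoff(track: SignalTrack, z: float = 3.0) -> float:
    """Background cutoff for class assignment: median + z * robust sd.

    The noise scale is estimated from the median absolute deviation
    (MAD * 1.4826), which is insensitive to the sparse signal bins, so the
    cutoff tracks the background of control-subtracted tracks rather than
    the peaks sitting on it.
    """
    values = track.values()
    if len(values) == 0:
        return 0.0
    med = float(np.median(values))
    mad_sd = 1.4826 * float(np.median(np.abs(values - med)))
    return med + z * mad_sd


def map_origins(
    sample_tracks: dict[str, SignalTrack],
    control_track: SignalTrack,
    z: float = 3.0,
    min_width: int = 2,
    merge_gap: int = 2,
    merge_window: int = 5_000,
    k: int = 15,
    half_window: int = 25_000,
    cluster_half_window: int = 10_000,
    seed: int = 0,
) -> MappingResult:
    """Run the full origin-mapping pipeline from raw binned tracks.

    ``sample_tracks`` must provide the keys CDT1, TRES1 and EDU; all four
    tracks (plus control) are normalized to the same total, the control is
    subtracted bin-wise, tracks are smoothed with the 5-bin window, peaks
    are called and merged, profiles are clustered, and classes assigned.

    Profile matrices span ``half_window`` (the 50-kb metaplot convention)
    but clustering uses only the central ``cluster_half_window`` columns:
    origin-discriminating signal is concentrated within ~10 kb of the
    summit, and the flanking columns would otherwise let k-means partition
    on background noise.
    """
    from .tracks import normalize_total, smooth, subtract_control

    order = [a for a in ASSAYS if a in sample_tracks]
    if set(order) != set(ASSAYS):
        raise ValueError(f"sample_tracks must contain {ASSAYS}")
    normed = normalize_total([sample_tracks[a] for a in order] + [control_track])
    control = smooth(normed[-1])
    processed = {a: smooth(subtract_control(t, normed[-1])) for a, t in zip(order, normed)}
    peaks = {a: call_peaks(processed[a], z, min_width, merge_gap, assay=a) for a in order}
    control_peaks = call_peaks(control, z, min_width, merge_gap, assay="CONTROL")
    calls = merge_peak_lists(peaks, control_peaks, merge_window, tracks=processed)
    if not calls:
        return MappingResult([], peaks, {}, {})
    anchors = [(c.chrom, c.pos) for c in calls]
    res = processed[order[0]].bin_size
    matrices = {a: extract_matrix(processed[a], anchors, half_window, res) for a in order}
    mid = half_window // res
    w = cluster_half_window // res
    central = {a: m[:, mid - w : mid + w] for a, m in matrices.items()}
    labels = cluster_origins(central, k=min(k, len(calls)), seed=seed)
    cutoffs = {a: robust_noise_cutoff(processed[a]) for a in order}
    enr = cluster_mean_enrichments(matrices, labels, res=res)
    classes = assign_classes(labels, enr, cutoffs)
    for call, label, cls in zip(calls, labels, classes):
        call.cluster_id = int(label)
        call.cls = cls  # type: ignore[assignment]
    return MappingResult(calls, peaks, matrices, cutoffs)


__all__ = [
    "Peak",
    "OriginCall",
    "ReplicationDomain",
    "call_peaks",
    "merge_peak_lists",
    "cluster_origins",
    "cluster_mean_enrichments",
    "assign_classes",
    "call_domains",
    "central_enrichment",
    "map_origins",
    "MappingResult",
    "robust_noise_cutoff",
    "metaplot",
]
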