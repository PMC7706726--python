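# Methods

## The replication model

S phase is modeled per cell on a fixed genome with a planted set of
origins. Each origin carries a class (early, late, dormant), a firing
efficiency (probability of being competent in a given cell), and a firing
clock drawn from a Normal distribution truncated at zero (per-origin mean
and sd, in minutes). A fired origin launches two forks that move outward
at a constant speed *v* (default 1.5 kb/min, the value measured by DNA
combing in embryonic cells). Forks terminate where they meet a converging
fork or an already-replicated region, so every base is replicated exactly
once per cell; an origin whose locus is replicated before its clock rings
is *passively replicated* and never fires. Forks may stall: a per-fork
Bernoulli draw (probability `stall_prob`) arrests the fork after it has
traveled the arrest distance δ.

Hydroxyurea is modeled as *fire-then-arrest*: origins fire on schedule
under HU, but their forks arrest after at most δ (default 2 kb). This
choice — rather than suppressing firing — reflects the short EdU-labeled
fork movements observed flanking early origins immediately after release
from an HU block, and it makes the characteristic double peak of early
EdU-seq signal an emergent property of the model. δ is a free parameter:
how far forks travel under nucleotide depletion before arresting is not
an experimentally pinned quantity.

Two engines implement these kinematics:

* `CellRealization` — a closed-form engine for free-running S phase.
  Firing decisions resolve passive silencing in clock order; fork extents
  at any time are exact expressions of the pairwise competition between
  facing forks of consecutive fired origins (equal speeds, stall caps,
  chromosome ends). Extents are non-decreasing in time, so pulse-labeled
  intervals are differences of extents at two times, and the completion
  time of a cell has a closed form. On evenly spaced origins (spacing
  *s*) that all fire at t = 0 with no stalls, completion time is exactly
  *s*/(2*v*) — the identity the origin-count estimator inverts.
* an event-driven engine for the HU protocol (`run_edu_protocol`), whose
  fork trajectories are piecewise linear across the block, release, and
  pulse phases. Events are phase boundaries and firings; between events,
  collisions between facing forks are resolved analytically, so the
  engine has no time-discretization error.

At HU release, each arrested fork fails to restart permanently with
probability `restart_fail_prob`; surviving forks (and forks created
later) draw a fresh stall. During the EdU pulse, HU is present again:
every active fork re-arrests after at most δ within the pulse, and every
base replicated during the pulse window is labeled. The composition of
restart failure and stalling at the release boundary is a modeling choice
(the simplest memoryless one); only their marginal rates matter for the
readouts used here.

Genotype presets set the two fault rates: WT uses 0.02/0.02
(stall/restart-failure), the H3.3-null mode 0.30/0.70, encoding the
interpretation that loss of the replication-independent H3 variant
impairs fork progression and, above all, fork restart after arrest.
Explicitly passed values always override the preset.

## Why the mutant signature emerges

Stress-activated dormant origins are parked ~40 kb from an early origin
and given late, broad clocks (mean 50 min, sd 20 min after release). In a
WT cell the early origin's fork, restarted at release, sweeps through the
dormant locus after ~25 minutes and silences it, so at a late EdU pulse
(release + 60 min) almost nothing is replicating at dormant centers. When
restart fails (H3.3-null mode), the sweep never happens: the dormant
origin fires on its own late clock, and with appreciable probability that
clock rings inside the pulse window — EdU accumulates exactly at the
dormant origin centers. The signature is therefore a *consequence* of the
restart-failure parameter, not a painted-on effect. It is measured on
library-normalized, control-subtracted tracks (the pipeline's standard
signal); because the WT value is a background-subtracted near-zero, the
reported ratio floors its denominator at 0.1 reads/bin.

## Synthetic data generation

* **ChEC-seq**: each origin emits a Gaussian peak (sd 2 kb) of expected
  read mass 250 per origin over a flat Poisson background of 4 reads per
  1-kb bin. CDT-1 (licensing) marks all origins; TRES-1 (firing) marks
  early and late origins and, under temperature stress only,
  stress-activated dormant origins at 0.3× amplitude — licensed backups
  visibly recruited to firing only under stress. The peak:background
  budget puts ~20 % of the library into peaks, in the range of a clean
  enrichment experiment, and keeps library-size normalization from
  distorting sample-versus-control backgrounds.
* **EdU-seq / Repli-seq read sampling**: per-bin counts are
  Poisson(depth · share + background), where *share* is the per-cell mean
  fraction of the bin's bases labeled during the pulse (depth 50 per
  fully labeled bin). ChEC/EdU tracks use 1-kb bins, Repli-seq 10-kb
  bins.
* **Repli-seq gating**: each of the `n_cells` (default 50) cells gets a
  uniform elapsed S-phase time; its replicated fraction *f* yields a
  noisy DNA content 2C(1 + f) + ε, ε ~ N(0, 0.05·2C), gated at content
  thresholds equivalent to f = 1/3 and 2/3 into exactly one of
  early/mid/late. Because fork merging slows late S phase, more cells sit
  at high *f*; the late gate is correspondingly the largest.
* **Fibers**: the speed protocol produces origin-centered fibers (central
  CldU segment 2·v·20 kb, IdU flanks v·20 kb per side, per-side stall
  draws truncating a flank at a uniform point); the restart protocol
  produces single forks whose IdU segment is absent when restart fails.
  Segment lengths carry Gaussian measurement noise (sd 0.8 kb), an
  unbiased stand-in for optical measurement error; a flank truncated to
  zero is emitted as an absent segment and scored as an unpaired
  structure by the measurement step.
* **Default scenario**: 3 chromosomes × 5 Mb, 60 origins (20 early, 20
  late, 20 dormant), firing origins evenly spaced and alternating
  early/late (~360 kb spacing), dormant origins attached 40 kb downstream
  of early origins (extras mid-gap). Efficiencies: early 0.98, late 0.90,
  dormant 0.90 under stress (0 at baseline). Late clocks N(20, 5) min
  from release, so late origins fire after the t = 0 EdU pulse ends —
  which is what makes them *late* in the three-assay classification.
  All sizes keep the full pipeline under a few seconds on one CPU.

All randomness flows from `SimConfig.seed` through per-cell
`SeedSequence` substreams; identical configurations reproduce tracks and
fibers bit for bit.

### What the generator does not emulate

Mappability and GC biases, fragment-size effects, replicate-to-replicate
variability, chromatin context (the gene annotation is a uniform tiling),
licensing variability beyond a scalar efficiency, and fine-grained fork
dynamics (speed heterogeneity along the molecule, fork reversal).
Passing tests demonstrate that the analysis recovers what this idealized
generative process planted — positional accuracy, class separation,
unbiasedness of the estimators — not that it is robust to every artifact
of real sequencing data.

## Analysis pipeline choices

* Coordinates are 0-based, half-open; bin *i* covers
  [i·bin, (i+1)·bin). Processing order: merge → normalize to the smallest
  library → subtract the matched control per bin (negatives retained) →
  smooth with a centered 5-bin window that shrinks at chromosome edges.
  Shrink-mean smoothing slightly inflates the genome-wide sum when edge
  bins are non-zero; the alternative (constant 1/window weights) would
  instead leak mass off the ends. Edge bins here are background, so the
  distinction is immaterial in practice.
* **Peak calling** re-implements a threshold-and-run caller with explicit
  parameters: threshold = mean + z·sd over positive bins (z = 3), runs
  joined across gaps ≤ 2 bins, runs < 2 bins dropped, summit = leftmost
  maximum bin. The published analyses used external tools whose
  parameters are not recoverable; a stated, tested rule replaces them.
* **Merging**: summits pooled across assays, collapsed within a 5-kb
  window to the summit of the highest peak, candidates within 5 kb of a
  control peak removed. The operation is idempotent.
* **Clustering and classes**: per-origin profiles (per-assay, column
  z-scored) are clustered with k-means (k = 15, fixed seed, k-means++,
  n_init = 10). Clustering uses only the central ±10 kb of the 50-kb
  profile matrices: the discriminating signal lives within ~10 kb of the
  summit, and including the flanking columns lets k-means partition on
  background noise instead. Cluster → class mapping is automated by a
  threshold rule on the cluster-mean central (±5 kb) enrichments, with a
  robust per-assay background cutoff (median + 3·MAD-sd of all bins — the
  MAD is insensitive to the sparse peak bins). A manual merge of
  similar clusters, as in interactive heatmap workflows, is replaced by
  this stated rule for reproducibility. EdU-only candidates survive to
  classification and are discarded there: incorporation without a
  licensing-factor footprint is not an origin.
* **Domains**: per 10-kb bin, score = early − late; domains are maximal
  constant-sign runs ≥ 50 kb; zero bins break runs. Early and late
  domains are disjoint by construction.
* **Metrics**: half-height width interpolates linearly between bin
  centers around the summit and returns NaN when the peak does not rise
  above background. Enrichment-versus-random excludes the summit bin from
  the random draws (its deterministic limit is the window mean excluding
  the summit). List overlap uses fixed genome tiling (two positions
  overlap when floor(pos/5 kb) matches), making the overlap count
  symmetric; a distance mode is available behind a flag.
* **Origin-count estimator**: N = G/(2·T·v). With the printed reference
  inputs for a ~100.3-Mb nematode genome (T ≈ 40 min, v ≈ 1.5 kb/min) it
  yields ≈ 836 origins; the plateau rule for T (mean of the two largest
  intensities, first sampled time reaching 95 % of it, minus the first
  time with any incorporation) quantizes T to the sampling grid, so
  estimates inherit one-sampling-interval resolution.
* **Fibers**: speeds are measured per flank (not per fiber average);
  symmetry uses flank ratio > 1.5 with the shorter flank clamped at
  0.5 kb; the unpaired t-test defaults to Welch's form, which does not
  assume equal variances — the pooled Student form sits behind a flag.
  The 2 kb/µm conversion is exposed as a parameter, not hard-coded.

## Numerical notes and limitations

* Exactness: single-origin intervals, forced-arrest caps, converging-fork
  midpoints, and the completion-time identity s/(2v) are exact (no grid);
  ties between simultaneously arriving forks resolve to the leftmost
  origin, a measure-zero convention.
* `k` for clustering is capped at the number of candidates; degenerate
  inputs (all-zero tracks, empty peak lists, all-zero time courses)
  return empty results or NaN sentinels rather than raising, except where
  an input is structurally invalid (bin-size mismatch, out-of-genome
  positions), which raises `ValueError`.
* Recovery statistics: sensitivity counts planted firing origins with a
  retained call within 2 kb; a call is false when no planted origin of
  any class is within 2 kb; class accuracy is scored over planted origins
  matched by their nearest call.
* The background cutoffs, peak-caller z, and clustering window are method
  parameters with stated defaults; they were chosen to separate
  background from the generator's emission scales and are expected to
  need re-tuning on real libraries with different depth or noise
  structure.
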