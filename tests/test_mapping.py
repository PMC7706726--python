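import numpy as np
import pytest

from oridyn import (
    GenomeSpec,
    Peak,
    assign_classes,
    call_domains,
    call_peaks,
    cluster_origins,
    merge_peak_lists,
)
from conftest import track_from

G7 = GenomeSpec((("chrA", 7_000),))


class TestCallPeaks:
    def test_run_rule_with_explicit_threshold(self):
        t = track_from(G7, 1000, chrA=[0, 0, 4, 9, 4, 0, 0])
        peaks = call_peaks(t, threshold=3.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end) == (2000, 5000)
        assert p.summit == 3500  # center of bin 3
        assert p.height == 9

    def test_merge_gap_joins_nearby_runs(self):
        t = track_from(G7, 1000, chrA=[0, 5, 0, 5, 5, 0, 0])
        peaks = call_peaks(t, threshold=3.0, merge_gap=2)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (1000, 5000)

    def test_min_width_drops_short_runs(self):
        t = track_from(G7, 1000, chrA=[0, 5, 0, 0, 0, 0, 0])
        assert call_peaks(t, threshold=3.0, merge_gap=0, min_width=2) == []

    def test_all_zero_track_yields_empty_list(self):
        assert call_peaks(track_from(G7, 1000), assay="EDU") == []

    def test_summit_leftmost_on_ties(self):
        t = track_from(G7, 1000, chrA=[0, 0, 7, 7, 7, 0, 0])
        (p,) = call_peaks(t, threshold=3.0)
        assert p.summit == 2500

    def test_matches_bruteforce_rescan_on_noise(self):
        genome = GenomeSpec((("chrA", 500_000),))
        rng = np.random.default_rng(42)
        vec = rng.poisson(5, 500).astype(float)
        t = track_from(genome, 1000, chrA=vec)
        z, merge_gap, min_width = 3.0, 2, 2
        pos = vec[vec > 0]
        thr = pos.mean() + z * pos.std()
        # independent oracle: scan runs above threshold directly
        expected = []
        i = 0
        while i < len(vec):
            if vec[i] > thr:
                j = i
                while j + 1 < len(vec):
                    nxt = next((k for k in range(j + 1, len(vec)) if vec[k] > thr), None)
                    if nxt is not None and nxt - j - 1 <= merge_gap:
                        j = nxt
                    else:
                        break
                if j - i + 1 >= min_width:
                    expected.append((i, j))
                i = j + 1
            else:
                i += 1
        called = call_peaks(t, z=z, min_width=min_width, merge_gap=merge_gap)
        assert [(p.start // 1000, p.end // 1000 - 1) for p in called] == expected


class TestMergePeakLists:
    @staticmethod
    def peak(summit, height=10.0, chrom="chrA", assay="CDT1"):
        return Peak(chrom, summit - 500, summit + 500, summit, height, assay)

    def test_nearby_summits_collapse_to_highest(self):
        calls = merge_peak_lists(
            {"CDT1": [self.peak(10_000, 12.0)], "TRES1": [self.peak(11_000, 8.0, assay="TRES1")]},
            window=5_000,
        )
        assert len(calls) == 1 and calls[0].pos == 10_000

    def test_control_peak_removes_candidate(self):
        calls = merge_peak_lists(
            {"CDT1": [self.peak(10_000)]},
            control_peaks=[self.peak(9_500, assay="CONTROL")],
            window=5_000,
        )
        assert calls == []

    def test_distant_summits_stay_separate(self):
        calls = merge_peak_lists(
            {"CDT1": [self.peak(10_000), self.peak(50_000)]}, window=5_000
        )
        assert [c.pos for c in calls] == [10_000, 50_000]

    def test_idempotent(self):
        first = merge_peak_lists(
            {"CDT1": [self.peak(10_000, 12.0), self.peak(13_000, 7.0), self.peak(40_000, 5.0)]},
            window=5_000,
        )
        again = merge_peak_lists(
            {"MERGED": [self.peak(c.pos, 1.0) for c in first]}, window=5_000
        )
        assert [c.pos for c in again] == [c.pos for c in first]


class TestClusterOrigins:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, size=(4, 6))
        b = rng.normal(5.0, 0.1, size=(4, 6))
        m = {"CDT1": np.vstack([a, b])}
        labels = cluster_origins(m, k=2, seed=0)
        # oracle: exhaustive best 2-partition of 8 points by within-cluster SS
        pts = np.vstack([a, b])
        pts = (pts - pts.mean(0)) / pts.std(0)
        best, best_ss = None, np.inf
        for mask in range(1, 2**7):  # fix point 0 in cluster 0
            assign = np.array([0] + [(mask >> i) & 1 for i in range(7)])
            ss = sum(
                ((pts[assign == c] - pts[assign == c].mean(0)) ** 2).sum()
                for c in (0, 1)
                if (assign == c).any()
            )
            if ss < best_ss:
                best, best_ss = assign, ss
        same = (labels[:, None] == labels[None, :])
        same_oracle = (best[:, None] == best[None, :])
        assert np.array_equal(same, same_oracle)

    def test_k_one_groups_everything(self):
        m = {"CDT1": np.random.default_rng(1).normal(size=(5, 4))}
        assert set(cluster_origins(m, k=1, seed=0)) == {0}

    def test_duplicate_rows_share_cluster(self):
        base = np.random.default_rng(2).normal(size=(3, 4))
        m = {"CDT1": np.vstack([base, base[0]])}
        labels = cluster_origins(m, k=3, seed=0)
        assert labels[0] == labels[3]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_origins({"CDT1": np.zeros((3, 4))}, k=5)

    def test_reproducible_under_seed(self):
        m = {"CDT1": np.random.default_rng(3).normal(size=(30, 10))}
        l1 = cluster_origins(m, k=5, seed=7)
        l2 = cluster_origins(m, k=5, seed=7)
        assert np.array_equal(l1, l2)


class TestAssignClasses:
    def test_rules(self):
        enr = {
            0: {"CDT1": 5.0, "TRES1": 4.0, "EDU": 3.0},
            1: {"CDT1": 5.0, "TRES1": 4.0, "EDU": 0.2},
            2: {"CDT1": 5.0, "TRES1": 0.3, "EDU": 0.2},
            3: {"CDT1": 0.2, "TRES1": 0.2, "EDU": 4.0},
            4: {"CDT1": 0.1, "TRES1": 0.1, "EDU": 0.1},
        }
        labels = np.array([0, 1, 2, 3, 4])
        assert assign_classes(labels, enr, 1.0) == [
            "early",
            "late",
            "dormant",
            "discarded",
            "discarded",
        ]

    def test_per_assay_cutoffs(self):
        enr = {0: {"CDT1": 5.0, "TRES1": 4.0, "EDU": 3.0}}
        cuts = {"CDT1": 1.0, "TRES1": 1.0, "EDU": 10.0}
        assert assign_classes(np.array([0]), enr, cuts) == ["late"]


class TestCallDomains:
    G = GenomeSpec((("chrA", 40_000),))

    def test_sign_runs_become_domains(self):
        early = track_from(self.G, 10_000, chrA=[10, 10, 0, 0])
        late = track_from(self.G, 10_000, chrA=[0, 0, 10, 10])
        doms = call_domains(early, late, min_length=20_000)
        assert [(d.start, d.end, d.timing) for d in doms] == [
            (0, 20_000, "early"),
            (20_000, 40_000, "late"),
        ]

    def test_equal_tracks_give_no_domains(self):
        t = track_from(self.G, 10_000, chrA=[5, 5, 5, 5])
        assert call_domains(t, t, min_length=10_000) == []

    def test_min_length_filters_alternating_bins(self):
        early = track_from(self.G, 10_000, chrA=[10, 0, 10, 0])
        late = track_from(self.G, 10_000, chrA=[0, 10, 0, 10])
        assert call_domains(early, late, min_length=50_000) == []

    def test_bin_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bin-size"):
            call_domains(
                track_from(self.G, 10_000), track_from(self.G, 5_000), min_length=10_000
            )

    def test_domains_disjoint_on_random_scores(self):
        rng = np.random.default_rng(5)
        early = track_from(self.G, 10_000, chrA=rng.poisson(5, 4))
        late = track_from(self.G, 10_000, chrA=rng.poisson(5, 4))
        doms = call_domains(early, late, min_length=10_000)
        ivs = sorted((d.start, d.end) for d in doms)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
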