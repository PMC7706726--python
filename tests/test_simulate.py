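import math

import numpy as np
import pytest

from oridyn import (
    GenomeSpec,
    OriginSpec,
    SimConfig,
    default_origin_set,
    read_origins_bed,
    run_edu_protocol,
    sample_track,
    simulate_chec_track,
    simulate_fibers,
    simulate_repliseq,
    simulate_sphase,
    write_origins_bed,
)

GENOME_1MB = GenomeSpec((("chrA", 1_000_000),))


def origin(pos, cls="early", mean=0.0, sd=0.0, eff=1.0, chrom="chrA", stress=False):
    return OriginSpec(chrom, pos, cls, mean, sd, eff, stress)


class TestSPhaseKinematics:
    def test_single_origin_interval_exact(self):
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=0.0, fork_speed=1.0)
        res = simulate_sphase(GENOME_1MB, [origin(500_000)], cfg, 10.0)
        assert res.intervals(0) == [("chrA", 490_000.0, 510_000.0)]

    def test_converging_forks_meet_at_midpoint(self):
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=0.0, fork_speed=1.0)
        res = simulate_sphase(GENOME_1MB, [origin(400_000), origin(500_000)], cfg, 200.0)
        trajs = {(t.origin_index, t.direction): t.extent_bp for t in res.trajectories(0)}
        assert trajs[(0, 1)] == pytest.approx(50_000.0)  # inner forks split the gap
        assert trajs[(1, -1)] == pytest.approx(50_000.0)
        # the gap is replicated exactly once: one merged interval
        ivs = res.intervals(0)
        assert len(ivs) == 1 and ivs[0][1] == 200_000.0 and ivs[0][2] == 700_000.0

    def test_forced_arrest_caps_interval(self):
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=1.0, hu_arrest_distance=5.0, fork_speed=1.0)
        for t_end in (10.0, 500.0):
            res = simulate_sphase(GENOME_1MB, [origin(500_000)], cfg, t_end)
            assert res.intervals(0) == [("chrA", 495_000.0, 505_000.0)]

    def test_passive_replication_silences_origin(self):
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=0.0, fork_speed=1.0)
        late = origin(510_000, cls="late", mean=20.0)  # fork arrives at t=10 < 20
        res = simulate_sphase(GENOME_1MB, [origin(500_000), late], cfg, 100.0)
        fired = {t.origin_index for t in res.trajectories(0)}
        assert fired == {0}

    def test_conservation_and_monotonicity(self, toy_genome, toy_origins):
        cfg = SimConfig(seed=5, n_cells=3)
        res = simulate_sphase(toy_genome, toy_origins, cfg, 60.0)
        for cell in res.cells:
            prev = 0.0
            for t in (0, 10, 20, 40, 80, 160):
                f = cell.replicated_fraction(t)
                assert f >= prev - 1e-12
                prev = f
                by_chrom = {}
                for c, a, b in cell.replicated_intervals(t):
                    assert a <= b
                    by_chrom.setdefault(c, []).append((a, b))
                for ivs in by_chrom.values():
                    ivs.sort()
                    assert all(x[1] <= y[0] + 1e-6 for x, y in zip(ivs, ivs[1:]))

    def test_full_completion_without_stalls(self):
        genome = GenomeSpec((("chrA", 100_000), ("chrB", 50_000)))
        oris = [origin(50_000), origin(25_000, chrom="chrB")]
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=0.0, fork_speed=1.0)
        res = simulate_sphase(genome, oris, cfg, 10_000.0)
        assert res.cells[0].replicated_fraction(10_000.0) == pytest.approx(1.0)
        assert math.isfinite(res.cells[0].completion_time())

    def test_formula_closure_exact(self):
        spacing, v = 120_000, 1.5
        genome = GenomeSpec((("chrA", 10 * spacing),))
        oris = [origin(int((i + 0.5) * spacing)) for i in range(10)]
        cfg = SimConfig(seed=0, n_cells=1, stall_prob=0.0, fork_speed=v)
        cell = simulate_sphase(genome, oris, cfg, 100.0).cells[0]
        assert cell.completion_time() == spacing / 1000.0 / (2 * v)

    def test_invalid_inputs_rejected(self):
        cfg = SimConfig(seed=0, n_cells=1)
        with pytest.raises(ValueError):
            simulate_sphase(GENOME_1MB, [origin(2_000_000)], cfg, 10.0)
        with pytest.raises(ValueError):
            simulate_sphase(GENOME_1MB, [origin(1)], cfg, -1.0)


class TestEdUProtocol:
    def test_release_zero_labels_flank_early_origins(self):
        oris = [origin(300_000), origin(700_000)]
        cfg = SimConfig(seed=1, n_cells=4, stall_prob=0.0, restart_fail_prob=0.0)
        labels = run_edu_protocol(GENOME_1MB, oris, cfg, 0.0)
        cap = min(cfg.delta_bp, cfg.v_bp * cfg.edu_pulse)
        assert labels.cells and all(cell for cell in labels.cells)
        for seg in labels.all_segments():
            assert seg.end - seg.start <= cap + 1e-6
            center_dist = min(abs((seg.start + seg.end) / 2 - o.pos) for o in oris)
            assert center_dist <= 2 * cfg.delta_bp

    def test_release_after_completion_is_empty(self):
        oris = [origin(500_000)]
        cfg = SimConfig(seed=1, n_cells=3, stall_prob=0.0, restart_fail_prob=0.0)
        labels = run_edu_protocol(GENOME_1MB, oris, cfg, 2_000.0)
        assert labels.all_segments() == []

    def test_restart_failure_silences_early_forks(self):
        early = [origin(200_000), origin(800_000)]
        late = [origin(500_000, cls="late", mean=25.0, sd=3.0)]
        cfg = SimConfig(seed=2, n_cells=10, stall_prob=0.0, restart_fail_prob=1.0)
        labels = run_edu_protocol(GENOME_1MB, early + late, cfg, 30.0)
        for seg in labels.all_segments():
            mid = (seg.start + seg.end) / 2
            assert all(abs(mid - o.pos) > 20_000 for o in early)

    def test_mutant_edu_persists_at_stress_activated_origins(self, toy_genome, toy_origins):
        dormant = [(o.chrom, o.pos) for o in toy_origins if o.cls == "dormant"]

        def mean_at(track, positions, half=2_500):
            vals = []
            for c, p in positions:
                lo = max(0, (p - half) // track.bin_size)
                hi = (p + half) // track.bin_size + 1
                vals.extend(track.data[c][lo:hi])
            return float(np.mean(vals))

        from oridyn import normalize_total, simulate_control_track, subtract_control

        means = {}
        for genotype in ("WT", "H3.3null"):
            cfg = SimConfig(seed=4, condition="stress25", genotype=genotype)
            labels = run_edu_protocol(toy_genome, toy_origins, cfg, 60.0)
            raw = sample_track(labels, toy_genome, cfg)
            ctrl = simulate_control_track(toy_genome, cfg)
            nt, nc = normalize_total([raw, ctrl])
            means[genotype] = mean_at(subtract_control(nt, nc), dormant)
        assert means["H3.3null"] >= 2.0 * means["WT"]


class TestSampleTrack:
    def test_no_labels_no_background_is_zero(self, small_genome):
        cfg = SimConfig(seed=0, background_rate=0.0)
        t = sample_track([], small_genome, cfg)
        assert not t.values().any()

    def test_monte_carlo_mean_matches_closed_form(self, small_genome):
        from oridyn import LabeledSegment

        cfg = SimConfig(seed=0, read_depth=40.0, background_rate=3.0)
        segs = [LabeledSegment("chrA", 1_000, 1_500, "EdU")]  # half of bin 1
        rng = np.random.default_rng(123)
        n = 1000
        sums = np.zeros(10)
        for _ in range(n):
            sums += sample_track(segs, small_genome, cfg, rng=rng).data["chrA"]
        mean = sums / n
        expected = np.full(10, 3.0)
        expected[1] += 40.0 * 0.5
        se = np.sqrt(expected / n)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)

    def test_total_reads_match_expectation(self, small_genome):
        cfg = SimConfig(seed=0, background_rate=2.0)
        rng = np.random.default_rng(7)
        n = 1000
        totals = [sample_track([], small_genome, cfg, rng=rng).total_reads for _ in range(n)]
        expected = 2.0 * 15  # 15 bins across both chromosomes
        se = math.sqrt(expected / n)
        assert abs(np.mean(totals) - expected) <= 3 * se

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec((("chrA", 0),))


class TestChecTracks:
    def test_dormant_origin_silent_in_tres1_at_baseline(self):
        o = origin(500_000, cls="dormant", mean=50.0, eff=0.9, stress=True)
        cfg = SimConfig(seed=0, condition="baseline20")
        cdt1 = simulate_chec_track([o], "CDT1", GENOME_1MB, cfg, noise=False)
        tres1 = simulate_chec_track([o], "TRES1", GENOME_1MB, cfg, noise=False)
        assert cdt1.data["chrA"][500] > cfg.background_rate
        assert np.allclose(tres1.data["chrA"], cfg.background_rate)

    def test_stress_activates_dormant_tres1_signal(self):
        o = origin(500_000, cls="dormant", mean=50.0, eff=0.9, stress=True)
        cfg = SimConfig(seed=0, condition="stress25")
        tres1 = simulate_chec_track([o], "TRES1", GENOME_1MB, cfg, noise=False)
        assert tres1.data["chrA"][500] > cfg.background_rate

    def test_noise_free_summit_within_one_bin(self):
        cfg = SimConfig(seed=0)
        t = simulate_chec_track([origin(123_456)], "CDT1", GENOME_1MB, cfg, noise=False)
        assert abs(int(np.argmax(t.data["chrA"])) - 123) <= 1


class TestRepliSeqGating:
    def test_every_cell_gated_exactly_once(self, toy_genome, toy_origins):
        cfg = SimConfig(seed=6, n_cells=30)
        rep = simulate_repliseq(toy_genome, toy_origins, cfg)
        assert len(rep.gates) == cfg.n_cells
        assert set(rep.gates) <= {"early", "mid", "late"}

    def test_low_fraction_gates_early(self):
        # content 2*(1+0.05) = 2.1 is far below the first threshold 8/3
        assert 2.0 * 1.05 < 2.0 * (1 + 1 / 3)

    def test_early_origin_region_enriched_in_early_fraction(self):
        genome = GenomeSpec((("chrA", 2_000_000),))
        oris = [
            origin(500_000, cls="early", mean=0.0, sd=1.0, eff=1.0),
            origin(1_500_000, cls="late", mean=40.0, sd=5.0, eff=1.0),
        ]
        cfg = SimConfig(seed=8, n_cells=200, stall_prob=0.0)
        rep = simulate_repliseq(genome, oris, cfg)
        bin_of = 500_000 // cfg.repliseq_bin_size
        w = 3
        early_sig = rep.early.data["chrA"][bin_of - w : bin_of + w + 1].mean()
        late_sig = rep.late.data["chrA"][bin_of - w : bin_of + w + 1].mean()
        assert early_sig > late_sig

    def test_requires_a_firing_origin(self):
        o = origin(500_000, cls="dormant", mean=50.0, eff=0.9)
        with pytest.raises(ValueError):
            simulate_repliseq(GENOME_1MB, [o], SimConfig(seed=0))


class TestTruthIO:
    def test_round_trip(self, toy_origins, tmp_path):
        p = tmp_path / "origins.bed"
        write_origins_bed(toy_origins, p)
        assert read_origins_bed(p) == toy_origins

    def test_point_convention(self, tmp_path):
        p = tmp_path / "o.bed"
        write_origins_bed([OriginSpec.with_class_defaults("chrA", 1234, "early")], p)
        chrom, start, end, name = p.read_text().split("\t")[:4]
        assert (chrom, int(start), int(end), name) == ("chrA", 1234, 1235, "early")

    def test_empty_list_gives_empty_body(self, tmp_path):
        p = tmp_path / "o.bed"
        write_origins_bed([], p)
        assert p.read_text() == ""


class TestDeterminism:
    def test_identical_seed_reproduces_tracks_and_fibers(self, toy_genome, toy_origins):
        outs = []
        for _ in range(2):
            cfg = SimConfig(seed=11)
            labels = run_edu_protocol(toy_genome, toy_origins, cfg, 30.0)
            outs.append(
                (
                    sample_track(labels, toy_genome, cfg),
                    simulate_chec_track(toy_origins, "TRES1", toy_genome, cfg),
                    simulate_fibers(cfg, "speed", 25),
                )
            )
        (t1, c1, f1), (t2, c2, f2) = outs
        assert t1 == t2 and c1 == c2 and f1 == f2

    def test_default_origin_set_counts(self, toy_origins):
        from collections import Counter

        counts = Counter(o.cls for o in toy_origins)
        assert counts == {"early": 20, "late": 20, "dormant": 20}
        assert all(o.stress_activated for o in toy_origins if o.cls == "dormant")
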