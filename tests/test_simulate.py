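"""Synthetic genome / read simulator: determinism, planted truth, moments."""

import numpy as np
import pytest

from insertmap._seq import revcomp
from insertmap.simulate import (
    RepeatFamilySpec,
    build_synthetic_genome,
    plant_insertions,
    score_detection,
    simulate_junction_reads,
    simulate_position_reads,
)

from conftest import make_sim_config


class TestBuildGenome:
    def test_fixed_seed_is_byte_identical(self):
        fams = [RepeatFamilySpec("A", 500, 3, 0.05)]
        g1 = build_synthetic_genome(fams, [20_000], seed=5)
        g2 = build_synthetic_genome(fams, [20_000], seed=5)
        assert g1.contigs == g2.contigs
        assert g1.repeat_annotation == g2.repeat_annotation

    def test_zero_families_gives_empty_annotation(self):
        g = build_synthetic_genome([], [5_000], seed=1)
        assert g.repeat_annotation == ()
        assert len(g.contigs["contig1"]) == 5_000

    def test_zero_divergence_copies_are_identical(self):
        g = build_synthetic_genome([RepeatFamilySpec("R", 800, 2, 0.0)], [20_000], seed=2)
        seqs = [g.contigs[iv.contig][iv.start:iv.end] for iv in g.repeat_annotation]
        assert len(seqs) == 2 and seqs[0] == seqs[1]

    def test_divergence_matches_binomial_expectation(self):
        # brute-force per-copy Hamming distance against the stored consensus
        g = build_synthetic_genome([RepeatFamilySpec("R", 1000, 6, 0.05)], [40_000], seed=3)
        cons = g.repeat_consensus["R"]
        sd = np.sqrt(1000 * 0.05 * 0.95)
        for iv in g.repeat_annotation:
            copy = g.contigs[iv.contig][iv.start:iv.end]
            dist = sum(a != b for a, b in zip(copy, cons))
            assert abs(dist - 50) <= 3 * sd

    def test_repeats_that_do_not_fit_raise(self):
        with pytest.raises(ValueError, match="fit"):
            build_synthetic_genome([RepeatFamilySpec("R", 5_000, 3, 0.0)], [10_000], seed=1)


class TestPlantInsertions:
    def test_n_zero_leaves_truth_unchanged(self, small_genome):
        assert plant_insertions(small_genome, 0, "LV", 0.5, seed=9) is small_genome

    def test_fraction_one_all_sites_in_repeats(self):
        g = build_synthetic_genome([RepeatFamilySpec("R", 1500, 5, 0.0)], [40_000], seed=4)
        g = plant_insertions(g, 10, "LV", 1.0, seed=5, min_distance=100)
        for ins in g.truth_insertions:
            assert any(
                iv.contig == ins.contig and iv.start <= ins.site < iv.end
                for iv in g.repeat_annotation
            )

    def test_fraction_half_brute_force_overlap_count(self):
        g = build_synthetic_genome([RepeatFamilySpec("R", 1500, 12, 0.0)], [120_000], seed=6)
        g = plant_insertions(g, 50, "LV", 0.5, seed=7, min_distance=300)
        n_in = sum(
            any(iv.contig == i.contig and iv.start <= i.site < iv.end
                for iv in g.repeat_annotation)
            for i in g.truth_insertions
        )
        assert len(g.truth_insertions) == 50
        assert n_in == 25

    def test_sites_are_distinct(self, small_genome):
        sites = [(i.contig, i.site) for i in small_genome.truth_insertions]
        assert len(sites) == len(set(sites))


class TestJunctionReads:
    def test_noiseless_read_is_exact_concatenation(self, unique_genome):
        cfg = make_sim_config(reads_per_site=1, length_sd=0.0, length_mean=300, seed=11)
        reads, truth = simulate_junction_reads(unique_genome, cfg)
        row = truth.iloc[0]
        read = next(r for r in reads if r.id == row["read_id"])
        ins = next(
            i for i in unique_genome.truth_insertions
            if i.contig == row["contig"] and i.site == row["site"]
        )
        seq = unique_genome.contigs[ins.contig]
        flank = (
            seq[ins.site:ins.site + 300]
            if ins.strand == "+"
            else revcomp(seq[ins.site - 300:ins.site])
        )
        expected = cfg.adapter + cfg.barcodes["BC01"] + row["umi"] + cfg.payload_end + flank
        assert read.bases in (expected, revcomp(expected))

    def test_read_count_conservation(self, unique_genome):
        cfg = make_sim_config(reads_per_site=None, n_reads=500, seed=12)
        reads, truth = simulate_junction_reads(unique_genome, cfg)
        assert len(reads) == 500 and len(truth) == 500

    def test_flank_length_moments(self):
        g = build_synthetic_genome([], [200_000], seed=13)
        g = plant_insertions(g, 10, "LV", 0.0, seed=14, min_distance=2000, edge_margin=5000)
        cfg = make_sim_config(length_mean=1000, length_sd=25, reads_per_site=1000, seed=15)
        _, truth = simulate_junction_reads(g, cfg)
        lens = truth.loc[~truth["truncated"], "flank_length"]
        assert len(lens) >= 9_000
        assert abs(lens.mean() - 1000) < 10  # within 1%
        assert abs(lens.std() - 25) < 2.5  # within 10%

    def test_fixed_seed_reads_are_identical(self, unique_genome):
        cfg = make_sim_config(seed=16, error_rates=(0.02, 0.01, 0.01))
        r1, t1 = simulate_junction_reads(unique_genome, cfg)
        r2, t2 = simulate_junction_reads(unique_genome, cfg)
        assert [x.bases for x in r1] == [x.bases for x in r2]
        assert t1.equals(t2)


class TestPositionReads:
    def test_truth_row_count_is_sites_times_replicates(self, unique_genome):
        _, truth = simulate_position_reads(unique_genome, 100, 10, 250, 10, seed=17)
        assert len(truth) == 1000

    def test_zero_sd_gives_exact_lengths(self, unique_genome):
        reads, _ = simulate_position_reads(unique_genome, 20, 2, 250, 0, seed=18)
        interior = [r for r in reads if len(r.bases) == 250]
        assert len(interior) >= 35  # all but contig-edge truncations

    def test_length_sd_recovered(self):
        g = build_synthetic_genome([], [300_000], seed=19)
        reads, _ = simulate_position_reads(g, 1000, 10, 250, 10, seed=20)
        lens = np.array([len(r.bases) for r in reads])
        lens = lens[lens > 200]  # exclude edge truncations
        assert abs(lens.std() - 10) < 1.0

    def test_positions_do_not_depend_on_length_setting(self, unique_genome):
        _, t1 = simulate_position_reads(unique_genome, 30, 3, 250, 10, seed=21)
        _, t2 = simulate_position_reads(unique_genome, 30, 3, 3000, 25, seed=21)
        assert t1[["replicate", "contig", "position", "strand"]].equals(
            t2[["replicate", "contig", "position", "strand"]]
        )


class TestScoreDetection:
    def _truth(self):
        import pandas as pd

        return pd.DataFrame(
            {"replicate": [0, 0, 0], "contig": ["c", "c", "c"], "position": [100, 500, 900]}
        )

    def test_exact_calls_detect_everything(self):
        t = score_detection(self._truth(), [("c", 100), ("c", 500), ("c", 900)], 20)
        assert t["detected"].all()

    def test_empty_calls_detect_nothing(self):
        t = score_detection(self._truth(), [], 20)
        assert not t["detected"].any()

    def test_tolerance_boundary(self):
        # call at truth+tol detected; at truth+tol+1 not (explicit distances)
        for tol in (0, 5, 20):
            t = score_detection(self._truth(), [("c", 100 + tol)], tol)
            assert bool(t["detected"][0])
            t = score_detection(self._truth(), [("c", 100 + tol + 1)], tol)
            assert not bool(t["detected"][0])

    def test_detection_monotone_in_tolerance(self, rng):
        import pandas as pd

        truth = pd.DataFrame(
            {"replicate": 0, "contig": "c", "position": rng.integers(0, 10_000, 50)}
        )
        calls = [("c", int(p)) for p in rng.integers(0, 10_000, 30)]
        rates = [
            score_detection(truth, calls, tol)["detected"].mean()
            for tol in (0, 10, 50, 200, 1000)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_missed_sites_classified_by_repeat(self, small_genome):
        import pandas as pd

        iv = small_genome.repeat_annotation[0]
        truth = pd.DataFrame(
            {
                "replicate": [0, 0],
                "contig": [iv.contig, iv.contig],
                "position": [(iv.start + iv.end) // 2, iv.end + 5_000],
            }
        )
        t = score_detection(truth, [], 20, genome=small_genome)
        assert t["missed_repeat_class"].tolist() == ["LINE_A", "non-repeat"]
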