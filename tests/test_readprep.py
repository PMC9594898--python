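"""Read preparation: QC thresholds, structure extraction, UMI clustering, consensus."""

import numpy as np
import pytest

from insertmap._seq import revcomp
from insertmap.readprep import (
    ProcessedRead,
    RawRead,
    cluster_umis,
    consensus,
    demultiplex_and_extract,
    quality_length_filter,
    UmiCluster,
)
from insertmap.simulate import simulate_junction_reads

from conftest import ADAPTER, BARCODES, PAYLOAD_END, make_sim_config


def _levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance (test oracle, independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _infix_distance(pattern: str, text: str) -> int:
    """Best edit distance of pattern against any substring of text (DP oracle)."""
    prev = [0] * (len(text) + 1)  # free start in text
    for i, ca in enumerate(pattern, 1):
        cur = [i]
        for j, cb in enumerate(text, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return min(prev)


def _read(rid, bases, q=20):
    return RawRead(rid, bases, (q,) * len(bases))


class TestQualityLengthFilter:
    def test_boundaries_are_strict(self):
        at_len = _read("a", "A" * 200, q=15)  # length == 200: removed
        at_q = _read("b", "A" * 201, q=10)  # mean Q == 10: removed
        passing = _read("c", "A" * 201, q=11)
        kept = quality_length_filter([at_len, at_q, passing], 10, 200)
        assert [r.id for r in kept] == ["c"]

    def test_empty_stream(self):
        assert quality_length_filter([], 10, 200) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            quality_length_filter([], -1, 200)


class TestDemultiplexExtract:
    def test_noiseless_roundtrip_recovers_umi_and_fragment(self, unique_genome, structure):
        cfg = make_sim_config(reads_per_site=5, seed=31)
        reads, truth = simulate_junction_reads(unique_genome, cfg)
        raw = [RawRead(r.id, r.bases, r.qualities) for r in reads]
        processed, rejects = demultiplex_and_extract(raw, structure)
        assert rejects == {}
        truth_by_id = truth.set_index("read_id")
        assert len(processed) == len(reads)
        for p in processed:
            row = truth_by_id.loc[p.id]
            assert p.umi == row["umi"]
            assert p.barcode_id == row["barcode"]
            assert len(p.fragment) == row["flank_length"]

    def test_missing_payload_rejected_with_reason(self, structure):
        bases = ADAPTER + BARCODES["BC01"] + "A" * 12 + "C" * 300
        processed, rejects = demultiplex_and_extract([_read("x", bases)], structure)
        assert processed == [] and rejects == {"no payload": 1}

    def test_missing_adapter_rejected(self, structure):
        processed, rejects = demultiplex_and_extract([_read("x", "ACGT" * 100)], structure)
        assert processed == [] and rejects == {"no adapter": 1}

    def test_ambiguous_barcode_rejected(self):
        from insertmap.readprep import ReadStructure

        st = ReadStructure(
            adapter=ADAPTER,
            barcodes={"B1": "AAAATTTT", "B2": "AAAACTTT"},  # 2 edits apart
            umi_length=8,
            payload_end=PAYLOAD_END,
            barcode_max_edits=1,
        )
        # observed barcode equidistant (1 edit) from both catalogue entries
        bases = ADAPTER + "AAAAGTTT" + "C" * 8 + PAYLOAD_END + "G" * 100
        _, rejects = demultiplex_and_extract([_read("x", bases)], st)
        assert rejects == {"ambiguous barcode": 1}

    @pytest.mark.parametrize("n_subs,accepted", [(0, True), (1, True), (2, True), (3, False)])
    def test_adapter_error_tolerance_matches_dp_oracle(self, n_subs, accepted):
        from insertmap.readprep import ReadStructure

        adapter20 = "ACGTACGGTTCAGATCCATG"
        st = ReadStructure(
            adapter=adapter20, barcodes={"BC01": BARCODES["BC01"]}, umi_length=12,
            payload_end=PAYLOAD_END, max_error_fraction=0.10,
        )
        mutated = list(adapter20)
        for i in range(n_subs):
            pos = 3 + 5 * i
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        mutated = "".join(mutated)
        bases = mutated + BARCODES["BC01"] + "A" * 12 + PAYLOAD_END + "GATC" * 60
        processed, rejects = demultiplex_and_extract([_read("x", bases)], st)
        # oracle: exhaustive infix edit distance vs the integer tolerance floor(0.1*20)
        oracle_accept = _infix_distance(adapter20, bases) <= int(0.10 * 20)
        assert oracle_accept == accepted
        assert (len(processed) == 1) == accepted

    def test_reverse_complement_read_yields_same_fragment(self, structure):
        frag = "GATTACA" * 40
        bases = ADAPTER + BARCODES["BC02"] + "ACGTACGTACGT" + PAYLOAD_END + frag
        fwd, _ = demultiplex_and_extract([_read("f", bases)], structure)
        rev, _ = demultiplex_and_extract([_read("r", revcomp(bases))], structure)
        assert fwd[0].fragment == rev[0].fragment == frag
        assert fwd[0].umi == rev[0].umi


def _proc(rid, umi, fragment, q=20):
    return ProcessedRead(rid, "BC01", umi, fragment, (q,) * len(fragment), "fwd", float(q))


class TestClusterUmis:
    def test_identical_reads_form_one_cluster(self, rng):
        from insertmap._seq import random_seq

        frag = random_seq(rng, 200)
        clusters = cluster_umis([_proc("a", "AAACCCGGGTTT", frag), _proc("b", "AAACCCGGGTTT", frag)])
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_distant_umis_from_distinct_loci_split(self, rng):
        from insertmap._seq import random_seq

        clusters = cluster_umis(
            [
                _proc("a", "AAAAAAAAAAAA", random_seq(rng, 200)),
                _proc("b", "AAAAAAAATTTT", random_seq(rng, 200)),
            ]
        )
        assert len(clusters) == 2

    def test_matches_connected_components_oracle(self):
        # ten reads engineered into three well-separated molecule groups
        rng = np.random.default_rng(42)
        from insertmap._seq import random_seq

        frags = [random_seq(rng, 150) for _ in range(3)]
        umis = ["AAAACCCCGGGG", "TTTTGGGGCCCC", "ACACACACACAC"]
        reads = []
        for g in range(3):
            for j in range(4 if g == 0 else 3):
                umi = list(umis[g])
                if j == 1:
                    umi[0] = "T" if umi[0] != "T" else "G"  # 1 edit: still joins
                reads.append(_proc(f"r{g}_{j}", "".join(umi), frags[g]))
        clusters = cluster_umis(reads)

        # oracle: connected components under (UMI dist <= 1 AND identity >= 0.9)
        def identity(a, b):
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            return 1 - min(
                _levenshtein(short, long_[i:i + len(short)])
                for i in range(len(long_) - len(short) + 1)
            ) / len(short)

        import networkx as nx

        gph = nx.Graph()
        gph.add_nodes_from(r.id for r in reads)
        for i, a in enumerate(reads):
            for b in reads[i + 1:]:
                if _levenshtein(a.umi, b.umi) <= 1 and identity(a.fragment, b.fragment) >= 0.9:
                    gph.add_edge(a.id, b.id)
        oracle = {frozenset(c) for c in nx.connected_components(gph)}
        ours = {frozenset(c.member_ids) for c in clusters}
        assert ours == oracle

    def test_partition_property(self, unique_genome, structure):
        cfg = make_sim_config(reads_per_site=6, seed=33, error_rates=(0.01, 0.0, 0.0))
        reads, _ = simulate_junction_reads(unique_genome, cfg)
        raw = [RawRead(r.id, r.bases, r.qualities) for r in reads]
        kept = quality_length_filter(raw, 10, 200)
        processed, rejects = demultiplex_and_extract(kept, structure)
        clusters = cluster_umis(processed)
        assert sum(rejects.values()) + sum(c.size for c in clusters) == len(kept)
        # every read in exactly one cluster
        ids = [m for c in clusters for m in c.member_ids]
        assert len(ids) == len(set(ids)) == len(processed)

    @pytest.mark.parametrize("k", [1, 7, 50])
    def test_duplication_leaves_cluster_count_invariant(self, rng, k):
        from insertmap._seq import random_seq

        reads = [_proc(f"r{i}", random_seq(rng, 12), random_seq(rng, 150)) for i in range(6)]
        base = cluster_umis(reads)
        dup = reads + [
            ProcessedRead(f"dup{j}", "BC01", reads[2].umi, reads[2].fragment,
                          reads[2].fragment_qualities, "fwd", reads[2].mean_quality)
            for j in range(k)
        ]
        after = cluster_umis(dup)
        assert len(after) == len(base)
        sizes_before = sorted(c.size for c in base)
        sizes_after = sorted(c.size for c in after)
        sizes_after[sizes_after.index(1 + k)] = 1
        assert sorted(sizes_after) == sizes_before


class TestConsensus:
    def _cluster(self, frags, quals=None):
        members = [
            _proc(f"m{i}", "AAAACCCCGGGG", f, q=(quals[i] if quals else 20))
            for i, f in enumerate(frags)
        ]
        return UmiCluster("AAAACCCCGGGG", [m.id for m in members], members)

    def test_identical_fragments_return_verbatim(self):
        c = self._cluster(["ACGTACGTAC"] * 4)
        assert consensus(c) == "ACGTACGTAC"

    def test_single_substitution_outvoted(self):
        c = self._cluster(["ACGTACGTAC", "ACGTACGTAC", "ACGAACGTAC"])
        assert consensus(c) == "ACGTACGTAC"

    def test_matches_column_majority_oracle(self):
        rng = np.random.default_rng(7)
        from insertmap._seq import mutate, random_seq

        truth = random_seq(rng, 150)
        frags = [mutate(truth, 0.05, rng) for _ in range(21)]
        c = self._cluster(frags)
        got = consensus(c)
        # oracle: per-column plurality over equal-length substitution-only members
        from collections import Counter

        oracle = "".join(
            Counter(f[i] for f in frags).most_common(1)[0][0] for i in range(150)
        )
        assert sum(a != b for a, b in zip(got, oracle)) == 0
        assert sum(a != b for a, b in zip(got, truth)) <= 2  # plurality repairs noise
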