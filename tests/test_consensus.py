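"""Consensus construction, presence filter, prioritization, TF screen."""

import numpy as np
import pytest

from sescreen import (
    GeneAnnotation,
    GenomicInterval,
    SampleSECalls,
    ScreenConfig,
    StitchedRegion,
    aggregate_and_prioritize,
    assign_genes,
    build_consensus,
    filter_presence,
    normalize_intensity,
    screen_tfs,
)
from sescreen.consensus import ConsensusMember, ConsensusSE


def make_calls(sample_id, regions_spec):
    """regions_spec: list of (chrom, start, end, signal, is_super)."""
    regions = []
    order = sorted(
        range(len(regions_spec)),
        key=lambda i: (-regions_spec[i][3], regions_spec[i][0], regions_spec[i][1]),
    )
    rank_of = {i: r + 1 for r, i in enumerate(order)}
    for i, (chrom, start, end, signal, is_super) in enumerate(regions_spec):
        iv = GenomicInterval(chrom, start, end)
        regions.append(
            StitchedRegion(iv, [iv], signal=signal, rank=rank_of[i], is_super=is_super)
        )
    return SampleSECalls(sample_id, regions, cutoff_index=1, cutoff_value=0.0)


class TestNormalizeIntensity:
    def test_division_by_sample_max(self):
        calls = make_calls("a", [
            ("chr1", 0, 100, 10.0, False),
            ("chr1", 1000, 1100, 5.0, False),
            ("chr1", 2000, 2100, 100.0, True),
        ])
        intensities = normalize_intensity(calls)
        assert sorted(intensities.values()) == pytest.approx([0.05, 0.10, 1.00])

    def test_single_region_is_one(self):
        calls = make_calls("a", [("chr1", 0, 100, 42.0, True)])
        assert list(normalize_intensity(calls).values()) == [1.0]

    def test_all_zero_signals_degenerate(self):
        calls = make_calls("a", [("chr1", 0, 100, 0.0, False), ("chr1", 500, 600, 0.0, False)])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_intensity(calls)


class TestBuildConsensus:
    def test_overlap_chaining(self):
        calls = [
            make_calls("A", [("chr1", 0, 10000, 10.0, True)]),
            make_calls("B", [("chr1", 9000, 20000, 10.0, True)]),
            make_calls("C", [("chr1", 50000, 60000, 10.0, True)]),
        ]
        clusters = build_consensus(calls)
        spans = [(c.interval.start, c.interval.end, c.presence) for c in clusters]
        assert spans == [(0, 20000, 2), (50000, 60000, 1)]

    def test_identical_se_in_nine_samples(self):
        calls = [
            make_calls(f"s{i}", [("chr1", 100, 5000, 10.0, True)]) for i in range(9)
        ]
        (cluster,) = build_consensus(calls)
        assert cluster.presence == 9 and len(cluster.members) == 9

    def test_abutting_ses_do_not_merge(self):
        calls = [
            make_calls("A", [("chr1", 0, 100, 10.0, True)]),
            make_calls("B", [("chr1", 100, 200, 10.0, True)]),
        ]
        assert len(build_consensus(calls)) == 2

    def test_sample_with_two_ses_in_one_cluster_counts_once(self):
        calls = [
            make_calls("A", [("chr1", 0, 1000, 10.0, True), ("chr1", 500, 2000, 8.0, True)]),
            make_calls("B", [("chr1", 900, 1500, 10.0, True)]),
        ]
        (cluster,) = build_consensus(calls)
        assert cluster.presence == 2 and len(cluster.members) == 3

    def test_partition_conserves_members(self):
        rng = np.random.default_rng(17)
        calls = []
        for i in range(6):
            spec = []
            for start in rng.integers(0, 200_000, 15):
                start = int(start)
                spec.append(("chr1", start, start + int(rng.integers(500, 8000)), 10.0, True))
            # avoid zero-signal degenerate + give unique signals
            spec = [(c, s, e, float(10 + j), su) for j, (c, s, e, _, su) in enumerate(spec)]
            calls.append(make_calls(f"s{i}", spec))
        clusters = build_consensus(calls)
        assert sum(len(c.members) for c in clusters) == sum(c.n_se for c in calls)
        for c in clusters:
            assert c.presence == len({m.sample_id for m in c.members})
            assert c.presence <= 6

    def test_only_super_regions_participate(self):
        calls = [
            make_calls("A", [("chr1", 0, 1000, 100.0, True), ("chr1", 5000, 6000, 1.0, False)])
        ]
        (cluster,) = build_consensus(calls)
        assert cluster.interval.start == 0 and len(cluster.members) == 1


class TestFilterPresence:
    def _clusters(self, presences):
        clusters = []
        for i, p in enumerate(presences):
            members = [
                ConsensusMember(f"s{j}", GenomicInterval("chr1", i * 1000, i * 1000 + 100), 1, 1.0)
                for j in range(p)
            ]
            clusters.append(ConsensusSE(GenomicInterval("chr1", i * 1000, i * 1000 + 100), members))
        return clusters

    def test_boundary_six_kept_five_dropped(self):
        clusters = self._clusters([6, 5])
        kept = filter_presence(clusters, ScreenConfig(min_presence=6))
        assert [c.presence for c in kept] == [6]

    def test_min_presence_one_is_identity(self):
        clusters = self._clusters([1, 3, 9])
        assert len(filter_presence(clusters, ScreenConfig(min_presence=1))) == 3

    def test_monotone_in_threshold(self):
        clusters = self._clusters([1, 2, 3, 4, 5, 6, 7, 8, 9])
        counts = [
            len(filter_presence(clusters, ScreenConfig(min_presence=m)))
            for m in range(1, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAggregateAndPrioritize:
    def _cluster(self, start, ranks, intensities):
        members = [
            ConsensusMember(f"s{i}", GenomicInterval("chr1", start, start + 100), r, x)
            for i, (r, x) in enumerate(zip(ranks, intensities))
        ]
        return ConsensusSE(GenomicInterval("chr1", start, start + 100), members)

    def test_mean_of_member_ranks(self):
        (c,) = aggregate_and_prioritize([self._cluster(0, [3, 5, 10], [0.5, 0.5, 0.5])])
        assert c.avg_rank == pytest.approx(6.0)

    def test_intensity_breaks_rank_ties(self):
        weak = self._cluster(0, [2], [0.5])
        strong = self._cluster(5000, [2], [0.9])
        ordered = aggregate_and_prioritize([weak, strong])
        assert ordered[0] is strong and ordered[0].priority == 1

    def test_smallest_avg_rank_gets_priority_one(self):
        clusters = [
            self._cluster(0, [9, 9], [0.2, 0.2]),
            self._cluster(5000, [1, 2], [0.9, 0.8]),
            self._cluster(9000, [4, 4], [0.5, 0.5]),
        ]
        ordered = aggregate_and_prioritize(clusters)
        assert ordered[0].avg_rank == pytest.approx(1.5)
        assert [c.priority for c in ordered] == [1, 2, 3]


class TestAssignGenes:
    def _gene(self, gene_id, tss, is_tf=False, strand="+"):
        body = (
            GenomicInterval("chr1", tss, tss + 1000, strand=strand)
            if strand == "+"
            else GenomicInterval("chr1", tss - 999, tss + 1, strand=strand)
        )
        return GeneAnnotation(gene_id, body, strand, is_tf=is_tf)

    def _cluster(self):
        iv = GenomicInterval("chr1", 100_000, 120_000)
        return ConsensusSE(iv, [ConsensusMember("a", iv, 1, 1.0)])

    def test_downstream_within_window(self):
        (a,) = assign_genes(self._cluster(), [self._gene("G", 130_000)], 50_000)
        assert a.distance == 10_000 and a.is_nearest

    def test_outside_window_not_assigned(self):
        assert assign_genes(self._cluster(), [self._gene("G", 300_000)], 50_000) == []

    def test_tss_inside_distance_zero(self):
        (a,) = assign_genes(self._cluster(), [self._gene("G", 110_000)], 50_000)
        assert a.distance == 0 and a.is_nearest

    def test_upstream_distance_negative_and_nearest_flag(self):
        genes = [self._gene("NEAR", 95_000), self._gene("FAR", 130_000)]
        assignments = assign_genes(self._cluster(), genes, 50_000)
        by_id = {a.gene_id: a for a in assignments}
        assert by_id["NEAR"].distance == -5_000
        assert by_id["NEAR"].is_nearest and not by_id["FAR"].is_nearest


class TestScreenTfs:
    def _pipeline(self, specs, genes):
        clusters = []
        for start, ranks, intensities in specs:
            members = [
                ConsensusMember(f"s{i}", GenomicInterval("chr1", start, start + 10_000), r, x)
                for i, (r, x) in enumerate(zip(ranks, intensities))
            ]
            clusters.append(ConsensusSE(GenomicInterval("chr1", start, start + 10_000), members))
        ordered = aggregate_and_prioritize(clusters)
        for c in ordered:
            assign_genes(c, genes, 50_000)
        return ordered

    def _gene(self, gene_id, tss, is_tf):
        return GeneAnnotation(
            gene_id, GenomicInterval("chr1", tss, tss + 1000, strand="+"), "+", is_tf=is_tf
        )

    def test_only_tfs_reported(self):
        genes = [
            self._gene("A", 105_000, False),
            self._gene("B", 106_000, True),
            self._gene("C", 107_000, False),
        ]
        ordered = self._pipeline([(100_000, [1], [1.0])], genes)
        table = screen_tfs(ordered, genes)
        assert list(table.gene_id) == ["B"]

    def test_best_rank_rule_across_clusters(self):
        genes = [self._gene("TFX", 105_000, True), self._gene("TFX2", 505_000, True)]
        # TFX near both clusters (second cluster far away) -> keeps rank 4 cluster
        ordered = self._pipeline(
            [(100_000, [4], [0.9]), (90_000, [9], [0.5])], [genes[0]]
        )
        table = screen_tfs(ordered, [genes[0]])
        assert len(table) == 1
        assert table.avg_rank.iloc[0] == pytest.approx(4.0)
        assert table.n_clusters.iloc[0] == 2

    def test_no_tf_anywhere_gives_empty_table(self, caplog):
        genes = [self._gene("A", 105_000, False)]
        ordered = self._pipeline([(100_000, [1], [1.0])], genes)
        table = screen_tfs(ordered, genes)
        assert table.empty and list(table.columns)[0] == "gene_id"


class TestOrderInvariance:
    def test_consensus_independent_of_sample_order(self):
        rng = np.random.default_rng(23)
        calls = []
        for i in range(5):
            spec = []
            for start in sorted(int(s) for s in rng.integers(0, 100_000, 10)):
                spec.append(("chr1", start, start + int(rng.integers(500, 6000)),
                             float(rng.gamma(1.5, 100) + 1), True))
            calls.append(make_calls(f"s{i}", spec))

        def run(order):
            clusters = aggregate_and_prioritize(build_consensus([calls[i] for i in order]))
            return [
                (c.interval.start, c.interval.end, c.presence, c.avg_rank,
                 c.avg_intensity, c.priority)
                for c in clusters
            ]

        assert run([0, 1, 2, 3, 4]) == run([4, 2, 0, 3, 1])
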