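"""Region calling and genomic-context partitions against per-base oracles."""

import numpy as np
import pandas as pd
import pytest

from methylcompare import annotate as ann
from methylcompare.io import (
    FragmentSet,
    GeneModelSet,
    GenomeSpec,
    IntervalSet,
    ValidationError,
)

GENE_COLS = ["gene_id", "seq", "strand", "tss", "start", "end", "feature", "pseudogene"]


def per_base_labels(partition, seq, length):
    """Brute-force per-base label array from a partition's intervals."""
    lab = np.full(length, "", dtype=object)
    for label, per_seq in partition.parts.items():
        iv = per_seq.get(seq)
        if iv is None:
            continue
        for s, e in zip(*iv):
            assert (lab[s:e] == "").all(), "overlap between partition labels"
            lab[s:e] = label
    assert (lab != "").all(), "uncovered bases"
    return lab


class TestCallRegions:
    GENOME = GenomeSpec(lengths={"chr1": 100_000})

    def test_overlapping_fragments_merge(self):
        fs = FragmentSet.from_records(
            "s", [("chr1", 100, 300), ("chr1", 200, 400)], genome=self.GENOME
        )
        regions = ann.call_regions(fs, self.GENOME)
        assert list(regions.regions.itertuples(index=False, name=None)) == [
            ("chr1", 100, 400)
        ]

    def test_one_uncovered_base_splits(self):
        fs = FragmentSet.from_records(
            "s", [("chr1", 100, 200), ("chr1", 201, 300)], genome=self.GENOME
        )
        assert len(ann.call_regions(fs, self.GENOME)) == 2

    def test_abutting_fragments_merge(self):
        fs = FragmentSet.from_records(
            "s", [("chr1", 100, 200), ("chr1", 200, 300)], genome=self.GENOME
        )
        regions = ann.call_regions(fs, self.GENOME)
        assert len(regions) == 1

    def test_matches_per_base_coverage_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            starts = rng.integers(0, 99_000, n)
            recs = [("chr1", int(s), int(s) + int(l))
                    for s, l in zip(starts, rng.integers(1, 1_500, n))]
            fs = FragmentSet.from_records("s", recs, genome=self.GENOME)
            regions = ann.call_regions(fs, self.GENOME)
            cov = np.zeros(100_000, dtype=int)
            for _, s, e in recs:
                cov[s:e] += 1
            covered = np.flatnonzero(cov > 0)
            brute = []
            if len(covered):
                breaks = np.flatnonzero(np.diff(covered) > 1)
                starts_b = np.concatenate([[covered[0]], covered[breaks + 1]])
                ends_b = np.concatenate([covered[breaks] + 1, [covered[-1] + 1]])
                brute = list(zip(starts_b, ends_b))
            got = [(s, e) for _, s, e in regions.regions.itertuples(index=False, name=None)]
            assert got == brute


class TestRegionCenter:
    def test_single_base(self):
        assert ann.region_center(100, 101) == 100

    def test_even_length_floor(self):
        assert ann.region_center(100, 104) == 101

    def test_center_always_inside(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 10_000, 10_000)
        lengths = rng.integers(1, 500, 10_000)
        for s, l in zip(starts, lengths):
            c = ann.region_center(int(s), int(s + l))
            assert s <= c < s + l


class TestIslandContext:
    def test_single_island_shore_shelf_layout(self):
        genome = GenomeSpec(lengths={"chr1": 100_000})
        islands = IntervalSet.from_records([("chr1", 10_000, 10_200)])
        part = ann.build_island_context(islands, genome)
        iv = part.parts["shore"]["chr1"]
        assert list(zip(*iv)) == [(8_000, 10_000), (10_200, 12_200)]
        iv = part.parts["shelf"]["chr1"]
        assert list(zip(*iv)) == [(6_000, 8_000), (12_200, 14_200)]

    def test_close_islands_gap_is_all_shore(self):
        genome = GenomeSpec(lengths={"chr1": 100_000})
        islands = IntervalSet.from_records(
            [("chr1", 10_000, 10_500), ("chr1", 11_500, 12_000)]
        )
        part = ann.build_island_context(islands, genome)
        labels = per_base_labels(part, "chr1", 100_000)
        assert (labels[10_500:11_500] == "shore").all()

    def test_partition_covers_genome_exactly(self, genome_fixture):
        genome, islands, _, _ = genome_fixture
        part = ann.build_island_context(islands, genome)
        lengths = part.label_lengths()
        assert sum(lengths.values()) == genome.total_length

    def test_matches_per_base_distance_oracle(self):
        genome = GenomeSpec(lengths={"chr1": 50_000})
        rng = np.random.default_rng(2)
        starts = np.sort(rng.choice(49_000, 5, replace=False))
        recs = [("chr1", int(s), int(s) + int(rng.integers(100, 900))) for s in starts]
        part = ann.build_island_context(IntervalSet.from_records(recs), genome)
        labels = per_base_labels(part, "chr1", 50_000)
        # oracle: distance from each base to nearest island base
        in_island = np.zeros(50_000, dtype=bool)
        for _, s, e in recs:
            in_island[s:e] = True
        pos = np.arange(50_000)
        island_pos = np.flatnonzero(in_island)
        dist = np.min(np.abs(pos[:, None] - island_pos[None, ::50]), axis=1)
        # coarse check on sampled bases (exact oracle below)
        d = np.full(50_000, 10**9)
        for p in island_pos:
            lo, hi = max(0, p - 4_100), min(50_000, p + 4_100)
            d[lo:hi] = np.minimum(d[lo:hi], np.abs(np.arange(lo, hi) - p))
        expect = np.where(
            in_island, "island",
            np.where(d <= 2_000, "shore", np.where(d <= 4_000, "shelf", "open_sea")),
        )
        assert (labels == expect).all()


class TestFunctionalPartition:
    def test_plus_strand_gene_layout(self):
        genome = GenomeSpec(lengths={"chr1": 50_000})
        rows = [
            ("g1", "chr1", "+", 10_000, 10_000, 20_000, "transcript", 0),
            ("g1", "chr1", "+", 10_000, 10_000, 10_600, "exon", 0),
        ]
        genes = GeneModelSet(table=pd.DataFrame(rows, columns=GENE_COLS))
        part = ann.build_functional_partition(genes, genome)
        assert list(zip(*part.parts["promoter"]["chr1"])) == [(8_500, 10_500)]
        assert list(zip(*part.parts["exon"]["chr1"])) == [(10_500, 10_600)]
        assert list(zip(*part.parts["intron"]["chr1"])) == [(10_600, 20_000)]

    def test_minus_strand_promoter_is_mirror_image(self):
        genome = GenomeSpec(lengths={"chr1": 50_000})
        rows = [("g1", "chr1", "-", 39_999, 30_000, 40_000, "transcript", 0)]
        genes = GeneModelSet(table=pd.DataFrame(rows, columns=GENE_COLS))
        part = ann.build_functional_partition(genes, genome)
        # 0.5 kb downstream of the TSS (leftward) through 1.5 kb upstream
        assert list(zip(*part.parts["promoter"]["chr1"])) == [(39_500, 41_500)]

    def test_promoter_clipped_to_genome(self):
        genome = GenomeSpec(lengths={"chr1": 41_000})
        rows = [("g1", "chr1", "-", 39_999, 30_000, 40_000, "transcript", 0)]
        genes = GeneModelSet(table=pd.DataFrame(rows, columns=GENE_COLS))
        part = ann.build_functional_partition(genes, genome)
        assert list(zip(*part.parts["promoter"]["chr1"])) == [(39_500, 41_000)]

    def test_pseudogene_truncated_by_real_gene(self):
        genome = GenomeSpec(lengths={"chr1": 50_000})
        rows = [
            ("g1", "chr1", "+", 10_000, 10_000, 20_000, "transcript", 0),
            ("p1", "chr1", "+", 18_000, 18_000, 25_000, "transcript", 1),
        ]
        genes = GeneModelSet(table=pd.DataFrame(rows, columns=GENE_COLS))
        part = ann.build_functional_partition(genes, genome)
        assert list(zip(*part.parts["pseudogene"]["chr1"])) == [(20_000, 25_000)]

    def test_partition_covers_fixture_genome_exactly(self, genome_fixture):
        genome, _, genes, _ = genome_fixture
        part = ann.build_functional_partition(genes, genome)
        assert sum(part.label_lengths().values()) == genome.total_length
        for seq in genome.names:
            per_base_labels(part, seq, genome.lengths[seq])


class TestAnnotatePosition:
    def test_island_and_boundaries(self):
        genome = GenomeSpec(lengths={"chr1": 100_000})
        islands = IntervalSet.from_records([("chr1", 10_000, 10_200)])
        part = ann.build_island_context(islands, genome)
        assert ann.annotate_position("chr1", 10_100, part) == "island"
        # base exactly 2000 bp left of the island start: last shore base
        assert ann.annotate_position("chr1", 8_000, part) == "shore"
        assert ann.annotate_position("chr1", 7_999, part) == "shelf"
        assert ann.annotate_position("chr1", 5_999, part) == "open_sea"

    def test_out_of_genome_rejected(self):
        genome = GenomeSpec(lengths={"chr1": 100})
        part = ann.build_island_context(IntervalSet.from_records([("chr1", 10, 20)]), genome)
        with pytest.raises(ValidationError):
            ann.annotate_position("chr1", 100, part)

    def test_annotation_independent_of_interval_order(self):
        genome = GenomeSpec(lengths={"chr1": 60_000})
        recs = [("chr1", 10_000, 10_500), ("chr1", 30_000, 30_800), ("chr1", 50_000, 50_100)]
        p1 = ann.build_island_context(IntervalSet.from_records(recs), genome)
        p2 = ann.build_island_context(IntervalSet.from_records(recs[::-1]), genome)
        for pos in (5, 9_000, 10_250, 12_300, 29_000, 40_000, 59_999):
            assert ann.annotate_position("chr1", pos, p1) == ann.annotate_position(
                "chr1", pos, p2
            )


class TestSummaries:
    def test_probe_region_ratio_hand_computed(self):
        genome = GenomeSpec(lengths={"chr1": 100_000})
        fs = FragmentSet.from_records(
            "s", [("chr1", i * 1_000, i * 1_000 + 200) for i in range(10)], genome=genome
        )
        regions = ann.call_regions(fs, genome)
        cov = np.array([1, 0, 2, 0])
        assert ann.probe_region_ratio(cov, regions) == pytest.approx(2 / 10)

    def test_zero_regions_is_error(self):
        genome = GenomeSpec(lengths={"chr1": 1_000})
        regions = ann.call_regions(FragmentSet.from_records("s", [], genome=genome), genome)
        with pytest.raises(ValidationError):
            ann.probe_region_ratio(np.array([1]), regions)

    def test_context_fractions_sum_and_chi_square(self):
        ref = {"island": 0.25, "shore": 0.25, "shelf": 0.25, "open_sea": 0.25}
        fr, chi2, p = ann.context_fractions(["island"] * 100, ref)
        assert fr.sum() == pytest.approx(1.0)
        assert fr["island"] == 1.0
        assert chi2 > 100 and p < 1e-10

    def test_context_fractions_type1_calibration(self):
        rng = np.random.default_rng(4)
        ref = {"a": 0.5, "b": 0.3, "c": 0.2}
        pvals = []
        for _ in range(500):
            labels = rng.choice(list(ref), size=200, p=list(ref.values()))
            _, _, p = ann.context_fractions(labels, ref)
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) < 0.10

    def test_paired_count_comparison(self):
        a = np.arange(1, 71, dtype=float)
        _, p = ann.compare_counts_paired(a, a + 5.0)
        assert p < 0.01
        with pytest.raises(ValidationError):
            ann.compare_counts_paired([1.0], [2.0])
        with pytest.raises(ValidationError):
            ann.compare_counts_paired(a, a)
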