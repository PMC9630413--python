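import pandas as pd
import pytest
from scipy import stats

from amplidiff import (
    GeneSetCollection,
    SimulationDesign,
    assign_nearest_gene,
    co_occupancy,
    fisher_overrepresentation,
    generate_annotation,
    generate_peaks,
    intersect_targets_degs,
    merge_replicate_peaks,
    promoter_windows,
    recurrent_peaks,
)
from amplidiff.containers import GeneAnnotation
from oracles import hypergeom_upper_tail_exact


def peaks(*intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


@pytest.fixture
def annotation():
    return generate_annotation(SimulationDesign(n_genes=200, n_samples=10, target_set_size=20, ifn_set_size=20, seed=3))


class TestMergeRecurrence:
    def test_overlapping_replicate_peaks_fuse_to_union(self):
        merged = merge_replicate_peaks(peaks(("chr1", 100, 200)), peaks(("chr1", 150, 250)))
        assert merged.iloc[0].tolist() == ["chr1", 100, 250]

    def test_disjoint_replicate_peaks_dropped(self):
        merged = merge_replicate_peaks(peaks(("chr1", 100, 200)), peaks(("chr1", 300, 400)))
        assert merged.empty

    def test_recurrence_support_thresholds(self):
        shared = ("chr1", 500, 600)
        sets = [peaks(shared), peaks(("chr1", 510, 620)), peaks(("chr2", 10, 20))] + [
            peaks(("chr1", 5000, 5100)),
            peaks(("chr1", 9000, 9100)),
        ]
        two = recurrent_peaks(sets, min_support=2)
        assert two.iloc[0].tolist() == ["chr1", 500, 620]
        assert len(two) == 1
        one = recurrent_peaks(sets, min_support=1)
        assert len(one) == 4  # per-cluster union of everything

    def test_idempotent_and_order_independent(self, annotation, rng):
        reps = generate_peaks(annotation.gene_ids[:40], annotation, 3, fpr=0.3, seed=9)
        loci = recurrent_peaks(reps, min_support=2)
        again = recurrent_peaks([loci], min_support=1)
        pd.testing.assert_frame_equal(loci, again)
        reversed_loci = recurrent_peaks(list(reversed(reps)), min_support=2)
        pd.testing.assert_frame_equal(loci, reversed_loci)

    def test_background_removed_by_replicate_support(self, annotation):
        targets = annotation.gene_ids[:100]
        rep1, rep2 = generate_peaks(targets, annotation, 2, fpr=0.5, seed=21)
        merged = merge_replicate_peaks(rep1, rep2)
        assigned = assign_nearest_gene(merged, annotation)
        assert set(assigned["gene_id"]) == set(targets)
        assert len(merged) == len(targets)


class TestNearestGene:
    def test_locus_on_tss_is_promoter_distance_zero(self, annotation):
        gene = annotation.table.iloc[5]
        locus = peaks((gene["chrom"], gene["tss"] - 50, gene["tss"] + 50))
        out = assign_nearest_gene(locus, annotation)
        assert out.iloc[0]["gene_id"] == gene["gene_id"]
        assert out.iloc[0]["distance"] == 0
        assert out.iloc[0]["region_class"] == "promoter"

    def test_minimal_tss_distance_wins(self):
        table = pd.DataFrame(
            {
                "gene_id": ["near", "far"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "+"],
                "start": [11_000, 33_000],
                "end": [15_000, 37_000],
                "tss": [11_000, 33_000],
            }
        )
        ann = GeneAnnotation(table, {"chr1": 50_000})
        locus = peaks(("chr1", 9_900, 10_000))  # gaps 1000 vs 23000, not in promoter?
        out = assign_nearest_gene(locus, ann, promoter_upstream=500, promoter_downstream=100)
        assert out.iloc[0]["gene_id"] == "near"
        assert out.iloc[0]["distance"] == 1001
        assert out.iloc[0]["region_class"] == "non-promoter"

    def test_distance_invariant_under_coordinate_shift(self, annotation):
        loci = peaks(("chr1", 40_000, 40_300), ("chr1", 90_000, 90_200))
        base = assign_nearest_gene(loci, annotation)
        shift = 7_777
        shifted_table = annotation.table.copy()
        for col in ("start", "end", "tss"):
            shifted_table[col] += shift
        shifted_ann = GeneAnnotation(
            shifted_table, {c: l + shift for c, l in annotation.chrom_lengths.items()}
        )
        shifted_loci = loci.assign(start=loci["start"] + shift, end=loci["end"] + shift)
        moved = assign_nearest_gene(shifted_loci, shifted_ann)
        assert moved["gene_id"].tolist() == base["gene_id"].tolist()
        assert moved["distance"].tolist() == base["distance"].tolist()

    def test_promoter_windows_strand_aware(self):
        table = pd.DataFrame(
            {
                "gene_id": ["plus", "minus"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "start": [10_000, 50_000],
                "end": [14_000, 54_000],
                "tss": [10_000, 53_999],
            }
        )
        ann = GeneAnnotation(table, {"chr1": 100_000})
        win = promoter_windows(ann, upstream=2000, downstream=500).set_index("gene_id")
        assert win.loc["plus", ["start", "end"]].tolist() == [8_000, 10_501]
        assert win.loc["minus", ["start", "end"]].tolist() == [53_499, 56_000]

    def test_missing_chromosome_errors(self, annotation):
        with pytest.raises(ValueError, match="chrM"):
            assign_nearest_gene(peaks(("chrM", 0, 100)), annotation)

    def test_truth_targets_recovered_exactly(self, annotation, rng):
        targets = list(rng.choice(annotation.gene_ids, size=100, replace=False))
        reps = generate_peaks(targets, annotation, 2, fpr=0.0, seed=5)
        merged = merge_replicate_peaks(*reps)
        out = assign_nearest_gene(merged, annotation)
        assert set(out["gene_id"]) == set(targets)
        assert (out["region_class"] == "promoter").all()


class TestCoOccupancy:
    def test_identical_sets_fully_co_occupied(self):
        a = peaks(("chr1", 10, 50), ("chr1", 100, 150))
        hits, counts = co_occupancy(a, a.copy())
        assert len(hits) == 2
        assert counts == {"a_overlapping_b": 2, "b_overlapping_a": 2}

    def test_disjoint_sets_empty(self):
        hits, counts = co_occupancy(peaks(("chr1", 10, 50)), peaks(("chr1", 60, 80)))
        assert hits.empty
        assert counts == {"a_overlapping_b": 0, "b_overlapping_a": 0}

    def test_partial_overlap_counted(self, annotation):
        targets = annotation.gene_ids[:40]
        myc = merge_replicate_peaks(*generate_peaks(targets, annotation, 2, 0.0, seed=1))
        miz1 = merge_replicate_peaks(*generate_peaks(targets[:20], annotation, 2, 0.0, seed=2))
        hits, counts = co_occupancy(myc, miz1)
        assert counts["a_overlapping_b"] == 20
        assert counts["b_overlapping_a"] == 20


class TestIntersectionAndFisher:
    def test_set_algebra(self):
        up, down = intersect_targets_degs({"a", "b", "c"}, {"z"}, {"b", "c", "d"})
        assert up == set() and down == {"b", "c"}
        assert intersect_targets_degs({"a"}, set(), set()) == (set(), set())

    def test_perfect_overlap_exact_probability(self):
        universe = {f"g{i}" for i in range(100)}
        members = tuple(sorted(universe)[:10])
        query = set(members)
        table = fisher_overrepresentation(query, universe, GeneSetCollection({"S": members}))
        # full overlap of a 10-gene query with a 10-gene set: p = 1 / C(100, 10)
        exact = float(hypergeom_upper_tail_exact(10, 100, 10, 10))
        assert table.iloc[0]["p"] == pytest.approx(exact, rel=1e-9)

    def test_overlap_at_expectation_not_significant(self, rng):
        universe = {f"g{i}" for i in range(100)}
        ordered = sorted(universe)
        members = tuple(ordered[:20])
        query = set(ordered[:4]) | set(ordered[50:66])  # overlap 4 = 20*20/100
        table = fisher_overrepresentation(query, universe, GeneSetCollection({"S": members}))
        assert table.iloc[0]["p"] >= 0.5

    def test_empty_overlap_probability_one(self):
        universe = {f"g{i}" for i in range(100)}
        ordered = sorted(universe)
        members = tuple(ordered[:50])
        query = set(ordered[60:70])
        table = fisher_overrepresentation(query, universe, GeneSetCollection({"S": members}))
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_exact_tail_sum_on_random_tables(self, rng):
        ordered = [f"g{i}" for i in range(150)]
        universe = set(ordered)
        for _ in range(25):
            set_size = int(rng.integers(5, 60))
            query_size = int(rng.integers(5, 40))
            members = tuple(rng.choice(ordered, size=set_size, replace=False))
            query = set(rng.choice(ordered, size=query_size, replace=False))
            table = fisher_overrepresentation(query, universe, GeneSetCollection({"S": members}))
            overlap = len(query & set(members))
            exact = float(hypergeom_upper_tail_exact(overlap, 150, set_size, query_size))
            assert table.iloc[0]["p"] == pytest.approx(exact, rel=1e-9)

    def test_matches_scipy_fisher_cross_check(self, rng):
        ordered = [f"g{i}" for i in range(80)]
        members = tuple(ordered[:30])
        query = set(ordered[10:35])
        table = fisher_overrepresentation(set(query), set(ordered), GeneSetCollection({"S": members}))
        overlap = len(query & set(members))
        contingency = [
            [overlap, len(query) - overlap],
            [30 - overlap, 80 - len(query) - 30 + overlap],
        ]
        assert table.iloc[0]["p"] == pytest.approx(
            stats.fisher_exact(contingency, alternative="greater")[1], rel=1e-9
        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fisher_overrepresentation({"x"}, {"a", "b"}, GeneSetCollection({"S": ("a",)}))
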