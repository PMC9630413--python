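import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplidiff import (
    GeneSetCollection,
    bh_fdr,
    enrich_all,
    enrichment_score,
    preranked_gsea,
    welch_set_test,
)
from amplidiff.enrichment import rank_genes
from oracles import bh_brute, gsea_es_brute, gsea_running_extrema_brute


def metric_series(values, prefix="g"):
    return pd.Series(np.asarray(values, dtype=float), index=[f"{prefix}{i}" for i in range(len(values))])


def es_via_package(metric: pd.Series, members) -> float:
    ranked = rank_genes(metric)
    positions = [i for i, g in enumerate(ranked.index) if g in set(members)]
    return enrichment_score(np.abs(ranked.to_numpy()), positions)


def es_via_brute(metric: pd.Series, members) -> float:
    ranked = rank_genes(metric)
    mask = [g in set(members) for g in ranked.index]
    return gsea_es_brute(ranked.to_numpy(), mask)


def assert_es_matches_brute(metric: pd.Series, members):
    """ES equals the brute-force running-sum extremum; when the positive and
    negative extrema tie in magnitude to float precision, the sign convention
    is ambiguous, so only the magnitude is compared."""
    es = es_via_package(metric, members)
    high, low = brute_extrema(metric, members)
    if high + low > 1e-9:
        assert es == pytest.approx(high, abs=1e-12)
    elif high + low < -1e-9:
        assert es == pytest.approx(low, abs=1e-12)
    else:
        assert abs(es) == pytest.approx(high, abs=1e-9)


def brute_extrema(metric: pd.Series, members):
    ranked = rank_genes(metric)
    mask = [g in set(members) for g in ranked.index]
    return gsea_running_extrema_brute(ranked.to_numpy(), mask)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.04] * 5), [0.04] * 5)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_brute(p), rtol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1, size=30)
        assert (bh_fdr(p) >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


class TestWelchSetTest:
    def test_undersized_set_filtered(self, rng):
        metrics = metric_series(rng.normal(0, 1, 100))
        members = list(metrics.index[:9])
        assert welch_set_test(metrics, members, min_size=10, max_size=500) is None

    def test_unmeasured_members_do_not_count(self, rng):
        metrics = metric_series(rng.normal(0, 1, 100))
        members = list(metrics.index[:9]) + [f"unmeasured{i}" for i in range(5)]
        assert welch_set_test(metrics, members, min_size=10, max_size=500) is None

    def test_forced_separation_detected(self, rng):
        values = rng.normal(0, 1, 300)
        values[:20] += 5.0
        metrics = metric_series(values)
        res = welch_set_test(metrics, list(metrics.index[:20]), 10, 500, set_name="hot")
        assert res.direction == 1
        assert res.p < 1e-6

    def test_null_calibration_over_random_sets(self, rng):
        metrics = metric_series(rng.normal(0, 1, 2000))
        rejections = 0
        n_sets = 200
        for _ in range(n_sets):
            members = rng.choice(metrics.index, size=40, replace=False)
            res = welch_set_test(metrics, members, 10, 500)
            rejections += res.p < 0.05
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rejections / n_sets - 0.05) < half_width

    def test_set_covering_universe_rejected(self, rng):
        metrics = metric_series(rng.normal(0, 1, 20))
        with pytest.raises(ValueError, match="every measured gene"):
            welch_set_test(metrics, list(metrics.index), 10, 500)


class TestEnrichAll:
    def test_duplicate_set_gets_identical_statistics(self, rng):
        metrics = metric_series(rng.normal(0, 1, 200))
        members = tuple(metrics.index[:25])
        collection = GeneSetCollection({"A": members, "B": members})
        table, _ = enrich_all(metrics, collection, 10, 500)
        a = table[table["set_name"] == "A"].iloc[0]
        b = table[table["set_name"] == "B"].iloc[0]
        assert a["t"] == b["t"] and a["p"] == b["p"] and a["fdr"] == b["fdr"]

    def test_single_surviving_set_fdr_equals_p(self, rng):
        metrics = metric_series(rng.normal(0, 1, 100))
        collection = GeneSetCollection(
            {"kept": tuple(metrics.index[:30]), "tiny": tuple(metrics.index[:3])}
        )
        table, filtered = enrich_all(metrics, collection, 10, 500)
        assert filtered == ["tiny"]
        assert table.iloc[0]["fdr"] == pytest.approx(table.iloc[0]["p"])

    def test_zero_surviving_sets_errors(self, rng):
        metrics = metric_series(rng.normal(0, 1, 50))
        collection = GeneSetCollection({"tiny": tuple(metrics.index[:3])})
        with pytest.raises(ValueError, match="survived"):
            enrich_all(metrics, collection, 10, 500)

    def test_suppressed_set_recovered(self, small_cohort):
        from amplidiff import differential_profile

        design, cohort = small_cohort
        groups = cohort.truth.groups
        profile = differential_profile(
            cohort.expression,
            list(groups.index[groups == "amplified"]),
            list(groups.index[groups == "neutral"]),
        )
        table, _ = enrich_all(profile, cohort.gene_sets, 10, 500)
        row = table[table["set_name"] == "IFN_SIGNALING"].iloc[0]
        assert row["direction"] == -1
        assert row["fdr"] < 0.05


class TestPrerankedGsea:
    def test_top_block_set_is_maximal(self, rng):
        metrics = metric_series(np.sort(rng.uniform(0.1, 5, 60))[::-1])
        top = tuple(metrics.index[:10])
        others = {
            f"S{i}": tuple(rng.choice(metrics.index[10:], size=10, replace=False))
            for i in range(5)
        }
        collection = GeneSetCollection({"top": top, **others})
        table = preranked_gsea(metrics, collection, n_perm=200, min_size=5, max_size=60, seed=0)
        top_row = table[table["set_name"] == "top"].iloc[0]
        assert top_row["es"] > 0
        assert top_row["es"] == table["es"].max()

    def test_small_instance_matches_hand_running_sum(self):
        metrics = metric_series([3.0, 2.0, 1.5, 1.2, 1.0, 0.8, 0.5, 0.4, 0.2, 0.1])
        members = ["g0", "g3", "g4"]
        assert es_via_package(metrics, members) == pytest.approx(
            es_via_brute(metrics, members), abs=1e-12
        )

    def test_exhaustive_brute_force_small_universes(self, rng):
        from itertools import combinations

        for n in (6, 8, 10):
            metrics = metric_series(rng.normal(0, 2, n))
            genes = list(metrics.index)
            for k in range(1, n):
                for members in combinations(genes, k):
                    assert_es_matches_brute(metrics, members)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        metrics = metric_series(rng.normal(0, 3, n))
        k = int(rng.integers(1, n))
        members = rng.choice(metrics.index, size=k, replace=False)
        assert_es_matches_brute(metrics, members)

    def test_es_matches_external_gsea_implementation(self, rng):
        gseapy = pytest.importorskip("gseapy")
        metrics = metric_series(np.round(rng.uniform(0.2, 6, 40), 3))
        metrics[:] = np.sort(metrics.to_numpy())[::-1]  # distinct, descending
        sets = {
            "A": list(rng.choice(metrics.index, size=6, replace=False)),
            "B": list(rng.choice(metrics.index, size=10, replace=False)),
        }
        res = gseapy.prerank(
            rnk=metrics.rename("metric").reset_index(),
            gene_sets=sets,
            permutation_num=10,
            min_size=2,
            max_size=50,
            seed=1,
            outdir=None,
            no_plot=True,
            weight=1.0,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            assert es_via_package(metrics, members) == pytest.approx(
                float(res.loc[name, "ES"]), abs=1e-6
            )

    def test_negated_metrics_negate_es(self, rng):
        values = rng.normal(0, 2, 200)
        metrics = metric_series(values)
        collection = GeneSetCollection(
            {"S": tuple(rng.choice(metrics.index, size=25, replace=False))}
        )
        fwd = preranked_gsea(metrics, collection, n_perm=500, min_size=5, max_size=300, seed=7)
        rev = preranked_gsea(-metrics, collection, n_perm=500, min_size=5, max_size=300, seed=7)
        assert fwd.iloc[0]["es"] == pytest.approx(-rev.iloc[0]["es"], abs=1e-12)
        assert abs(fwd.iloc[0]["nes"]) == pytest.approx(abs(rev.iloc[0]["nes"]), rel=0.25)

    def test_unmeasured_members_change_nothing(self, rng):
        metrics = metric_series(rng.normal(0, 1, 100))
        members = tuple(rng.choice(metrics.index, size=20, replace=False))
        padded = members + tuple(f"ghost{i}" for i in range(10))
        t1 = preranked_gsea(metrics, GeneSetCollection({"S": members}), 200, 5, 100, seed=3)
        t2 = preranked_gsea(metrics, GeneSetCollection({"S": padded}), 200, 5, 100, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_deterministic_under_seed(self, rng):
        metrics = metric_series(rng.normal(0, 1, 150))
        collection = GeneSetCollection(
            {"S": tuple(rng.choice(metrics.index, size=20, replace=False))}
        )
        t1 = preranked_gsea(metrics, collection, 300, 5, 100, seed=9)
        t2 = preranked_gsea(metrics, collection, 300, 5, 100, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_weight_set_errors(self):
        metrics = metric_series([0.0, 0.0, 1.0, 2.0, 3.0])
        collection = GeneSetCollection({"S": ("g0", "g1")})
        with pytest.raises(ValueError, match="zero"):
            preranked_gsea(metrics, collection, 100, 2, 5, seed=0)
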