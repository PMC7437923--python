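import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catnip.features import (
    PairFeatureTable,
    bioassay_similarity,
    build_feature_table,
    essentiality_similarity,
    feature_correlation_matrix,
    geneset_membership,
    impute_median,
    jaccard_index,
    ks_screen,
    ppi_min_target_distance,
    structure_dice,
)
from catnip.io import ConfigurationError

sets = st.sets(st.integers(0, 20), max_size=8)


@given(sets, sets)
@settings(deadline=None, max_examples=200)
def test_jaccard_matches_set_arithmetic(a, b):
    got = jaccard_index(a, b)
    if not (a | b):
        assert got is None
    else:
        assert got == pytest.approx(len(a & b) / len(a | b))
        assert got == jaccard_index(b, a)  # symmetric
        assert 0.0 <= got <= 1.0


@given(sets, sets)
@settings(deadline=None, max_examples=200)
def test_dice_matches_set_arithmetic(a, b):
    got = structure_dice(a, b)
    if not (a or b):
        assert got is None
    else:
        assert got == pytest.approx(2 * len(a & b) / (len(a) + len(b)))
        assert got == structure_dice(b, a)


def test_jaccard_dice_examples():
    assert jaccard_index({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
    assert jaccard_index({"a"}, {"a"}) == 1.0
    assert jaccard_index(set(), set()) is None
    assert structure_dice({1, 2}, {1, 2}) == 1.0
    assert structure_dice({1}, {2}) == 0.0
    assert structure_dice(None, {1}) is None
    # add-one smoothed variant used by the ChemmineR similarity convention
    assert structure_dice({1, 2, 3}, {2, 3, 4}, add_one=True) == pytest.approx(5 / 7)


def test_geneset_membership():
    coll = {"S1": {"A", "B"}, "S2": {"C"}}
    assert geneset_membership({"A"}, coll) == {"S1"}
    assert geneset_membership({"A", "C"}, coll) == {"S1", "S2"}
    assert geneset_membership({"Z"}, coll) == set()
    assert geneset_membership(set(), coll) == set()


class TestEssentialitySimilarity:
    def test_identical_and_reversed_rows(self):
        m = pd.DataFrame([[1.0, 2, 3], [3, 2, 1]], index=["GA", "GB"], columns=list("xyz"))
        assert essentiality_similarity({"GA"}, {"GA"}, m) == pytest.approx(1.0)
        assert essentiality_similarity({"GA"}, {"GB"}, m) == pytest.approx(-1.0)

    def test_mean_over_cross_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(4, 4)), index=["G1", "G2", "G3", "G4"])
        got = essentiality_similarity({"G1", "G2"}, {"G3", "G4"}, m)
        expected = np.mean(
            [np.corrcoef(m.loc[a], m.loc[b])[0, 1] for a in ("G1", "G2") for b in ("G3", "G4")]
        )
        assert got == pytest.approx(expected)

    def test_missing_when_too_few_shared_lines(self):
        m = pd.DataFrame(
            [[1.0, np.nan, 3, np.nan], [np.nan, 2, np.nan, 4]], index=["GA", "GB"]
        )
        assert essentiality_similarity({"GA"}, {"GB"}, m) is None
        assert essentiality_similarity({"ZZ"}, {"GB"}, m) is None


class TestPpiMinDistance:
    def test_examples(self):
        g = nx.path_graph(["A", "B", "C"])
        assert ppi_min_target_distance({"A"}, {"A", "X"}, g) == 0
        assert ppi_min_target_distance({"A"}, {"C"}, g) == 2
        g.add_node("Z")
        assert ppi_min_target_distance({"A"}, {"Z"}, g) is None
        assert ppi_min_target_distance({"Q"}, {"A"}, g) is None

    def test_matches_exhaustive_bfs_oracle(self):
        def bfs_dist(graph, src, dst):
            # hand-rolled BFS, independent of the implementation's search
            seen, frontier, d = {src}, [src], 0
            while frontier:
                if dst in frontier:
                    return d
                nxt = []
                for node in frontier:
                    for nb in graph[node]:
                        if nb not in seen:
                            seen.add(nb)
                            nxt.append(nb)
                frontier, d = nxt, d + 1
            return None

        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.3), seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
            ta = {f"N{i}" for i in rng.choice(n, size=int(rng.integers(1, 4)), replace=False)}
            tb = {f"N{i}" for i in rng.choice(n, size=int(rng.integers(1, 4)), replace=False)}
            dists = [bfs_dist(g, a, b) for a in ta for b in tb]
            dists = [d for d in dists if d is not None]
            expected = min(dists) if dists else None
            assert ppi_min_target_distance(ta, tb, g) == expected


def test_bioassay_similarity():
    assert bioassay_similarity({"a1", "a2"}, {"a2", "a3"}) == pytest.approx(1 / 3)
    assert bioassay_similarity({"a"}, {"a"}) == 1.0
    assert bioassay_similarity(None, {"a"}) is None


def _toy_table(values, labels=None, registry=None):
    registry = registry or [f"f{i}" for i in range(len(values[0]))]
    idx = pd.MultiIndex.from_tuples(
        [(f"A{i}", f"B{i}") for i in range(len(values))], names=["drug_a", "drug_b"]
    )
    feats = pd.DataFrame(values, index=idx, columns=registry, dtype=float)
    observed = feats.notna()
    labels = pd.Series(labels if labels is not None else [True] * len(values), index=idx)
    return PairFeatureTable(feats, labels, observed, registry)


class TestImputeMedian:
    def test_median_fill(self):
        t = _toy_table([[0.2], [np.nan], [0.4]])
        out = impute_median(t)
        assert list(out.features["f0"]) == [0.2, pytest.approx(0.3), 0.4]
        assert list(out.observed["f0"]) == [True, False, True]

    def test_identity_when_complete(self):
        t = _toy_table([[0.2], [0.4]])
        pd.testing.assert_frame_equal(impute_median(t).features, t.features)

    def test_all_missing_feature_is_error(self):
        t = _toy_table([[np.nan], [np.nan]])
        with pytest.raises(ConfigurationError, match="f0"):
            impute_median(t)

    def test_observed_medians_unchanged_and_no_missing(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=(50, 3))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        t = _toy_table(vals.tolist())
        out = impute_median(t)
        assert not out.features.isna().any().any()
        for col in out.registry:
            obs = t.features[col][t.observed[col]]
            assert out.features[col][out.observed[col]].median() == pytest.approx(obs.median())


class TestKsScreen:
    def test_identical_groups_d_zero(self):
        vals = [[0.1], [0.2], [0.1], [0.2]]
        t = _toy_table(vals, labels=[True, True, False, False])
        assert ks_screen(t).loc["f0", "D"] == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        t = _toy_table([[1.0], [2.0], [5.0], [6.0]], labels=[False, False, True, True])
        assert ks_screen(t).loc["f0", "D"] == pytest.approx(1.0)

    def test_matches_ecdf_sup_difference_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=18)
        y = rng.normal(0.7, size=13)
        t = _toy_table([[v] for v in np.concatenate([x, y])],
                       labels=[True] * 18 + [False] * 13)
        grid = np.concatenate([x, y])
        ecdf_x = [(x <= g).mean() for g in grid]
        ecdf_y = [(y <= g).mean() for g in grid]
        expected = max(abs(a - b) for a, b in zip(ecdf_x, ecdf_y))
        assert ks_screen(t).loc["f0", "D"] == pytest.approx(expected)

    def test_empty_group_is_error(self):
        t = _toy_table([[0.1], [0.2]], labels=[True, True])
        with pytest.raises(ValueError):
            ks_screen(t)


class TestFeatureCorrelation:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        t = _toy_table(np.column_stack([x, x, -x]).tolist())
        corr = feature_correlation_matrix(t)
        assert corr.loc["f0", "f1"] == pytest.approx(1.0)
        assert corr.loc["f0", "f2"] == pytest.approx(-1.0)
        assert (corr.values.T == pytest.approx(corr.values)) and corr.loc["f0", "f0"] == 1.0

    def test_constant_column_flagged_nan(self):
        t = _toy_table([[1.0, 0.2], [1.0, 0.4], [1.0, 0.1]])
        corr = feature_correlation_matrix(t)
        assert np.isnan(corr.loc["f0", "f1"])

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        t = _toy_table(rng.normal(size=(10_000, 2)).tolist())
        assert abs(feature_correlation_matrix(t).loc["f0", "f1"]) < 0.05


class TestBuildFeatureTable(object):
    def test_shapes_and_symmetric_canonical_pairs(self, small_cohort, small_feature_table):
        n = len(small_cohort.records)
        t = small_feature_table
        assert len(t.features) == n * (n - 1) // 2
        assert all(a < b for a, b in t.features.index)
        assert not t.features.isna().any().any()

    def test_bounded_features(self, small_feature_table):
        t = small_feature_table
        for feat in t.registry:
            if feat in ("essentiality_corr",):
                assert t.features[feat].between(-1, 1).all()
            elif feat != "ppi_min_distance":
                assert t.features[feat].between(0, 1).all()

    def test_missing_fingerprint_imputed(self, small_cohort):
        # drugs without fingerprints have every structure cell flagged imputed
        no_fp = {r.drug_id for r in small_cohort.records if r.fingerprint is None}
        t = build_feature_table(small_cohort.records, small_cohort.resources)
        for (a, b), obs in t.observed["structure_dice"].items():
            if a in no_fp or b in no_fp:
                assert not obs

    def test_unknown_registry_feature(self, small_cohort):
        with pytest.raises(ConfigurationError):
            build_feature_table(
                small_cohort.records, small_cohort.resources, registry=["nonexistent"]
            )

    def test_swapping_drug_order_gives_same_table(self, small_cohort):
        recs = list(reversed(small_cohort.records))
        t1 = build_feature_table(small_cohort.records, small_cohort.resources)
        t2 = build_feature_table(recs, small_cohort.resources)
        pd.testing.assert_frame_equal(t1.features.sort_index(), t2.features.sort_index())

    def test_tsv_round_trip(self, small_feature_table, tmp_path):
        p = tmp_path / "features.tsv"
        small_feature_table.to_tsv(p)
        back = PairFeatureTable.from_tsv(p)
        assert back.registry == small_feature_table.registry
        pd.testing.assert_frame_equal(
            back.features, small_feature_table.features, check_exact=False, atol=1e-9
        )
        pd.testing.assert_series_equal(
            back.labels, small_feature_table.labels, check_names=False
        )
        pd.testing.assert_frame_equal(back.observed, small_feature_table.observed)
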