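import numpy as np
import pandas as pd
import pytest

from dtikit.dataset import (
    PairFeatureMatrix,
    SamplingPlan,
    assemble_pairs,
    positive_center,
    rank_unlabeled,
    sample_negatives,
    split_cv,
)
from dtikit.drug_features import featurize_drugs
from dtikit.io import DrugRecord, InteractionTable, ProteinRecord
from dtikit.protein_features import featurize_proteins
def toy_matrix(features, labels, keys=None):
    """Build a PairFeatureMatrix straight from arrays (any width)."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    keys = keys or [f"d{i:03d}|p{i:03d}" for i in range(n)]
    frame = pd.DataFrame(
        features,
        index=pd.Index(keys, name="pair"),
        columns=[f"f{i:03d}" for i in range(features.shape[1])],
    )
    frame.insert(0, "drug_id", [k.split("|")[0] for k in keys])
    frame.insert(1, "protein_id", [k.split("|")[1] for k in keys])
    frame.insert(2, "label", labels)
    return PairFeatureMatrix(frame)


@pytest.fixture(scope="module")
def tiny_assembled():
    drugs = [DrugRecord("d1", "CCO"), DrugRecord("d2", "c1ccccc1")]
    prots = [ProteinRecord("p1", "A" * 40), ProteinRecord("p2", "ACDEFGHIKLMNPQRSTVWY" * 3)]
    table = InteractionTable(("d1", "d2"), ("p1", "p2"), frozenset({("d1", "p1")}))
    return assemble_pairs(table, featurize_drugs(drugs), featurize_proteins(prots))


class TestAssemble:
    def test_counts_and_width(self, tiny_assembled):
        counts = tiny_assembled.counts()
        assert counts == {"positive": 1, "negative": 0, "unlabeled": 3}
        assert tiny_assembled.width == 159

    def test_row_is_drug_concat_protein(self, tiny_assembled):
        row = tiny_assembled.features(["d1|p1"])[0]
        drugs = featurize_drugs([DrugRecord("d1", "CCO")])
        assert np.array_equal(row[:79], drugs.loc["d1"].to_numpy())

    def test_missing_feature_row_is_error(self):
        table = InteractionTable(("d1",), ("p1",), frozenset({("d1", "p1")}))
        empty_drugs = pd.DataFrame(np.zeros((0, 79)))
        prots = featurize_proteins([ProteinRecord("p1", "A" * 40)])
        with pytest.raises(ValueError, match="d1"):
            assemble_pairs(table, empty_drugs, prots)

    def test_empty_positives_rejected(self):
        table = InteractionTable(("d1",), ("p1",), frozenset())
        with pytest.raises(ValueError, match="positive"):
            assemble_pairs(table, pd.DataFrame(), pd.DataFrame())

    def test_round_trip_csv(self, tiny_assembled, tmp_path):
        path = tmp_path / "pairs.csv"
        tiny_assembled.save(path)
        back = PairFeatureMatrix.load(path)
        assert list(back.frame.index) == list(tiny_assembled.frame.index)
        assert (
            back.features() == tiny_assembled.features()
        ).all(), "CSV round trip must preserve values exactly"
        assert (back.labels() == tiny_assembled.labels()).all()


class TestPositiveCenter:
    def test_mean_of_two_rows(self):
        m = toy_matrix([[0, 0, 0], [2, 2, 2], [9, 9, 9]],
                       ["positive", "positive", "unlabeled"])
        center = positive_center(m)
        assert np.allclose(center.center, [1, 1, 1])

    def test_single_positive_is_its_own_center(self):
        m = toy_matrix([[3, 1], [0, 0]], ["positive", "unlabeled"])
        assert np.allclose(positive_center(m).center, [3, 1])

    def test_no_positives_rejected(self):
        m = toy_matrix([[0.0, 1.0]], ["unlabeled"])
        with pytest.raises(ValueError):
            positive_center(m)

    def test_pca_all_components_ranks_like_mean(self):
        # a complete rotation preserves Euclidean distances
        rng = np.random.default_rng(5)
        labels = ["positive"] * 10 + ["unlabeled"] * 50
        m = toy_matrix(rng.standard_normal((60, 8)), labels)
        by_mean = rank_unlabeled(m, positive_center(m, "mean"))
        by_pca = rank_unlabeled(m, positive_center(m, "pca-mean", "all"))
        assert [k for k, _ in by_mean] == [k for k, _ in by_pca]
        assert np.allclose([d for _, d in by_mean], [d for _, d in by_pca])

    def test_pca_truncation_changes_distances(self):
        rng = np.random.default_rng(6)
        labels = ["positive"] * 10 + ["unlabeled"] * 20
        m = toy_matrix(rng.standard_normal((30, 8)), labels)
        full = positive_center(m, "pca-mean", "all")
        trunc = positive_center(m, "pca-mean", 2)
        x = m.features(m.keys("unlabeled"))
        assert not np.allclose(full.distances(x), trunc.distances(x))


class TestRanking:
    def test_descending_by_distance(self):
        m = toy_matrix(
            [[0, 0], [1, 0], [3, 0], [2, 0]],
            ["positive", "unlabeled", "unlabeled", "unlabeled"],
            keys=["d0|p0", "dA|pA", "dB|pB", "dC|pC"],
        )
        ranked = rank_unlabeled(m, positive_center(m))
        assert [k for k, _ in ranked] == ["dB|pB", "dC|pC", "dA|pA"]

    def test_ties_broken_lexicographically(self):
        m = toy_matrix(
            [[0, 0], [0, 2], [2, 0]],
            ["positive", "unlabeled", "unlabeled"],
            keys=["d0|p0", "dZ|p1", "dA|p1"],
        )
        ranked = rank_unlabeled(m, positive_center(m))
        assert [k for k, _ in ranked] == ["dA|p1", "dZ|p1"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(42)
        n = 1000
        labels = ["positive"] * 10 + ["unlabeled"] * (n - 10)
        keys = [f"d{rng.integers(100):03d}|p{i:04d}" for i in range(n)]
        m = toy_matrix(rng.standard_normal((n, 6)), labels, keys)
        center = positive_center(m)
        ranked = rank_unlabeled(m, center)
        pos_mean = m.features(m.keys("positive")).mean(axis=0)
        brute = sorted(
            (
                (-float(np.sqrt(((row - pos_mean) ** 2).sum())), key)
                for key, row in zip(keys[10:], m.features(m.keys("unlabeled")))
            ),
        )
        assert [k for k, _ in ranked] == [key for _, key in brute]


class TestSampling:
    def test_distance_takes_farthest(self):
        m = toy_matrix(
            [[0, 0], [1, 0], [2, 0], [3, 0]],
            ["positive", "unlabeled", "unlabeled", "unlabeled"],
            keys=["a|a", "b|b", "c|c", "d|d"],
        )
        out = sample_negatives(m, SamplingPlan(method="distance", k=2))
        assert set(out.keys("negative")) == {"d|d", "c|c"}

    def test_k_defaults_to_positive_count(self, small_matrix):
        out = sample_negatives(small_matrix, SamplingPlan(method="distance"))
        counts = out.counts()
        assert counts["negative"] == counts["positive"]

    def test_random_is_seed_deterministic(self, small_matrix):
        a = sample_negatives(small_matrix, SamplingPlan("random", seed=17))
        b = sample_negatives(small_matrix, SamplingPlan("random", seed=17))
        c = sample_negatives(small_matrix, SamplingPlan("random", seed=18))
        assert a.keys("negative") == b.keys("negative")
        assert set(a.keys("negative")) != set(c.keys("negative"))

    def test_conservation_of_totals(self, small_matrix):
        before = small_matrix.counts()
        after = sample_negatives(small_matrix, SamplingPlan("distance")).counts()
        assert sum(before.values()) == sum(after.values())
        assert after["positive"] == before["positive"]

    def test_k_exceeding_pool_rejected(self):
        m = toy_matrix([[0, 0], [1, 1]], ["positive", "unlabeled"])
        with pytest.raises(ValueError, match="exceeds"):
            sample_negatives(m, SamplingPlan("distance", k=5))

    def test_distance_enriches_displaced_true_negatives(self):
        """Positives cluster at the origin; true negatives sit in a displaced
        cluster; hidden (unlabeled) positives overlap the positive cluster.
        The farthest-from-center rule must recover more true negatives than a
        random draw of the same size, in at least 95% of 50 seeded trials."""
        wins = 0
        for trial in range(50):
            rng = np.random.default_rng(trial)
            pos = rng.standard_normal((40, 10))
            hidden = rng.standard_normal((60, 10))  # true interactions, unlabeled
            displaced = rng.standard_normal((60, 10)) + 2.5  # true negatives
            m = toy_matrix(
                np.vstack([pos, hidden, displaced]),
                ["positive"] * 40 + ["unlabeled"] * 120,
                keys=[f"d{i:03d}|p{i:03d}" for i in range(160)],
            )
            truth = {f"d{i:03d}|p{i:03d}": i >= 100 for i in range(40, 160)}

            def tn_fraction(plan):
                negs = sample_negatives(m, plan).keys("negative")
                return sum(truth[k] for k in negs) / len(negs)

            dist = tn_fraction(SamplingPlan("distance"))
            rand = tn_fraction(SamplingPlan("random", seed=trial))
            wins += dist > rand
        assert wins >= 48  # >= 95% of 50


class TestSplitCV:
    @pytest.fixture(scope="class")
    def balanced(self):
        rng = np.random.default_rng(1)
        return toy_matrix(
            rng.standard_normal((200, 4)), ["positive"] * 100 + ["negative"] * 100
        )

    def test_fold_sizes_stratified(self, balanced):
        splits = split_cv(balanced, folds=5, seed=3)
        assert len(splits) == 5
        for train, test in splits:
            assert len(test) == 40 and len(train) == 160
            test_labels = balanced.labels(test)
            assert (test_labels == "positive").sum() == 20

    def test_test_folds_partition_all_keys(self, balanced):
        splits = split_cv(balanced, folds=5, seed=3)
        tests = [set(test) for _, test in splits]
        assert set().union(*tests) == set(balanced.keys())
        assert sum(len(t) for t in tests) == 200  # pairwise disjoint

    def test_seed_determinism(self, balanced):
        assert split_cv(balanced, seed=9) == split_cv(balanced, seed=9)
        assert split_cv(balanced, seed=9) != split_cv(balanced, seed=10)

    def test_too_few_rows_rejected(self):
        m = toy_matrix(np.zeros((4, 2)), ["positive", "positive", "negative", "negative"])
        with pytest.raises(ValueError, match="fewer"):
            split_cv(m, folds=5)


def test_gold_standard_scale_pair_count():
    """The enzyme-scale study implies 445 x 664 = 295,480 candidate pairs."""
    table = InteractionTable(
        tuple(f"d{i}" for i in range(445)),
        tuple(f"p{i}" for i in range(664)),
        frozenset({("d0", "p0")}),
    )
    assert table.n_pairs == 295_480
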