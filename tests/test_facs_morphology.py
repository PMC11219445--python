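import numpy as np
import pytest

from yawnscope import facs_morphology as fm
from yawnscope.errors import (
    DegenerateInputError,
    InsufficientDistinctPointsError,
    UnknownAUCodeError,
)


def cfg(yid, codes, label=None):
    return fm.AUConfiguration(yid, frozenset(codes), label)


class TestAUConfiguration:
    def test_mutual_exclusivity_enforced(self):
        with pytest.raises(ValueError):
            cfg("y", {"AU25+26", "AU25+27"})

    def test_unknown_code_rejected(self):
        with pytest.raises(UnknownAUCodeError):
            cfg("y", {"AU99"})

    def test_mouth_coded_flag(self):
        assert cfg("y", {"AU25+26"}).mouth_coded
        assert not cfg("y", {"AU6"}).mouth_coded


class TestOneHot:
    def test_single_code_row(self):
        X = fm.one_hot_encode([cfg("y", {"AU25+26"})])
        cols = fm.one_hot_columns()
        assert X.shape == (1, 24)
        assert X[0, cols.index("AU25+26=1")] == 1
        assert X[0, cols.index("AU25+26=0")] == 0
        # the other 11 codes are all marked absent
        assert X[0].sum() == 12

    def test_empty_configuration(self):
        X = fm.one_hot_encode([cfg("y", set())])
        assert X[0].sum() == 12
        assert X[0, ::2].sum() == 0  # no presence dummies

    def test_identical_configs_identical_rows(self):
        X = fm.one_hot_encode([cfg("a", {"AU6", "AU43"}), cfg("b", {"AU6", "AU43"})])
        assert np.array_equal(X[0], X[1])

    def test_row_sums_always_vocab_size(self, table3_configs):
        X = fm.one_hot_encode(table3_configs)
        assert np.all(X.sum(axis=1) == len(fm.AU_VOCABULARY))


def mca_oracle(Z):
    """Independent eigendecomposition of the correspondence form of Z."""
    Z = np.asarray(Z, float)
    total = Z.sum()
    P = Z / total
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-12
    coords = evecs[:, keep] * np.sqrt(evals[keep]) / np.sqrt(r)[:, None]
    return coords, evals[keep] / evals[keep].sum()


class TestMixedPCA:
    def test_two_block_design_separates_on_dim1(self):
        a = cfg("a", {"AU6", "AU43", "AU45"})
        b = cfg("b", set())
        X = fm.one_hot_encode([a, a, a, b, b, b])
        with pytest.warns(UserWarning):
            res = fm.project_mixed_pca(X)
        d1 = res.coordinates[:, 0]
        assert np.all(np.sign(d1[:3]) == np.sign(d1[0]))
        assert np.all(np.sign(d1[3:]) == -np.sign(d1[0]))

    def test_duplicated_dataset_same_variance_fractions(self, table3_configs):
        X = fm.one_hot_encode(table3_configs)
        r1 = fm.project_mixed_pca(X)
        r2 = fm.project_mixed_pca(np.vstack([X, X]))
        np.testing.assert_allclose(r1.variance_fractions, r2.variance_fractions,
                                   atol=1e-12)

    def test_against_eigendecomposition_oracle(self):
        configs = [
            cfg("1", {"AU6", "AU43"}),
            cfg("2", {"AU6"}),
            cfg("3", {"AU43", "AU45"}),
            cfg("4", {"AU45"}),
            cfg("5", {"AU6", "AU45"}),
            cfg("6", set()),
        ]
        X = fm.one_hot_encode(configs)
        keep = X.sum(axis=0) > 0
        with pytest.warns(UserWarning):
            res = fm.project_mixed_pca(X, n_dims=3)
        coords, fracs = mca_oracle(X[:, keep])
        np.testing.assert_allclose(res.variance_fractions, fracs[:3], atol=1e-10)
        for k in range(res.coordinates.shape[1]):
            got, want = res.coordinates[:, k], coords[:, k]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)

    def test_variance_fractions_monotone_and_bounded(self, table3_configs):
        X = fm.one_hot_encode(table3_configs)
        res = fm.project_mixed_pca(X, n_dims=5)
        f = res.variance_fractions
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() <= 1 + 1e-9

    def test_coordinates_centered(self, table3_configs):
        X = fm.one_hot_encode(table3_configs)
        res = fm.project_mixed_pca(X)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_degenerate_input_rejected(self):
        X = fm.one_hot_encode([cfg(str(i), {"AU6"}) for i in range(5)])
        with pytest.raises(DegenerateInputError), pytest.warns(UserWarning):
            fm.project_mixed_pca(X)


def kmeans_sse_bruteforce(X):
    """Exhaustive best 2-partition by within-cluster sum of squares."""
    n = len(X)
    best, best_sse = None, np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for m in (mask, ~mask):
            if m.sum() == 0:
                sse = np.inf
                break
            mu = X[m].mean(axis=0)
            sse += float(((X[m] - mu) ** 2).sum())
        if sse < best_sse:
            best, best_sse = mask.copy(), sse
    return best, best_sse


class TestKMeans:
    def test_two_block_perfect_split(self):
        X = np.vstack([np.zeros((5, 4)), np.ones((5, 4))])
        labels = fm.cluster_kmeans(X, k=2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_seed_stability_on_separated_data(self):
        X = np.vstack([np.zeros((5, 4)), np.ones((5, 4))])
        l1 = fm.cluster_kmeans(X, k=2, seed=1)
        l2 = fm.cluster_kmeans(X, k=2, seed=99)
        same = np.array_equal(l1, l2) or np.array_equal(l1, 1 - l2)
        assert same

    def test_matches_bruteforce_sse_enumeration(self):
        # 10 points on a line, two tight pairs of 5
        x = np.concatenate([np.linspace(0, 0.4, 5), np.linspace(10, 10.4, 5)])
        X = x[:, None]
        labels = fm.cluster_kmeans(X, k=2, seed=3)
        best_mask, _ = kmeans_sse_bruteforce(X)
        agree = np.array_equal(labels.astype(bool), best_mask) or \
            np.array_equal(~labels.astype(bool), best_mask)
        assert agree

    def test_insufficient_distinct_points(self):
        X = np.ones((4, 3))
        with pytest.raises(InsufficientDistinctPointsError):
            fm.cluster_kmeans(X, k=2)


class TestPurity:
    def test_identical_labels(self):
        assert fm.cluster_purity([0, 0, 1, 1], ["CT", "CT", "UCT", "UCT"]) == 100.0

    def test_complement_labels(self):
        assert fm.cluster_purity([1, 1, 0, 0], ["CT", "CT", "UCT", "UCT"]) == 100.0

    def test_one_of_ten_misassigned(self):
        labels = [0] * 5 + [1] * 5
        apriori = ["CT"] * 5 + ["UCT"] * 4 + ["CT"]
        assert fm.cluster_purity(labels, apriori) == 90.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fm.cluster_purity([0, 1], ["CT"])

    def test_invariant_under_permutation(self, table3_configs):
        rng = np.random.default_rng(7)
        X = fm.one_hot_encode(table3_configs)
        labels = fm.cluster_kmeans(X, k=2, seed=0)
        apriori = np.array([c.apriori_label for c in table3_configs])
        base = fm.cluster_purity(labels, apriori)
        perm = rng.permutation(len(labels))
        assert fm.cluster_purity(labels[perm], apriori[perm]) == base
        assert fm.cluster_purity(1 - labels, apriori) == base


class TestContrastTable:
    def test_published_p_values(self, table3_configs):
        ct = [c for c in table3_configs if c.apriori_label == "CT"]
        uct = [c for c in table3_configs if c.apriori_label == "UCT"]
        table = fm.au_contrast_table(ct, uct).set_index("au_code")
        assert round(table.loc["AU1/2", "p_value"], 3) == 0.149
        assert round(table.loc["AU43", "p_value"], 3) == 0.728
        assert table.loc["AU6", "p_value"] < 0.001
        assert table.loc["AU8", "p_value"] < 0.001

    def test_absent_everywhere_gives_p_one(self):
        ct = [cfg("a", {"AU25+26"}), cfg("b", {"AU25+26"})]
        uct = [cfg("c", {"AU25+27"}), cfg("d", {"AU25+27"})]
        table = fm.au_contrast_table(ct, uct).set_index("au_code")
        assert table.loc["AU45", "p_value"] == 1.0

    def test_percentages_within_group(self, table3_configs):
        ct = [c for c in table3_configs if c.apriori_label == "CT"]
        uct = [c for c in table3_configs if c.apriori_label == "UCT"]
        table = fm.au_contrast_table(ct, uct).set_index("au_code")
        assert table.loc["AU45", "pct_uct"] == 61.54
        assert table.loc["AU25+26", "pct_ct"] == 100.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fm.au_contrast_table([], [cfg("a", {"AU25+27"})])


class TestSeparatingAUForcesFullPurity:
    @pytest.mark.parametrize("seed", range(5))
    def test_any_seed(self, table3_configs, seed):
        result = fm.discover_morphs(table3_configs, k=2, seed=seed)
        assert result.purity == 100.0
        assert sum(result.cluster_sizes.values()) == len(table3_configs)
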