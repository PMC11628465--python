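"""Bray-Curtis, PCoA, PERMANOVA and signature-transfer distances."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microsig.diversity import (DistanceMatrix, apply_signature, bray_curtis,
                                compare_group_distances, distance_to_reference,
                                pcoa, permanova)
from microsig.selection import FeatureMatrix, GroupingError, Signature


def matrix(values, kind="taxon"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureMatrix([f"s{i}" for i in range(n)],
                         [f"f{j}" for j in range(p)], values, kind)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(matrix([[0.2, 0.8], [0.2, 0.8]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_one(self):
        d = bray_curtis(matrix([[1.0, 0.0], [0.0, 1.0]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_worked_triple(self):
        d = bray_curtis(matrix([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]]))
        assert d.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_both_zero_pair_defined_as_zero(self):
        with pytest.warns(UserWarning, match="both-zero"):
            d = bray_curtis(matrix([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(matrix([[-0.1, 1.1], [0.5, 0.5]]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_range_symmetry_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.dirichlet(np.ones(6) * 0.7, size=5)
        d = bray_curtis(matrix(X)).values
        assert d.min() >= 0 and d.max() <= 1 + 1e-12
        np.testing.assert_allclose(d, d.T, atol=1e-15)
        d2 = bray_curtis(matrix(X * 37.5)).values
        np.testing.assert_allclose(d, d2, atol=1e-12)


class TestPCoA:
    def test_reconstructs_euclidean_configuration(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 2], [-1, 1]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ord_ = pcoa(DistanceMatrix([f"s{i}" for i in range(4)], D))
        got = np.linalg.norm(ord_.coordinates[:, None]
                             - ord_.coordinates[None, :], axis=2)
        np.testing.assert_allclose(got, D, atol=1e-8)

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        ord_ = pcoa(DistanceMatrix(["a", "b", "c"], D))
        pos = ord_.eigenvalues > 1e-10
        assert pos.sum() == 1
        axis = ord_.coordinates[:, 0]
        gaps = np.sort(np.diff(np.sort(axis)))  # axis sign is arbitrary
        assert gaps[1] / gaps[0] == pytest.approx(2.0, abs=1e-8)

    def test_two_points(self):
        D = np.array([[0.0, 0.37], [0.37, 0.0]])
        ord_ = pcoa(DistanceMatrix(["a", "b"], D), k=1)
        sep = abs(ord_.coordinates[0, 0] - ord_.coordinates[1, 0])
        assert sep == pytest.approx(0.37, abs=1e-12)

    def test_pct_variance_sums_to_100(self):
        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(8), size=10)
        d = bray_curtis(matrix(X))
        ord_ = pcoa(d)
        assert ord_.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(ord_.eigenvalues) <= 1e-12).all()

    def test_positive_variance_equals_centered_trace(self):
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(8), size=12)
        D = bray_curtis(matrix(X)).values
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        ord_ = pcoa(DistanceMatrix([f"s{i}" for i in range(n)], D))
        # trace = sum of ALL eigenvalues; positive-ev variance >= trace
        assert ord_.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-8)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        X = rng.dirichlet(np.ones(7), size=9)
        D = bray_curtis(matrix(X)).values
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(9)], D))
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), method="eigh")
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:5],
            np.asarray(theirs.eigvals)[:5], atol=1e-8)
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, 0]),
            np.abs(np.asarray(theirs.samples)[:, 0]), atol=1e-8)


class TestPermanova:
    @staticmethod
    def _exhaustive_p(D, labels):
        """Brute-force permutation p over all distinct label arrangements."""
        from itertools import permutations

        D2 = D ** 2
        n = len(labels)
        groups = sorted(set(labels))
        g = len(groups)

        def f_stat(lab):
            lab = np.asarray(lab)
            ss_t = D2.sum() / (2 * n)
            ss_w = sum(D2[np.ix_(lab == x, lab == x)].sum()
                       / (2 * (lab == x).sum()) for x in groups)
            ss_b = ss_t - ss_w
            return (ss_b / (g - 1)) / (ss_w / (n - g))

        obs = f_stat(labels)
        perms = set(permutations(labels))
        count = sum(1 for p in perms if f_stat(p) >= obs - 1e-12)
        return count / len(perms)

    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(5), size=6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        D = bray_curtis(matrix(X)).values
        exact = self._exhaustive_p(D, labels)
        res = permanova(DistanceMatrix([f"s{i}" for i in range(6)], D),
                        labels, n_permutations=50_000, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_disjoint_groups_minimal_p(self):
        # n=20 so no random permutation reproduces the observed split
        X = np.zeros((20, 4))
        X[:10, :2] = [[0.5, 0.5]]
        X[10:, 2:] = [[0.5, 0.5]]
        labels = np.array(["a"] * 10 + ["b"] * 10)
        d = bray_curtis(matrix(X))
        res = permanova(d, labels, n_permutations=199, seed=1)
        # a permutation reproducing the exact split would tie the observed F;
        # with these sizes that is a ~0.2% event and seed 1 has none
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r_squared > 0.9

    def test_matches_skbio_stats(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        X = rng.dirichlet(np.ones(6), size=12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        D = bray_curtis(matrix(X)).values
        ours = permanova(DistanceMatrix([f"s{i}" for i in range(12)], D),
                         labels, n_permutations=999, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D), labels, permutations=999)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                              rel=1e-10)

    def test_label_renaming_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.dirichlet(np.ones(5), size=10)
        d = bray_curtis(matrix(X))
        l1 = np.array(["a"] * 5 + ["b"] * 5)
        l2 = np.array(["zzz"] * 5 + ["aaa"] * 5)
        r1 = permanova(d, l1, n_permutations=99, seed=3)
        r2 = permanova(d, l2, n_permutations=99, seed=3)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        assert r1.r_squared == pytest.approx(r2.r_squared)

    def test_singleton_group_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        with pytest.raises(GroupingError):
            permanova(d, np.array(["x", "x", "y"]), 99, 0)


class TestApplySignature:
    def test_column_subset_in_signature_order(self):
        mat = matrix(np.arange(12, dtype=float).reshape(3, 4))
        sig = Signature(["f2", "f0"], np.array([1.0, 0.5]))
        out = apply_signature(sig, mat)
        assert out.feature_ids == ["f2", "f0"]
        np.testing.assert_array_equal(out.values[:, 0], mat.values[:, 2])

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            apply_signature(Signature([], np.empty(0)),
                            matrix(np.ones((2, 2))))

    def test_missing_features_listed(self):
        sig = Signature(["f9"], np.ones(1))
        with pytest.raises(KeyError, match="f9"):
            apply_signature(sig, matrix(np.ones((2, 2))))

    def test_full_signature_is_identity(self):
        mat = matrix(np.random.default_rng(0).dirichlet(np.ones(3), size=4))
        sig = Signature(list(mat.feature_ids), np.ones(3))
        out = apply_signature(sig, mat)
        np.testing.assert_array_equal(out.values, mat.values)


class TestDistanceToReference:
    def test_identical_query_zero(self):
        X = np.tile([0.25, 0.75], (4, 1))
        res = distance_to_reference(matrix(X), ["s0"], ["s1", "s2", "s3"])
        assert res.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_one(self):
        X = np.array([[1.0, 0, 0], [0, 0.5, 0.5], [0, 0.7, 0.3]])
        res = distance_to_reference(matrix(X), ["s0"], ["s1", "s2"])
        assert res.distances[0] == pytest.approx(1.0)

    def test_hand_mean(self):
        # BC(q,r1)=0.2, BC(q,r2)=0.6 -> mean 0.4
        q = np.array([0.5, 0.5, 0.0])
        r1 = np.array([0.4, 0.4, 0.2])  # BC = 1-2*0.8/2 = 0.2
        r2 = np.array([0.2, 0.2, 0.6])  # BC = 1-2*0.4/2 = 0.6
        res = distance_to_reference(matrix(np.vstack([q, r1, r2])),
                                    ["s0"], ["s1", "s2"])
        assert res.distances[0] == pytest.approx(0.4, abs=1e-12)

    def test_query_reference_overlap_rejected(self):
        X = np.random.default_rng(0).dirichlet(np.ones(3), size=4)
        with pytest.raises(GroupingError):
            distance_to_reference(matrix(X), ["s0", "s1"], ["s1", "s2"])


class TestCompareGroupDistances:
    @staticmethod
    def _result(distances, groups):
        from microsig.diversity import SignatureDistanceResult

        return SignatureDistanceResult(
            [f"q{i}" for i in range(len(distances))],
            np.asarray(distances, dtype=float), list(groups))

    def test_fully_separated_exact_p(self):
        res = self._result([0.1, 0.2, 0.3, 0.35, 0.4,
                            0.6, 0.7, 0.8, 0.85, 0.9],
                           ["g1"] * 5 + ["g2"] * 5)
        out = compare_group_distances(res)
        assert out.loc[0, "p_value"] == pytest.approx(2 / 252)

    def test_three_groups_give_three_pairs(self):
        res = self._result(np.linspace(0, 1, 9), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = compare_group_distances(res)
        assert len(out) == 3

    def test_identical_distributions_large_p(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(size=40)
        res = self._result(d, ["a"] * 20 + ["b"] * 20)
        out = compare_group_distances(res)
        assert out.loc[0, "p_value"] > 0.05
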