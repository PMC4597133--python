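import numpy as np
import pandas as pd
import pytest

from gapkit import (
    GridLayer,
    blomberg_k,
    blomberg_k_table,
    conservatism_fraction,
    cophenetic_distances,
    extract_env,
    geographic_distances,
    hcpc_clusters,
    mahalanobis_distances,
    mantel,
    make_tree_and_traits,
    pca,
    phylo_covariance,
    read_newick,
    sister_pairs,
)
from gapkit.eco_phylo import KResult


# ---------------------------------------------------------------------
# independent oracle: K from a hand-rolled newick parse, explicit loops
# ---------------------------------------------------------------------

def naive_blomberg_k(newick, traits):
    """Dense-matrix K oracle built from scratch (no gapkit internals)."""
    C = _covariance_by_node_identity(newick)
    tips = sorted(C.keys())
    n = len(tips)
    M = np.array([[C[a][b] for b in tips] for a in tips])
    x = np.array([traits[t] for t in tips])
    Mi = np.linalg.inv(M)
    ones = np.ones(n)
    ahat = (ones @ Mi @ x) / (ones @ Mi @ ones)
    r = x - ahat
    observed = (r @ r) / (r @ Mi @ r)
    expected = (np.trace(M) - n / Mi.sum()) / (n - 1)
    return observed / expected


def _covariance_by_node_identity(newick):
    """Shared root-to-MRCA length for every tip pair, by explicit recursion."""
    s = newick.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            pos += 1  # ")"
            while pos < len(s) and s[pos] not in ":,();":
                pos += 1
            node = {"children": children}
        else:
            label = ""
            while s[pos] not in ":,()":
                label += s[pos]
                pos += 1
            node = {"tip": label}
        node["length"] = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            num = ""
            while pos < len(s) and s[pos] not in ",()":
                num += s[pos]
                pos += 1
            node["length"] = float(num)
        return node

    root = parse()
    cov = {}

    def tips_below(node):
        if "tip" in node:
            return [node["tip"]]
        return [t for c in node["children"] for t in tips_below(c)]

    all_tips = tips_below(root)
    for t in all_tips:
        cov[t] = {u: 0.0 for u in all_tips}

    def walk(node, depth):
        d = depth + node["length"]
        below = tips_below(node)
        if "tip" in node:
            cov[node["tip"]][node["tip"]] = d
            return
        for ci, a_child in enumerate(node["children"]):
            for b_child in node["children"][ci + 1:]:
                for a in tips_below(a_child):
                    for b in tips_below(b_child):
                        cov[a][b] = cov[b][a] = d
            walk(a_child, d)

    walk(root, -root["length"])  # root edge (if any) adds no shared history
    return cov


class TestExtractEnv:
    @pytest.fixture
    def layers(self):
        tpl = GridLayer(np.zeros((4, 4)), 0.0, 4.0, 1.0)
        const = tpl.copy_with(np.full((4, 4), 7.0))
        step = tpl.copy_with(np.r_[np.zeros((2, 4)), np.ones((2, 4))])
        return {"const": const, "step": step}

    def test_cell_center_value(self, layers):
        mat, dropped = extract_env([(0.5, 3.5)], layers)
        assert mat.loc[0, "const"] == 7.0 and dropped == 0

    def test_point_outside_grid_dropped_and_counted(self, layers):
        mat, dropped = extract_env([(0.5, 3.5), (10.0, 10.0)], layers)
        assert len(mat) == 1 and dropped == 1

    def test_step_layer_cell_membership(self, layers):
        mat, _ = extract_env([(0.5, 3.5), (0.5, 1.5), (3.5, 0.5)], layers)
        assert list(mat["step"]) == [0.0, 1.0, 1.0]

    def test_all_points_invalid_rejected(self, layers):
        with pytest.raises(ValueError):
            extract_env([(99.0, 99.0)], layers)


class TestPca:
    def test_collinear_points_put_all_variance_on_pc1(self):
        X = pd.DataFrame({"x": [0, 1, 2, 3.0], "y": [0, 2, 4, 6.0]})
        res = pca(X)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_descending(self):
        rng = np.random.default_rng(0)
        res = pca(pd.DataFrame(rng.normal(size=(20, 5))))
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert list(res.variance_fractions) == sorted(res.variance_fractions, reverse=True)

    def test_covariance_eigenvalue_hand_example(self):
        X = pd.DataFrame({"x": [2, -2, 0, 0.0], "y": [0, 0, 1, -1.0]})
        res = pca(X, standardize=False)
        np.testing.assert_allclose(res.variance_fractions, [0.8, 0.2], atol=1e-12)

    def test_reconstruction_of_standardized_input(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(15, 4)))
        res = pca(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        back = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(back, Z.to_numpy(), atol=1e-8)

    def test_zero_variance_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1, 2, 3.0], "flat": [5, 5, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pca(X)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        a, b = pca(X), pca(X.copy())
        np.testing.assert_allclose(a.loadings, b.loadings)
        for j in a.loadings.columns:
            col = a.loadings[j]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


class TestHcpc:
    def clouds(self, seed=0, n=30, sep=20.0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([
            rng.normal([0, 0], 1, size=(n, 2)),
            rng.normal([sep, 0], 1, size=(n, 2)),
            rng.normal([0, sep], 1, size=(n, 2)),
        ])
        taxa = ["a"] * n + ["b"] * n + ["c"] * n
        return pts, taxa

    def test_separated_clouds_recovered(self):
        pts, taxa = self.clouds()
        res = hcpc_clusters(pts, taxa, k=3, n_pcs=2)
        assert len(set(res.assignments.values())) == 3

    def test_k_one_collapses_everything(self):
        pts, taxa = self.clouds()
        res = hcpc_clusters(pts, taxa, k=1, n_pcs=2)
        assert set(res.assignments.values()) == {1}

    def test_point_order_shuffle_invariant(self):
        pts, taxa = self.clouds(seed=4)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(taxa))
        shuffled = hcpc_clusters(pts[perm], [taxa[i] for i in perm], k=3, n_pcs=2)
        baseline = hcpc_clusters(pts, taxa, k=3, n_pcs=2)
        # cluster ids may relabel; the induced taxon partition must match
        def partition(assign):
            groups = {}
            for t, c in assign.items():
                groups.setdefault(c, set()).add(t)
            return sorted(map(frozenset, groups.values()), key=sorted)
        assert partition(shuffled.assignments) == partition(baseline.assignments)

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            hcpc_clusters(np.zeros((3, 2)), ["a", "b", "c"], k=5)


class TestSisterPairs:
    @pytest.mark.parametrize(
        "newick, expected",
        [
            ("((A:1,B:1):1,(C:1,D:1):1);", [("A", "B"), ("C", "D")]),
            ("((A:1,B:1):1,C:2);", [("A", "B")]),
            ("(((A:1,B:1):1,C:2):1,D:3);", [("A", "B")]),
        ],
    )
    def test_cherry_detection(self, newick, expected):
        assert sister_pairs(read_newick(newick)) == expected

    def test_each_tip_in_at_most_one_pair(self):
        tree, _ = make_tree_and_traits(20, seed=5)
        tips = [t for pair in sister_pairs(tree) for t in pair]
        assert len(tips) == len(set(tips))


class TestBlombergK:
    def test_star_tree_gives_exactly_one(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        for _ in range(5):
            traits = dict(zip("ABCDE", rng.normal(size=5)))
            res = blomberg_k(star, traits, n_perm=0)
            assert res.k == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_dense_oracle(self):
        for seed in range(6):
            tree, traits = make_tree_and_traits(12 + 3 * seed, seed=seed)
            newick = tree.as_string(schema="newick", unquoted_underscores=True)
            ours = blomberg_k(tree, traits["trait_1"], n_perm=0).k
            oracle = naive_blomberg_k(newick, traits["trait_1"].to_dict())
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_brownian_traits_center_near_one(self):
        tree, traits = make_tree_and_traits(40, seed=3, n_traits=60)
        C = phylo_covariance(tree)
        ks = [blomberg_k(tree, traits[c], n_perm=0, C=C).k for c in traits]
        assert 0.8 <= np.mean(ks) <= 1.2

    def test_white_noise_traits_fall_below_one(self):
        tree, traits = make_tree_and_traits(40, seed=8, mode="white_noise", n_traits=40)
        C = phylo_covariance(tree)
        ks = [blomberg_k(tree, traits[c], n_perm=0, C=C).k for c in traits]
        assert np.median(ks) < 1.0

    def test_permutation_p_detects_strong_signal(self):
        tree, traits = make_tree_and_traits(30, seed=2)
        res = blomberg_k(tree, traits["trait_1"], n_perm=199, seed=5)
        res2 = blomberg_k(tree, traits["trait_1"], n_perm=199, seed=5)
        assert res.p_value == res2.p_value  # reproducible given seed
        assert 0 < res.p_value <= 1.0

    def test_name_mismatch_rejected(self):
        tree, traits = make_tree_and_traits(6, seed=1)
        bad = traits["trait_1"].rename(index={"t001": "wrong"})
        with pytest.raises(ValueError, match="wrong"):
            blomberg_k(tree, bad)


class TestMantel:
    def dist_from_points(self, rng, n):
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return d

    def test_identical_matrices_give_r_one(self):
        d = self.dist_from_points(np.random.default_rng(0), 8)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_reversed_matrix_gives_r_minus_one(self):
        d = self.dist_from_points(np.random.default_rng(1), 8)
        rev = d.max() - d
        np.fill_diagonal(rev, 0.0)
        assert mantel(d, rev, n_perm=0).r == pytest.approx(-1.0)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        a = self.dist_from_points(rng, 9)
        b = self.dist_from_points(rng, 9)
        perm = rng.permutation(9)
        r1 = mantel(a, b, n_perm=0).r
        r2 = mantel(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)], n_perm=0).r
        assert r1 == pytest.approx(r2)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            mantel(bad, bad)

    def test_p_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        a, b = self.dist_from_points(rng, 10), self.dist_from_points(rng, 10)
        assert mantel(a, b, 199, seed=4).p_value == mantel(a, b, 199, seed=4).p_value


class TestDistanceBuilders:
    def test_identity_covariance_reduces_to_euclidean(self):
        # sample covariance of these scaled corners is the identity
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]) * np.sqrt(3)
        table = pd.DataFrame(pts, index=list("abcd"), columns=["u", "v"])
        D = mahalanobis_distances(table)
        expected = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(D.to_numpy(), expected, atol=1e-8)

    def test_self_distance_zero_everywhere(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        assert np.all(np.diag(mahalanobis_distances(table)) == 0)
        cents = {t: (float(rng.uniform(-100, -90)), float(rng.uniform(30, 40))) for t in "abc"}
        assert np.all(np.diag(geographic_distances(cents)) == 0)

    def test_cherry_cophenetic_path_sum(self):
        tree = read_newick("((A:1.2,B:1.8):1,C:2);")
        D = cophenetic_distances(tree)
        assert D.loc["A", "B"] == pytest.approx(3.0)

    def test_singular_covariance_ridged(self):
        table = pd.DataFrame({"u": [0, 1, 2, 3.0], "v": [0, 2, 4, 6.0]}, index=list("abcd"))
        D = mahalanobis_distances(table)  # rank-1 covariance, ridge applies
        assert np.isfinite(D.to_numpy()).all()


class TestConservatism:
    def kr(self, k, p):
        return KResult("v", k, p, 100)

    def test_fraction_counting(self):
        results = [self.kr(1.5, 0.01)] * 13 + [self.kr(0.5, 0.5)] * 13
        assert conservatism_fraction(results) == pytest.approx(0.5)

    def test_all_or_none(self):
        assert conservatism_fraction([self.kr(2, 0.001)] * 4) == 1.0
        assert conservatism_fraction([self.kr(0.2, 0.9)] * 4) == 0.0

    def test_strict_rule_requires_k_above_one(self):
        results = [self.kr(0.5, 0.01), self.kr(1.5, 0.01)]
        assert conservatism_fraction(results, rule="k_and_p") == pytest.approx(0.5)
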