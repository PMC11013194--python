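"""Alpha/beta diversity indices and covariate-adjusted PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio

from microdii.diversity import (
    alpha_diversity,
    alpha_test,
    beta_diversity,
    load_tree,
    permanova,
)

from conftest import bray_curtis_oracle, unifrac_oracle


def frame(rows, ids=None, features=None):
    rows = np.asarray(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"f{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=features)


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        table = frame([[5, 5, 5, 5]])
        assert alpha_diversity(table, "shannon").iloc[0] == pytest.approx(math.log(4))
        assert alpha_diversity(table, "simpson").iloc[0] == pytest.approx(1 - 1 / 4)

    def test_single_taxon_degenerate(self):
        table = frame([[7, 0, 0]])
        assert alpha_diversity(table, "shannon").iloc[0] == 0.0
        assert alpha_diversity(table, "simpson").iloc[0] == pytest.approx(0.0)

    def test_hand_computed_proportions(self):
        table = frame([[2, 3, 5]])
        p = np.array([0.2, 0.3, 0.5])
        assert alpha_diversity(table, "shannon").iloc[0] == pytest.approx(
            -(p * np.log(p)).sum()
        )
        assert alpha_diversity(table, "simpson").iloc[0] == pytest.approx(
            1 - (p**2).sum()
        )

    def test_agrees_with_plugin_formula_on_random_samples(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(1, 200, (100, 15)).astype(float)
        table = frame(counts)
        shannon = alpha_diversity(table, "shannon").to_numpy()
        simpson = alpha_diversity(table, "simpson").to_numpy()
        for i in range(100):
            p = counts[i] / counts[i].sum()
            assert abs(shannon[i] - (-(p * np.log(p)).sum())) < 1e-12
            assert abs(simpson[i] - (1 - (p**2).sum())) < 1e-12

    def test_empty_sample_error(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_diversity(frame([[0, 0]]), "shannon")


class TestAlphaTest:
    def test_identical_groups_p_one(self):
        vals = pd.Series([1.0, 1.0, 1.0, 1.0, 1.0, 1.0], index=range(6))
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=range(6))
        out = alpha_test(vals, groups)
        assert out["p"].item() == pytest.approx(1.0)

    def test_fully_separated_3v3_matches_enumeration(self):
        """One extreme arrangement of C(6,3)=20 -> exact two-sided p = 2/20."""
        vals = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], index=range(6))
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=range(6))
        out = alpha_test(vals, groups)
        # enumeration oracle: count arrangements with rank-sum >= observed
        ranks = np.arange(1, 7)
        observed = 4 + 5 + 6
        extreme = sum(
            1
            for combo in itertools.combinations(ranks, 3)
            if sum(combo) >= observed
        )
        assert out["p"].item() == pytest.approx(2 * extreme / 20)
        assert out["method"].item() == "exact"

    def test_small_group_error(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=range(3))
        groups = pd.Series([1, 2, 2], index=range(3))
        with pytest.raises(ValueError, match="<2 samples"):
            alpha_test(vals, groups)


def random_tree(features, rng) -> skbio.TreeNode:
    nodes = [skbio.TreeNode(name=f, length=float(rng.exponential(1.0))) for f in features]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(skbio.TreeNode(length=float(rng.exponential(1.0)), children=[a, b]))
    nodes[0].length = None
    return nodes[0]


class TestBetaDiversity:
    def test_identical_samples_distance_zero(self):
        table = frame([[3, 1, 4], [3, 1, 4]])
        dm = beta_diversity(table, "bray_curtis")
        assert dm[("s0", "s1")] == pytest.approx(0.0)

    def test_disjoint_samples_bray_curtis_one(self):
        table = frame([[3, 0, 4, 0], [0, 2, 0, 9]])
        dm = beta_diversity(table, "bray_curtis")
        assert dm[("s0", "s1")] == pytest.approx(1.0)

    def test_three_leaf_unit_tree_unifrac(self):
        tree = skbio.TreeNode.read(["((a:1,b:1):1,c:1):0;"])
        table = frame([[1, 0, 0], [0, 1, 0]], features=["a", "b", "c"])
        dm = beta_diversity(table, "unifrac", tree=tree)
        # spanned: a-edge (1), b-edge (1), shared internal edge (1); unique: a+b
        assert dm[("s0", "s1")] == pytest.approx(2.0 / 3.0)
        assert dm[("s0", "s1")] == pytest.approx(
            unifrac_oracle(tree, {"a"}, {"b"})
        )

    def test_random_instances_match_brute_force_oracles(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n_feat = int(rng.integers(3, 8))
            features = [f"t{j}" for j in range(n_feat)]
            tree = random_tree(features, rng)
            counts = rng.integers(0, 6, (2, n_feat))
            if counts.sum(axis=1).min() == 0:
                counts[:, 0] += 1
            table = frame(counts, features=features)
            bc = beta_diversity(table, "bray_curtis")[("s0", "s1")]
            assert bc == pytest.approx(
                bray_curtis_oracle(counts[0].astype(float), counts[1].astype(float)),
                abs=1e-12,
            )
            uf = beta_diversity(table, "unifrac", tree=tree)[("s0", "s1")]
            oracle = unifrac_oracle(
                tree,
                {f for f, c in zip(features, counts[0]) if c > 0},
                {f for f, c in zip(features, counts[1]) if c > 0},
            )
            assert uf == pytest.approx(oracle, abs=1e-10)

    def test_metrics_bounded_and_symmetric(self):
        rng = np.random.default_rng(10)
        table = frame(rng.integers(0, 20, (6, 10)) + (rng.random((6, 10)) < 0.5))
        dm = beta_diversity(table, "bray_curtis")
        assert np.allclose(dm.data, dm.data.T)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(np.diag(dm.data), 0)

    def test_missing_tree_feature_error(self):
        tree = skbio.TreeNode.read(["(a:1,b:1):0;"])
        table = frame([[1, 1, 1], [1, 0, 1]], features=["a", "b", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            beta_diversity(table, "unifrac", tree=tree)


class TestPermanova:
    @staticmethod
    def null_case(seed, n=30):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        table = frame(rng.gamma(1.0, 1.0, (n, 20)), ids=ids)
        dm = beta_diversity(table, "bray_curtis")
        exposure = pd.Series(rng.normal(0, 2, n), index=ids)
        covs = pd.DataFrame({"age": rng.normal(29, 6, n)}, index=ids)
        return dm, exposure, covs

    def test_relabeling_invariance_of_pseudo_f(self):
        dm, exposure, covs = self.null_case(0)
        res1 = permanova(dm, exposure, covs, n_perm=99, seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(dm.ids))
        ids2 = [dm.ids[i] for i in perm]
        dm2 = skbio.DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids2)
        res2 = permanova(dm2, exposure, covs, n_perm=99, seed=1)
        assert res2.pseudo_f == pytest.approx(res1.pseudo_f, rel=1e-9)

    def test_collinear_exposure_error(self):
        dm, exposure, covs = self.null_case(3)
        covs["dup"] = exposure
        with pytest.raises(ValueError, match="collinear"):
            permanova(dm, exposure, covs, n_perm=99)

    def test_seed_reproducibility(self):
        dm, exposure, covs = self.null_case(4)
        a = permanova(dm, exposure, covs, n_perm=99, seed=7)
        b = permanova(dm, exposure, covs, n_perm=99, seed=7)
        assert a.p_value == b.p_value

    def test_planted_gradient_detected(self):
        rng = np.random.default_rng(6)
        n = 40
        ids = [f"s{i}" for i in range(n)]
        exposure = pd.Series(rng.normal(0, 1, n), index=ids)
        abund = rng.gamma(1.0, 1.0, (n, 20))
        abund[:, :5] *= np.exp(1.5 * exposure.to_numpy()[:, None])
        dm = beta_diversity(frame(abund, ids=ids), "bray_curtis")
        covs = pd.DataFrame({"age": rng.normal(29, 6, n)}, index=ids)
        res = permanova(dm, exposure, covs, n_perm=199, seed=0)
        assert res.p_value < 0.05

    def test_by_tertile_mode(self):
        dm, exposure, covs = self.null_case(8)
        tert = pd.Series(
            pd.qcut(exposure, 3, labels=[1, 2, 3]).astype(int), index=exposure.index
        )
        res = permanova(dm, tert, covs, n_perm=99, seed=0, by_tertile=True)
        assert res.df_exposure == 2
        assert 0 < res.p_value <= 1


class TestLoadTree:
    def test_negative_branch_length_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("(a:1,b:-0.5):0;\n")
        with pytest.raises(ValueError, match="negative branch length"):
            load_tree(p)
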