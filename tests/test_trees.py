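import numpy as np
import pandas as pd
import pytest

import turnoverscan as ts
from turnoverscan.errors import FormatError
from turnoverscan.trees import TissueTree, unrooted_splits


def labelled(df_values, labels):
    return pd.DataFrame(df_values, index=labels, columns=labels)


class TestExpressionDistance:
    def test_identical_columns_have_zero_distance(self, rng):
        base = rng.normal(size=50)
        prof = pd.DataFrame({
            "A": base, "B": base, "C": rng.normal(size=50), "D": rng.normal(size=50),
        })
        D = ts.expression_distance(prof)
        assert D.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_anticorrelated_columns_have_distance_two(self, rng):
        base = rng.normal(size=50)
        prof = pd.DataFrame({
            "A": base, "B": -base, "C": rng.normal(size=50), "D": rng.normal(size=50),
        })
        D = ts.expression_distance(prof)
        assert D.loc["A", "B"] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_tissue_is_named_in_error(self, rng):
        prof = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("ABCD"))
        prof["C"] = 1.0
        with pytest.raises(FormatError, match="C"):
            ts.expression_distance(prof)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = labelled([[0, 2, 3], [2, 0, 4], [3, 4, 0]], list("abc"))
        tree = ts.neighbor_joining(D)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    @pytest.mark.parametrize("seed", [0, 5, 9])
    @pytest.mark.parametrize("n_tips", [8, 12])
    def test_exact_on_additive_matrices(self, seed, n_tips):
        # oracle: patristic distances of a known random tree are additive,
        # so NJ must reconstruct both topology and path lengths exactly
        true = ts.make_random_tree(n_tips, seed=seed)
        D = ts.patristic_matrix(true)
        rebuilt = ts.neighbor_joining(D)
        assert unrooted_splits(rebuilt) == unrooted_splits(true)
        D2 = ts.patristic_matrix(rebuilt).loc[D.index, D.columns]
        assert np.abs(D.values - D2.values).max() < 1e-9

    def test_invariant_to_taxon_order(self):
        true = ts.make_random_tree(9, seed=2)
        D = ts.patristic_matrix(true)
        perm = list(D.index[::-1])
        t1 = ts.neighbor_joining(D)
        t2 = ts.neighbor_joining(D.loc[perm, perm])
        assert unrooted_splits(t1) == unrooted_splits(t2)
        d1 = ts.patristic_matrix(t1)
        d2 = ts.patristic_matrix(t2).loc[d1.index, d1.columns]
        assert np.abs(d1.values - d2.values).max() < 1e-9

    def test_topology_matches_skbio_oracle(self, rng):
        # independent implementation cross-check on a noisy matrix
        skbio = pytest.importorskip("skbio")
        labels = [f"x{i}" for i in range(7)]
        true = ts.make_random_tree(7, seed=3)
        D = ts.patristic_matrix(true)
        noise = rng.uniform(0, 0.01, size=D.shape)
        noisy = D.values + noise + noise.T
        noisy = (noisy + noisy.T) / 2.0
        np.fill_diagonal(noisy, 0.0)
        Dn = pd.DataFrame(noisy, index=D.index, columns=D.columns)
        ours = unrooted_splits(ts.neighbor_joining(Dn))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(D.index)))
        all_tips = frozenset(t.name for t in sk_tree.tips())
        ref = min(all_tips)
        theirs = set()
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            split = frozenset(all_tips - below) if ref in below else below
            if 2 <= len(split) <= len(all_tips) - 2:
                theirs.add(split)
        assert ours == theirs

    def test_rejects_asymmetric_and_negative(self):
        D = labelled([[0, 1, 2, 1], [1, 0, 1, 1], [2, 1, 0, 1], [1, 1, 1, 0]], list("abcd"))
        bad = D.copy()
        bad.iloc[0, 1] = 5.0
        with pytest.raises(FormatError):
            ts.neighbor_joining(bad)
        neg = D.astype(float)
        neg.iloc[0, 1] = neg.iloc[1, 0] = -0.5
        with pytest.raises(FormatError):
            ts.neighbor_joining(neg)

    def test_result_is_midpoint_rooted_binary(self):
        tree = ts.neighbor_joining(ts.patristic_matrix(ts.make_random_tree(6, seed=1)))
        assert tree.is_rooted_binary()


class TestGeometry:
    def test_two_tips_joined_at_root(self):
        tree = TissueTree.from_newick("(A:1.0,B:1.0);")
        C = ts.shared_path_matrix(tree)
        assert np.allclose(C.loc[["A", "B"], ["A", "B"]].values, np.eye(2))

    def test_cherry_depths(self):
        tree = TissueTree.from_newick("((A:0.4,B:0.4):0.6,C:1.0);")
        C = ts.shared_path_matrix(tree)
        assert C.loc["A", "B"] == pytest.approx(0.6)
        assert C.loc["A", "A"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_shared_path_psd_and_dominance(self, seed):
        tree = ts.make_random_tree(10, seed=seed)
        C = ts.shared_path_matrix(tree).values
        assert np.linalg.eigvalsh(C).min() >= -1e-9
        assert (np.diag(C)[:, None] - C >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_patristic_shared_path_identity(self, seed):
        tree = ts.make_random_tree(10, seed=seed)
        C = ts.shared_path_matrix(tree)
        d = ts.patristic_matrix(tree).loc[C.index, C.columns].values
        Cv = C.values
        expected = np.diag(Cv)[:, None] + np.diag(Cv)[None, :] - 2 * Cv
        assert np.abs(d - expected).max() < 1e-9
        assert np.allclose(np.diag(d), 0.0)

    def test_unrooted_input_rejected(self):
        star = TissueTree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ts.TurnoverScanError, match="root"):
            ts.shared_path_matrix(star)

    def test_newick_round_trip(self, tree8):
        again = TissueTree.from_newick(tree8.to_newick())
        assert sorted(again.tip_labels) == sorted(tree8.tip_labels)
        d1 = ts.patristic_matrix(tree8)
        d2 = ts.patristic_matrix(again).loc[d1.index, d1.columns]
        assert np.abs(d1.values - d2.values).max() < 1e-8


class TestBootstrap:
    @staticmethod
    def block_profiles(rng, n_genes=150):
        # two tissue blocks with opposite gene-expression patterns, so the
        # correlation distance cleanly separates {T0,T1,T2} from {T3,T4,T5}
        values = rng.normal(0, 0.3, size=(n_genes, 6))
        values[: n_genes // 2, 3:] += 8.0
        values[n_genes // 2 :, :3] += 8.0
        return pd.DataFrame(values, columns=[f"T{i}" for i in range(6)])

    def test_dominant_split_has_full_support(self, rng):
        prof = self.block_profiles(rng)
        tree = ts.bootstrap_support(prof, n_boot=50, seed=1)
        split = frozenset({"T3", "T4", "T5"})
        assert tree.supports[split] == pytest.approx(1.0)

    def test_single_replicate_supports_are_binary(self, rng):
        prof = self.block_profiles(rng)
        tree = ts.bootstrap_support(prof, n_boot=1, seed=1)
        assert set(tree.supports.values()) <= {0.0, 1.0}

    def test_seeded_determinism(self, rng):
        prof = self.block_profiles(rng)
        t1 = ts.bootstrap_support(prof, n_boot=25, seed=9)
        t2 = ts.bootstrap_support(prof, n_boot=25, seed=9)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_gene_order_does_not_change_confident_supports(self, rng):
        prof = self.block_profiles(rng)
        shuffled = prof.sample(frac=1.0, random_state=4)
        t1 = ts.bootstrap_support(prof, n_boot=40, seed=2)
        t2 = ts.bootstrap_support(shuffled, n_boot=40, seed=2)
        split = frozenset({"T3", "T4", "T5"})
        assert t1.supports[split] == t2.supports[split] == 1.0
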