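"""Hierarchical FDR: Simes aggregation, tree-consistent selection, pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from content.hfdr import (
    build_tree,
    hierarchical_bh,
    pool_methods,
    simes_aggregate,
)


def leaf_frame(p_by_leaf):
    rows = [(g, c, m, p) for (g, c, m), p in p_by_leaf.items()]
    return pd.DataFrame(rows, columns=["gene", "context", "method", "p"])


def random_tree(rng, n_genes=20, n_ctx=4, methods=("shared", "specific", "full")):
    rows = []
    for g in range(n_genes):
        for c in range(n_ctx):
            for m in methods:
                rows.append((f"g{g}", f"c{c}", m, rng.uniform()))
    return pd.DataFrame(rows, columns=["gene", "context", "method", "p"])


class TestSimes:
    def test_closed_form_pair(self):
        assert simes_aggregate([0.01, 0.04]) == pytest.approx(0.02)

    def test_single_p_identity(self):
        assert simes_aggregate([0.37]) == 0.37

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simes_aggregate([])

    def test_uniform_under_independent_nulls(self, rng):
        reps, k = 10_000, 5
        P = rng.uniform(size=(reps, k))
        Ps = np.sort(P, axis=1)
        simes = (Ps * k / np.arange(1, k + 1)).min(axis=1)
        ours = np.array([simes_aggregate(P[i]) for i in range(0, reps, 100)])
        assert np.allclose(ours, simes[::100])  # vectorized oracle agrees
        assert stats.kstest(simes, "uniform").pvalue > 0.01

    def test_tree_aggregation_matches_manual(self, rng):
        df = random_tree(rng, n_genes=3, n_ctx=2)
        tree = build_tree(df)
        ctx = tree.context_pvalues()
        for (g, c), val in ctx.items():
            manual = simes_aggregate(df[(df.gene == g) & (df.context == c)]["p"])
            assert val == pytest.approx(manual)
        gene = tree.gene_pvalues()
        for g, val in gene.items():
            manual = simes_aggregate(ctx.loc[g])
            assert val == pytest.approx(manual)


class TestHierarchicalBH:
    def test_all_ones_selects_nothing(self):
        tree = build_tree(leaf_frame({("g1", "c1", "m"): 1.0, ("g2", "c1", "m"): 1.0}))
        res = hierarchical_bh(tree, q=0.05)
        assert res.genes == [] and res.gene_contexts == [] and len(res.leaves) == 0

    def test_single_extreme_leaf_selected_with_ancestors(self):
        leaves = {("g%d" % g, "c%d" % c, "m"): 1.0 for g in range(5) for c in range(3)}
        leaves[("g2", "c1", "m")] = 1e-12
        res = hierarchical_bh(build_tree(leaf_frame(leaves)), q=0.05)
        assert res.genes == ["g2"]
        assert res.gene_contexts == [("g2", "c1")]
        assert len(res.leaves) == 1 and res.leaves.iloc[0]["gene"] == "g2"

    def test_tree_consistency(self, rng):
        df = random_tree(rng, n_genes=30)
        df.loc[rng.choice(len(df), 40, replace=False), "p"] /= 1e6
        res = hierarchical_bh(build_tree(df), q=0.1)
        genes = set(res.genes)
        for g, c in res.gene_contexts:
            assert g in genes
        pairs = set(res.gene_contexts)
        for _, row in res.leaves.iterrows():
            assert (row.gene, row.context) in pairs

    def test_monotonicity_lowering_p_keeps_rejections(self, rng):
        df = random_tree(rng, n_genes=15)
        df.loc[rng.choice(len(df), 15, replace=False), "p"] /= 1e8
        before = hierarchical_bh(build_tree(df), q=0.1)
        df2 = df.copy()
        # lower one currently-unselected leaf
        sel = set(map(tuple, before.leaves[["gene", "context", "method"]].to_numpy()))
        for i in range(len(df2)):
            key = tuple(df2.loc[i, ["gene", "context", "method"]])
            if key not in sel and df2.loc[i, "p"] > 0.5:
                df2.loc[i, "p"] = 1e-12
                break
        after = hierarchical_bh(build_tree(df2), q=0.1)
        kept = set(map(tuple, after.leaves[["gene", "context", "method"]].to_numpy()))
        assert sel <= kept

    def test_gene_level_fdr_controlled_under_global_null(self, rng):
        # BH on Simes gene p-values: under the global null any rejection is
        # false, so the empirical FDR is the fraction of replicates with >= 1
        # selected gene
        n_genes, n_ctx, n_models, reps = 200, 8, 3, 150
        false_rej = 0
        genes = np.repeat(np.arange(n_genes), n_ctx * n_models)
        ctxs = np.tile(np.repeat(np.arange(n_ctx), n_models), n_genes)
        mods = np.tile(np.arange(n_models), n_genes * n_ctx)
        for r in range(reps):
            df = pd.DataFrame({
                "gene": genes, "context": ctxs, "method": mods,
                "p": rng.uniform(size=genes.size),
            })
            res = hierarchical_bh(build_tree(df), q=0.05)
            false_rej += bool(res.genes)
        rate = false_rej / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 2 * se

    def test_invalid_q(self, rng):
        with pytest.raises(ValueError):
            hierarchical_bh(build_tree(random_tree(rng)), q=1.5)


class TestPooling:
    def test_single_method_pool_is_identity(self, rng):
        df = random_tree(rng, n_genes=4)
        pooled = pool_methods(build_tree(df))
        pd.testing.assert_frame_equal(pooled.leaves, build_tree(df).leaves)

    def test_duplicate_leaves_rejected(self, rng):
        df = random_tree(rng, n_genes=3)
        with pytest.raises(ValueError):
            pool_methods(build_tree(df), build_tree(df))

    def test_pooling_all_ones_inflates_by_simes_factor_only(self):
        # 3 informative leaves pooled with 3 p=1 leaves: hand-computed bound
        base = leaf_frame({("g", "c", "a1"): 0.01, ("g", "c", "a2"): 0.04,
                           ("g", "c", "a3"): 0.09})
        ones = leaf_frame({("g", "c", "b1"): 1.0, ("g", "c", "b2"): 1.0,
                           ("g", "c", "b3"): 1.0})
        p_before = build_tree(base).context_pvalues().iloc[0]
        pooled = pool_methods(build_tree(base), build_tree(ones))
        p_after = pooled.context_pvalues().iloc[0]
        # K grows from 3 to 6: the combined p can inflate at most twofold
        assert p_before == pytest.approx(0.03)  # min(0.03, 0.06, 0.09)
        assert p_after == pytest.approx(0.06)  # min(0.06, 0.12, 0.18, ...)
        assert p_after <= 2 * p_before + 1e-12
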