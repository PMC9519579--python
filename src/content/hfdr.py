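"""Hierarchical FDR control over the gene -> context -> model hypothesis tree.

Leaves are (gene, context, model-or-method) p-values; internal nodes aggregate
their children with Simes' combination.  Selection proceeds top down:
Benjamini-Hochberg on the gene-level Simes p-values at level q, then, within
each selected gene, BH on its context-level Simes p-values at level
q * (selected genes / tested genes), and within each selected gene-context, BH
on the leaf p-values at the correspondingly adjusted level.  The multiplicative
level adjustment is the Benjamini-Bogomolov rule used by TreeQTL, which keeps
the expected false discovery proportion controlled at every level of the tree
while gaining power for genes significant in several contexts.  Leaves from
several methods can be pooled into one tree so different predictors compete
within the same correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HypothesisTree",
    "RejectionSet",
    "simes_aggregate",
    "build_tree",
    "hierarchical_bh",
    "pool_methods",
]


def simes_aggregate(pvals) -> float:
    """Simes' combined p-value: min over sorted p of p_(k) * K / k."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("cannot aggregate an empty p-value set")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    k = np.arange(1, p.size + 1)
    return float(min(1.0, (p * p.size / k).min()))


def _grouped_simes(codes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Simes p per group for integer group codes (vectorized)."""
    order = np.lexsort((p, codes))
    pc, cc = p[order], codes[order]
    starts = np.flatnonzero(np.r_[True, cc[1:] != cc[:-1]])
    sizes = np.diff(np.r_[starts, cc.size])
    sizes_rep = np.repeat(sizes, sizes)
    rank = np.arange(cc.size) - np.repeat(starts, sizes) + 1
    return np.minimum(np.minimum.reduceat(pc * sizes_rep / rank, starts), 1.0)


@dataclass
class HypothesisTree:
    """Leaf table (gene, context, method, p) with Simes-aggregated inner nodes."""

    leaves: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "context", "method", "p"}
        if not required.issubset(self.leaves.columns):
            raise ValueError(f"leaf table needs columns {sorted(required)}")
        if self.leaves.duplicated(["gene", "context", "method"]).any():
            raise ValueError("duplicate (gene, context, method) leaves")
        p = self.leaves["p"].to_numpy()
        if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
            raise ValueError("leaf p-values must be finite and in [0, 1]")

    def context_pvalues(self) -> pd.Series:
        """Simes p per (gene, context) over its model/method leaves."""
        idx = pd.MultiIndex.from_frame(self.leaves[["gene", "context"]])
        codes, uniques = pd.factorize(idx)
        vals = _grouped_simes(codes, self.leaves["p"].to_numpy(dtype=float))
        first = np.sort(np.unique(codes, return_index=True)[1])
        out_index = pd.MultiIndex.from_tuples(idx[first], names=["gene", "context"])
        # _grouped_simes returns groups in code order; codes are assigned in
        # first-appearance order, matching out_index
        return pd.Series(vals, index=out_index)

    def gene_pvalues(self) -> pd.Series:
        """Simes p per gene over its context-level aggregated p-values."""
        ctx = self.context_pvalues()
        genes = ctx.index.get_level_values("gene")
        codes, uniques = pd.factorize(genes)
        vals = _grouped_simes(codes, ctx.to_numpy())
        return pd.Series(vals, index=uniques)


@dataclass
class RejectionSet:
    """Tree-consistent selections at every level of the hierarchy."""

    genes: list = field(default_factory=list)
    gene_contexts: list = field(default_factory=list)
    leaves: pd.DataFrame | None = None
    q: float = 0.05


def build_tree(leaves: pd.DataFrame) -> HypothesisTree:
    return HypothesisTree(leaves.reset_index(drop=True))


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Boolean BH rejections at level q."""
    n = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * np.arange(1, n + 1) / n
    passed = p[order] <= thresh
    out = np.zeros(n, dtype=bool)
    if passed.any():
        kmax = int(np.max(np.flatnonzero(passed)))
        out[order[: kmax + 1]] = True
    return out


def hierarchical_bh(tree: HypothesisTree, q: float = 0.05) -> RejectionSet:
    """Top-down BH selection over the gene/context/leaf hierarchy."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    gene_p = tree.gene_pvalues()
    genes = gene_p.index.to_numpy()
    rej_genes = _bh_reject(gene_p.to_numpy(), q)
    selected_genes = list(genes[rej_genes])
    result = RejectionSet(genes=selected_genes, q=q)
    if not selected_genes:
        result.leaves = tree.leaves.iloc[0:0]
        return result

    q2 = q * len(selected_genes) / len(genes)
    ctx_p = tree.context_pvalues()
    selected_pairs: list[tuple] = []
    pair_fraction: dict[tuple, float] = {}
    for g in selected_genes:
        sub = ctx_p.loc[g]
        rej = _bh_reject(sub.to_numpy(), q2)
        for ctx in sub.index[rej]:
            selected_pairs.append((g, ctx))
        if rej.any():
            frac = rej.sum() / rej.size
            for ctx in sub.index[rej]:
                pair_fraction[(g, ctx)] = frac
    result.gene_contexts = selected_pairs

    frames = []
    grouped = tree.leaves.groupby(["gene", "context"], sort=False)
    for pair in selected_pairs:
        leaf = grouped.get_group(pair)
        q3 = q2 * pair_fraction[pair]
        rej = _bh_reject(leaf["p"].to_numpy(), q3)
        frames.append(leaf[rej])
    result.leaves = pd.concat(frames) if frames else tree.leaves.iloc[0:0]
    return result


def pool_methods(*trees: HypothesisTree) -> HypothesisTree:
    """Merge leaf tables of several methods into a single hypothesis tree.

    Raises on duplicate (gene, context, method) keys, so pooling a tree with
    itself is an error.
    """
    combined = pd.concat([t.leaves for t in trees], ignore_index=True)
    if combined.duplicated(["gene", "context", "method"]).any():
        raise ValueError("duplicate (gene, context, method) leaves across pooled trees")
    return HypothesisTree(combined)
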