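"""Alpha diversity indices and beta diversity distance matrices.

Conventions pinned here: Chao1 is bias-corrected, Shannon uses natural log,
Faith PD is root-inclusive (the path from the root to every present tip is
counted), and unweighted UniFrac sums branch lengths over branches on
root-to-tip paths of taxa present in either sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .core_io import AsvTable, CoverageError, DistanceMatrix, check_tip_coverage


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon-Wiener entropy in nats over positive entries."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        return float("nan")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


class BranchTable:
    """Branch lengths and tip-incidence of every non-root branch of a tree.

    ``incidence[b, t]`` is True iff tip ``t`` descends from branch ``b``
    (the branch above each non-root node).  Tips are ordered per
    ``asv_ids``.  This is the workhorse for Faith PD and UniFrac.
    """

    def __init__(self, tree: TreeNode, asv_ids: list[str]):
        check_tip_coverage(tree, asv_ids)
        tip_pos = {a: i for i, a in enumerate(asv_ids)}
        lengths = []
        rows = []
        for node in tree.postorder(include_self=False):
            tips_below = np.zeros(len(asv_ids), dtype=bool)
            if node.is_tip():
                if node.name in tip_pos:
                    tips_below[tip_pos[node.name]] = True
                node._tipmask = tips_below
            else:
                for child in node.children:
                    tips_below |= child._tipmask
                node._tipmask = tips_below
            lengths.append(node.length or 0.0)
            rows.append(tips_below)
        for node in tree.postorder(include_self=False):
            del node._tipmask
        self.lengths = np.asarray(lengths, dtype=float)
        self.incidence = np.asarray(rows, dtype=bool)
        self.asv_ids = list(asv_ids)

    def spanned(self, presence: np.ndarray) -> np.ndarray:
        """Boolean branch mask: branches with >=1 present tip below."""
        return self.incidence @ presence > 0


def faith_pd(presence, tree: TreeNode, asv_ids: list[str] | None = None) -> float:
    """Faith phylogenetic diversity, root-inclusive.

    ``presence`` is either an iterable of taxon names or a boolean vector
    aligned to ``asv_ids``.
    """
    if asv_ids is None:
        names = list(presence)
        asv_ids = names
        vec = np.ones(len(names), dtype=bool)
    else:
        vec = np.asarray(presence, dtype=bool)
    if vec.sum() == 0:
        return 0.0
    bt = tree if isinstance(tree, BranchTable) else BranchTable(tree, list(asv_ids))
    return float(bt.lengths[bt.spanned(vec)].sum())


def alpha_diversity_table(table: AsvTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Observed richness, Chao1, Shannon and (if a tree is given) Faith PD."""
    rows = {}
    bt = None
    if tree is not None:
        bt = BranchTable(tree, table.asv_ids)
    for i, s in enumerate(table.sample_ids):
        c = table.counts[i]
        row = {
            "observed_richness": int((c > 0).sum()),
            "chao1": chao1(c),
            "shannon": shannon(c),
        }
        if bt is not None:
            row["faith_pd"] = faith_pd(c > 0, bt, table.asv_ids)
        rows[s] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), per sample pair."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total have undefined Bray-Curtis: {bad}")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def bray_curtis_matrix(counts: np.ndarray) -> np.ndarray:
    """Square Bray-Curtis matrix straight from a counts/abundance array."""
    return squareform(pdist(np.asarray(counts, dtype=float), metric="braycurtis"))


def unweighted_unifrac(table: AsvTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac over branches spanned by either sample's taxa.

    d(A,B) = sum_b l_b |I_A(b) - I_B(b)| / sum_b l_b max(I_A(b), I_B(b))
    with I_X(b) = 1 iff any tip below b is present in X.
    """
    present_any = table.counts.sum(axis=0) > 0
    covered = [a for a, p in zip(table.asv_ids, present_any) if p]
    check_tip_coverage(tree, covered)
    bt = BranchTable(tree, table.asv_ids)
    presence = table.counts > 0
    # spanned: samples x branches
    spanned = (presence @ bt.incidence.T) > 0
    n = table.n_samples
    d = np.zeros((n, n))
    w = bt.lengths
    for i in range(n):
        for j in range(i + 1, n):
            a, b = spanned[i], spanned[j]
            union = w[a | b].sum()
            if union == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            unique = w[a ^ b].sum()
            d[i, j] = d[j, i] = unique / union
    return DistanceMatrix(list(table.sample_ids), d)
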