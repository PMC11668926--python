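"""Phylogenetic and taxonomic null models for community-assembly inference.

Per sample pair this module computes the between-community mean
nearest-taxon distance (beta-MNTD), its z-score against a tip-shuffling
null (beta-NTI), and an abundance-based Raup-Crick score on Bray-Curtis
(RC-bray).  The (beta-NTI, RC-bray) pair is then mapped to one of five
ecological processes:

    beta-NTI >  2                  -> heterogeneous_selection
    beta-NTI < -2                  -> homogeneous_selection
    |beta-NTI| < 2, RC >  0.95     -> dispersal_limitation
    |beta-NTI| < 2, RC < -0.95     -> homogenizing_dispersal
    |beta-NTI| < 2, |RC| < 0.95    -> undominated

Ties at the cutoffs fall to the non-selection / non-dominant side.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import AsvTable, DistanceMatrix, patristic_matrix
from .diversity import bray_curtis_matrix

logger = logging.getLogger("asvkit")

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)
STOCHASTIC = ("dispersal_limitation", "homogenizing_dispersal", "undominated")
DETERMINISTIC = ("heterogeneous_selection", "homogeneous_selection")


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI
# ---------------------------------------------------------------------------


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance or 1/richness."""
    counts = np.asarray(counts, dtype=float)
    if weighted:
        totals = counts.sum(axis=1, keepdims=True)
        return np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    presence = (counts > 0).astype(float)
    richness = presence.sum(axis=1, keepdims=True)
    return np.divide(presence, richness, out=np.zeros_like(presence),
                     where=richness > 0)


def beta_mntd_matrix(
    counts: np.ndarray, dist: np.ndarray, weighted: bool = True
) -> np.ndarray:
    """All-pairs beta-MNTD for a samples x taxa matrix and patristic matrix.

    For each sample B and every taxon i, the minimum distance from i to any
    taxon present in B is collected once; beta-MNTD(A, B) is then half the
    sum of the two abundance-weighted cross lookups.
    """
    counts = np.asarray(counts)
    n, t = counts.shape
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("empty sample: beta-MNTD undefined")
    F = _weights(counts, weighted)
    present = counts > 0
    M = np.empty((t, n))
    for b in range(n):
        M[:, b] = dist[:, present[b]].min(axis=1)
    cross = F @ M  # cross[a, b] = sum_i f_ia * min-dist(i -> B)
    out = 0.5 * (cross + cross.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(
    counts_a,
    counts_b,
    tree_or_dist,
    asv_ids: list[str] | None = None,
    weighted: bool = True,
) -> float:
    """beta-MNTD for one pair of abundance vectors."""
    if isinstance(tree_or_dist, TreeNode):
        dist = patristic_matrix(tree_or_dist, list(asv_ids))
    else:
        dist = np.asarray(tree_or_dist, dtype=float)
    counts = np.vstack([counts_a, counts_b])
    return float(beta_mntd_matrix(counts, dist, weighted=weighted)[0, 1])


def beta_nti(
    table: AsvTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> DistanceMatrix:
    """beta-NTI z-scores from a regional tip-shuffling null.

    Each null replicate permutes taxon labels across all tips of the
    supplied tree (equivalently the rows/columns of the patristic matrix)
    and recomputes beta-MNTD.  When the number of taxa is small enough that
    all permutations fit within ``n_null`` the null is enumerated
    exhaustively.  Pairs with zero null standard deviation come back NaN.
    """
    dist = patristic_matrix(tree, table.asv_ids)
    return beta_nti_from_dist(table.counts, dist, table.sample_ids,
                              n_null=n_null, seed=seed, weighted=weighted)


def beta_nti_from_dist(
    counts: np.ndarray,
    dist: np.ndarray,
    sample_ids: list[str],
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> DistanceMatrix:
    t = dist.shape[0]
    obs = beta_mntd_matrix(counts, dist, weighted=weighted)
    if math.factorial(t) <= n_null:
        perms = [np.asarray(p) for p in itertools.permutations(range(t))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(t) for _ in range(n_null)]
    nulls = np.empty((len(perms), counts.shape[0], counts.shape[0]))
    for r, perm in enumerate(perms):
        nulls[r] = beta_mntd_matrix(counts, dist[np.ix_(perm, perm)], weighted=weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, 0.0)
    n_degenerate = int(np.isnan(z[np.triu_indices_from(z, k=1)]).sum())
    if n_degenerate:
        logger.warning("%d sample pairs have degenerate (sd=0) beta-MNTD nulls",
                       n_degenerate)
    return DistanceMatrix(list(sample_ids), z)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occupancy_p: np.ndarray,
    abundance_p: np.ndarray,
) -> np.ndarray:
    """One null sample: occupancy-weighted taxon draw + abundance fill."""
    t = len(occupancy_p)
    chosen = rng.choice(t, size=richness, replace=False, p=occupancy_p)
    counts = np.zeros(t, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        w = abundance_p[chosen]
        w = w / w.sum()
        counts[chosen] += rng.multinomial(remaining, w)
    return counts


def raup_crick_bray(
    table: AsvTable,
    n_null: int = 999,
    seed: int | None = None,
    tie_tol: float = 1e-10,
) -> DistanceMatrix:
    """Raup-Crick scores on Bray-Curtis, rescaled to [-1, 1].

    Null communities preserve each sample's richness and total reads; taxa
    are drawn without replacement with probability proportional to regional
    occupancy, then remaining reads are allocated multinomially with
    probability proportional to regional relative abundance.  RC compares
    the observed Bray-Curtis of a pair against its null distribution
    ((below + half ties) / n_null, mapped to 2*RC - 1).
    """
    counts = table.counts
    n, t = counts.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = occupancy > 0
    if np.any(richness > pool.sum()):
        raise ValueError("sample richness exceeds regional pool size")
    occupancy_p = occupancy / occupancy.sum()
    abundance = counts.sum(axis=0).astype(float)
    abundance_p = abundance / abundance.sum()

    rng = np.random.default_rng(seed)
    obs = bray_curtis_matrix(counts)
    iu = np.triu_indices(n, k=1)
    obs_c = obs[iu]

    below = np.zeros(len(obs_c))
    ties = np.zeros(len(obs_c))
    for _ in range(n_null):
        null_counts = np.empty_like(counts)
        for s in range(n):
            null_counts[s] = _null_community(
                rng, int(richness[s]), int(totals[s]), occupancy_p, abundance_p
            )
        null_c = bray_curtis_matrix(null_counts)[iu]
        tol = tie_tol * np.maximum(np.abs(null_c), np.abs(obs_c)) + 1e-300
        tie = np.abs(null_c - obs_c) <= tol
        ties += tie
        below += (null_c < obs_c) & ~tie
    rc = (below + 0.5 * ties) / n_null
    rc = 2.0 * rc - 1.0
    out = np.zeros((n, n))
    out[iu] = rc
    out = out + out.T
    return DistanceMatrix(list(table.sample_ids), out)


# ---------------------------------------------------------------------------
# five-way process classification
# ---------------------------------------------------------------------------


@dataclass
class AssemblyClassification:
    """Long-format per-pair beta-NTI, RC-bray and process label."""

    pairs: pd.DataFrame  # sample_i, sample_j, beta_nti, rc_bray, process
    n_excluded: int  # pairs dropped for missing beta-NTI


def classify_pair(nti: float, rc: float, nti_cut: float = 2.0,
                  rc_cut: float = 0.95) -> str:
    if np.isnan(nti):
        return "unclassified"
    if nti > nti_cut:
        return "heterogeneous_selection"
    if nti < -nti_cut:
        return "homogeneous_selection"
    if rc > rc_cut:
        return "dispersal_limitation"
    if rc < -rc_cut:
        return "homogenizing_dispersal"
    return "undominated"


def classify_processes(
    beta_nti: DistanceMatrix,
    rc: DistanceMatrix,
    nti_cut: float = 2.0,
    rc_cut: float = 0.95,
) -> AssemblyClassification:
    """Apply the five-way decision rule to every sample pair."""
    if beta_nti.ids != rc.ids:
        raise ValueError("beta-NTI and RC matrices must share sample ids")
    ids = beta_nti.ids
    rows = []
    n_excluded = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            nti = beta_nti.data[i, j]
            rcv = rc.data[i, j]
            label = classify_pair(nti, rcv, nti_cut, rc_cut)
            if label == "unclassified":
                n_excluded += 1
                continue
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "beta_nti": nti,
                    "rc_bray": rcv,
                    "process": label,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "beta_nti", "rc_bray", "process"]
    )
    return AssemblyClassification(frame, n_excluded)


def process_fractions(
    cls: AssemblyClassification,
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction of classified pairs per process, within each stratum.

    Only pairs whose two samples share a stratum label are counted; with
    ``strata=None`` all pairs form one stratum named "all".  Adds the
    deterministic (both selections) and stochastic (the rest) totals.
    """
    df = cls.pairs
    if strata is None:
        df = df.assign(stratum="all")
    else:
        lab_i = df["sample_i"].map(strata)
        lab_j = df["sample_j"].map(strata)
        df = df.assign(stratum=lab_i.where(lab_i == lab_j))
        df = df.dropna(subset=["stratum"])
    rows = []
    for stratum, grp in df.groupby("stratum"):
        counts = grp["process"].value_counts()
        total = len(grp)
        row = {"stratum": stratum, "n_pairs": total}
        for proc in PROCESSES:
            row[proc] = counts.get(proc, 0) / total
        row["deterministic"] = sum(row[p] for p in DETERMINISTIC)
        row["stochastic"] = sum(row[p] for p in STOCHASTIC)
        rows.append(row)
    return pd.DataFrame(rows)
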