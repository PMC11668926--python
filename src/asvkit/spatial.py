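"""Distance-decay regression and ANOSIM with permutation significance.

Both tests permute sample identities.  When the full permutation group is
no larger than the requested number of permutations it is enumerated
exhaustively (exact p, observed arrangement included); otherwise random
permutations are drawn and the add-one rule keeps p > 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import DistanceMatrix, SampleMetadata


@dataclass
class DecayFit:
    slope: float  # similarity units per 1,000 km
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    n_permutations: int
    exhaustive: bool


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    grouping: str
    group_sizes: dict


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = (xc * xc).sum()
    if sxx == 0:
        raise ValueError("geographic separations are constant; slope undefined")
    slope = (xc * yc).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    syy = (yc * yc).sum()
    r2 = 0.0 if syy == 0 else slope * slope * sxx / syy
    return slope, intercept, r2


def _permutations(n: int, n_perm: int, seed) -> tuple[list[np.ndarray], bool]:
    """All n! permutations if that is <= n_perm, else n_perm random draws."""
    if math.factorial(n) <= n_perm:
        return [np.asarray(p) for p in itertools.permutations(range(n))], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def distance_decay(
    beta: DistanceMatrix,
    meta: SampleMetadata,
    n_perm: int = 9999,
    seed: int | None = None,
) -> DecayFit:
    """Regress pairwise similarity (1 - d) on along-river separation.

    Separation between two samples is the absolute difference of their
    distance-to-mouth, in units of 1,000 km so the slope is per 1,000 km.
    The permutation test shuffles which sample carries which position and
    is two-sided on |slope|.
    """
    meta = meta.aligned_to(beta.ids)
    pos_km = meta.frame["dist_to_mouth_km"].to_numpy(dtype=float)
    n = beta.n
    iu = np.triu_indices(n, k=1)
    sim = 1.0 - beta.condensed()

    def fit(positions):
        g = np.abs(positions[iu[0]] - positions[iu[1]]) / 1000.0
        return _ols_slope(g, sim)

    slope, intercept, r2 = fit(pos_km)
    perms, exhaustive = _permutations(n, n_perm, seed)
    hits = 0
    for p in perms:
        s_perm, _, _ = fit(pos_km[p])
        if abs(s_perm) >= abs(slope) - 1e-12:
            hits += 1
    if exhaustive:
        p_value = hits / len(perms)
    else:
        p_value = (hits + 1) / (len(perms) + 1)
    return DecayFit(slope, intercept, r2, p_value, len(sim), len(perms), exhaustive)


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, n: int) -> float:
    rb = ranks[~same_group].mean()
    rw = ranks[same_group].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(
    beta: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    grouping: str = "group",
) -> AnosimResult:
    """Rank-based ANOSIM; p counts permutations with R >= observed R.

    Groups of size one are excluded with a warning; at least two groups of
    size >= 2 must remain.
    """
    groups = pd.Series(list(groups), index=beta.ids)
    sizes = groups.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        import logging

        logging.getLogger("asvkit").warning(
            "excluding singleton groups from ANOSIM: %s", small
        )
        keep = [s for s in beta.ids if groups[s] not in small]
        beta = beta.filter(keep)
        groups = groups.loc[keep]
        sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups with >= 2 samples")

    n = beta.n
    labels = groups.to_numpy()
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(beta.condensed())

    def stat(lab):
        same = lab[iu[0]] == lab[iu[1]]
        return _anosim_r(ranks, same, n)

    r_obs = stat(labels)
    perms, exhaustive = _permutations(n, n_perm, seed)
    hits = sum(1 for p in perms if stat(labels[p]) >= r_obs - 1e-12)
    if exhaustive:
        p_value = hits / len(perms)
    else:
        p_value = (hits + 1) / (len(perms) + 1)
    return AnosimResult(r_obs, p_value, len(perms), grouping, sizes.to_dict())


def pairwise_anosim(
    beta: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One ANOSIM per unordered group pair, as a long-format table."""
    groups = pd.Series(list(groups), index=beta.ids)
    levels = sorted(groups.unique())
    rows = []
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1 :]:
            ids = [s for s in beta.ids if groups[s] in (g1, g2)]
            sub_groups = groups.loc[ids]
            if min(sub_groups.value_counts().reindex([g1, g2], fill_value=0)) < 2:
                rows.append(
                    {"group1": g1, "group2": g2, "r": np.nan, "p_value": np.nan}
                )
                continue
            res = anosim(
                beta.filter(ids), sub_groups, n_perm=n_perm, seed=seed,
                grouping=f"{g1} vs {g2}",
            )
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "r": res.r_statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
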