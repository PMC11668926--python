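"""Environmental attribution: Mantel tests, variance partitioning, rank tests."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .core_io import AsvTable, DistanceMatrix, SampleMetadata


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    controlled: str | None = None
    exhaustive: bool = False


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return dm.condensed()


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _perm_indices(n: int, n_perm: int, seed):
    if math.factorial(n) <= n_perm:
        return [np.asarray(p) for p in itertools.permutations(range(n))], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    p is the one-sided (greater) fraction of row/column permutations of
    ``dm2`` whose correlation reaches the observed one, with the add-one
    rule under random sampling and exact enumeration when n! <= n_perm.
    """
    if dm1.ids != dm2.ids:
        dm2 = dm2.filter(dm1.ids)
    n = dm1.n
    if n < 4:
        raise ValueError("Mantel needs at least 4 samples")
    v1 = _condensed(dm1)
    r_obs = _corr(v1, _condensed(dm2), method)
    perms, exhaustive = _perm_indices(n, n_perm, seed)
    hits = 0
    for p in perms:
        v2p = dm2.data[np.ix_(p, p)][np.triu_indices(n, k=1)]
        if _corr(v1, v2p, method) >= r_obs - 1e-12:
            hits += 1
    p_value = hits / len(perms) if exhaustive else (hits + 1) / (len(perms) + 1)
    return MantelResult(r_obs, p_value, len(perms), method, None, exhaustive)


def partial_mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    dm_c: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel r of A~B controlling C, permuting B."""
    for other in (dm_b, dm_c):
        if other.ids != dm_a.ids:
            raise ValueError("distance matrices must share ids in order")
    n = dm_a.n
    va = _condensed(dm_a)
    vc = _condensed(dm_c)

    def partial_r(vb: np.ndarray) -> float:
        r_ab = _corr(va, vb, method)
        r_ac = _corr(va, vc, method)
        r_bc = _corr(vb, vc, method)
        denom2 = max(1.0 - r_ac**2, 0.0) * max(1.0 - r_bc**2, 0.0)
        if denom2 < 1e-24:
            raise ValueError("control matrix perfectly correlated; undefined")
        denom = math.sqrt(denom2)
        return (r_ab - r_ac * r_bc) / denom

    r_obs = partial_r(_condensed(dm_b))
    perms, exhaustive = _perm_indices(n, n_perm, seed)
    hits = 0
    for p in perms:
        vbp = dm_b.data[np.ix_(p, p)][np.triu_indices(n, k=1)]
        if partial_r(vbp) >= r_obs - 1e-12:
            hits += 1
    p_value = hits / len(perms) if exhaustive else (hits + 1) / (len(perms) + 1)
    return MantelResult(r_obs, p_value, len(perms), method, "dm_c", exhaustive)


def env_distance(meta: SampleMetadata, factor: str) -> DistanceMatrix:
    """Euclidean distance on one z-scored environmental factor."""
    if factor == "dist_to_mouth_km":
        vals = meta.frame["dist_to_mouth_km"].to_numpy(dtype=float)
    else:
        vals = meta.env_matrix([factor]).to_numpy(dtype=float).ravel()
    sd = vals.std(ddof=1)
    if sd == 0:
        import logging

        logging.getLogger("asvkit").warning("factor %s is constant", factor)
        z = np.zeros_like(vals)
    else:
        z = (vals - vals.mean()) / sd
    d = np.abs(z[:, None] - z[None, :])
    return DistanceMatrix(meta.sample_ids, d)


def env_distance_block(meta: SampleMetadata, factors: list[str]) -> DistanceMatrix:
    """Euclidean distance on a z-scored block of factors."""
    x = meta.env_matrix(factors).to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(meta.sample_ids, d)


# ---------------------------------------------------------------------------
# variance partitioning (RDA)
# ---------------------------------------------------------------------------


@dataclass
class VpaResult:
    """Adjusted-R2 shares: a (pure set1), b (shared), c (pure set2), d (resid).

    ``raw`` keeps the untruncated values; the top-level fields truncate
    negative fractions to 0 as commonly reported.
    """

    a: float
    b: float
    c: float
    d: float
    raw: dict
    n: int


def hellinger(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.sqrt(counts / totals)


def _rda_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Share of total (centered) sum of squares explained by predictors."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    xc = xc / sd
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        raise ValueError("rank-deficient predictor set (collinear columns)")
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    ss_tot = float((yc**2).sum())
    if ss_tot == 0:
        raise ValueError("community matrix has zero variance")
    return float((fitted**2).sum()) / ss_tot, xc.shape[1]


def _adj(r2: float, n: int, m: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def vpa_two_sets(
    community,
    set1: pd.DataFrame | np.ndarray,
    set2: pd.DataFrame | np.ndarray,
    transform: str = "hellinger",
) -> VpaResult:
    """Two-set variance partitioning via RDA and Ezekiel-adjusted R2.

    ``community`` is an :class:`AsvTable` or a plain response matrix;
    counts are Hellinger-transformed unless ``transform='none'``.
    """
    y = community.counts if isinstance(community, AsvTable) else np.asarray(
        community, dtype=float
    )
    if transform == "hellinger":
        y = hellinger(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    x1 = np.asarray(set1, dtype=float)
    x2 = np.asarray(set2, dtype=float)
    n = y.shape[0]
    if x1.ndim == 1:
        x1 = x1[:, None]
    if x2.ndim == 1:
        x2 = x2.reshape(n, -1) if x2.size else x2.reshape(n, 0)
    m1, m2 = x1.shape[1], x2.shape[1]
    if n <= m1 + m2 + 1:
        raise ValueError("need n samples > total predictors + 1")

    r2_1, _ = _rda_r2(y, x1)
    adj1 = _adj(r2_1, n, m1)
    if m2 == 0:
        r2_2, adj2 = 0.0, 0.0
        r2_u, adju = r2_1, adj1
    else:
        r2_2, _ = _rda_r2(y, x2)
        r2_u, _ = _rda_r2(y, np.hstack([x1, x2]))
        adj2 = _adj(r2_2, n, m2)
        adju = _adj(r2_u, n, m1 + m2)

    a = adju - adj2
    c = adju - adj1
    b = adj1 + adj2 - adju
    d = 1.0 - adju
    raw = {
        "a": a, "b": b, "c": c, "d": d,
        "adj_set1": adj1, "adj_set2": adj2, "adj_union": adju,
        "r2_set1": r2_1, "r2_set2": r2_2, "r2_union": r2_u,
    }
    return VpaResult(max(a, 0.0), max(b, 0.0), max(c, 0.0), max(d, 0.0), raw, n)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_max_n: int = 12) -> tuple[float, float]:
    """Rank-sum test with average-rank ties.

    Returns (W, p) where W is the rank-sum of ``x`` in the pooled ranking.
    Exact p by enumerating all assignments when n_x + n_y <= exact_max_n,
    otherwise normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = float(ranks[:nx].sum())
    mean_w = nx * (n + 1) / 2.0

    if n <= exact_max_n:
        dev_obs = abs(w_obs - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            w = ranks[list(combo)].sum()
            total += 1
            if alternative == "two-sided":
                if abs(w - mean_w) >= dev_obs - 1e-12:
                    count += 1
            elif alternative == "less":
                if w <= w_obs + 1e-12:
                    count += 1
            elif alternative == "greater":
                if w >= w_obs - 1e-12:
                    count += 1
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return w_obs, count / total

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return w_obs, 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return w_obs, float(min(p, 1.0))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mantel_table(
    targets: dict[str, DistanceMatrix],
    meta: SampleMetadata,
    factors: list[str],
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
    control: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Mantel (or partial Mantel, if ``control`` is given) r/p per
    factor x target matrix — the long-format analogue of a factor table."""
    rows = []
    for target_name, dm in targets.items():
        sub_meta = meta.aligned_to(dm.ids)
        for factor in factors:
            ed = env_distance(sub_meta, factor)
            if control is not None:
                res = partial_mantel(dm, ed, control.filter(dm.ids),
                                     method=method, n_perm=n_perm, seed=seed)
            else:
                res = mantel(dm, ed, method=method, n_perm=n_perm, seed=seed)
            rows.append(
                {
                    "target": target_name,
                    "factor": factor,
                    "r": res.r,
                    "p_value": res.p_value,
                    "controlled": res.controlled is not None,
                }
            )
    return pd.DataFrame(rows)
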