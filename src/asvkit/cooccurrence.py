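"""Thresholded Spearman co-occurrence networks and random-graph nulls.

The network keeps an edge when Spearman's rho exceeds the (positive)
threshold and the t-approximation p-value is below alpha.  Null ensembles
are uniform G(n, m) graphs — the same node and edge counts as the observed
network — sampled directly as arrays so ten-thousand-replicate ensembles
stay cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .core_io import AsvTable

logger = logging.getLogger("asvkit")


def prevalence_filter(table: AsvTable, min_detection: float = 0.20) -> AsvTable:
    """Keep ASVs detected (count > 0) in at least ``min_detection`` of samples."""
    frac = (table.counts > 0).mean(axis=0)
    keep = [a for a, f in zip(table.asv_ids, frac) if f >= min_detection]
    return table.select_asvs(keep)


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph over ASV nodes with rho/p edge attributes."""

    graph: nx.Graph
    rho_min: float
    alpha: float
    absolute: bool = False

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"node1": u, "node2": v, "rho": d["rho"], "p_value": d["p_value"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "rho", "p_value"])


def spearman_correlations(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p-values.

    Columns are variables.  Ties get average ranks.  Returns (rho, p) square
    matrices; zero-variance columns yield NaN rows/columns.
    """
    n, m = counts.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation edges")
    ranks = np.apply_along_axis(rankdata, 0, counts.astype(float))
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - ranks.mean(axis=0)) / sd
    z[:, sd == 0] = 0.0
    rho = (z.T @ z) / n
    rho = np.clip(rho, -1.0, 1.0)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def spearman_edges(
    table: AsvTable,
    rho_min: float = 0.8,
    alpha: float = 0.01,
    absolute: bool = False,
    node_attrs: dict[str, dict] | None = None,
) -> CooccurrenceNetwork:
    """Build the co-occurrence network from pairwise Spearman correlations.

    By default only positive correlations (rho > rho_min) form edges;
    ``absolute=True`` admits |rho| > rho_min.  Nodes are the ASVs incident
    to at least one retained edge.
    """
    rho, p = spearman_correlations(table.counts)
    zero_var = np.isnan(np.diag(rho))
    if zero_var.any():
        names = [a for a, z in zip(table.asv_ids, zero_var) if z]
        logger.warning("%d zero-variance ASVs excluded from network: %s",
                       len(names), names[:5])
    strength = np.abs(rho) if absolute else rho
    iu = np.triu_indices(table.n_asvs, k=1)
    keep = (strength[iu] > rho_min) & (p[iu] < alpha)
    keep &= ~np.isnan(rho[iu])

    g = nx.Graph()
    ids = table.asv_ids
    pos = {a: i for i, a in enumerate(ids)}
    rel_mean = table.relative_abundance().mean(axis=0)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(ids[i], ids[j], rho=float(rho[i, j]), p_value=float(p[i, j]))
    for node in g.nodes:
        g.nodes[node]["mean_relabund"] = float(rel_mean[pos[node]])
        if node_attrs:
            for key, mapping in node_attrs.items():
                g.nodes[node][key] = mapping.get(node)
    return CooccurrenceNetwork(g, rho_min, alpha, absolute)


def topology(net: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """Per-node degree, raw betweenness and normalized closeness.

    Betweenness is unnormalized shortest-path count (the keystone cutoff is
    on the raw scale); closeness uses the component-size scaling so it lies
    in [0, 1], and isolated nodes get 0.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    betw = nx.betweenness_centrality(g, normalized=False)
    close = nx.closeness_centrality(g, wf_improved=True)
    df = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
        }
    )
    df.index.name = "node"
    return df


def keystones(
    topo: pd.DataFrame,
    degree_min: float = 100,
    betweenness_max: float = 5000,
) -> list[str]:
    """Nodes with degree > degree_min and betweenness < betweenness_max."""
    mask = (topo["degree"] > degree_min) & (topo["betweenness"] < betweenness_max)
    return list(topo.index[mask])


# ---------------------------------------------------------------------------
# Erdos-Renyi G(n, m) null ensemble
# ---------------------------------------------------------------------------


def _decode_pairs(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear upper-triangle indices to (i, j) node pairs, i < j."""
    # row i satisfies k within [i*n - i(i+1)/2 - i, ...); solve quadratic
    kk = k.astype(np.float64)
    i = np.floor(((2 * n - 1) - np.sqrt((2 * n - 1) ** 2 - 8 * kk)) / 2).astype(np.int64)
    # pairs preceding row i: i*(n-1) - i*(i-1)/2
    offset = i * (n - 1) - (i * (i - 1)) // 2
    j = k - offset + i + 1
    # guard against float rounding at row boundaries
    bad = j <= i
    if np.any(bad):
        i[bad] -= 1
        offset = i[bad] * (n - 1) - (i[bad] * (i[bad] - 1)) // 2
        j[bad] = k[bad] - offset + i[bad] + 1
    return i, j


@dataclass
class ErEnsemble:
    """A stack of G(n, m) replicates stored as edge-endpoint arrays."""

    n_nodes: int
    n_edges: int
    edges_i: np.ndarray  # (reps, m)
    edges_j: np.ndarray

    @property
    def reps(self) -> int:
        return self.edges_i.shape[0]

    def degree_sequences(self) -> np.ndarray:
        """(reps, n_nodes) array of degrees."""
        out = np.zeros((self.reps, self.n_nodes), dtype=np.int64)
        for r in range(self.reps):
            out[r] = np.bincount(self.edges_i[r], minlength=self.n_nodes) + np.bincount(
                self.edges_j[r], minlength=self.n_nodes
            )
        return out

    def mean_spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble-averaged integer-degree frequency spectrum.

        This is what gets plotted (and fitted) when the degree distribution
        of "the" random network is reported for a many-replicate ensemble.
        """
        degs = self.degree_sequences()
        top = int(degs.max()) + 1
        freq = np.zeros(top)
        for row in degs:
            freq += np.bincount(row, minlength=top)
        freq /= self.reps
        lo = int(degs.min())
        return np.arange(lo, top), freq[lo:]

    def graph(self, rep: int = 0) -> nx.Graph:
        g = nx.empty_graph(self.n_nodes)
        g.add_edges_from(zip(self.edges_i[rep].tolist(), self.edges_j[rep].tolist()))
        return g


def er_null_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 10000,
    seed: int | None = None,
) -> ErEnsemble:
    """Sample ``reps`` uniform simple graphs with exactly ``n_edges`` edges."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    if n_edges < 0 or reps < 1:
        raise ValueError("n_edges and reps must be nonnegative/positive")
    rng = np.random.default_rng(seed)
    ei = np.empty((reps, n_edges), dtype=np.int64)
    ej = np.empty((reps, n_edges), dtype=np.int64)
    for r in range(reps):
        k = rng.choice(max_edges, size=n_edges, replace=False)
        ei[r], ej[r] = _decode_pairs(k, n_nodes)
    return ErEnsemble(n_nodes, n_edges, ei, ej)


# ---------------------------------------------------------------------------
# degree-distribution fits
# ---------------------------------------------------------------------------


@dataclass
class DegreeFit:
    model: str
    parameters: dict
    r_squared: float
    adjusted_r_squared: float
    n_points: int


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def degree_spectrum(degrees: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer degrees (min..max of positive-degree nodes) and frequencies."""
    degrees = np.asarray(degrees)
    degrees = degrees[degrees > 0]
    freq = np.bincount(degrees)
    lo = degrees.min()
    ks = np.arange(lo, degrees.max() + 1)
    return ks, freq[lo:].astype(float)


def fit_degree_distribution(graph_or_degrees, model: str) -> DegreeFit:
    """Fit the degree-frequency spectrum with a power law or a Gaussian.

    power_law: OLS of log10(freq) on log10(k), zero-frequency degrees
    dropped.  gaussian: least squares of a*exp(-(k-mu)^2/(2 sigma^2)) on the
    unbinned integer spectrum.
    """
    if isinstance(graph_or_degrees, (nx.Graph,)):
        degrees = np.array([d for _, d in graph_or_degrees.degree()])
    elif isinstance(graph_or_degrees, CooccurrenceNetwork):
        degrees = np.array([d for _, d in graph_or_degrees.graph.degree()])
    elif (
        isinstance(graph_or_degrees, tuple) and len(graph_or_degrees) == 2
    ):  # a pre-tabulated (degrees, frequencies) spectrum
        degrees = None
    else:
        degrees = np.asarray(graph_or_degrees)
    if degrees is None:
        ks = np.asarray(graph_or_degrees[0])
        freq = np.asarray(graph_or_degrees[1], dtype=float)
    else:
        if (degrees >= 1).sum() < 10:
            raise ValueError("need at least 10 nodes with degree >= 1")
        ks, freq = degree_spectrum(degrees)

    if model == "power_law":
        pos = freq > 0
        x = np.log10(ks[pos])
        y = np.log10(freq[pos])
        if len(x) < 3:
            raise ValueError("too few distinct degrees for a power-law fit")
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return DegreeFit(
            "power_law",
            {"exponent": float(slope), "log10_intercept": float(intercept)},
            r2,
            _adjusted_r2(r2, len(x), 1),
            len(x),
        )
    if model == "gaussian":
        if len(ks) < 4:
            raise ValueError("too few distinct degrees for a Gaussian fit")
        w = freq / freq.sum()
        mu0 = float((ks * w).sum())
        sd0 = float(np.sqrt(((ks - mu0) ** 2 * w).sum())) or 1.0
        p0 = [float(freq.max()), mu0, sd0]

        def gauss(k, a, mu, sigma):
            return a * np.exp(-((k - mu) ** 2) / (2.0 * sigma**2))

        popt, _ = curve_fit(gauss, ks.astype(float), freq, p0=p0, maxfev=20000)
        fitted = gauss(ks.astype(float), *popt)
        ss_res = float(((freq - fitted) ** 2).sum())
        ss_tot = float(((freq - freq.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return DegreeFit(
            "gaussian",
            {"a": float(popt[0]), "mu": float(popt[1]), "sigma": abs(float(popt[2]))},
            r2,
            _adjusted_r2(r2, len(ks), 3),
            len(ks),
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# group co-existence (O/R)
# ---------------------------------------------------------------------------


def o_r_ratios(
    net: CooccurrenceNetwork,
    groups: dict[str, str],
    ensemble: ErEnsemble,
) -> pd.DataFrame:
    """Observed vs null-expected edge counts between node groups.

    Nodes of the observed network are mapped onto the ensemble's node
    indices in ``net.nodes`` order, so labels stay fixed to nodes across
    replicates.  Returns one row per unordered label pair with O, R, O% and
    O/R (infinite when R = 0 with O > 0).
    """
    nodes = net.nodes
    missing = [v for v in nodes if v not in groups]
    if missing:
        raise KeyError(f"unlabeled nodes: {missing[:5]}")
    if ensemble.n_nodes != len(nodes):
        raise ValueError("ensemble node count must match network node count")
    labels = sorted({groups[v] for v in nodes})
    lab_idx = {g: i for i, g in enumerate(labels)}
    L = len(labels)
    node_lab = np.array([lab_idx[groups[v]] for v in nodes])

    def pair_counts(ei: np.ndarray, ej: np.ndarray) -> np.ndarray:
        a = node_lab[ei]
        b = node_lab[ej]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        flat = lo * L + hi
        return np.bincount(flat, minlength=L * L).reshape(L, L)

    node_pos = {v: i for i, v in enumerate(nodes)}
    obs_i = np.array([node_pos[u] for u, v in net.graph.edges()], dtype=np.int64)
    obs_j = np.array([node_pos[v] for u, v in net.graph.edges()], dtype=np.int64)
    observed = pair_counts(obs_i, obs_j)

    null_sum = np.zeros((L, L), dtype=float)
    for r in range(ensemble.reps):
        null_sum += pair_counts(ensemble.edges_i[r], ensemble.edges_j[r])
    expected = null_sum / ensemble.reps

    total_edges = net.n_edges
    rows = []
    for i in range(L):
        for j in range(i, L):
            o = float(observed[i, j])
            rr = float(expected[i, j])
            if rr > 0:
                ratio = o / rr
            else:
                ratio = np.inf if o > 0 else 0.0
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "observed": o,
                    "expected": rr,
                    "o_percent": 100.0 * o / total_edges if total_edges else np.nan,
                    "o_r_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
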