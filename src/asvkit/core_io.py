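"""Canonical data model and I/O for ASV count tables, trees and metadata.

The count table is held samples-as-rows throughout the package.  Readers
accept both orientations (TSV with either samples or ASVs as rows, plus a
minimal BIOM-JSON dialect, which is ASVs-as-rows and gets transposed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("asvkit")

ENV_FACTORS = (
    "WT",
    "pH",
    "NH3-N",
    "NO3-N",
    "TN",
    "TOC",
    "TP",
    "river_flow",
    "channel_slope",
)

LANDFORMS = ("mountain", "hill", "basin", "mountain-hill", "plain")

SEASONS = ("spring", "autumn")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class CoverageError(ValueError):
    """Raised when tree tips do not cover the taxa they must cover."""


@dataclass
class AsvTable:
    """Integer count matrix, samples x ASVs, with row/column identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, one per row.
    asv_ids : list of str
        Unique ASV labels, one per column.
    counts : ndarray of int
        Nonnegative counts with shape ``(len(sample_ids), len(asv_ids))``.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"ASV {self.asv_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise FormatError("duplicate ASV ids")
        self.counts = self.counts.astype(np.int64, copy=False)

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; rows with zero total are left at zero."""
        totals = self.sample_totals().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def select_asvs(self, asv_ids: list[str]) -> "AsvTable":
        idx = {a: i for i, a in enumerate(self.asv_ids)}
        missing = [a for a in asv_ids if a not in idx]
        if missing:
            raise KeyError(f"unknown ASV ids: {missing[:5]}")
        cols = [idx[a] for a in asv_ids]
        return AsvTable(list(self.sample_ids), list(asv_ids), self.counts[:, cols])

    def select_samples(self, sample_ids: list[str]) -> "AsvTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return AsvTable(list(sample_ids), list(self.asv_ids), self.counts[rows, :])


@dataclass
class SampleMetadata:
    """Per-sample season, landform, river position and environmental vector."""

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = {"season", "landform", "dist_to_mouth_km"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        if (self.frame["dist_to_mouth_km"] < 0).any():
            raise FormatError("dist_to_mouth_km must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def env_matrix(self, factors: list[str] | None = None) -> pd.DataFrame:
        factors = list(factors) if factors is not None else [
            f for f in ENV_FACTORS if f in self.frame.columns
        ]
        unknown = [f for f in factors if f not in self.frame.columns]
        if unknown:
            raise KeyError(f"unknown environmental factors: {unknown}")
        return self.frame[factors].astype(float)

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(self.frame.loc[sample_ids].copy())


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distance/dissimilarity matrix."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(self.data, self.data.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        diag = np.diag(self.data)
        if not np.allclose(diag[~np.isnan(diag)], 0.0):
            raise ValueError("matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]

    def filter(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        rows = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(rows, rows)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_asv_table(
    path,
    format: str = "tsv",
    samples_as_rows: bool | None = None,
) -> AsvTable:
    """Read a count table from TSV or minimal BIOM-JSON.

    For TSV the first column holds row ids and the header holds column ids.
    ``samples_as_rows=None`` auto-detects orientation from the corner-cell
    label (``sample_id`` vs anything else defaults to samples-as-rows).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        corner = df.index.name or ""
        if samples_as_rows is None:
            samples_as_rows = corner.lower() not in {"asv_id", "asv", "otu_id", "otu"}
        if not samples_as_rows:
            df = df.T
    elif format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(rows), len(cols)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        # BIOM rows are observations (ASVs); transpose to canonical layout.
        df = pd.DataFrame(mat, index=rows, columns=cols).T
    else:
        raise ValueError(f"unknown format {format!r}")

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(_is_number)(values))
        i, j = bad[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise FormatError(
            f"non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return AsvTable(
        [str(s) for s in df.index],
        [str(a) for a in df.columns],
        values.astype(np.int64),
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_asv_table(table: AsvTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"cannot parse newick tree {path!r}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branches had no length; set to 0", n_missing)
    return tree


def check_tip_coverage(tree: TreeNode, asv_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise CoverageError(
            f"{len(missing)} ASVs absent from tree tips, e.g. {missing[:5]}"
        )


def patristic_matrix(tree: TreeNode, asv_ids: list[str]) -> np.ndarray:
    """Pairwise patristic (sum of branch length) distances between tips."""
    check_tip_coverage(tree, asv_ids)
    dm = tree.tip_tip_distances(endpoints=list(asv_ids))
    return dm.filter(asv_ids).data.copy()


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("metadata CSV must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, index_label="sample_id")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = dm.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# rarefaction & coverage
# ---------------------------------------------------------------------------


def rarefy(
    table: AsvTable,
    depth: int | None = None,
    seed: int | None = None,
    drop_short: bool = True,
) -> AsvTable:
    """Subsample every sample to even depth without replacement.

    ``depth=None`` uses the minimum sample total.  Samples whose total is
    below ``depth`` are dropped with a warning when ``drop_short`` is true,
    otherwise an error is raised.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    short = totals < depth
    if short.any():
        names = [s for s, f in zip(table.sample_ids, short) if f]
        if not drop_short:
            raise ValueError(f"samples below depth {depth}: {names}")
        logger.warning("dropping %d samples below depth %d: %s", len(names), depth, names)
    keep = [i for i in range(table.n_samples) if not short[i]]
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.n_asvs), dtype=np.int64)
    for r, i in enumerate(keep):
        row = table.counts[i]
        if row.sum() == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
    return AsvTable([table.sample_ids[i] for i in keep], list(table.asv_ids), out)


def goods_coverage(table: AsvTable) -> pd.Series:
    """Good's coverage 1 - F1/N per sample; empty samples get NaN."""
    totals = table.sample_totals().astype(float)
    singletons = (table.counts == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = 1.0 - singletons / totals
    cov = np.where(totals > 0, cov, np.nan)
    return pd.Series(cov, index=table.sample_ids, name="goods_coverage")


def aggregate_replicates(table: AsvTable, site_of: dict[str, str]) -> pd.DataFrame:
    """Average relative abundances of replicate samples per site.

    Returns a site x ASV DataFrame of mean relative abundances; replicate
    counts themselves are never summed (library sizes differ).
    """
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.asv_ids
    )
    sites = pd.Series({s: site_of[s] for s in table.sample_ids})
    return rel.groupby(sites).mean()
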