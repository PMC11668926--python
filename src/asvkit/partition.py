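"""Six-way abundance-class partition of ASVs and sub-table extraction.

Every ASV with a positive total count is assigned exactly one category from
the (min, max) of its per-sample relative abundance:

=====  =============================  =================================
code   min relative abundance         max relative abundance
=====  =============================  =================================
AAT    >= abundant_cut                (implied >= abundant_cut)
CAT    rare_cut <= min < abundant     >= abundant_cut
CRAT   < rare_cut                     >= abundant_cut
MT     >= rare_cut                    < abundant_cut
CRT    < rare_cut                     rare_cut <= max < abundant_cut
ART    (implied < rare_cut)           < rare_cut
=====  =============================  =================================

Ties at exactly ``rare_cut`` count as not-rare and ties at exactly
``abundant_cut`` count as abundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core_io import AsvTable


class AbundanceCategory(str, Enum):
    AAT = "AAT"  # always abundant
    CAT = "CAT"  # conditionally abundant
    CRAT = "CRAT"  # conditionally rare and abundant
    MT = "MT"  # moderate
    CRT = "CRT"  # conditionally rare
    ART = "ART"  # always rare


RARE_GROUP = frozenset({AbundanceCategory.CRT, AbundanceCategory.ART})
ABUNDANT_GROUP = frozenset({AbundanceCategory.CRAT})


@dataclass
class PartitionResult:
    """Per-ASV category assignment plus the thresholds that produced it."""

    assignments: pd.DataFrame  # index asv_id; category, min/max/mean rel. abund.
    rare_cut: float
    abundant_cut: float
    dropped: list[str]  # ASVs absent from every sample

    def category_of(self, asv_id: str) -> AbundanceCategory:
        return AbundanceCategory(self.assignments.loc[asv_id, "category"])

    def members(self, which) -> list[str]:
        which = {AbundanceCategory(w).value for w in which}
        mask = self.assignments["category"].isin(which)
        return list(self.assignments.index[mask])

    def richness_counts(self) -> pd.Series:
        return (
            self.assignments["category"]
            .value_counts()
            .reindex([c.value for c in AbundanceCategory], fill_value=0)
        )


def classify_asvs(
    table: AsvTable,
    rare_cut: float = 1e-4,
    abundant_cut: float = 1e-2,
) -> PartitionResult:
    """Assign each ASV to one of the six abundance categories."""
    if table.n_samples < 1:
        raise ValueError("table must contain at least one sample")
    if not (0 < rare_cut < abundant_cut <= 1):
        raise ValueError("need 0 < rare_cut < abundant_cut <= 1")

    rel = table.relative_abundance()
    totals = table.counts.sum(axis=0)
    present = totals > 0

    mins = rel.min(axis=0)
    maxs = rel.max(axis=0)
    means = rel.mean(axis=0)

    cat = np.empty(table.n_asvs, dtype=object)
    is_abund_max = maxs >= abundant_cut
    is_abund_min = mins >= abundant_cut
    is_rare_min = mins < rare_cut
    is_rare_max = maxs < rare_cut

    cat[is_abund_max & is_abund_min] = AbundanceCategory.AAT.value
    cat[is_abund_max & ~is_abund_min & ~is_rare_min] = AbundanceCategory.CAT.value
    cat[is_abund_max & is_rare_min] = AbundanceCategory.CRAT.value
    cat[~is_abund_max & ~is_rare_min] = AbundanceCategory.MT.value
    cat[~is_abund_max & is_rare_min & ~is_rare_max] = AbundanceCategory.CRT.value
    cat[is_rare_max] = AbundanceCategory.ART.value

    df = pd.DataFrame(
        {
            "category": cat,
            "min_relabund": mins,
            "max_relabund": maxs,
            "mean_relabund": means,
        },
        index=pd.Index(table.asv_ids, name="asv_id"),
    )
    dropped = [a for a, p in zip(table.asv_ids, present) if not p]
    df = df.loc[present]
    return PartitionResult(df, rare_cut, abundant_cut, dropped)


def subcommunity(table: AsvTable, part: PartitionResult, which) -> AsvTable:
    """Column-subset of ``table`` restricted to the given categories."""
    ids = part.members(which)
    if not ids:
        import logging

        logging.getLogger("asvkit").warning(
            "subcommunity selection %s is empty", sorted({str(w) for w in which})
        )
    # preserve original column order
    keep = set(ids)
    ordered = [a for a in table.asv_ids if a in keep]
    return table.select_asvs(ordered)


def partition_summary(
    part: PartitionResult,
    table: AsvTable,
    taxonomy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-category (optionally per-phylum) richness % and abundance % shares.

    Abundance share is each category's fraction of total reads across the
    whole table; richness share is its fraction of retained ASVs.
    """
    assign = part.assignments
    totals = pd.Series(
        table.counts.sum(axis=0), index=table.asv_ids, dtype=float
    ).reindex(assign.index)
    grand = totals.sum()
    n_asvs = len(assign)

    rows = []
    groups = [assign["category"]]
    names = ["category"]
    if taxonomy is not None:
        phylum = pd.Series(
            {a: taxonomy.get(a, "Unassigned") for a in assign.index}, name="phylum"
        )
        groups.append(phylum)
        names.append("phylum")
    grouped = totals.groupby(groups)
    for key, vals in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(
                zip(names, key),
                richness=int(len(vals)),
                richness_pct=100.0 * len(vals) / n_asvs,
                abundance_pct=100.0 * vals.sum() / grand if grand > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)
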