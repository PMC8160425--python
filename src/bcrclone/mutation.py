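"""Somatic-hypermutation summaries by population and isotype.

Bulk repertoires are summarized per clonal lineage first — the
duplicate-weighted median of member mutation frequencies — and then
aggregated across lineages (arithmetic mean by default, median available),
yielding the "averaged median lineage mutation frequency" of a population or
of an isotype fraction within a population.  Single-cell consensus
heavy-chain tables (one row per cell) are summarized per isotype with group
means and pairwise two-tailed Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Lineage
from .io import RearrangementTable


@dataclass
class MutationSummary:
    population: str
    isotype: str | None
    per_lineage_medians: list[float] = field(default_factory=list)
    summary_value: float | None = None
    n_lineages: int = 0
    per_sequence_values: list[float] = field(default_factory=list)


def weighted_median(values: list[float], weights: list[int]) -> float:
    """Median of each value repeated ``weight`` times (even count: mean of the
    two central order statistics), computed without expansion."""
    if len(values) != len(weights) or not values:
        raise ValueError("values and weights must be equal-length and nonempty")
    if any(w < 1 for w in weights):
        raise ValueError("weights must be positive integers")
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=np.int64)[order]
    cum = np.cumsum(w)
    total = int(cum[-1])
    # 1-based ranks of the central element(s) of the expanded sample
    if total % 2 == 1:
        ranks = [(total + 1) // 2]
    else:
        ranks = [total // 2, total // 2 + 1]
    picked = [v[int(np.searchsorted(cum, r))] for r in ranks]
    return float(np.mean(picked))


def lineage_median_mutation(
    lineage: Lineage,
    rows: pd.DataFrame,
    population: str,
    isotype: str | None = None,
) -> float | None:
    """Duplicate-weighted median mutation frequency of a lineage's members
    restricted to (population, isotype); ``None`` if no member qualifies."""
    sub = rows[rows["lineage_id"] == lineage.lineage_id]
    sub = sub[sub["population"] == population]
    if isotype is not None:
        sub = sub[sub["c_call"] == isotype]
    sub = sub.dropna(subset=["mutation_freq"])
    if sub.empty:
        return None
    return weighted_median(
        sub["mutation_freq"].tolist(), sub["duplicate_count"].astype(int).tolist()
    )


def population_mutation_summary(
    lineages: list[Lineage],
    rows: pd.DataFrame,
    population: str,
    isotype: str | None = None,
    aggregate: str = "mean",
) -> MutationSummary:
    """Per-lineage medians aggregated across a population's lineages.

    ``aggregate`` is ``mean`` (default) or ``median``.  Lineages with no
    qualifying member are excluded; a summary over zero lineages carries
    ``summary_value=None``.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    medians = []
    for lin in lineages:
        med = lineage_median_mutation(lin, rows, population, isotype)
        if med is not None:
            medians.append(med)
    summary = MutationSummary(population, isotype, medians, n_lineages=len(medians))
    if medians:
        agg = np.mean if aggregate == "mean" else np.median
        summary.summary_value = float(agg(medians))
    return summary


def single_cell_mutation_table(
    table: RearrangementTable, group_by: str = "c_call"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isotype mutation distributions from a per-cell consensus table.

    Returns ``(summary, pvalues)``: per-group n, mean and median of the
    per-cell mutation frequencies, and the pairwise two-tailed Welch t-test
    p-value matrix (NaN where a group has fewer than 2 cells).
    """
    df = table.df.dropna(subset=["mutation_freq"])
    groups = {
        str(name): grp["mutation_freq"].to_numpy(dtype=float)
        for name, grp in df.groupby(group_by, sort=True)
    }
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
            for name, vals in groups.items()
        ]
    )
    names = sorted(groups)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in combinations(names, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            continue
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        pvals.loc[a, b] = pvals.loc[b, a] = float(res.pvalue)
    return summary, pvals
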