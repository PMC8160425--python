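"""Clonal lineage clustering.

A clonal lineage (clone) is a set of rearrangements sharing identical V gene,
identical J gene, identical CDR3 length, connected at >= 85% CDR3 nucleotide
Hamming identity.  Within each (V, J, CDR3-length) group, sequences are nodes
of a graph with edges wherever pairwise identity meets the threshold
(inclusive); single-linkage lineages are the connected components,
complete-linkage is available behind a flag.  Lineage identifiers are a hash
of the sorted member ids, so ids and memberships are invariant under input
permutation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .reference import gene_call

DEFAULT_IDENTITY_THRESHOLD = 0.85


@dataclass
class Lineage:
    lineage_id: str
    v_call: str
    j_call: str
    cdr3_length: int
    member_ids: list[str]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def population_count(self, population: str, isotype: str | None = None) -> int:
        return sum(
            c
            for (pop, iso), c in self.counts.items()
            if pop == population and (isotype is None or iso == isotype)
        )

    @property
    def populations(self) -> set[str]:
        return {pop for (pop, _), c in self.counts.items() if c > 0}


def hamming_identity(a: str, b: str) -> float:
    """Fraction of agreeing positions between equal-length CDR3s.

    Positions where either base is N count as mismatches (an N carries no
    evidence of identity).  Unequal lengths are a caller error: sequences
    must be grouped by CDR3 length first.
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(f"hamming_identity requires equal nonzero lengths, got {len(a)} and {len(b)}")
    mism = sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))
    return 1.0 - mism / len(a)


def _pairwise_identity_matrix(cdr3s: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(
        len(cdr3s), len(cdr3s[0])
    )
    is_n = arr == ord("N")
    neq = (arr[:, None, :] != arr[None, :, :]) | is_n[:, None, :] | is_n[None, :, :]
    return 1.0 - neq.mean(axis=2)


def _lineage_id(member_ids: list[str]) -> str:
    digest = hashlib.sha1("\n".join(sorted(member_ids)).encode()).hexdigest()
    return f"L{digest[:12]}"


def cluster_lineages(
    df: pd.DataFrame,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    linkage: str = "single",
    gene_level: bool = True,
) -> tuple[list[Lineage], pd.DataFrame]:
    """Partition annotated, duplicate-collapsed rearrangements into lineages.

    ``df`` needs columns sequence_id, population, v_call, j_call, cdr3,
    c_call, duplicate_count.  Allele-level calls are collapsed to gene level
    before grouping unless ``gene_level=False``.  Returns the lineages sorted
    by lineage_id and a copy of ``df`` with a ``lineage_id`` column.
    """
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    out = df.copy()
    vg = out["v_call"].map(gene_call) if gene_level else out["v_call"]
    jg = out["j_call"].map(gene_call) if gene_level else out["j_call"]
    out["_v_group"] = vg
    out["_j_group"] = jg
    out["_cdr3_len"] = out["cdr3"].str.len()
    lineages: list[Lineage] = []
    assignment: dict[str, str] = {}
    for (v, j, clen), grp in out.groupby(["_v_group", "_j_group", "_cdr3_len"], sort=True):
        grp = grp.sort_values("sequence_id", kind="mergesort")
        ids = grp["sequence_id"].tolist()
        cdr3s = grp["cdr3"].tolist()
        for members in _components(ids, cdr3s, identity_threshold, linkage):
            lid = _lineage_id(members)
            counts: dict[tuple[str, str], int] = {}
            sub = grp[grp["sequence_id"].isin(members)]
            for row in sub.itertuples(index=False):
                key = (row.population, row.c_call)
                counts[key] = counts.get(key, 0) + int(row.duplicate_count)
            lineages.append(
                Lineage(lid, v, j, int(clen), sorted(members), counts)
            )
            for m in members:
                assignment[m] = lid
    out["lineage_id"] = out["sequence_id"].map(assignment)
    out = out.drop(columns=["_v_group", "_j_group", "_cdr3_len"])
    lineages.sort(key=lambda lin: lin.lineage_id)
    return lineages, out


def _components(ids, cdr3s, threshold, linkage_method) -> list[list[str]]:
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    ident = _pairwise_identity_matrix(cdr3s)
    if linkage_method == "single":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        ii, jj = np.nonzero(np.triu(ident >= threshold, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        comps = nx.connected_components(g)
        return [[ids[i] for i in comp] for comp in comps]
    dist = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = scipy_linkage(condensed, method="complete")
    # small positive slack keeps the threshold inclusive under float round-off
    labels = fcluster(z, t=(1.0 - threshold) + 1e-9, criterion="distance")
    groups: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(ids[idx])
    return list(groups.values())


def lineage_table(lineages: list[Lineage]) -> pd.DataFrame:
    """Long-format lineage summary: one row per (lineage, population, isotype)."""
    rows = []
    for lin in lineages:
        for (pop, iso), count in sorted(lin.counts.items()):
            rows.append(
                {
                    "lineage_id": lin.lineage_id,
                    "v_call": lin.v_call,
                    "j_call": lin.j_call,
                    "cdr3_length": lin.cdr3_length,
                    "n_members": len(lin.member_ids),
                    "population": pop,
                    "c_call": iso,
                    "duplicate_count": count,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id", "v_call", "j_call", "cdr3_length",
            "n_members", "population", "c_call", "duplicate_count",
        ],
    )


def lineages_from_table(df: pd.DataFrame) -> list[Lineage]:
    """Rebuild Lineage objects from a long-format lineage table."""
    lineages: dict[str, Lineage] = {}
    for row in df.itertuples(index=False):
        lin = lineages.get(row.lineage_id)
        if lin is None:
            lin = Lineage(
                row.lineage_id, row.v_call, row.j_call, int(row.cdr3_length), []
            )
            lineages[row.lineage_id] = lin
        lin.counts[(row.population, row.c_call)] = int(row.duplicate_count)
    return sorted(lineages.values(), key=lambda lin: lin.lineage_id)
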