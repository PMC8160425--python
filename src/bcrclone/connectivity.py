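"""Inter-population clonal connectivity and diversity statistics.

Connectivity between two cell populations is measured on lineage sets: the
percentage of one population's lineages also observed in another
(shared-lineage fraction, optionally restricted to an isotype in the
reference population) and the SIM index, an isotype-resolved set-overlap
statistic offered in three variants (reference-normalized fraction, Jaccard,
Sorensen-Dice).  Clonal dominance is summarized by D50 — the smallest number
of top-ranked lineages accounting for at least half of a population's
sequences.  Lineage-level link and segment files for circular (circos-style)
visualization are exported as deterministic plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .clustering import Lineage

SIM_VARIANTS = ("reference_fraction", "jaccard", "sorensen")

#: A shared lineage is drawn emphasized when its summed sequence count is
#: strictly greater than this (legend convention: "more than 50 sequences").
EMPHASIS_COUNT = 50


@dataclass
class LinkRecord:
    lineage_id: str
    pop_a: str
    count_a: int
    pop_b: str
    count_b: int
    emphasized: bool


@dataclass
class ConnectivityResult:
    reference_population: str
    reference_isotype: str | None
    shared_fractions: dict[str, float | None] = field(default_factory=dict)
    sim_indices: dict[tuple[str, str], float | None] = field(default_factory=dict)
    links: list[LinkRecord] = field(default_factory=list)


@dataclass
class DiversityStats:
    population: str
    n_lineages: int
    n_sequences: int
    d50_count: int

    @property
    def d50_fraction(self) -> float:
        return self.d50_count / self.n_lineages


def _lineage_set(
    lineages: list[Lineage], population: str, isotype: str | None = None
) -> set[str]:
    return {
        lin.lineage_id
        for lin in lineages
        if lin.population_count(population, isotype) > 0
    }


def shared_lineage_fraction(
    lineages: list[Lineage],
    reference_pop: str,
    target_pop: str,
    reference_isotype: str | None = None,
) -> float | None:
    """Percentage of reference-population lineages that also contain the target.

    Reference lineages are those with at least one sequence of
    ``reference_pop`` (of ``reference_isotype``, when given).  Returns
    ``None`` — not 0 — when there are no reference lineages.
    """
    ref = _lineage_set(lineages, reference_pop, reference_isotype)
    if not ref:
        return None
    target = _lineage_set(lineages, target_pop)
    return 100.0 * len(ref & target) / len(ref)


def sim_index(
    lineages: list[Lineage],
    pop_a: str,
    isotype_a: str | None,
    pop_b: str,
    isotype_b: str | None,
    variant: str = "reference_fraction",
) -> float | None:
    """Isotype-resolved set overlap of lineage sets A and B, in [0, 1].

    A is the set of lineages with at least one (pop_a, isotype_a) member, B
    likewise for (pop_b, isotype_b).  ``reference_fraction`` = |A∩B|/|A|
    (asymmetric, A is the reference); ``jaccard`` = |A∩B|/|A∪B|;
    ``sorensen`` = 2|A∩B|/(|A|+|B|).  Undefined cases return ``None``.
    """
    if variant not in SIM_VARIANTS:
        raise ValueError(f"unknown SIM variant {variant!r}; choose from {SIM_VARIANTS}")
    a = _lineage_set(lineages, pop_a, isotype_a)
    b = _lineage_set(lineages, pop_b, isotype_b)
    inter = len(a & b)
    if variant == "reference_fraction":
        return inter / len(a) if a else None
    if variant == "jaccard":
        union = len(a | b)
        return inter / union if union else None
    return 2 * inter / (len(a) + len(b)) if (a or b) else None


def _ranked_lineages(lineages: list[Lineage], population: str) -> list[tuple[Lineage, int]]:
    counted = [
        (lin, lin.population_count(population))
        for lin in lineages
        if lin.population_count(population) > 0
    ]
    counted.sort(key=lambda t: (-t[1], t[0].lineage_id))
    return counted


def d50(lineages: list[Lineage], population: str) -> DiversityStats | None:
    """Smallest number of top lineages holding >= 50% of the population's
    sequences (duplicate-weighted).  ``None`` for an empty population."""
    ranked = _ranked_lineages(lineages, population)
    if not ranked:
        return None
    total = sum(c for _, c in ranked)
    cum = 0
    for k, (_, count) in enumerate(ranked, start=1):
        cum += count
        if 2 * cum >= total:  # cum >= 50% of total, exact in integers
            return DiversityStats(population, len(ranked), total, k)
    raise AssertionError("unreachable: cumulative count must reach the total")


def compute_connectivity(
    lineages: list[Lineage],
    reference_pop: str,
    target_pops: list[str],
    reference_isotype: str | None = None,
    isotypes: list[str] | None = None,
    variant: str = "reference_fraction",
) -> ConnectivityResult:
    """Shared fractions, isotype-resolved SIM indices, and link records from
    one reference population to each target population."""
    result = ConnectivityResult(reference_pop, reference_isotype)
    for target in target_pops:
        result.shared_fractions[target] = shared_lineage_fraction(
            lineages, reference_pop, target, reference_isotype
        )
        for iso in isotypes or [None]:
            result.sim_indices[(target, iso or "ALL")] = sim_index(
                lineages, reference_pop, reference_isotype, target, iso, variant
            )
    ref_set = _lineage_set(lineages, reference_pop, reference_isotype)
    for lin in lineages:
        if lin.lineage_id not in ref_set:
            continue
        count_ref = lin.population_count(reference_pop)
        for target in target_pops:
            count_t = lin.population_count(target)
            if count_t > 0:
                result.links.append(
                    LinkRecord(
                        lin.lineage_id,
                        reference_pop,
                        count_ref,
                        target,
                        count_t,
                        emphasized=(count_ref + count_t) > EMPHASIS_COUNT,
                    )
                )
    return result


def export_circular_plot_data(
    connectivity: ConnectivityResult,
    lineages: list[Lineage],
    populations: list[str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write circos-style karyotype, D50-highlight and link files.

    One karyotype segment per population, sized by its total duplicate-weighted
    sequence count; a highlight sub-range marks the top-D50 lineages of each
    segment.  One link per shared lineage between the reference and each
    target population, positioned at the lineage's interval within each
    segment; links above the emphasis count carry ``emphasized=true``, the
    rest the gray class.  Output is deterministic given its inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    karyotype_path = out_dir / "karyotype.txt"
    highlight_path = out_dir / "highlights.txt"
    links_path = out_dir / "links.txt"

    intervals: dict[tuple[str, str], tuple[int, int]] = {}
    with open(karyotype_path, "w") as kfh, open(highlight_path, "w") as hfh:
        for pop in populations:
            ranked = _ranked_lineages(lineages, pop)
            total = sum(c for _, c in ranked)
            kfh.write(f"chr - {pop} {pop} 0 {total} grey\n")
            pos = 0
            stats = d50(lineages, pop)
            for rank, (lin, count) in enumerate(ranked, start=1):
                intervals[(pop, lin.lineage_id)] = (pos, pos + count)
                pos += count
            if stats is not None:
                d50_end = intervals[(pop, ranked[stats.d50_count - 1][0].lineage_id)][1]
                hfh.write(f"{pop} 0 {d50_end} fill_color=dark\n")

    with open(links_path, "w") as lfh:
        for link in sorted(
            connectivity.links, key=lambda l: (l.lineage_id, l.pop_a, l.pop_b)
        ):
            a = intervals[(link.pop_a, link.lineage_id)]
            b = intervals[(link.pop_b, link.lineage_id)]
            cls = "emphasized=true" if link.emphasized else "class=gray"
            lfh.write(
                f"{link.pop_a} {a[0]} {a[1]} {link.pop_b} {b[0]} {b[1]} {cls}\n"
            )
    return {
        "karyotype": karyotype_path,
        "highlights": highlight_path,
        "links": links_path,
    }
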