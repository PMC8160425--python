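"""Ground-truth repertoire simulator.

Generates multi-population heavy-chain repertoires with planted clonal
structure so the whole pipeline can be tested without external data:

* clones share a germline V, J and an ancestral CDR3; members diversify the
  CDR3 by a bounded number of substitutions so within-clone pairwise identity
  stays at or above 0.90 (unambiguous under the 0.85 lineage threshold);
* cross-population clonal overlap is planted exactly: a chosen fraction of a
  reference population's clones is replicated into a partner population,
  optionally restricted to specific isotypes on either side (a clone shared
  between IgE antibody-secreting cells and the IgG fraction of IgD+ cells,
  for instance);
* isotypes are drawn from per-population mixtures (the bundled profile gives
  the IgD+ population an 83/11/6 IgM/IgG/IgA mixture and blood naive cells
  >99% IgM);
* somatic mutations are planted in the V region 5' of the CDR3 as a Poisson
  load with per-clone rate dispersion, so naive-like subsets carry low and
  memory/ASC-like subsets high mutation frequencies.

``simulate_repertoire`` returns truth tables plus a clean annotated
rearrangement table; ``emit_reads`` turns the clean sequences into paired
FASTQ with configurable per-base error, mimicking a 2x301 amplicon run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import PRIMER_MASK_LEN
from .io import RearrangementTable
from .preprocess import revcomp
from .reference import GermlineReference

BASES = np.array(list("ACGT"))

#: Maximum per-member CDR3 substitutions, as a fraction of CDR3 length; twice
#: this bounds the within-clone pairwise distance (kept <= 0.10).
WITHIN_CLONE_DIVERSITY = 0.05

#: Default population profile patterned on the study design: nasal-polyp
#: antibody-secreting cells, IgD+ and CD27+ memory cells, blood naive and
#: CD27+ memory cells, with subset-specific isotype mixtures and mutation
#: loads (naive-like low, memory/ASC-like high).
DEFAULT_POPULATIONS = (
    ("NP_ASC", {"IGM": 0.10, "IGG": 0.45, "IGA": 0.35, "IGE": 0.10}, 0.06),
    ("NP_IgD", {"IGM": 0.83, "IGG": 0.11, "IGA": 0.06}, 0.02),
    ("NP_CD27M", {"IGM": 0.30, "IGG": 0.40, "IGA": 0.30}, 0.06),
    ("PBL_naive", {"IGM": 0.995, "IGG": 0.003, "IGA": 0.002}, 0.005),
    ("PBL_CD27M", {"IGM": 0.35, "IGG": 0.40, "IGA": 0.25}, 0.06),
)


class SimulationConfigError(ValueError):
    pass


@dataclass
class PopulationSpec:
    label: str
    n_clones: int
    isotype_mixture: dict[str, float]
    mutation_rate_mean: float
    mutation_rate_dispersion: float = 0.0
    clone_size_distribution: tuple[str, float] = ("geometric", 0.2)

    def validate(self) -> None:
        if not self.label:
            raise SimulationConfigError("population label must be nonempty")
        if self.n_clones < 1:
            raise SimulationConfigError(f"{self.label}: n_clones must be >= 1")
        total = sum(self.isotype_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"{self.label}: isotype mixture sums to {total}, expected 1"
            )
        kind, _ = self.clone_size_distribution
        if kind not in ("geometric", "zipf"):
            raise SimulationConfigError(f"{self.label}: unknown size distribution {kind!r}")


@dataclass
class OverlapSpec:
    pop_a: str
    isotype_a: str | None
    pop_b: str
    isotype_b: str | None
    fraction: float

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise SimulationConfigError(f"overlap fraction {self.fraction} outside [0,1]")


@dataclass
class SimulationConfig:
    seed: int
    populations: list[PopulationSpec]
    overlap_specs: list[OverlapSpec] = field(default_factory=list)
    read_error_rate: float = 0.0
    library_mode: str = "combined"  # "combined" | "per-isotype"
    read_length: int = 301
    cdr3_length_range: tuple[int, int] = (24, 72)

    def validate(self) -> None:
        for pop in self.populations:
            pop.validate()
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise SimulationConfigError("duplicate population labels")
        for ov in self.overlap_specs:
            ov.validate()
            if ov.pop_a not in labels or ov.pop_b not in labels:
                raise SimulationConfigError(
                    f"overlap references unknown population {ov.pop_a!r}/{ov.pop_b!r}"
                )
        if self.library_mode not in ("combined", "per-isotype"):
            raise SimulationConfigError(f"unknown library_mode {self.library_mode!r}")
        if not 0.0 <= self.read_error_rate < 1.0:
            raise SimulationConfigError("read_error_rate must be in [0,1)")


@dataclass
class SimulationTruth:
    per_sequence: pd.DataFrame
    per_clone: pd.DataFrame
    config: SimulationConfig


def default_config(
    seed: int,
    n_clones: int = 100,
    overlap_specs: list[OverlapSpec] | None = None,
    read_error_rate: float = 0.0,
    **kwargs,
) -> SimulationConfig:
    """The study-profile configuration: five populations with their default
    isotype mixtures and mutation loads, ``n_clones`` clones each."""
    pops = [
        PopulationSpec(label, n_clones, dict(mix), rate, mutation_rate_dispersion=0.2)
        for label, mix, rate in DEFAULT_POPULATIONS
    ]
    return SimulationConfig(
        seed=seed,
        populations=pops,
        overlap_specs=overlap_specs
        or [
            OverlapSpec("NP_ASC", None, "NP_IgD", None, 0.20),
            OverlapSpec("NP_ASC", None, "NP_CD27M", None, 0.25),
            OverlapSpec("NP_ASC", None, "PBL_CD27M", None, 0.10),
            OverlapSpec("NP_ASC", None, "PBL_naive", None, 0.02),
        ],
        read_error_rate=read_error_rate,
        **kwargs,
    )


def _clone_sizes(rng, spec: PopulationSpec, n: int) -> np.ndarray:
    kind, param = spec.clone_size_distribution
    if kind == "geometric":
        return rng.geometric(param, size=n)
    sizes = rng.zipf(param, size=n)
    return np.minimum(sizes, 500)


def _random_cdr3(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng, seq: str, n_sub: int, region_end: int | None = None) -> tuple[str, list[int]]:
    """Apply ``n_sub`` substitutions at distinct positions < region_end."""
    limit = len(seq) if region_end is None else region_end
    n_sub = min(n_sub, limit)
    if n_sub == 0:
        return seq, []
    positions = rng.choice(limit, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out), sorted(int(p) for p in positions)


def simulate_repertoire(
    config: SimulationConfig, reference: GermlineReference
) -> tuple[SimulationTruth, RearrangementTable]:
    """Generate planted clones and clean (error-free) annotated sequences.

    Deterministic under ``config.seed``.  Overlap fractions are planted as
    exact clone counts (``floor(fraction * n_clones)``); overlap specs sharing
    a reference population draw from disjoint clone pools so each planted
    count is realized independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cdr3_length_range

    clone_rows = []
    clones_by_pop: dict[str, list[dict]] = {}
    for spec in config.populations:
        clones = []
        for i in range(spec.n_clones):
            v = reference.v_segments[rng.integers(len(reference.v_segments))]
            j = reference.j_segments[rng.integers(len(reference.j_segments))]
            cdr3_len = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            clone = {
                "clone_id": f"{spec.label}_C{i:04d}",
                "population": spec.label,
                "v_call": v.name,
                "j_call": j.name,
                "cdr3_len": cdr3_len,
                "ancestor_cdr3": _random_cdr3(rng, cdr3_len),
                "shared_into": [],  # list of (pop_b, isotype_b, isotype_a)
                "forced_isotype_a": None,
            }
            clones.append(clone)
        clones_by_pop[spec.label] = clones

    # plant overlap on disjoint pools per reference population
    free_pool = {label: list(range(len(cl))) for label, cl in clones_by_pop.items()}
    for ov in config.overlap_specs:
        pool = free_pool[ov.pop_a]
        k = int(ov.fraction * len(clones_by_pop[ov.pop_a]))
        if k > len(pool):
            k = len(pool)
        chosen = rng.choice(len(pool), size=k, replace=False)
        chosen_idx = sorted(pool[c] for c in chosen)
        for idx in chosen_idx:
            clone = clones_by_pop[ov.pop_a][idx]
            clone["shared_into"].append((ov.pop_b, ov.isotype_b, ov.isotype_a))
            if ov.isotype_a is not None:
                clone["forced_isotype_a"] = ov.isotype_a
        free_pool[ov.pop_a] = [p for p in pool if p not in set(chosen_idx)]

    spec_by_label = {p.label: p for p in config.populations}
    seq_rows = []
    table_rows = []
    counter = {p.label: 0 for p in config.populations}

    def emit_members(clone, pop_label, n_members, forced_isotype, first_forced_isotype):
        spec = spec_by_label[pop_label]
        v = reference.v_by_name[clone["v_call"]]
        j = reference.j_by_name[clone["j_call"]]
        v_part = v.seq_nt[: v.cys_anchor + 3]
        j_part = j.seq_nt[j.wf_anchor :]
        rate = spec.mutation_rate_mean
        if spec.mutation_rate_dispersion > 0 and rate > 0:
            disp = spec.mutation_rate_dispersion
            shape = 1.0 / disp**2
            rate = rng.gamma(shape, rate / shape)
        isotypes = list(spec.isotype_mixture)
        probs = np.array([spec.isotype_mixture[i] for i in isotypes])
        max_cdr3_sub = int(WITHIN_CLONE_DIVERSITY * clone["cdr3_len"])
        for m in range(n_members):
            sid = f"{pop_label}_S{counter[pop_label]:06d}"
            counter[pop_label] += 1
            if forced_isotype is not None:
                isotype = forced_isotype
            elif m == 0 and first_forced_isotype is not None:
                isotype = first_forced_isotype
            else:
                isotype = isotypes[rng.choice(len(isotypes), p=probs)]
            n_cdr3_sub = int(rng.integers(0, max_cdr3_sub + 1))
            cdr3, _ = _mutate(rng, clone["ancestor_cdr3"], n_cdr3_sub)
            n_v_mut = int(rng.poisson(rate * v.cys_anchor))
            v_mutated, positions = _mutate(rng, v_part, n_v_mut, region_end=v.cys_anchor)
            n_eval_mut = sum(1 for p in positions if p >= PRIMER_MASK_LEN)
            eval_len = v.cys_anchor - PRIMER_MASK_LEN
            signature = reference.constant_signatures[isotype]
            full_seq = v_mutated + cdr3 + j_part + signature
            seq_rows.append(
                {
                    "sequence_id": sid,
                    "population": pop_label,
                    "clone_id": clone["clone_id"],
                    "v_call": clone["v_call"],
                    "j_call": clone["j_call"],
                    "cdr3_nt": cdr3,
                    "isotype": isotype,
                    "n_planted_mutations": len(positions),
                    "n_eval_mutations": n_eval_mut,
                }
            )
            table_rows.append(
                {
                    "sequence_id": sid,
                    "population": pop_label,
                    "sequence": full_seq,
                    "v_call": clone["v_call"],
                    "j_call": clone["j_call"],
                    "cdr3": cdr3,
                    "cdr3_aa": "",
                    "c_call": isotype,
                    "v_mutations": n_eval_mut,
                    "v_eval_len": eval_len,
                    "mutation_freq": 100.0 * n_eval_mut / eval_len,
                    "duplicate_count": 1,
                }
            )

    for spec in config.populations:
        for clone in clones_by_pop[spec.label]:
            size = int(_clone_sizes(rng, spec, 1)[0])
            emit_members(clone, spec.label, size, None, clone["forced_isotype_a"])
            for pop_b, isotype_b, _iso_a in clone["shared_into"]:
                size_b = int(_clone_sizes(rng, spec_by_label[pop_b], 1)[0])
                emit_members(clone, pop_b, size_b, isotype_b, None)
            clone_rows.append(
                {
                    "clone_id": clone["clone_id"],
                    "population": clone["population"],
                    "v_call": clone["v_call"],
                    "j_call": clone["j_call"],
                    "cdr3_len": clone["cdr3_len"],
                    "ancestor_cdr3": clone["ancestor_cdr3"],
                    "shared": bool(clone["shared_into"]),
                    "shared_into": ";".join(
                        f"{p}:{i or 'ANY'}" for p, i, _ in clone["shared_into"]
                    ),
                }
            )

    truth = SimulationTruth(
        per_sequence=pd.DataFrame(seq_rows),
        per_clone=pd.DataFrame(clone_rows),
        config=config,
    )
    provenance = {
        "simulator_seed": str(config.seed),
        "read_error_rate": str(config.read_error_rate),
        "library_mode": config.library_mode,
    }
    table = RearrangementTable(pd.DataFrame(table_rows), provenance)
    return truth, table


def simulate_boundary_pairs(
    seed: int,
    reference: GermlineReference,
    cdr3_length: int = 100,
    n_pairs: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stress fixture for the clustering threshold: sequence pairs planted at
    CDR3 identity exactly at and just below the 0.85 lineage cutoff.

    Returns ``(at_threshold, below_threshold)`` rearrangement frames: in the
    first every pair differs at exactly ``round(0.15 * L)`` positions (at the
    default L=100 that is 15 mismatches, identity exactly 0.85 — one lineage
    expected under the inclusive rule), in the second at one more position
    (identity 0.84 — two lineages expected).  Clustering operates on CDR3
    nucleotides only, so lengths need not be in frame here.
    """
    rng = np.random.default_rng(seed)
    n_at = int(round(0.15 * cdr3_length))
    frames = []
    for n_sub in (n_at, n_at + 1):
        rows = []
        for p in range(n_pairs):
            v = reference.v_segments[rng.integers(len(reference.v_segments))]
            j = reference.j_segments[rng.integers(len(reference.j_segments))]
            # anchor each pair on a distinct, well-separated ancestral CDR3
            cdr3_a = _random_cdr3(rng, cdr3_length)
            cdr3_b, _ = _mutate(rng, cdr3_a, n_sub)
            for suffix, cdr3 in (("a", cdr3_a), ("b", cdr3_b)):
                rows.append(
                    {
                        "sequence_id": f"pair{p:03d}_{suffix}_{n_sub}",
                        "population": "stress",
                        "sequence": v.seq_nt[: v.cys_anchor + 3] + cdr3 + j.seq_nt[j.wf_anchor :],
                        "v_call": v.name,
                        "j_call": j.name,
                        "cdr3": cdr3,
                        "c_call": "IGM",
                        "mutation_freq": 0.0,
                        "duplicate_count": 1,
                    }
                )
        frames.append(pd.DataFrame(rows))
    return frames[0], frames[1]


def _phred_profile(length: int) -> np.ndarray:
    """Deterministic per-cycle quality: high early cycles, mild 3' decay."""
    qual = np.full(length, 37, dtype=int)
    tail = max(0, length - 200)
    if tail:
        qual[200:] = np.maximum(30, 37 - (np.arange(tail) // 25))
    return qual


def emit_reads(
    table: RearrangementTable,
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict:
    """Write paired 2x``read_length`` FASTQ files plus a manifest.

    Each clean sequence becomes a forward read (5' prefix) and a reverse read
    (reverse complement of the 3' suffix) with per-base substitution errors at
    ``config.read_error_rate``.  Combined mode writes one pair per
    population; per-isotype mode one pair per (population, isotype).
    Sequences whose length leaves less than 10 nt of mate overlap are skipped
    and reported in the manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    handles: dict[tuple[str, str | None], tuple] = {}
    entries = []
    skipped = []

    def get_handles(pop: str, iso: str | None):
        key = (pop, iso)
        if key not in handles:
            stem = pop if iso is None else f"{pop}_{iso}"
            r1 = out_dir / f"{stem}_R1.fastq"
            r2 = out_dir / f"{stem}_R2.fastq"
            handles[key] = (open(r1, "w"), open(r2, "w"))
            entry = {"population": pop, "r1": r1.name, "r2": r2.name}
            if iso is not None:
                entry["isotype"] = iso
            entries.append(entry)
        return handles[key]

    def add_errors(seq: str) -> str:
        if config.read_error_rate <= 0:
            return seq
        arr = np.array(list(seq))
        hits = np.nonzero(rng.random(len(arr)) < config.read_error_rate)[0]
        for pos in hits:
            choices = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = choices[rng.integers(3)]
        return "".join(arr)

    df = table.df.sort_values("sequence_id", kind="mergesort")
    for row in df.itertuples(index=False):
        seq = row.sequence
        if len(seq) > 2 * rl - 10:
            skipped.append(row.sequence_id)
            continue
        fwd = add_errors(seq[:rl])
        rev = add_errors(revcomp(seq)[:rl])
        iso = row.c_call if config.library_mode == "per-isotype" else None
        fh1, fh2 = get_handles(row.population, iso)
        q1 = "".join(chr(q + 33) for q in _phred_profile(len(fwd)))
        q2 = "".join(chr(q + 33) for q in _phred_profile(len(rev)))
        fh1.write(f"@{row.sequence_id}/1\n{fwd}\n+\n{q1}\n")
        fh2.write(f"@{row.sequence_id}/2\n{rev}\n+\n{q2}\n")

    for fh1, fh2 in handles.values():
        fh1.close()
        fh2.close()
    manifest = {
        "library_mode": config.library_mode,
        "read_length": rl,
        "read_error_rate": config.read_error_rate,
        "inputs": sorted(entries, key=lambda e: (e["population"], e.get("isotype") or "")),
        "skipped_too_long": skipped,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
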