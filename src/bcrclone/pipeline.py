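"""One-command orchestration: merge -> filter -> orient -> isotype ->
annotate -> collapse -> cluster -> connectivity -> mutation summaries.

Stages run in the fixed amplicon-analysis order and every stage's record
counts are conserved into a run manifest (input = output + per-reason drops),
so a run is auditable and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from .clustering import cluster_lineages, lineage_table
from .connectivity import compute_connectivity, d50, export_circular_plot_data
from .io import RearrangementTable, read_sequences, write_rearrangements
from .mutation import population_mutation_summary
from .preprocess import (
    DEFAULT_MAX_SIGNATURE_MISMATCHES,
    assign_isotype,
    length_quality_filter,
    merge_pair,
    orient_sequence,
)
from .reference import ISOTYPES, UNASSIGNED, bundled_reference, load_germline_reference

log = logging.getLogger("bcrclone")


class PipelineConfigError(ValueError):
    pass


@dataclass
class InputSpec:
    population: str
    r1: str
    r2: str | None = None
    isotype: str | None = None  # declared isotype for per-isotype libraries


@dataclass
class PipelineConfig:
    inputs: list[InputSpec]
    output_dir: str
    reference_fasta: str | None = None
    reference_anchors: str | None = None
    reference_signatures: str | None = None
    min_len: int = 200
    min_mean_q: float = 20.0
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    max_signature_mismatches: int = DEFAULT_MAX_SIGNATURE_MISMATCHES
    identity_threshold: float = 0.85
    linkage: str = "single"
    sim_variant: str = "reference_fraction"
    aggregate: str = "mean"
    reference_pop: str | None = None
    reference_isotype: str | None = None
    library_mode: str = "combined"
    primer_mask_len: int = 25

    def validate(self) -> None:
        if not self.inputs:
            raise PipelineConfigError("no inputs declared")
        if not 0.0 <= self.identity_threshold <= 1.0:
            raise PipelineConfigError(
                f"identity_threshold {self.identity_threshold} outside [0,1]"
            )
        if not 0.0 <= self.max_mismatch_rate <= 1.0:
            raise PipelineConfigError("max_mismatch_rate outside [0,1]")
        if self.min_len <= 0 or self.min_overlap <= 0:
            raise PipelineConfigError("lengths must be positive")
        if self.library_mode not in ("combined", "per-isotype"):
            raise PipelineConfigError(f"unknown library_mode {self.library_mode!r}")
        if self.library_mode == "per-isotype":
            for inp in self.inputs:
                if inp.isotype is None:
                    raise PipelineConfigError(
                        f"per-isotype mode requires a declared isotype for {inp.population}"
                    )
        for inp in self.inputs:
            for path in (inp.r1, inp.r2):
                if path is not None and not Path(path).exists():
                    raise PipelineConfigError(f"input path does not exist: {path}")
        refs = (self.reference_fasta, self.reference_anchors, self.reference_signatures)
        if any(refs) and not all(refs):
            raise PipelineConfigError(
                "reference_fasta, reference_anchors and reference_signatures "
                "must be given together (or all omitted for the bundled fixture)"
            )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a validated PipelineConfig from a key-value YAML file.

    Schema: ``output_dir`` (str); ``inputs`` (list of mappings with keys
    ``population``, ``r1``, optional ``r2`` and ``isotype``); optional
    ``reference`` mapping (``fasta``, ``anchors``, ``signatures``); optional
    ``params`` mapping overriding any stage parameter.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    inputs = [
        InputSpec(
            population=item["population"],
            r1=str(base / item["r1"]),
            r2=str(base / item["r2"]) if item.get("r2") else None,
            isotype=item.get("isotype"),
        )
        for item in raw.get("inputs", [])
    ]
    ref = raw.get("reference") or {}
    params = raw.get("params") or {}
    cfg = PipelineConfig(
        inputs=inputs,
        output_dir=str(base / raw["output_dir"]),
        reference_fasta=str(base / ref["fasta"]) if ref else None,
        reference_anchors=str(base / ref["anchors"]) if ref else None,
        reference_signatures=str(base / ref["signatures"]) if ref else None,
        **params,
    )
    cfg.validate()
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.reference_fasta:
        reference = load_germline_reference(
            config.reference_fasta, config.reference_anchors, config.reference_signatures
        )
    else:
        reference = bundled_reference()
    aligner = ann.make_aligner()

    qc_rows = []
    rows = []
    for inp in config.inputs:
        counts = {
            "input": 0, "merged": 0, "dropped_unmerged": 0,
            "dropped_length": 0, "dropped_quality": 0,
            "dropped_isotype_unassigned": 0, "dropped_isotype_contradiction": 0,
            "kept": 0,
        }
        iso_counts = {iso: 0 for iso in ISOTYPES}
        if inp.r2 is not None:
            stream = (
                merge_pair(f, r, config.min_overlap, config.max_mismatch_rate)
                for f, r in read_sequences([inp.r1, inp.r2], inp.population, "fastq-paired")
            )
        else:
            fmt = "fasta" if inp.r1.endswith((".fasta", ".fa")) else "fastq"
            stream = iter(list(read_sequences([inp.r1], inp.population, fmt)))
        for merged in stream:
            counts["input"] += 1
            if merged is None:
                counts["dropped_unmerged"] += 1
                continue
            counts["merged"] += 1
            verdict = length_quality_filter(merged, config.min_len, config.min_mean_q)
            if not verdict.keep:
                counts[f"dropped_{verdict.reason}"] += 1
                continue
            oriented, _strand = orient_sequence(merged, reference)
            call = assign_isotype(oriented, reference, config.max_signature_mismatches)
            if call.isotype == UNASSIGNED:
                counts["dropped_isotype_unassigned"] += 1
                continue
            if config.library_mode == "per-isotype" and call.isotype != inp.isotype:
                counts["dropped_isotype_contradiction"] += 1
                continue
            counts["kept"] += 1
            iso_counts[call.isotype] += 1
            rows.append(
                {
                    "sequence_id": oriented.read_id,
                    "population": inp.population,
                    "sequence": oriented.seq_nt,
                    "c_call": call.isotype,
                    "duplicate_count": 1,
                }
            )
        qc_rows.append(
            {"population": inp.population, "declared_isotype": inp.isotype or "",
             **counts, **{f"n_{iso}": c for iso, c in iso_counts.items()}}
        )
        log.info(
            "preprocess population=%s input=%d kept=%d", inp.population,
            counts["input"], counts["kept"],
        )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "preprocess_qc.tsv", sep="\t", index=False)

    ann_counts = {"input": len(rows), "annotated": 0, "unannotatable": 0, "nonproductive": 0}
    annotated = []
    for row in rows:
        try:
            result = ann.annotate_sequence(
                row["sequence"], reference, aligner, config.primer_mask_len
            )
        except ann.AnnotationError:
            ann_counts["unannotatable"] += 1
            continue
        if not result.pop("productive"):
            ann_counts["nonproductive"] += 1
            continue
        ann_counts["annotated"] += 1
        annotated.append({**row, **result})
    log.info("annotate %s", ann_counts)

    df = pd.DataFrame(annotated)
    df = ann.collapse_duplicates(df) if not df.empty else df
    lineages, df = cluster_lineages(
        df, config.identity_threshold, config.linkage
    ) if not df.empty else ([], df)
    provenance = {
        "identity_threshold": str(config.identity_threshold),
        "linkage": config.linkage,
        "min_len": str(config.min_len),
        "min_mean_q": str(config.min_mean_q),
        "library_mode": config.library_mode,
        "primer_mask_len": str(config.primer_mask_len),
    }
    write_rearrangements(RearrangementTable(df, provenance), out / "rearrangements.tsv")
    lineage_table(lineages).to_csv(out / "lineages.tsv", sep="\t", index=False)

    populations = [inp.population for inp in config.inputs]
    populations = sorted(dict.fromkeys(populations))
    reference_pop = config.reference_pop or populations[0]
    target_pops = [p for p in populations if p != reference_pop]
    conn = compute_connectivity(
        lineages, reference_pop, target_pops,
        config.reference_isotype, list(ISOTYPES), config.sim_variant,
    )
    conn_rows = [
        {"reference_pop": reference_pop, "target_pop": t,
         "shared_fraction_pct": "" if v is None else v}
        for t, v in sorted(conn.shared_fractions.items())
    ]
    pd.DataFrame(conn_rows).to_csv(out / "connectivity.tsv", sep="\t", index=False)
    sim_rows = [
        {"reference_pop": reference_pop,
         "reference_isotype": config.reference_isotype or "ALL",
         "target_pop": t, "target_isotype": iso, "variant": config.sim_variant,
         "sim_index": "" if v is None else v}
        for (t, iso), v in sorted(conn.sim_indices.items())
    ]
    pd.DataFrame(sim_rows).to_csv(out / "sim_indices.tsv", sep="\t", index=False)
    div_rows = []
    for pop in populations:
        stats = d50(lineages, pop)
        if stats is not None:
            div_rows.append(
                {"population": pop, "n_lineages": stats.n_lineages,
                 "n_sequences": stats.n_sequences, "d50_count": stats.d50_count,
                 "d50_fraction": stats.d50_fraction}
            )
    pd.DataFrame(div_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
    export_circular_plot_data(conn, lineages, populations, out / "circos")

    mut_rows = []
    for pop in populations:
        for iso in [None, *ISOTYPES]:
            summary = population_mutation_summary(
                lineages, df, pop, iso, config.aggregate
            )
            if summary.n_lineages:
                mut_rows.append(
                    {"population": pop, "isotype": iso or "ALL",
                     "aggregate": config.aggregate,
                     "summary_mutation_freq_pct": summary.summary_value,
                     "n_lineages": summary.n_lineages}
                )
    pd.DataFrame(mut_rows).to_csv(out / "mutation_summary.tsv", sep="\t", index=False)

    total_counts = {k: int(sum(r[k] for r in qc_rows)) for k in
                    ("input", "merged", "dropped_unmerged", "dropped_length",
                     "dropped_quality", "dropped_isotype_unassigned",
                     "dropped_isotype_contradiction", "kept")}
    conserved = (
        total_counts["input"]
        == total_counts["kept"]
        + total_counts["dropped_unmerged"] + total_counts["dropped_length"]
        + total_counts["dropped_quality"] + total_counts["dropped_isotype_unassigned"]
        + total_counts["dropped_isotype_contradiction"]
    )
    manifest = {
        "parameters": {
            k: getattr(config, k)
            for k in (
                "min_len", "min_mean_q", "min_overlap", "max_mismatch_rate",
                "max_signature_mismatches", "identity_threshold", "linkage",
                "sim_variant", "aggregate", "library_mode", "primer_mask_len",
            )
        },
        "reference_pop": reference_pop,
        "input_checksums": {
            Path(p).name: _sha256(p)
            for inp in config.inputs
            for p in (inp.r1, inp.r2)
            if p is not None
        },
        "counts": {
            "preprocess": total_counts,
            "annotate": ann_counts,
            "n_collapsed_rows": int(len(df)),
            "n_lineages": len(lineages),
            "record_conservation_ok": bool(conserved),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
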