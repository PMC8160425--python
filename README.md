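# bcrclone

B-cell receptor (BCR) heavy-chain repertoire informatics for multi-population
amplicon sequencing: read preprocessing, isotype calling, V/J/CDR3
annotation, clonal lineage clustering, inter-population connectivity and
diversity statistics, and somatic-hypermutation summaries — plus a
ground-truth repertoire simulator so the whole pipeline is testable without
any external data.

## Who this is for

Groups studying the clonal relationships between B-cell subsets — for
example, asking whether tissue antibody-secreting cells (ASC) of a given
isotype derive from local naive-like IgD+ B cells or from circulating memory
cells — using bulk IGH amplicon sequencing of sorted populations (e.g.
nasal-polyp ASC, IgD+ and CD27+ memory cells, blood naive and memory cells)
and, optionally, per-cell consensus heavy-chain tables from single-cell VDJ
sequencing.

## The method

**Clonal lineages.** Two heavy-chain sequences are assigned to the same
clonal lineage (clone) when they share an identical V gene, identical J gene,
identical CDR3 length, and CDR3 nucleotide Hamming identity ≥ 0.85
(single-linkage chaining; complete linkage available). The heavy-chain CDR3
is the junction strictly between the conserved V cysteine codon and the
conserved J tryptophan/phenylalanine codon, both anchors excluded.

**Connectivity.** For a reference population *R* (optionally restricted to
an isotype, e.g. IgE ASC), the shared-lineage fraction to a target *T* is

    100 · |{lineages with ≥1 R member and ≥1 T member}| / |{lineages with ≥1 R member}|

The isotype-resolved SIM index between lineage sets *A* and *B* is offered in
three set-overlap variants: |A∩B|/|A| (reference fraction, default),
Jaccard |A∩B|/|A∪B|, and Sørensen–Dice 2|A∩B|/(|A|+|B|).

**Diversity.** D50 is the smallest number of top-ranked lineages accounting
for at least 50% of a population's (duplicate-weighted) sequences.

**Mutation load.** Per sequence, somatic hypermutation is the percentage of
substitutions versus the germline V over the aligned span, excluding a 25-nt
FR1 primer footprint and everything from the Cys anchor onward. Bulk
populations are summarized as the *averaged median lineage mutation
frequency*: duplicate-weighted median within each lineage, arithmetic mean
across lineages. Single-cell tables are summarized per isotype with pairwise
two-tailed Welch t-tests.

**Preprocessing.** Paired 2×301 reads are merged on their maximal admissible
3′ overlap (mismatch rate ≤ 0.1, higher-quality base wins at conflicts),
filtered (length ≥ 200 nt strictly, mean Phred ≥ 20), oriented V→constant,
and isotype-called by scanning the 3′ window for constant-region signature
sequences (IgM/IgG/IgA/IgE primer-derived 19–21-mers plus a synthetic IgD
signature in the bundled test reference).

## Worked example

```python
import bcrclone as bc

ref = bc.bundled_reference()            # small synthetic V/J/signature fixture
cfg = bc.default_config(seed=1, n_clones=30)   # 5 populations, planted overlap
truth, table = bc.simulate_repertoire(cfg, ref)
manifest = bc.emit_reads(table, cfg, "reads/")  # paired FASTQ per population

from bcrclone.pipeline import InputSpec
pcfg = bc.PipelineConfig(
    inputs=[InputSpec(e["population"], f"reads/{e['r1']}", f"reads/{e['r2']}")
            for e in manifest["inputs"]],
    output_dir="out/", reference_pop="NP_ASC",
)
result = bc.run_pipeline(pcfg)
print(result["counts"])
```

prints (seed 1):

```
{'preprocess': {'input': 868, 'merged': 868, 'dropped_unmerged': 0,
  'dropped_length': 0, 'dropped_quality': 0, 'dropped_isotype_unassigned': 0,
  'dropped_isotype_contradiction': 0, 'kept': 868},
 'annotate': {'input': 868, 'annotated': 868, 'unannotatable': 0, 'nonproductive': 0},
 'n_collapsed_rows': 856, 'n_lineages': 150, 'record_conservation_ok': True}
```

All 868 simulated read pairs merge back to their clean sequences, annotate
successfully, and cluster into exactly the 150 planted clones (30 per
population; clones planted as shared appear as single lineages spanning two
populations). `out/` then contains the per-population QC table, the
AIRR-style rearrangement table with lineage ids, the lineage table,
connectivity/SIM/diversity tables, circos-format karyotype/link files and a
reproducibility manifest.

The same stages are available from the shell:

```bash
bcrclone simulate sim.yaml --out-dir reads/
bcrclone run pipeline.yaml
```

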