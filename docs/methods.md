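# Methods

## Scope and model

`bcrclone` analyzes bulk IGH amplicon repertoires from sorted B-cell
populations. Its unit of inference is the clonal lineage: the set of
sequences descending from one V(D)J recombination event, operationalized as
identical V gene, identical J gene, identical CDR3 nucleotide length and
CDR3 Hamming identity of at least 0.85 connected by single linkage. All
abundance statistics are duplicate-weighted: identical sequences within a
population are collapsed to one row whose `duplicate_count` carries the read
count.

## Preprocessing

*Merging.* For a read pair, the reverse read is reverse-complemented and the
longest 3′ overlap with per-position mismatch rate ≤ `max_mismatch_rate`
(default 0.1) and length ≥ `min_overlap` (default 10) is accepted. At
mismatching overlap positions the base with the higher Phred score is kept
with its quality; at agreeing positions the higher quality is kept. No
admissible overlap → the pair is dropped and counted.

*Filtering.* Reads shorter than 200 nt are excluded, reading the length rule
strictly (exactly 200 nt is kept). The quality criterion is a mean-Phred
threshold, default 20, because the source protocol names only "a quality
threshold" without a metric; both are configurable. FASTA input (pre-merged
consensus sequences) receives a uniform placeholder quality of Q40 so it is
never quality-filtered.

*Orientation and isotype.* Each read is oriented V→constant by choosing the
strand whose 3′ terminal window (longest signature + 30 nt) carries the
better constant-signature match; ties go to forward, and reads with no
near-full-length signature hit on either strand are kept forward and
flagged. Isotype calling scans the same window for each signature allowing
substitutions only — the signatures are primer-derived, where an indel
indicates an artifact rather than biology. The default mismatch cap is 2
(~10% of a 20-nt signature, the same tolerance used in read merging): a cap
of 1 makes the call fragile at percent-scale sequencing error, since the
probability of two errors inside a 20-mer at 1% per-base error is ~1.7%,
which would violate the ≥99.5% call-accuracy behavior the pipeline is
designed to (and, in its tests, does) achieve. A tie in mismatch count
between two isotypes is reported UNASSIGNED/ambiguous, never guessed. When a
library is declared single-isotype (isotypes amplified individually, the
protocol that precludes isotype quantification), calls contradicting the
declaration are dropped and counted separately; combined-primer libraries
are instead quantified per population.

## Annotation

V and J are assigned by affine-gap semi-global alignment (free end gaps on
both sequences) with match +5, mismatch −4, gap open −12, gap extend −2 and
a score floor of 50 — conventional Ig-amplicon settings; the method itself
is not specified by the source protocol. Ties break by fewer mismatches,
then name. Two deliberate restrictions keep the CDR3 anchors mappable:

* the germline V is aligned only up to the end of its conserved Cys codon —
  nucleotides 3′ of it are removed during recombination, and letting them
  align into the junction displaces the anchor;
* the germline J is aligned only from its conserved Trp/Phe codon onward,
  for the symmetric reason (any retained J-derived junction nucleotides
  belong to the CDR3), and J search is restricted 3′ of the V alignment end.

CDR3 is the read segment strictly between the mapped anchor codons, both
excluded (the IMGT CDR3 convention); an empty or out-of-frame CDR3 flags the
row nonproductive and excludes it from clustering. Mutation load counts
substitutions against the germline V over aligned columns with germline
coordinate in `[25, cys_anchor)`: the first 25 nt are a FR1 primer footprint
(primer-encoded sequence, not biology) and positions at or beyond the Cys
anchor are junction-adjacent. Gap columns count in neither numerator nor
denominator. Whether mutation frequencies should span V only or V+J is not
stated by the source protocol; V-only is computed (the J span is short and
partly primer-constrained). Allele-level calls collapse to gene level before
clustering (`IGHV3-23*01` → `IGHV3-23`), the robust reading of "identical V
and J selection"; allele-level grouping is available.

## Clustering

Within each (V gene, J gene, CDR3 length) group, pairwise CDR3 identity is
1 − mismatches/length with N counting as a mismatch (an N carries no
evidence of identity). The threshold is inclusive (≥ 0.85), following the
protocol's "at least 85%" wording over the informal ">85%" elsewhere.
Single-linkage connected components are the default (nearest-neighbor
chaining matches the lineage-identifier tradition this rule comes from);
complete linkage is available behind a flag and uses a +1e-9 slack on the
distance cutoff so the threshold stays inclusive under float round-off.
Lineage ids are a SHA-1 hash of the sorted member ids, so ids and
memberships are invariant under input permutation.

## Connectivity, SIM and D50

Shared-lineage fractions and SIM indices operate on lineage sets defined by
"contains at least one sequence of (population, isotype)". The SIM index has
no published formula; three set-overlap variants are implemented
(|A∩B|/|A|, Jaccard, Sørensen–Dice) and the reference-normalized fraction is
the default because the quantity is described as a *fraction of reference
connectivity related to isotypes*; the variant used is recorded in every
output. Undefined cases (empty reference set) return a sentinel (`None` /
empty field), never 0. D50 ranks a population's lineages by
duplicate-weighted count (ties by lineage id) and returns the smallest k
whose cumulative count reaches 50% of the population total, computed in
exact integer arithmetic. Whether D50 should be duplicate-weighted or
unique-sequence-based is unstated upstream; duplicate-weighted is the
default. Circular-plot export writes circos-style karyotype, highlight
(top-D50 sub-range) and link files; a link is emphasized when its lineage's
summed count across the two populations is strictly greater than 50
("more than 50 sequences"), exactly 50 falling to the gray class.

## Mutation summaries

"Averaged median lineage mutation frequency" is parsed as: duplicate-
weighted median of member frequencies within each lineage (even counts:
mean of the two central order statistics of the expanded sample), then
arithmetic mean across lineages; a cross-lineage median is available via
`aggregate="median"` since the phrase is ambiguous. Lineages with no member
matching the (population, isotype) filter are excluded rather than counted
as zero. Single-cell consensus tables (one row per cell) are summarized per
isotype; pairwise comparisons use the unequal-variance (Welch) two-tailed
t-test — the source protocol says only "t-testing (two-tailed)", and Welch
is the safe default under unequal group sizes such as 52 vs 2192 cells.
Groups with fewer than 2 cells report a mean but no test.

## Simulator

The generator emulates the study design so every pipeline claim is testable
against planted truth:

* **Populations** default to the five-subset profile (NP_ASC, NP_IgD,
  NP_CD27M, PBL_naive, PBL_CD27M). Isotype mixtures default to 83/11/6
  IgM/IgG/IgA for NP_IgD and 99.5% IgM for PBL_naive — the two mixtures the
  combined-primer quantification measures — with plausible switched-heavy
  mixtures for ASC/memory subsets.
* **Clones** draw a V and J from the reference and a random in-frame CDR3 of
  24–72 nt. Members diversify the CDR3 by at most 5% of its length from the
  clone ancestor, bounding within-clone pairwise distance at 10% so planted
  clones are unambiguous under the 0.85 threshold. Clone sizes are
  geometric(p = 0.2) by default (mean 5, the skewed sizes circular outer
  tracks display), zipf available for heavier tails. A separate stress
  generator plants sequence pairs at CDR3 identity exactly 0.85 and 0.84
  (15 vs 16 mismatches at length 100) to probe the inclusive boundary.
* **Overlap** specs replicate a chosen fraction of a reference population's
  clones into a partner population, optionally forcing the isotype on either
  side (isotype-restricted connectivity). Counts are planted exactly
  (`floor(fraction × n_clones)`); multiple specs sharing a reference
  population draw from disjoint clone pools so each count is realized
  independently.
* **Mutations** are planted only in the V region 5′ of the Cys anchor, as a
  Poisson load with rate = subset mean × anchor position, at uniform distinct
  positions, with optional per-clone gamma rate dispersion (mean-preserving).
  Uniform placement makes the measured frequency over the evaluated span an
  unbiased estimate of the planted rate. Default subset means (naive 0.5%,
  IgD+ 2%, memory/ASC 6%) reproduce the qualitative naive-low /
  switched-high ordering; they are simulator defaults, not measurements.
* **Reads** are emitted as 2×301 pairs over the clean amplicon
  (V[:Cys+3] + CDR3 + J[Trp:] + constant signature, ~380–440 nt), with
  independent per-base substitution errors at the configured rate and a
  deterministic Phred profile (Q37 with mild 3′ decay). Per-isotype mode
  writes one FASTQ pair per (population, isotype); combined mode one per
  population. Everything is byte-deterministic under the config seed.

What the simulator does **not** model — and hence what passing tests do not
demonstrate about real data: indel sequencing errors and indel SHM, SHM
hotspot motifs and phylogenetic structure within clones, quality-correlated
error profiles, chimeric/crossover PCR artifacts, allele-level germline
variation, and D segments. The bundled reference is a 5-V/3-J synthetic
fixture (its IgD signature is likewise synthetic); real analyses should
supply an IMGT-style reference in the same FASTA + anchors + signatures
format, which is pluggable because the upstream database/version is
unstated.

## Numerical and engineering choices

Alignment scores are integers; all thresholds are inclusive as documented
above. Lineage clustering is exact (no heuristics): within-group all-pairs
identity on byte matrices, components via the graph library. Determinism is
a contract: no hidden global randomness, every stochastic component takes a
seed, dictionary orderings are sorted before writing, and rerunning the
pipeline on identical inputs is byte-identical (asserted in tests). Problem
sizes in the test suite (e.g. ~100 clones per population, ~10,000 reads for
isotype-accuracy checks, ~2,000 sequences per subset for mutation recovery)
were chosen as the smallest scales at which the binomial/Poisson sampling
error is comfortably below the asserted tolerances.

## Known limitations

Merging assumes the amplicon is no longer than the two reads minus the
minimum overlap; longer fragments are skipped with a log note. The
mean-Phred filter is a crude proxy for per-base quality trimming. Isotype
calling assumes the constant signature survives intact near the 3′ end;
heavily degraded 3′ ends become UNASSIGNED rather than rescued. Statistical
testing is limited to the Welch t-tests the single-cell summary reports;
subject-level inference (paired designs across individuals) is left to the
caller, which also decides how to aggregate per-individual summaries.
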