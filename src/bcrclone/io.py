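"""Sequence and rearrangement-table input/output.

Reads FASTQ (Phred+33), FASTA and synchronized paired FASTQ into
:class:`ReadRecord` streams, and round-trips annotated rearrangements as
AIRR-style tab-separated tables (columns ``sequence_id``, ``v_call``,
``j_call``, ``cdr3``, ``c_call``, ``duplicate_count`` plus ``population`` and
``mutation_freq``).  Pipeline parameters travel with the table as ``#``
key=value header lines so a written table is a self-describing artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .reference import ISOTYPES, UNASSIGNED

VALID_BASES = frozenset("ACGTN")

#: Placeholder per-base quality for FASTA input (pre-merged consensus reads).
FASTA_PLACEHOLDER_Q = 40

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "cdr3")

_COLUMN_ORDER = [
    "sequence_id", "population", "sequence", "v_call", "j_call",
    "v_score", "j_score", "cdr3", "cdr3_aa", "c_call",
    "v_mutations", "v_eval_len", "mutation_freq", "duplicate_count",
    "lineage_id",
]


class SequenceIOError(ValueError):
    """Fatal input problem: malformed records, desynchronized pairs, bad labels."""


@dataclass
class ReadRecord:
    read_id: str
    seq_nt: str
    quals: list[int]
    population: str
    mate: str = "merged"  # "1" | "2" | "merged"

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq_nt):
            raise SequenceIOError(
                f"{self.read_id}: quality length {len(self.quals)} != "
                f"sequence length {len(self.seq_nt)}"
            )
        if not self.population:
            raise SequenceIOError(f"{self.read_id}: empty population label")

    def __len__(self) -> int:
        return len(self.seq_nt)


def _check_bases(read_id: str, seq: str) -> str:
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in VALID_BASES:
            raise SequenceIOError(
                f"{read_id}: non-IUPAC character {b!r} at position {i}"
            )
    return seq


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def read_sequences(
    paths: list[str | Path],
    population_label: str,
    format: str = "fastq",
) -> Iterator[ReadRecord] | Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream reads from FASTQ/FASTA files, tagging each with its population.

    ``format`` is one of ``fastq``, ``fasta``, ``fastq-paired``.  Paired mode
    takes exactly two synchronized files and yields ``(fwd, rev)`` tuples,
    failing fast at the first read-id mismatch.  FASTA records receive a
    uniform placeholder quality (Q40) so pre-merged consensus input is not
    quality-filtered.
    """
    if format == "fastq-paired":
        if len(paths) != 2:
            raise SequenceIOError("paired mode requires exactly two files")
        return _read_paired(paths[0], paths[1], population_label)
    if format not in ("fastq", "fasta"):
        raise SequenceIOError(f"unknown format {format!r}")
    return _read_single(paths, population_label, format)


def _read_single(paths, population, format) -> Iterator[ReadRecord]:
    for path in paths:
        for rec in SeqIO.parse(str(path), format):
            seq = _check_bases(rec.id, str(rec.seq))
            if format == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            else:
                quals = [FASTA_PLACEHOLDER_Q] * len(seq)
            yield ReadRecord(rec.id, seq, quals, population)


def _read_paired(path1, path2, population) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        id1, id2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
        if id1 != id2:
            raise SequenceIOError(f"desynchronized pair files: {id1!r} vs {id2!r}")
        yield (
            ReadRecord(id1, _check_bases(id1, str(rec1.seq)),
                       list(rec1.letter_annotations["phred_quality"]), population, "1"),
            ReadRecord(id2, _check_bases(id2, str(rec2.seq)),
                       list(rec2.letter_annotations["phred_quality"]), population, "2"),
        )


@dataclass
class RearrangementTable:
    """Annotated heavy-chain rearrangements plus the parameters that produced them."""

    df: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df["sequence_id"].duplicated().any():
            dupes = self.df.loc[self.df["sequence_id"].duplicated(), "sequence_id"]
            raise SequenceIOError(f"duplicate sequence_id: {dupes.iloc[0]!r}")
        if "c_call" in self.df.columns:
            allowed = set(ISOTYPES) | {UNASSIGNED}
            bad = set(self.df["c_call"].dropna()) - allowed
            if bad:
                raise SequenceIOError(
                    f"unknown isotype label(s) {sorted(bad)}; "
                    f"allowed: {sorted(allowed)}"
                )

    def __len__(self) -> int:
        return len(self.df)


def write_rearrangements(table: RearrangementTable, path: str | Path) -> None:
    cols = [c for c in _COLUMN_ORDER if c in table.df.columns]
    cols += [c for c in table.df.columns if c not in cols]
    with open(path, "w") as fh:
        for key in sorted(table.provenance):
            fh.write(f"#{key}={table.provenance[key]}\n")
        table.df[cols].to_csv(fh, sep="\t", index=False)


def read_rearrangements(path: str | Path) -> RearrangementTable:
    provenance: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            provenance[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"sequence_id": str})
    if "isotype" in df.columns and "c_call" not in df.columns:
        df = df.rename(columns={"isotype": "c_call"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceIOError(f"rearrangement table missing columns: {missing}")
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    if "population" not in df.columns:
        df["population"] = "unspecified"
    return RearrangementTable(df, provenance)
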