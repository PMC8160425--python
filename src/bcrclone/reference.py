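"""Germline reference bundle: V/J segments with CDR3 anchors, constant-region signatures.

The reference couples three pieces of information the rest of the pipeline
needs: germline V and J nucleotide sequences, the position of the conserved
CDR3-proximal cysteine (in V) and tryptophan/phenylalanine (in J) codons that
delimit the heavy-chain CDR3, and the constant-region signature sequences used
to call the isotype of each read.  A small synthetic fixture reference is
bundled for testing; a full IMGT-style reference can be supplied in the same
format (FASTA + anchors TSV + signatures TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

ISOTYPES = ("IGM", "IGG", "IGA", "IGE", "IGD")
UNASSIGNED = "UNASSIGNED"

#: Minimum length for a constant-region signature.
MIN_SIGNATURE_LEN = 15


class ReferenceValidationError(ValueError):
    """Raised when a germline reference bundle violates a structural invariant."""


@dataclass(frozen=True)
class VSegment:
    """A germline V segment with the 0-based start of the conserved Cys codon."""

    name: str
    seq_nt: str
    cys_anchor: int


@dataclass(frozen=True)
class JSegment:
    """A germline J segment with the 0-based start of the conserved Trp/Phe codon."""

    name: str
    seq_nt: str
    wf_anchor: int


@dataclass
class GermlineReference:
    v_segments: list[VSegment]
    j_segments: list[JSegment]
    constant_signatures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def v_by_name(self) -> dict[str, VSegment]:
        return {v.name: v for v in self.v_segments}

    @property
    def j_by_name(self) -> dict[str, JSegment]:
        return {j.name: j for j in self.j_segments}

    @property
    def max_signature_len(self) -> int:
        return max(len(s) for s in self.constant_signatures.values())

    def validate(self) -> None:
        v_names = [v.name for v in self.v_segments]
        j_names = [j.name for j in self.j_segments]
        if len(set(v_names)) != len(v_names):
            raise ReferenceValidationError("duplicate V segment names")
        if len(set(j_names)) != len(j_names):
            raise ReferenceValidationError("duplicate J segment names")
        for v in self.v_segments:
            _check_anchor(v.name, v.seq_nt, v.cys_anchor, expected="C")
        for j in self.j_segments:
            _check_anchor(j.name, j.seq_nt, j.wf_anchor, expected="WF")
        for label, sig in self.constant_signatures.items():
            if len(sig) < MIN_SIGNATURE_LEN:
                raise ReferenceValidationError(
                    f"signature {label!r} shorter than {MIN_SIGNATURE_LEN} nt"
                )
        sigs = sorted(self.constant_signatures.items())
        for i, (la, sa) in enumerate(sigs):
            for lb, sb in sigs[i + 1 :]:
                if len(sa) == len(sb):
                    dist = sum(x != y for x, y in zip(sa, sb))
                    if dist <= 2:
                        raise ReferenceValidationError(
                            f"signatures {la!r} and {lb!r} are within Hamming distance 2"
                        )


def _check_anchor(name: str, seq_nt: str, anchor: int, expected: str) -> None:
    if not 0 <= anchor <= len(seq_nt) - 3:
        raise ReferenceValidationError(
            f"segment {name!r}: anchor {anchor} out of range for length {len(seq_nt)}"
        )
    codon = seq_nt[anchor : anchor + 3]
    aa = str(Seq(codon).translate())
    if aa not in expected:
        raise ReferenceValidationError(
            f"segment {name!r}: anchor codon {codon} translates to {aa!r}, "
            f"expected one of {expected!r}"
        )


def load_germline_reference(
    fasta_path: str | Path,
    anchors_path: str | Path,
    signatures_path: str | Path,
) -> GermlineReference:
    """Load and validate a germline reference bundle.

    ``fasta_path`` holds both V and J segments; ``anchors_path`` is a TSV with
    columns ``segment``, ``segment_type`` (V or J) and ``anchor`` (0-based
    codon start); ``signatures_path`` is a TSV with columns ``isotype`` and
    ``signature``.  Any invariant violation is fatal, never a warning.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    anchors = pd.read_csv(anchors_path, sep="\t", dtype={"anchor": int})
    missing = set(anchors["segment"]) - set(records)
    if missing:
        raise ReferenceValidationError(
            f"anchor entries reference absent segments: {', '.join(sorted(missing))}"
        )
    unanchored = set(records) - set(anchors["segment"])
    if unanchored:
        raise ReferenceValidationError(
            f"segments missing anchor entries: {', '.join(sorted(unanchored))}"
        )
    v_segments, j_segments = [], []
    for row in anchors.itertuples(index=False):
        seg_type = str(row.segment_type).upper()
        if seg_type == "V":
            v_segments.append(VSegment(row.segment, records[row.segment], int(row.anchor)))
        elif seg_type == "J":
            j_segments.append(JSegment(row.segment, records[row.segment], int(row.anchor)))
        else:
            raise ReferenceValidationError(
                f"segment {row.segment!r}: unknown segment_type {row.segment_type!r}"
            )
    sig_df = pd.read_csv(signatures_path, sep="\t")
    signatures = {
        str(r.isotype): str(r.signature).upper() for r in sig_df.itertuples(index=False)
    }
    return GermlineReference(v_segments, j_segments, signatures)


def bundled_reference() -> GermlineReference:
    """The small synthetic test reference shipped with the package.

    Five V-like and three J-like segments plus the four constant-region
    primer-derived signatures (IgM/IgG/IgA/IgE) and a synthetic IgD signature.
    Sufficient for simulation and testing; not a biological database.
    """
    data = resources.files("bcrclone") / "data"
    return load_germline_reference(
        str(data / "germline.fasta"),
        str(data / "anchors.tsv"),
        str(data / "signatures.tsv"),
    )


def gene_call(call: str) -> str:
    """Collapse an allele-level segment call (``IGHV3-23*01``) to gene level."""
    return call.split("*")[0]
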