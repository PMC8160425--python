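"""Germline V/J assignment, CDR3 extraction and somatic-hypermutation counting.

Segment assignment uses affine-gap semi-global alignment (free end gaps on
both sequences) with conventional Ig-amplicon scoring: match +5, mismatch -4,
gap open -12, gap extend -2, score floor 50.  The heavy-chain CDR3 is the
read sequence strictly between the mapped conserved-Cys codon of the V and
the mapped conserved-Trp/Phe codon of the J, both anchor codons excluded.
Mutation load is the substitution count versus the germline V over the
aligned span, excluding a 5' primer footprint (the FR1 primer overwrites
true sequence there) and everything from the Cys anchor onward.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .reference import GermlineReference, JSegment, VSegment

MATCH_SCORE = 5
MISMATCH_SCORE = -4
GAP_OPEN = -12
GAP_EXTEND = -2

#: Minimum admissible alignment score for a V or J call.
SCORE_FLOOR = 50

#: 5' nt of the aligned V excluded from mutation counting (FR1 primer footprint).
PRIMER_MASK_LEN = 25


class AnnotationError(ValueError):
    """A sequence that cannot be annotated (reason carried in the message)."""


@dataclass
class SegmentAlignment:
    """One germline segment aligned to a read.

    ``blocks`` pairs half-open read and germline intervals of the aligned
    (gap-free) runs; coordinates are in the full read even when the search
    was restricted to a sub-window.
    """

    call: str
    score: float
    n_mismatches: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]

    @property
    def read_end(self) -> int:
        return self.blocks[-1][0][1]

    def map_position(self, germline_pos: int) -> int | None:
        """Read coordinate of a germline position, or None if it falls in a gap."""
        for (rs, _), (gs, ge) in self.blocks:
            if gs <= germline_pos < ge:
                return rs + (germline_pos - gs)
        return None

    def map_codon(self, germline_pos: int) -> int | None:
        """Read coordinate of a germline codon start; the whole codon must map
        contiguously (no gap inside or at the codon edges)."""
        for (rs, _), (gs, ge) in self.blocks:
            if gs <= germline_pos and germline_pos + 3 <= ge:
                return rs + (germline_pos - gs)
        return None


def make_aligner(
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on read (insertions) and germline (deletions): overlap mode
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def _align_segment(
    seq: str,
    segment_seq: str,
    aligner: Align.PairwiseAligner,
    read_offset: int = 0,
    germ_offset: int = 0,
) -> tuple[float, int, list]:
    aln = aligner.align(seq, segment_seq)[0]
    target_blocks, query_blocks = aln.aligned
    blocks = []
    n_mismatches = 0
    for (ts, te), (qs, qe) in zip(target_blocks.tolist(), query_blocks.tolist()):
        read_frag = seq[ts:te]
        germ_frag = segment_seq[qs:qe]
        n_mismatches += sum(a != b for a, b in zip(read_frag, germ_frag))
        blocks.append(((ts + read_offset, te + read_offset), (qs + germ_offset, qe + germ_offset)))
    return aln.score, n_mismatches, blocks


def _best_segment(
    seq, segments, aligner, read_offset=0, window=None
) -> SegmentAlignment | None:
    """Best segment alignment; ``window(seg)`` -> (start, end) restricts the
    germline to a sub-span while block coordinates stay in full-segment frame."""
    best: SegmentAlignment | None = None
    for seg in segments:
        start, end = (0, len(seg.seq_nt)) if window is None else window(seg)
        seg_seq = seg.seq_nt[start:end]
        score, mism, blocks = _align_segment(
            seq, seg_seq, aligner, read_offset, germ_offset=start
        )
        if not blocks:
            continue
        cand = SegmentAlignment(seg.name, score, mism, blocks)
        if (
            best is None
            or cand.score > best.score
            or (
                cand.score == best.score
                and (cand.n_mismatches, cand.call) < (best.n_mismatches, best.call)
            )
        ):
            best = cand
    if best is None or best.score < SCORE_FLOOR:
        return None
    return best


def assign_v(
    seq: str, reference: GermlineReference, aligner: Align.PairwiseAligner | None = None
) -> SegmentAlignment:
    """Best-scoring germline V for an oriented read; ties broken by fewer
    mismatches, then lexicographic segment name.

    The germline V is aligned only up to the end of its conserved Cys codon:
    nucleotides 3' of it are removed by V(D)J recombination, and letting them
    align into the junction would displace the CDR3 anchor.
    """
    aligner = aligner or make_aligner()
    best = _best_segment(
        seq, reference.v_segments, aligner, window=lambda seg: (0, seg.cys_anchor + 3)
    )
    if best is None:
        raise AnnotationError("no V alignment above score floor")
    return best


def assign_j(
    seq: str,
    reference: GermlineReference,
    v_alignment: SegmentAlignment,
    aligner: Align.PairwiseAligner | None = None,
) -> SegmentAlignment:
    """Best germline J, searched strictly 3' of the V alignment end.

    The germline J is aligned from its conserved Trp/Phe codon onward: its 5'
    end is trimmed during recombination (any retained J-derived junction
    nucleotides belong to the CDR3) and letting it align would displace the
    CDR3 anchor.
    """
    aligner = aligner or make_aligner()
    start = v_alignment.read_end
    sub = seq[start:]
    if not sub:
        raise AnnotationError("no sequence 3' of the V alignment to search for J")
    best = _best_segment(
        sub, reference.j_segments, aligner, read_offset=start,
        window=lambda seg: (seg.wf_anchor, len(seg.seq_nt)),
    )
    if best is None:
        raise AnnotationError("no J alignment above score floor")
    return best


def extract_cdr3(
    seq: str,
    v_alignment: SegmentAlignment,
    j_alignment: SegmentAlignment,
    reference: GermlineReference,
) -> tuple[str, str, bool]:
    """CDR3 nucleotides between the mapped anchor codons (both excluded).

    Returns ``(cdr3_nt, cdr3_aa, productive)``; a CDR3 that is empty or whose
    length is not divisible by 3 is flagged nonproductive (``cdr3_aa`` empty).
    """
    v_seg: VSegment = reference.v_by_name[v_alignment.call]
    j_seg: JSegment = reference.j_by_name[j_alignment.call]
    cys_read = v_alignment.map_codon(v_seg.cys_anchor)
    wf_read = j_alignment.map_codon(j_seg.wf_anchor)
    if cys_read is None or wf_read is None:
        raise AnnotationError("anchor codon falls in an alignment gap")
    cdr3_nt = seq[cys_read + 3 : wf_read]
    if not cdr3_nt or len(cdr3_nt) % 3 != 0:
        return cdr3_nt, "", False
    cdr3_aa = str(Seq(cdr3_nt).translate())
    return cdr3_nt, cdr3_aa, True


def mutation_frequency(
    seq: str,
    v_alignment: SegmentAlignment,
    reference: GermlineReference,
    primer_mask_len: int = PRIMER_MASK_LEN,
) -> tuple[int, int, float]:
    """Substitutions vs germline V over the evaluated span, as a percentage.

    Evaluated positions are aligned (gap-free) columns with germline
    coordinate in ``[primer_mask_len, cys_anchor)``; alignment gaps count in
    neither numerator nor denominator.  Returns
    ``(v_mutations, v_eval_len, mutation_freq_percent)``.
    """
    v_seg = reference.v_by_name[v_alignment.call]
    germ = v_seg.seq_nt
    n_mut = 0
    n_eval = 0
    for (rs, re_), (gs, ge) in v_alignment.blocks:
        for k in range(ge - gs):
            g = gs + k
            if g < primer_mask_len or g >= v_seg.cys_anchor:
                continue
            n_eval += 1
            if seq[rs + k] != germ[g]:
                n_mut += 1
    if n_eval <= 0:
        raise AnnotationError("no evaluable V positions after primer masking")
    return n_mut, n_eval, 100.0 * n_mut / n_eval


def annotate_sequence(
    seq: str,
    reference: GermlineReference,
    aligner: Align.PairwiseAligner | None = None,
    primer_mask_len: int = PRIMER_MASK_LEN,
) -> dict:
    """Run V, J, CDR3 and mutation annotation on one oriented sequence.

    Returns a row dict (AIRR-style keys).  Raises :class:`AnnotationError`
    for unannotatable sequences; nonproductive CDR3s are returned with
    ``productive=False`` for the caller to exclude from clustering.
    """
    aligner = aligner or make_aligner()
    v_aln = assign_v(seq, reference, aligner)
    j_aln = assign_j(seq, reference, v_aln, aligner)
    cdr3_nt, cdr3_aa, productive = extract_cdr3(seq, v_aln, j_aln, reference)
    n_mut, n_eval, freq = mutation_frequency(seq, v_aln, reference, primer_mask_len)
    return {
        "sequence": seq,
        "v_call": v_aln.call,
        "j_call": j_aln.call,
        "v_score": v_aln.score,
        "j_score": j_aln.score,
        "cdr3": cdr3_nt,
        "cdr3_aa": cdr3_aa,
        "productive": productive,
        "v_mutations": n_mut,
        "v_eval_len": n_eval,
        "mutation_freq": freq,
    }


def collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Merge rows identical in (population, sequence), summing duplicate_count.

    The representative row keeps the lexicographically smallest sequence_id of
    its group so output is independent of input order.
    """
    if df.empty:
        return df.copy()
    work = df.sort_values("sequence_id", kind="mergesort")
    grouped = work.groupby(["population", "sequence"], sort=True, as_index=False)
    counts = grouped["duplicate_count"].sum()
    first = grouped.nth(0).drop(columns=["duplicate_count"])
    out = first.merge(counts, on=["population", "sequence"])
    return out.sort_values("sequence_id", kind="mergesort").reset_index(drop=True)
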