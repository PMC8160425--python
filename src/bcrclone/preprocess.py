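"""Read preprocessing: pair merging, length/quality filtering, orientation
normalization and isotype assignment from the constant-region signature.

The amplicon design places a constant-region primer-derived signature near the
3' end of each (V-to-constant oriented) sequence, so isotype calling is a
bounded substitution-only scan of the 3' terminal window — indels in
primer-derived sequence indicate artifacts and are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReadRecord
from .reference import GermlineReference, UNASSIGNED

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Extra slack, in nt, added to the longest signature to form the 3' scan window.
SIGNATURE_WINDOW_SLACK = 30

#: Default cap on substitutions tolerated in a signature match (~10% of a
#: 20-nt signature; keeps the call robust at percent-scale sequencing error).
DEFAULT_MAX_SIGNATURE_MISMATCHES = 2


class MergeError(ValueError):
    """Mates with different read ids cannot be merged."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergedRead:
    read_id: str
    seq_nt: str
    quals: list[int]
    population: str
    overlap_len: int
    n_overlap_mismatches: int

    def __len__(self) -> int:
        return len(self.seq_nt)


@dataclass
class FilterResult:
    keep: bool
    reason: str | None = None  # "length" | "quality"


@dataclass
class IsotypeCall:
    isotype: str
    signature_mismatches: int | None
    signature_position: int | None
    reason: str | None = None  # for UNASSIGNED: "no_match" | "ambiguous"


def merge_pair(
    fwd: ReadRecord,
    rev: ReadRecord,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair on the maximal admissible 3' overlap.

    The reverse read is reverse-complemented and slid against the forward
    read's 3' end; the longest overlap whose mismatch rate is at most
    ``max_mismatch_rate`` (and length at least ``min_overlap``) wins.  At
    mismatching overlap positions the base with the higher Phred score is
    kept, with its quality; at agreeing positions the higher quality is kept.
    Returns ``None`` when no admissible overlap exists.
    """
    if fwd.read_id != rev.read_id:
        raise MergeError(f"read_id mismatch: {fwd.read_id!r} vs {rev.read_id!r}")
    rc_seq = revcomp(rev.seq_nt)
    rc_quals = rev.quals[::-1]
    f_arr = np.frombuffer(fwd.seq_nt.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
    lf, lr = len(f_arr), len(r_arr)
    for L in range(min(lf, lr), min_overlap - 1, -1):
        mism = int(np.count_nonzero(f_arr[lf - L :] != r_arr[:L]))
        if mism <= max_mismatch_rate * L:
            break
    else:
        return None
    seq = list(fwd.seq_nt[: lf - L])
    quals = list(fwd.quals[: lf - L])
    for i in range(L):
        fb, fq = fwd.seq_nt[lf - L + i], fwd.quals[lf - L + i]
        rb, rq = rc_seq[i], rc_quals[i]
        if fb == rb:
            seq.append(fb)
            quals.append(max(fq, rq))
        elif rq > fq:
            seq.append(rb)
            quals.append(rq)
        else:
            seq.append(fb)
            quals.append(fq)
    seq += list(rc_seq[L:])
    quals += rc_quals[L:]
    return MergedRead(fwd.read_id, "".join(seq), quals, fwd.population, L, mism)


def length_quality_filter(
    read: ReadRecord | MergedRead,
    min_len: int = 200,
    min_mean_q: float = 20.0,
) -> FilterResult:
    """Keep reads of length >= ``min_len`` (strict: exactly 200 is kept when
    the threshold is 200) and mean Phred >= ``min_mean_q``."""
    if len(read.seq_nt) < min_len:
        return FilterResult(False, "length")
    if float(np.mean(read.quals)) < min_mean_q:
        return FilterResult(False, "quality")
    return FilterResult(True)


def _best_signature_scan(
    seq: str, reference: GermlineReference
) -> dict[str, tuple[int, int]]:
    """Per isotype: (fewest mismatches, 0-based match start) over the 3' window."""
    window_len = reference.max_signature_len + SIGNATURE_WINDOW_SLACK
    offset = max(0, len(seq) - window_len)
    window = seq[offset:]
    w_arr = np.frombuffer(window.encode(), dtype=np.uint8)
    best: dict[str, tuple[int, int]] = {}
    for isotype, sig in reference.constant_signatures.items():
        s_arr = np.frombuffer(sig.encode(), dtype=np.uint8)
        k = len(s_arr)
        best_m, best_pos = len(sig) + 1, -1
        for start in range(len(w_arr) - k + 1):
            m = int(np.count_nonzero(w_arr[start : start + k] != s_arr))
            if m < best_m:
                best_m, best_pos = m, offset + start
        best[isotype] = (best_m, best_pos)
    return best


def orient_sequence(
    read: ReadRecord | MergedRead, reference: GermlineReference
) -> tuple[ReadRecord | MergedRead, str]:
    """Return the read in V-to-constant orientation plus a strand flag.

    The strand whose 3' window carries the better constant-signature match
    (more matching positions) is chosen; ties go to forward.  ``"?"`` flags
    reads with no signature evidence on either strand (kept forward).
    """
    fwd_best = _best_signature_scan(read.seq_nt, reference)
    rc = revcomp(read.seq_nt)
    rev_best = _best_signature_scan(rc, reference)

    def score(best):  # matching positions of the best signature hit
        return max(
            len(reference.constant_signatures[iso]) - m
            for iso, (m, _) in best.items()
        )

    f_score, r_score = score(fwd_best), score(rev_best)
    # require at least a near-full-length signature hit to count as evidence
    evidence = max(f_score, r_score) >= reference.max_signature_len - 5
    if not evidence:
        return read, "?"
    if r_score > f_score:
        flipped = type(read)(**{**read.__dict__, "seq_nt": rc, "quals": read.quals[::-1]})
        return flipped, "-"
    return read, "+"


def assign_isotype(
    read: ReadRecord | MergedRead,
    reference: GermlineReference,
    max_mismatches: int = DEFAULT_MAX_SIGNATURE_MISMATCHES,
) -> IsotypeCall:
    """Call the isotype from the best constant-signature match in the 3' window.

    The unique signature with the fewest mismatches (at most
    ``max_mismatches``) wins; a tie between two distinct isotypes is never
    guessed and yields UNASSIGNED with reason ``ambiguous``.
    """
    best = _best_signature_scan(read.seq_nt, reference)
    ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    (iso1, (m1, p1)) = ranked[0]
    if m1 > max_mismatches:
        return IsotypeCall(UNASSIGNED, None, None, "no_match")
    if len(ranked) > 1 and ranked[1][1][0] == m1:
        return IsotypeCall(UNASSIGNED, None, None, "ambiguous")
    return IsotypeCall(iso1, m1, p1)
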