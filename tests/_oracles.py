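"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (nested loops, full enumeration) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_merge(fwd_seq, fwd_quals, rev_seq, rev_quals, min_overlap, max_mismatch_rate):
    """Enumerate every overlap length; return (seq, overlap_len, n_mismatches)
    for the longest admissible one, else None."""
    rc = brute_revcomp(rev_seq)
    rcq = list(reversed(rev_quals))
    best = None
    for L in range(min_overlap, min(len(fwd_seq), len(rc)) + 1):
        f_tail = fwd_seq[-L:]
        r_head = rc[:L]
        mism = sum(a != b for a, b in zip(f_tail, r_head))
        if mism / L <= max_mismatch_rate:
            best = L, mism
    if best is None:
        return None
    L, mism = best
    merged = []
    for i in range(L):
        fi = len(fwd_seq) - L + i
        if fwd_seq[fi] == rc[i]:
            merged.append(fwd_seq[fi])
        elif rcq[i] > fwd_quals[fi]:
            merged.append(rc[i])
        else:
            merged.append(fwd_seq[fi])
    return fwd_seq[: len(fwd_seq) - L] + "".join(merged) + rc[L:], L, mism


def brute_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    mism = sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))
    return 1.0 - mism / len(a)


def brute_lineage_partition(rows, threshold):
    """All-pairs single-linkage components.

    ``rows``: list of (sequence_id, v_gene, j_gene, cdr3).  Returns a set of
    frozensets of sequence_ids.
    """
    n = len(rows)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if a[1] != b[1] or a[2] != b[2] or len(a[3]) != len(b[3]):
                continue
            if brute_identity(a[3], b[3]) >= threshold:
                union(i, j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(rows[i][0])
    return {frozenset(g) for g in groups.values()}


def brute_set_overlap(a: set, b: set, variant: str):
    inter = len(a & b)
    if variant == "reference_fraction":
        return inter / len(a) if a else None
    if variant == "jaccard":
        return inter / len(a | b) if (a | b) else None
    if variant == "sorensen":
        return 2 * inter / (len(a) + len(b)) if (a or b) else None
    raise ValueError(variant)


def brute_d50(sizes) -> int:
    """Defining inequality, checked by expansion: smallest k with the top-k
    cumulative count at >= 50% of the total."""
    ordered = sorted(sizes, reverse=True)
    total = sum(ordered)
    cum = 0
    for k, s in enumerate(ordered, 1):
        cum += s
        if cum >= total / 2:
            return k
    raise AssertionError


def expanded_median(values, weights) -> float:
    return float(np.median(np.repeat(np.asarray(values, float), weights)))


def random_repertoire_rows(rng, n, n_v=3, n_j=2, lengths=(9, 12)):
    """Random annotated rows with deliberately collision-prone CDR3s: drawn by
    mutating a handful of ancestral CDR3s so identity values straddle 0.85."""
    ancestors = {}
    rows = []
    for i in range(n):
        v = f"V{rng.integers(n_v)}"
        j = f"J{rng.integers(n_j)}"
        length = int(rng.choice(lengths))
        key = (v, j, length, int(rng.integers(3)))
        if key not in ancestors:
            ancestors[key] = "".join(rng.choice(list("ACGT"), size=length))
        base = list(ancestors[key])
        n_sub = int(rng.integers(0, max(2, length // 3)))
        for pos in rng.choice(length, size=n_sub, replace=False):
            base[pos] = rng.choice([b for b in "ACGTN" if b != base[pos]])
        rows.append((f"seq{i:04d}", v, j, "".join(base)))
    return rows
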