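"""V/J assignment, CDR3 extraction and mutation quantification against
planted simulator truth."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import bcrclone as bc
from bcrclone.annotate import AnnotationError


def build_sequence(reference, v_idx=2, j_idx=1, cdr3="GATTACAGATTACAGA" + "T" * 2,
                   isotype="IGM"):
    v = reference.v_segments[v_idx]
    j = reference.j_segments[j_idx]
    return (
        v.seq_nt[: v.cys_anchor + 3]
        + cdr3
        + j.seq_nt[j.wf_anchor :]
        + reference.constant_signatures[isotype]
    )


def substitute(rng, seq, positions):
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestAssignVJ:
    def test_planted_v_recovered_exactly(self, reference, aligner):
        seq = build_sequence(reference, v_idx=2)
        v_aln = bc.assign_v(seq, reference, aligner)
        assert v_aln.call == reference.v_segments[2].name
        assert v_aln.n_mismatches == 0

    def test_planted_v_recovered_under_mutation(self, reference, aligner):
        """5 random V substitutions leave the call correct in >=99% of 500 seeds."""
        correct = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            v_idx = int(rng.integers(5))
            seq = build_sequence(reference, v_idx=v_idx)
            cys = reference.v_segments[v_idx].cys_anchor
            seq = substitute(rng, seq, rng.choice(cys, size=5, replace=False))
            if bc.assign_v(seq, reference, aligner).call == reference.v_segments[v_idx].name:
                correct += 1
        assert correct >= 495

    def test_planted_j_recovered_under_mutation(self, reference, aligner):
        """2 J substitutions leave the J call correct in >=99% of 500 seeds."""
        correct = 0
        for seed in range(500):
            rng = np.random.default_rng(1000 + seed)
            j_idx = int(rng.integers(3))
            seq = build_sequence(reference, j_idx=j_idx)
            j = reference.j_segments[j_idx]
            j_region_start = len(seq) - len(reference.constant_signatures["IGM"]) - (
                len(j.seq_nt) - j.wf_anchor
            )
            positions = j_region_start + rng.choice(
                len(j.seq_nt) - j.wf_anchor, size=2, replace=False
            )
            mutated = substitute(rng, seq, positions)
            v_aln = bc.assign_v(mutated, reference, aligner)
            if bc.assign_j(mutated, reference, v_aln, aligner).call == j.name:
                correct += 1
        assert correct >= 495

    def test_pure_n_read_unannotatable(self, reference, aligner):
        with pytest.raises(AnnotationError):
            bc.assign_v("N" * 350, reference, aligner)

    def test_truncated_read_has_no_j(self, reference, aligner):
        v = reference.v_segments[0]
        seq = v.seq_nt[:200]  # ends inside V
        v_aln = bc.assign_v(seq, reference, aligner)
        with pytest.raises(AnnotationError):
            bc.assign_j(seq, reference, v_aln, aligner)


class TestCdr3:
    def test_planted_15mer(self, reference, aligner):
        seq = build_sequence(reference, cdr3="GCAGCAGCAGCAGCA")
        row = bc.annotate_sequence(seq, reference, aligner)
        assert row["cdr3"] == "GCAGCAGCAGCAGCA"
        assert len(row["cdr3_aa"]) == 5
        assert row["productive"]

    def test_out_of_frame_cdr3_flagged_nonproductive(self, reference, aligner):
        seq = build_sequence(reference, cdr3="GCAGCAGCAGCAGC")  # 14 nt
        row = bc.annotate_sequence(seq, reference, aligner)
        assert not row["productive"]

    def test_simulated_cdr3s_match_planted_truth(self, reference, aligner, small_sim):
        """Error-free simulated sequences: extracted CDR3 equals planted CDR3
        in >= 99.5% of rows (here: all of them)."""
        _, truth, table = small_sim
        planted = dict(zip(truth.per_sequence.sequence_id, truth.per_sequence.cdr3_nt))
        n_match = 0
        for row in table.df.itertuples(index=False):
            ann = bc.annotate_sequence(row.sequence, reference, aligner)
            n_match += ann["cdr3"] == planted[row.sequence_id]
        assert n_match / len(table.df) >= 0.995

    def test_cdr3_aa_is_translation(self, reference, aligner, small_sim):
        _, _, table = small_sim
        for seq in table.df["sequence"].head(40):
            row = bc.annotate_sequence(seq, reference, aligner)
            if row["productive"]:
                assert row["cdr3_aa"] == str(Seq(row["cdr3"]).translate())


class TestMutationFrequency:
    def test_germline_identical_read_is_zero(self, reference, aligner):
        seq = build_sequence(reference)
        row = bc.annotate_sequence(seq, reference, aligner)
        assert row["v_mutations"] == 0
        assert row["mutation_freq"] == 0.0
        assert row["v_eval_len"] == reference.v_segments[2].cys_anchor - 25

    def test_five_substitutions_exact_percentage(self, reference, aligner):
        rng = np.random.default_rng(5)
        seq = build_sequence(reference, v_idx=0)
        positions = 25 + rng.choice(
            reference.v_segments[0].cys_anchor - 25, size=5, replace=False
        )
        mutated = substitute(rng, seq, positions)
        n_mut, n_eval, freq = bc.mutation_frequency(
            mutated, bc.assign_v(mutated, reference, aligner), reference
        )
        assert (n_mut, n_eval) == (5, reference.v_segments[0].cys_anchor - 25)
        assert freq == pytest.approx(100 * 5 / n_eval)

    def test_primer_footprint_not_counted(self, reference, aligner):
        rng = np.random.default_rng(6)
        seq = build_sequence(reference, v_idx=1)
        mutated = substitute(rng, seq, [0, 5, 10, 24])  # all inside the mask
        n_mut, _, _ = bc.mutation_frequency(
            mutated, bc.assign_v(mutated, reference, aligner), reference
        )
        assert n_mut == 0

    def test_measured_equals_planted_on_clean_reads(self, reference, aligner, small_sim):
        _, truth, table = small_sim
        planted = dict(
            zip(truth.per_sequence.sequence_id, truth.per_sequence.n_eval_mutations)
        )
        for row in table.df.sample(60, random_state=0).itertuples(index=False):
            ann = bc.annotate_sequence(row.sequence, reference, aligner)
            assert ann["v_mutations"] == planted[row.sequence_id]

    def test_invariant_to_orientation(self, reference, aligner):
        from bcrclone.io import ReadRecord

        seq = build_sequence(reference, isotype="IGA")
        flipped = ReadRecord("r", bc.revcomp(seq), [37] * len(seq), "p")
        oriented, strand = bc.orient_sequence(flipped, reference)
        assert strand == "-"
        a = bc.annotate_sequence(seq, reference, aligner)
        b = bc.annotate_sequence(oriented.seq_nt, reference, aligner)
        assert a["mutation_freq"] == b["mutation_freq"]


class TestCollapseDuplicates:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["sequence_id", "population", "sequence", "duplicate_count"]
        )

    def test_identical_rows_merge_with_summed_count(self):
        df = self._frame(
            [("s1", "NP_ASC", "AAAA", 1), ("s2", "NP_ASC", "AAAA", 1), ("s3", "NP_ASC", "AAAA", 1)]
        )
        out = bc.collapse_duplicates(df)
        assert len(out) == 1
        assert out.loc[0, "duplicate_count"] == 3
        assert out.loc[0, "sequence_id"] == "s1"

    def test_same_sequence_different_population_not_merged(self):
        df = self._frame([("s1", "NP_ASC", "AAAA", 1), ("s2", "NP_IgD", "AAAA", 1)])
        assert len(bc.collapse_duplicates(df)) == 2

    def test_order_independence(self, rng):
        rows = [
            (f"s{i}", rng.choice(["a", "b"]), rng.choice(["AAAA", "CCCC", "GGGG"]), 1)
            for i in range(30)
        ]
        df = self._frame(rows)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        out1 = bc.collapse_duplicates(df).reset_index(drop=True)
        out2 = bc.collapse_duplicates(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(out1, out2)
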