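import random

import pytest

from transannot.blasttab import HitTable, Hsp
from transannot.rbh_annotator import (
    PredictorConfig,
    assign_orthology,
    evaluate_against_known,
    reverse_best_index,
)
from transannot import synthdata


def fwd_hsp(protein, transcript, p_start, p_end, evalue=1e-30, bitscore=300.0):
    """Forward (proteome→transcriptome) HSP: protein residues in the query."""
    return Hsp(
        query_id=protein,
        subject_id=transcript,
        pct_identity=90.0,
        aln_len=p_end - p_start + 1,
        mismatches=3,
        gap_opens=0,
        q_start=p_start,
        q_end=p_end,
        s_start=1,
        s_end=3 * (p_end - p_start + 1),
        evalue=evalue,
        bitscore=bitscore,
    )


def rev_hsp(transcript, protein, evalue=1e-30):
    return Hsp(
        query_id=transcript,
        subject_id=protein,
        pct_identity=90.0,
        aln_len=100,
        mismatches=3,
        gap_opens=0,
        q_start=1,
        q_end=300,
        s_start=1,
        s_end=100,
        evalue=evalue,
        bitscore=300.0,
    )


class TestReverseBestIndex:
    def test_best_subject_selected(self):
        table = HitTable(
            hsps=[rev_hsp("t1", "pA", 1e-30), rev_hsp("t1", "pB", 1e-10)]
        )
        assert reverse_best_index(table) == {"t1": "pA"}

    def test_insignificant_query_absent(self):
        table = HitTable(hsps=[rev_hsp("t2", "pA", 1e-3)])
        assert reverse_best_index(table) == {}

    def test_matches_generator_truth_at_zero_noise(self):
        truth = synthdata.generate_truth(200, seed=5)
        rev = synthdata.emulate_hits(truth, "reverse")
        index = reverse_best_index(rev)
        assert index == {
            t: p for t, (p, _cat) in truth.ortholog_pairs.items()
        }


class TestAssignOrthology:
    KINDS = {"t1": "isotig", "t2": "isotig", "t3": "singleton"}
    GROUPS = {"t1": "g1", "t2": "g1"}

    def _run(self, forward_rows, reverse_map, groups=None, kinds=None):
        return assign_orthology(
            HitTable(hsps=forward_rows, program="tblastn"),
            reverse_map,
            groups if groups is not None else self.GROUPS,
            kinds if kinds is not None else self.KINDS,
        )

    def test_disjoint_regions_both_orthologs(self):
        # residues 1–100 and 120–200 overlap by 0 ≤ 14
        rows = [
            fwd_hsp("P", "t1", 1, 100, evalue=1e-40),
            fwd_hsp("P", "t2", 120, 200, evalue=1e-30),
        ]
        table = self._run(rows, {"t1": "P", "t2": "P"})
        assert [(c.transcript_id, c.category) for c in table.calls] == [
            ("t1", "ortholog"),
            ("t2", "ortholog"),
        ]

    def test_overlap_boundary_14_vs_15(self):
        # overlap of exactly 14 residues stays ortholog; 15 flips the branch
        for overlap, expected in ((14, "ortholog"), (15, "isoform")):
            rows = [
                fwd_hsp("P", "t1", 1, 100, evalue=1e-40),
                fwd_hsp("P", "t2", 101 - overlap, 200, evalue=1e-30),
            ]
            table = self._run(rows, {"t1": "P", "t2": "P"})
            assert table.calls[1].category == expected, overlap

    def test_isoform_paralog_singleton_branches(self):
        rows = [
            fwd_hsp("P", "t1", 1, 150, evalue=1e-40),
            fwd_hsp("P", "t2", 100, 200, evalue=1e-30),  # overlap 51 > 14
        ]
        # same isogroup → isoform
        table = self._run(rows, {"t1": "P", "t2": "P"})
        assert table.calls[1].category == "isoform"
        # different isogroup → paralog
        table = self._run(
            rows, {"t1": "P", "t2": "P"}, groups={"t1": "g1", "t2": "g2"}
        )
        assert table.calls[1].category == "paralog"
        # singleton → isoform regardless of isogroup
        rows_singleton = [
            fwd_hsp("P", "t1", 1, 150, evalue=1e-40),
            fwd_hsp("P", "t3", 100, 200, evalue=1e-30),
        ]
        table = self._run(rows_singleton, {"t1": "P", "t3": "P"})
        assert table.calls[1].category == "isoform"

    def test_unconfirmed_candidate_skipped_not_discarded(self):
        # t1 reciprocally maps to Q, not P: skipped for P, accepted for Q
        rows = [
            fwd_hsp("P", "t1", 1, 100, evalue=1e-50),
            fwd_hsp("Q", "t1", 1, 100, evalue=1e-40),
        ]
        table = self._run(rows, {"t1": "Q"})
        assert [(c.transcript_id, c.protein_id) for c in table.calls] == [
            ("t1", "Q")
        ]

    def test_transcript_assigned_at_most_once(self):
        rows = [
            fwd_hsp("A", "t1", 1, 100),
            fwd_hsp("B", "t1", 1, 100),
        ]
        table = self._run(rows, {"t1": "A"})
        assert len(table.calls) == 1
        table.by_transcript()  # raises if any transcript appears twice

    def test_unknown_kind_is_an_error(self):
        rows = [fwd_hsp("P", "mystery", 1, 100)]
        with pytest.raises(ValueError, match="mystery"):
            self._run(rows, {})

    def test_row_permutation_invariance(self):
        truth = synthdata.generate_truth(80, seed=9)
        fwd = synthdata.emulate_hits(truth, "forward")
        rev = synthdata.emulate_hits(truth, "reverse")
        index = reverse_best_index(rev)
        base = assign_orthology(
            fwd, index, truth.isogroup_map, truth.kinds()
        )
        rng = random.Random(0)
        rows = list(fwd.hsps)
        for _ in range(3):
            rng.shuffle(rows)
            shuffled = assign_orthology(
                HitTable(hsps=list(rows), program="tblastn"),
                index,
                truth.isogroup_map,
                truth.kinds(),
            )
            assert shuffled.calls == base.calls

    def test_accepted_orthologs_pairwise_nonoverlapping(self, truth500, noise_free_tables):
        index = reverse_best_index(noise_free_tables["reverse"])
        table = assign_orthology(
            noise_free_tables["forward"],
            index,
            truth500.isogroup_map,
            truth500.kinds(),
        )
        for protein, calls in table.by_protein().items():
            orthologs = [c for c in calls if c.category == "ortholog"]
            for i, a in enumerate(orthologs):
                for b in orthologs[i + 1 :]:
                    lo = max(a.protein_interval[0], b.protein_interval[0])
                    hi = min(a.protein_interval[1], b.protein_interval[1])
                    assert hi - lo + 1 <= 14, (protein, a, b)

    def test_planted_triples_fully_recovered(self, truth500, noise_free_tables):
        index = reverse_best_index(noise_free_tables["reverse"])
        table = assign_orthology(
            noise_free_tables["forward"],
            index,
            truth500.isogroup_map,
            truth500.kinds(),
        )
        got = {
            c.transcript_id: (c.protein_id, c.category) for c in table.calls
        }
        assert got == truth500.ortholog_pairs

    def test_dropping_reverse_entries_loses_exactly_affected_pairs(self):
        truth = synthdata.generate_truth(
            150, isoform_rate=0.0, paralog_rate=0.0, region_split_rate=0.0,
            dup_rate=0.0, seed=21,
        )
        fwd = synthdata.emulate_hits(truth, "forward")
        rev = synthdata.emulate_hits(truth, "reverse")
        index = reverse_best_index(rev)
        dropped = dict(list(index.items())[::2])  # drop every other entry
        table = assign_orthology(
            fwd, dropped, truth.isogroup_map, truth.kinds()
        )
        recovered = {c.transcript_id for c in table.calls}
        assert recovered == set(dropped)


class TestEvaluateAgainstKnown:
    def _table_with(self, pairs):
        from transannot.rbh_annotator import AnnotationTable, OrthologyCall

        return AnnotationTable(
            calls=[
                OrthologyCall(t, p, "ortholog", (1, 100), 1e-30)
                for t, p in pairs.items()
            ]
        )

    def test_published_recovery_arithmetic(self):
        known = {f"t{i}": f"p{i}" for i in range(52)}
        matched = {f"t{i}": f"p{i}" for i in range(36)}
        report = evaluate_against_known(self._table_with(matched), known)
        assert report["n_known"] == 52
        assert report["n_recovered"] == 36
        assert report["fraction"] == pytest.approx(36 / 52)
        assert round(100 * report["fraction"], 1) == 69.2

    def test_empty_table_gives_zero(self):
        known = {"t1": "p1"}
        report = evaluate_against_known(self._table_with({}), known)
        assert report["fraction"] == 0

    def test_identity_gives_one(self):
        known = {f"t{i}": f"p{i}" for i in range(10)}
        report = evaluate_against_known(self._table_with(known), known)
        assert report["fraction"] == 1

    def test_wrong_protein_not_counted(self):
        known = {"t1": "p1"}
        report = evaluate_against_known(self._table_with({"t1": "pX"}), known)
        assert report["n_recovered"] == 0
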