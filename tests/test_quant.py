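import numpy as np
import pytest

from pamquant import (AmpliconRef, EditSpectrum, ErrorModel, call_edits,
                      classify_read, infer_cut_site, orient_and_align,
                      quantify_sample, simulate_amplicon_reads)
from pamquant.quant import EDITED_INDEL, UNEDITED, EditCall


def _ref_with_proto(strand):
    seq = list(np.random.default_rng(1).choice(list("ACGT"), size=240))
    if strand == "+":
        pam_start, pam_end = 96, 100
        seq[pam_start:pam_end] = list("TTTA")
    else:
        pam_start, pam_end = 123, 127
        seq[pam_start:pam_end] = list("TAAA")
    return AmpliconRef("r", "".join(seq), 100, 123, pam_start, pam_end, strand)


class TestInferCutSite:
    def test_plus_strand_offset18(self):
        assert infer_cut_site(_ref_with_proto("+"), 18) == 118

    def test_minus_strand_mirrored(self):
        assert infer_cut_site(_ref_with_proto("-"), 18) == 105

    def test_offset_beyond_protospacer_rejected(self):
        with pytest.raises(ValueError):
            infer_cut_site(_ref_with_proto("+"), 30)

    def test_offset_configurable(self):
        assert infer_cut_site(_ref_with_proto("+"), 23) == 123


class TestCallEdits:
    def _aln_with_ops(self, amplicon, ops):
        from pamquant.align import AlignmentResult
        return AlignmentResult("r1", "+", 0, ops=ops, ref_start=0,
                               ref_end=len(amplicon.sequence),
                               read_length=0)

    def test_deletion_spanning_cut_in_window(self, amplicon):
        cut = infer_cut_site(amplicon)
        aln = self._aln_with_ops(amplicon, [("deletion", 3, cut - 1)])
        calls = call_edits(aln, amplicon)
        assert len(calls) == 1 and calls[0].in_window
        assert calls[0].type == "deletion" and calls[0].length == 3

    def test_insertion_just_outside_window(self, amplicon):
        cut = infer_cut_site(amplicon)
        calls = call_edits(
            self._aln_with_ops(amplicon, [("insertion", 1, cut + 61)]),
            amplicon)
        assert len(calls) == 1 and not calls[0].in_window

    def test_insertion_on_window_edge_included(self, amplicon):
        cut = infer_cut_site(amplicon)
        calls = call_edits(
            self._aln_with_ops(amplicon, [("insertion", 1, cut + 60)]),
            amplicon)
        assert calls[0].in_window

    def test_deletion_poking_into_window_included(self, amplicon):
        cut = infer_cut_site(amplicon)
        # starts outside but its last base reaches cut+60
        calls = call_edits(
            self._aln_with_ops(amplicon, [("deletion", 5, cut + 60)]),
            amplicon)
        assert calls[0].in_window

    def test_mismatches_reported(self, amplicon):
        cut = infer_cut_site(amplicon)
        aln = self._aln_with_ops(amplicon, [
            ("mismatch", 1, cut - 5), ("match", 9, cut - 4),
            ("mismatch", 1, cut + 5)])
        calls = call_edits(aln, amplicon)
        assert [c.type for c in calls] == ["mismatch", "mismatch"]
        assert all(c.in_window for c in calls)


class TestClassifyRead:
    def test_one_inwindow_deletion_is_edited(self):
        assert classify_read([EditCall("deletion", 10, 13, 3, True)]) \
            == EDITED_INDEL

    def test_mismatches_alone_never_edited(self):
        calls = [EditCall("mismatch", i, i + 1, 1, True) for i in range(5)]
        assert classify_read(calls) == UNEDITED

    def test_out_of_window_insertion_unedited(self):
        assert classify_read([EditCall("insertion", 200, 200, 2, False)]) \
            == UNEDITED


def _mutate(seq, pos, rng):
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[int(rng.integers(0, 3))] + seq[pos + 1:]


class TestQuantifySample:
    def test_counting_example(self, amplicon):
        """10 anchor-passing reads: 3 in-window indels, 2 out-of-window
        indels, 5 unedited -> frequency 0.30."""
        seq = amplicon.sequence
        cut = infer_cut_site(amplicon)
        reads = []
        for i in range(3):  # in-window deletions at the cut
            reads.append((f"in{i}", seq[:cut] + seq[cut + 2 + i:]))
        far = cut + 70
        for i in range(2):  # indels > 60 bp downstream
            reads.append((f"out{i}", seq[:far] + seq[far + 3 + i:]))
        for i in range(5):
            reads.append((f"clean{i}", seq))
        res = quantify_sample(reads, amplicon, min_reads=5)
        assert res.total_reads == 10
        assert res.filtered_reads == 10
        assert res.indel_reads == 3
        assert res.indel_frequency == pytest.approx(0.30)
        assert not res.excluded

    def test_both_denominators_reported(self, amplicon, rng):
        seq = amplicon.sequence
        cut = infer_cut_site(amplicon)
        ruined = seq
        for p in range(0, 14, 2):  # 7 anchor mismatches -> filtered out
            ruined = _mutate(ruined, p, rng)
        reads = [("bad", ruined),
                 ("edit", seq[:cut] + seq[cut + 3:]),
                 ("clean", seq)]
        res = quantify_sample(reads, amplicon, min_reads=1)
        assert (res.total_reads, res.filtered_reads, res.indel_reads) == (3, 2, 1)
        assert res.indel_frequency == pytest.approx(1 / 2)
        assert res.indel_frequency_total == pytest.approx(1 / 3)

    def test_exclusion_rule_999(self, amplicon):
        reads = [(f"r{i}", amplicon.sequence) for i in range(999)]
        res = quantify_sample(reads, amplicon, collect_details=False)
        assert res.excluded
        res2 = quantify_sample(reads + [("r999", amplicon.sequence)],
                               amplicon, collect_details=False)
        assert not res2.excluded

    def test_zero_filtered_reads_reports_missing(self, amplicon, rng):
        ruined = amplicon.sequence
        for p in range(0, 16, 2):
            ruined = _mutate(ruined, p, rng)
        res = quantify_sample([("r0", ruined)], amplicon, min_reads=1)
        assert res.indel_frequency is None
        assert res.missing_reason

    def test_read_order_permutation_invariant(self, amplicon, rng):
        recs, _ = simulate_amplicon_reads(
            amplicon, 80, EditSpectrum(indel_rate=0.3),
            ErrorModel(substitution_rate=0.002), seed=3)
        reads = [(r, s) for r, s, _ in recs]
        res_a = quantify_sample(reads, amplicon, min_reads=1,
                                collect_details=False)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        res_b = quantify_sample(shuffled, amplicon, min_reads=1,
                                collect_details=False)
        assert res_a.indel_frequency == res_b.indel_frequency
        assert res_a.filtered_reads == res_b.filtered_reads

    def test_recovery_from_simulation(self, amplicon):
        rate, n = 0.2, 2000
        recs, truth = simulate_amplicon_reads(
            amplicon, n, EditSpectrum(indel_rate=rate, position_jitter=10),
            ErrorModel(substitution_rate=0.001), seed=11)
        res = quantify_sample(((r, s) for r, s, _ in recs), amplicon,
                              collect_details=False)
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(res.indel_frequency - rate) < 3 * se
        # and the pipeline agrees with the truth table almost exactly
        assert abs(res.indel_frequency - truth["edited"].mean()) < 0.01

    def test_window_specificity(self, amplicon):
        """All edits placed > 60 bp from the cut: frequency drops to the
        noise-off baseline of exactly 0."""
        spectrum = EditSpectrum(indel_rate=0.3, position_jitter=3,
                                center_offset=80)
        recs, truth = simulate_amplicon_reads(
            amplicon, 300, spectrum, ErrorModel(substitution_rate=0.0),
            seed=5)
        assert truth["edited"].mean() > 0.2  # edits exist, just far away
        res = quantify_sample(((r, s) for r, s, _ in recs), amplicon,
                              min_reads=1, collect_details=False)
        assert res.indel_frequency == 0.0
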