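"""MSA components: legality check, distance matrix, center choice, merge ledger."""

import random

import numpy as np
import pytest

from starmsa import (
    ContractViolationError,
    GapLedger,
    SequenceValidationError,
    align,
    brute_force_score,
    build_distance_matrix,
    check_sequences,
    finalize_msa,
    merge_sequence,
    select_center,
    sum_rows,
)
from starmsa.components import DistanceMatrix
from .conftest import random_dna


class TestCheckSequences:
    def test_valid_set_passes_unchanged(self, demo_seqs):
        assert check_sequences(demo_seqs) == demo_seqs

    def test_lowercase_upper_cased_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert check_sequences(["acgt", "ACGT"]) == ["ACGT", "ACGT"]
        assert any("lowercase" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seqs,msg", [
        ([], "too few"),
        (["ACGT"], "too few"),
        (["ACGT", ""], "empty sequence"),
        (["ACGX", "ACGT"], "invalid base"),
    ])
    def test_rejections(self, seqs, msg):
        with pytest.raises(SequenceValidationError, match=msg):
            check_sequences(seqs)

    def test_invalid_base_error_names_position(self):
        with pytest.raises(SequenceValidationError, match="position 3"):
            check_sequences(["ACGX", "ACGT"])


class TestDistanceMatrix:
    def test_worked_example_matrix(self, demo_seqs):
        dm = build_distance_matrix(demo_seqs)
        expect = np.array([[0, -1, -1], [-1, 0, -2], [-1, -2, 0]])
        assert np.array_equal(dm.dist, expect)
        assert sum_rows(dm) == [-2, -3, -3]

    def test_identical_pair_scores_full_match(self):
        dm = build_distance_matrix(["ACGT", "ACGT"])
        assert dm.dist[0, 1] == 4
        assert sum_rows(dm) == [4, 4]

    def test_matrix_symmetric_and_cells_match_oracle(self):
        rng = random.Random(3)
        seqs = [random_dna(rng, 6, 1) for _ in range(4)]
        dm = build_distance_matrix(seqs)
        assert np.array_equal(dm.dist, dm.dist.T)
        for i in range(4):
            for j in range(i + 1, 4):
                assert dm.dist[i, j] == brute_force_score(seqs[i], seqs[j])

    def test_tracebacks_cached_for_every_pair(self, demo_seqs):
        dm = build_distance_matrix(demo_seqs)
        assert set(dm.alignments) == {(0, 1), (0, 2), (1, 2)}
        assert dm.get_alignment(2, 0) is dm.get_alignment(0, 2)


class TestSelectCenter:
    def test_worked_example_selects_first_sequence(self, demo_seqs):
        assert select_center(build_distance_matrix(demo_seqs)).center_index == 0

    def test_tie_resolved_to_smallest_index(self):
        dm = DistanceMatrix(dist=np.zeros((2, 2), dtype=int),
                            row_sums=np.array([5, 5]), n_seqs=2)
        assert select_center(dm).center_index == 0

    def test_single_row_is_contract_violation(self):
        dm = DistanceMatrix(dist=np.zeros((1, 1), dtype=int),
                            row_sums=np.array([1]), n_seqs=1)
        with pytest.raises(ContractViolationError):
            select_center(dm)


class TestMergeLedger:
    def test_gapless_alignment_appends_row_verbatim(self):
        ledger = GapLedger(center="ACGT")
        merge_sequence(ledger, align("ACGT", "ACGT"), seq_index=1)
        assert ledger.master_center == "ACGT"
        assert ledger.rows == ["ACGT"]
        assert ledger.gap_log == [[]]

    def test_worked_example_merge_matches_hand_derivation(self, demo_seqs):
        """Merging s2 then s3 into center s1, executed by hand under the
        leave-blank-once-leave-blank-everywhere rule, gives master -CGCT-
        with rows GCG-T- and -C-CTG (frozen regression fixture)."""
        s1, s2, s3 = demo_seqs
        ledger = GapLedger(center=s1)
        merge_sequence(ledger, align(s1, s2), seq_index=1)
        assert (ledger.master_center, ledger.rows) == ("-CGCT", ["GCG-T"])
        merge_sequence(ledger, align(s1, s3), seq_index=2)
        assert ledger.master_center == "-CGCT-"
        assert ledger.rows == ["GCG-T-", "-C-CTG"]
        assert ledger.gap_log == [[0], [5]]

    def test_remerging_same_alignment_adds_no_new_master_gaps(self, demo_seqs):
        s1, s2, _ = demo_seqs
        pa = align(s1, s2)
        ledger = GapLedger(center=s1)
        merge_sequence(ledger, pa, seq_index=1)
        width = len(ledger.master_center)
        merge_sequence(ledger, pa, seq_index=1)
        assert len(ledger.master_center) == width
        assert ledger.gap_log[1] == []

    def test_foreign_center_rejected(self):
        ledger = GapLedger(center="ACGT")
        with pytest.raises(ContractViolationError):
            merge_sequence(ledger, align("TTTT", "ACGT"))

    def test_rows_and_master_stay_equal_length_at_every_step(self):
        rng = random.Random(11)
        center = random_dna(rng, 8, 4)
        ledger = GapLedger(center=center)
        for k in range(4):
            merge_sequence(ledger, align(center, random_dna(rng, 8, 1)), seq_index=k + 1)
            assert all(len(r) == len(ledger.master_center) for r in ledger.rows)
            assert ledger.master_center.replace("-", "") == center


class TestFinalize:
    def test_identical_pair_roundtrip(self):
        ledger = GapLedger(center="ACGT")
        merge_sequence(ledger, align("ACGT", "ACGT"), seq_index=1)
        res = finalize_msa(ledger, center_index=0, n_seqs=2)
        assert res.rows == ("ACGT", "ACGT") and res.width == 4

    def test_worked_example_rows_degap_to_inputs(self, demo_seqs):
        s1, s2, s3 = demo_seqs
        ledger = GapLedger(center=s1)
        merge_sequence(ledger, align(s1, s2), seq_index=1)
        merge_sequence(ledger, align(s1, s3), seq_index=2)
        res = finalize_msa(ledger, center_index=0, n_seqs=3)
        assert [r.replace("-", "") for r in res.rows] == demo_seqs
        assert not any(all(row[c] == "-" for row in res.rows) for c in range(res.width))

    def test_incomplete_ledger_rejected(self):
        ledger = GapLedger(center="ACGT")
        with pytest.raises(ContractViolationError):
            finalize_msa(ledger, center_index=0, n_seqs=3)
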