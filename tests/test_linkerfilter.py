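import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from chiapet.io_core import RawPETPair
from chiapet.linkerfilter import (LinkerFilterParams, align_linker,
                                  classify_long_pet, classify_short_pet,
                                  run_linker_filter)
from chiapet.synth import LINKER_A, LINKER_B, SynthConfig, generate_pet_library

TAG = "ACGTTGCAACGGTTAACCGG"  # 20 bp
Q36 = "I" * 36


def _pair(seq1, seq2):
    return RawPETPair("p", seq1, "I" * len(seq1), seq2, "I" * len(seq2))


def _sw_oracle():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


class TestAlignLinker:
    def test_exact_half_linker_scores_full_length(self):
        read = TAG + LINKER_A
        aln = align_linker(read, LINKER_A)
        assert aln.score == 16
        assert (aln.read_start, aln.read_end) == (20, 36)
        assert (aln.linker_start, aln.linker_end) == (0, 16)

    def test_all_n_read_scores_zero(self):
        assert align_linker("N" * 36, LINKER_A).score == 0

    def test_single_internal_mismatch(self):
        corrupted = LINKER_A[:8] + ("C" if LINKER_A[8] != "C" else "G") + LINKER_A[9:]
        read = TAG + corrupted
        ours = align_linker(read, LINKER_A).score
        oracle = _sw_oracle().score(read, LINKER_A)
        assert ours == oracle == 14

    @settings(max_examples=150, deadline=None)
    @given(read=st.text(alphabet="ACGT", min_size=5, max_size=60),
           linker=st.text(alphabet="ACGT", min_size=4, max_size=20))
    def test_score_matches_independent_aligner(self, read, linker):
        ours = align_linker(read, linker).score
        oracle = _sw_oracle().score(read, linker)
        assert ours == oracle

    def test_aligned_pairs_reconstruct_interval(self):
        aln = align_linker(TAG + LINKER_A, LINKER_A)
        reads = [rp for rp, _ in aln.pairs]
        assert reads == list(range(aln.read_start, aln.read_end))


class TestClassifyShort:
    def test_perfect_same_linker(self, linkers):
        tagged = classify_short_pet(_pair(TAG + LINKER_A, TAG + LINKER_A), linkers)
        assert tagged.pet_class == "same"
        assert (tagged.label1, tagged.label2) == ("A", "A")
        assert tagged.tag1 == TAG and len(tagged.tag1) == 20

    def test_different_linker(self, linkers):
        tagged = classify_short_pet(_pair(TAG + LINKER_A, TAG + LINKER_B), linkers)
        assert tagged.pet_class == "different"
        assert (tagged.label1, tagged.label2) == ("A", "B")

    def test_scrambled_linker_is_ambiguous(self, linkers):
        scrambled = TAG + "TTTTTTTTTTTTTTTT"
        tagged = classify_short_pet(_pair(TAG + LINKER_A, scrambled), linkers)
        assert tagged.pet_class == "ambiguous"

    def test_short_tag_not_retained(self, linkers):
        # 15-bp tag falls below the 18-bp minimum, so the PET is rejected
        read = TAG[:15] + LINKER_A + "AAAAA"
        tagged = classify_short_pet(_pair(read, TAG + LINKER_A), linkers)
        assert tagged.pet_class == "ambiguous"

    def test_barcode_mismatch_is_ambiguous(self, linkers):
        corrupted = LINKER_A[:5] + "G" + LINKER_A[6:]  # barcode TAAG -> GAAG
        tagged = classify_short_pet(_pair(TAG + corrupted, TAG + LINKER_A), linkers)
        assert tagged.pet_class == "ambiguous"

    def test_trimmed_tag_plus_linker_is_read_prefix(self, linkers):
        pair = _pair(TAG + LINKER_A, TAG + LINKER_B)
        tagged = classify_short_pet(pair, linkers)
        assert pair.seq1.startswith(tagged.tag1)
        assert pair.seq1[len(tagged.tag1):].startswith(LINKER_A)


class TestClassifyLong:
    def _cfg(self):
        return LinkerFilterParams(min_score=14)

    def test_bridge_plus_minus_retained(self, long_linkers):
        tag1, tag2 = "A" * 60, "C" * 70
        pair = _pair(tag1 + long_linkers.bridge_f + "G" * 21,
                     tag2 + long_linkers.bridge_r + "G" * 11)
        tagged = classify_long_pet(pair, long_linkers, self._cfg())
        assert tagged.pet_class == "same"
        assert (tagged.label1, tagged.label2) == ("A", "B")
        assert (len(tagged.tag1), len(tagged.tag2)) == (60, 70)

    def test_no_linker_on_either_read_excluded(self, long_linkers):
        pair = _pair("ACGT" * 25, "TGCA" * 25)
        tagged = classify_long_pet(pair, long_linkers, self._cfg())
        assert tagged.pet_class == "ambiguous"
        assert tagged.combo == "X_X"

    def test_one_sided_linker_retained(self, long_linkers):
        pair = _pair("A" * 60 + long_linkers.bridge_f + "G" * 21, "TGCA" * 25)
        tagged = classify_long_pet(pair, long_linkers, self._cfg())
        assert tagged.pet_class == "same"
        assert tagged.combo == "A_X"

    def test_both_plus_strand_chimeric(self, long_linkers):
        pair = _pair("A" * 60 + long_linkers.bridge_f + "G" * 21,
                     "C" * 60 + long_linkers.bridge_f + "G" * 21)
        tagged = classify_long_pet(pair, long_linkers, self._cfg())
        assert tagged.pet_class == "chimeric-excluded"


class TestRunLinkerFilter:
    def test_classes_match_generator_truth(self, read_library):
        pairs, truth, ctx = read_library
        retained, stats = run_linker_filter(pairs, ctx["linkers"])
        truth_counts = truth.linker_class.value_counts().to_dict()
        assert stats.combo_counts["A_A"] == truth_counts["A_A"]
        assert stats.combo_counts["B_B"] == truth_counts["B_B"]
        same = truth_counts["A_A"] + truth_counts["B_B"]
        assert stats.retained == same
        assert {t.pet_id for t in retained} == set(
            truth[truth.linker_class.isin(["A_A", "B_B"])].pet_id)

    def test_class_counts_partition_input(self, read_library):
        pairs, _, ctx = read_library
        _, stats = run_linker_filter(pairs, ctx["linkers"])
        assert sum(stats.class_counts.values()) == stats.total == len(pairs)

    def test_output_invariant_to_worker_count(self, read_library):
        pairs, _, ctx = read_library
        out = []
        for workers in (1, 4):
            params = LinkerFilterParams(workers=workers)
            retained, _ = run_linker_filter(pairs, ctx["linkers"], params)
            out.append([(t.pet_id, t.tag1, t.tag2, t.combo) for t in retained])
        assert out[0] == out[1]

    def test_table_like_mixture_reproduced_exactly(self):
        # deterministic classification: reported fractions equal the planted ones
        config = SynthConfig(seed=55, n_molecules=400, chrom_length=150_000)
        pairs, truth, ctx = generate_pet_library(config)
        _, stats = run_linker_filter(pairs, ctx["linkers"])
        for combo in ("A_A", "B_B"):
            assert stats.combo_counts[combo] == (truth.linker_class == combo).sum()
        ambiguous = stats.class_counts["ambiguous"]
        assert ambiguous == (truth.linker_class == "ambiguous").sum()
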