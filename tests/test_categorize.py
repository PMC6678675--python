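import numpy as np
import pytest

from chiapet.categorize import (categorize_pets, compute_span_distributions,
                                default_span_bins,
                                estimate_self_ligation_cutoff,
                                median_self_ligation_span, SpanDistributions,
                                DEFAULT_CUTOFF)
from chiapet.io_core import MappedPET
from chiapet.purify import merge_exact, merge_similar
from chiapet.synth import SynthConfig, generate_mapped_pets


def _pet(chrom1="chr1", fp1=1000, strand1="-", chrom2="chr1", fp2=1500,
         strand2="+", length=20):
    s1 = (fp1, fp1 + length) if strand1 == "+" else (fp1 - length, fp1)
    s2 = (fp2, fp2 + length) if strand2 == "+" else (fp2 - length, fp2)
    return MappedPET(chrom1, s1[0], s1[1], strand1, chrom2, s2[0], s2[1], strand2)


class TestSpanDistributions:
    def test_single_pet_lands_in_composition_histogram(self):
        pet = _pet(fp1=1000, strand1="-", fp2=1500, strand2="+")
        dists = compute_span_distributions([pet])
        assert dists.n == {"++": 0, "+-": 0, "-+": 1, "--": 0}
        edges = dists.bin_edges
        idx = np.searchsorted(edges, 500, side="right") - 1
        assert dists.counts["-+"][idx] == 1

    def test_inter_chromosomal_excluded(self):
        pet = _pet(chrom2="chr2")
        dists = compute_span_distributions([pet])
        assert sum(dists.n.values()) == 0

    def test_planted_minus_plus_excess_visible(self, coord_library):
        pets, _, _ = coord_library
        unique, _ = merge_exact(pets)
        dists = compute_span_distributions(unique)
        short = dists.bin_edges[:-1] < 5000
        mp_short = dists.counts["-+"][short].sum()
        other_short = np.mean([dists.counts[c][short].sum()
                               for c in ("++", "+-", "--")])
        assert mp_short > 3 * other_short  # self-ligation rides on -/+ only


class TestCutoffEstimator:
    def test_identical_histograms_fall_back(self):
        edges = default_span_bins()
        counts = np.ones(len(edges) - 1, dtype=int) * 10
        dists = SpanDistributions(edges, {c: counts.copy() for c in
                                          ("++", "+-", "-+", "--")},
                                  {c: int(counts.sum()) for c in
                                   ("++", "+-", "-+", "--")})
        assert estimate_self_ligation_cutoff(dists) == DEFAULT_CUTOFF

    def test_empty_distributions_warn_and_fall_back(self):
        edges = default_span_bins()
        zero = np.zeros(len(edges) - 1, dtype=int)
        dists = SpanDistributions(edges, {c: zero.copy() for c in
                                          ("++", "+-", "-+", "--")},
                                  {c: 0 for c in ("++", "+-", "-+", "--")})
        with pytest.warns(UserWarning):
            assert estimate_self_ligation_cutoff(dists) == DEFAULT_CUTOFF

    def test_planted_5kb_limit_recovered(self):
        edges = default_span_bins()
        true_bin = np.searchsorted(edges, 5000, side="right") - 1
        for seed in (201, 202, 203):
            config = SynthConfig(seed=seed, n_molecules=3000,
                                 self_span_kind="loguniform",
                                 self_span_low=100, self_span_high=5000)
            pets, _, _ = generate_mapped_pets(config)
            exact, _ = merge_exact(pets)
            unique, _ = merge_similar(exact)
            est = estimate_self_ligation_cutoff(compute_span_distributions(unique))
            est_bin = np.searchsorted(edges, est, side="right") - 1
            assert abs(est_bin - true_bin) <= 1


class TestCategorize:
    CUTOFF = 8000

    def test_self_ligation_signature(self):
        pet = _pet(fp1=10_000, strand1="-", fp2=15_000, strand2="+")
        result = categorize_pets([pet], self.CUTOFF)
        assert result.counts["self_ligation"] == 1

    def test_long_span_is_inter_ligation(self):
        pet = _pet(fp1=10_000, strand1="-", fp2=30_000, strand2="+")
        result = categorize_pets([pet], self.CUTOFF)
        assert result.counts["intra_inter"] == 1

    def test_different_chromosomes(self):
        result = categorize_pets([_pet(chrom2="chr2")], self.CUTOFF)
        assert result.counts["inter_chrom"] == 1

    def test_wrong_composition_short_span_is_other(self):
        pet = _pet(fp1=10_000, strand1="+", fp2=11_000, strand2="-")
        result = categorize_pets([pet], self.CUTOFF)
        assert result.counts["other"] == 1

    def test_partition_and_order_independence(self, coord_library):
        pets, _, _ = coord_library
        unique, _ = merge_exact(pets)
        res = categorize_pets(unique, self.CUTOFF)
        assert res.total == len(unique)
        reversed_res = categorize_pets(list(reversed(unique)), self.CUTOFF)
        assert res.counts == reversed_res.counts

    def test_truth_categories_recovered(self, coord_library):
        """Every purified PET is assigned its planted category (spans are
        planted below the cutoff for self/other, far above for inter)."""
        pets, truth, _ = coord_library
        exact, _ = merge_exact(pets)
        unique, _ = merge_similar(exact)
        res = categorize_pets(unique, self.CUTOFF)
        planted = truth.set_index("pet_id").category
        label_map = {"self": "self_ligation", "intra_inter": "intra_inter",
                     "inter_chrom": "inter_chrom", "other": "other"}
        for name, group in (("self_ligation", res.self_ligation),
                            ("intra_inter", res.intra_inter),
                            ("inter_chrom", res.inter_chrom),
                            ("other", res.other)):
            for pet in group:
                assert label_map[planted.loc[pet.pet_id]] == name


class TestMedianSpan:
    def test_median_of_planted_spans(self):
        pets = [_pet(fp1=1000, strand1="-", fp2=1000 + d, strand2="+")
                for d in (300, 500, 900)]
        assert median_self_ligation_span(pets) == 500

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_self_ligation_span([])
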