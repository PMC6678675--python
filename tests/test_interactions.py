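import itertools
import math

import numpy as np
import pytest

from chiapet.categorize import categorize_pets, median_self_ligation_span
from chiapet.interactions import (build_anchors, call_interactions,
                                  extend_tags, hypergeometric_pvalue)
from chiapet.io_core import GenomeInfo, MappedPET
from chiapet.purify import merge_exact, merge_similar
from chiapet.synth import SynthConfig, generate_mapped_pets


def _pet(chrom1, fp1, strand1, chrom2, fp2, strand2, length=20, pid="p"):
    s1 = (fp1, fp1 + length) if strand1 == "+" else (fp1 - length, fp1)
    s2 = (fp2, fp2 + length) if strand2 == "+" else (fp2 - length, fp2)
    return MappedPET(chrom1, s1[0], s1[1], strand1,
                     chrom2, s2[0], s2[1], strand2, pet_id=pid)


def hypergeom_enumeration(k, n_a, n_b, n_total):
    """Exhaustive upper-tail sum with exact integer binomials."""
    num = 0
    den = math.comb(n_total, n_b)
    for i in range(k, min(n_a, n_b) + 1):
        if n_b - i > n_total - n_a:
            continue
        num += math.comb(n_a, i) * math.comb(n_total - n_a, n_b - i)
    return num / den


class TestExtendTags:
    def test_plus_tag_extends_right(self):
        pet = _pet("chr1", 10_000, "+", "chr1", 30_000, "+")
        (w1, w2), = extend_tags([pet], 500)
        assert w1 == ("chr1", 10_000, 10_500)

    def test_minus_tag_extends_left(self):
        pet = _pet("chr1", 10_000, "-", "chr1", 30_000, "+")
        (w1, _), = extend_tags([pet], 500)
        assert w1 == ("chr1", 9_500, 10_000)

    def test_clipped_at_chromosome_end(self):
        genome = GenomeInfo({"chr1": 30_200})
        pet = _pet("chr1", 100, "+", "chr1", 30_000, "+")
        (_, w2), = extend_tags([pet], 500, genome)
        assert w2 == ("chr1", 30_000, 30_200)

    def test_auto_extension_equals_median_self_span(self, coord_library):
        pets, _, _ = coord_library
        unique, _ = merge_exact(pets)
        res = categorize_pets(unique, 8000)
        ext = median_self_ligation_span(res.self_ligation)
        assert abs(ext - 500) <= 50  # planted log-normal median 500 bp


class TestBuildAnchors:
    def test_overlapping_tags_merge(self):
        pets = [_pet("chr1", 100, "+", "chr1", 100_000, "+"),
                _pet("chr1", 550, "+", "chr1", 100_300, "+")]
        anchors, assignments = build_anchors(extend_tags(pets, 500))
        starts = [(a.start, a.end) for a in anchors]
        assert (100, 1050) in starts
        assert all(isinstance(a, tuple) for a in assignments)

    def test_both_tags_in_one_anchor_is_self_pair(self):
        pets = [_pet("chr1", 1000, "+", "chr1", 1200, "+")]
        _, assignments = build_anchors(extend_tags(pets, 500))
        assert assignments == ["self"]

    def test_anchor_tag_counts(self):
        pets = [_pet("chr1", 100, "+", "chr1", 100_000, "+") for _ in range(3)]
        anchors, _ = build_anchors(extend_tags(pets, 500))
        assert sorted(a.n_tags for a in anchors) == [3, 3]


class TestHypergeometric:
    def test_worked_example(self):
        assert hypergeometric_pvalue(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeometric_pvalue(0, 5, 4, 10) == 1.0

    def test_forced_overlap_is_certain(self):
        assert hypergeometric_pvalue(4, 10, 4, 10) == pytest.approx(1.0, rel=1e-12)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(2, 11, 5, 10)

    def test_matches_enumeration_small_universe(self):
        for n in range(2, 13):
            for n_a in range(1, n + 1):
                for n_b in range(1, n + 1):
                    for k in range(0, min(n_a, n_b) + 1):
                        want = hypergeom_enumeration(k, n_a, n_b, n)
                        got = hypergeometric_pvalue(k, n_a, n_b, n)
                        assert got == pytest.approx(want, rel=1e-12, abs=1e-300)


def bh_reference(pvals):
    """Step-up Benjamini–Hochberg written from the definition."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestBenjaminiHochberg:
    def test_matches_reference_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 80)))
            got = multipletests(p, method="fdr_bh")[1]
            want = bh_reference(p)
            np.testing.assert_allclose(got, want, rtol=1e-14, atol=0)


def _loop_library(seed):
    return SynthConfig(seed=seed, n_molecules=4000, chrom_length=1_000_000)


def _recover(config):
    pets, _, ctx = generate_mapped_pets(config)
    exact, _ = merge_exact(pets)
    unique, _ = merge_similar(exact)
    res = categorize_pets(unique, 8000)
    ext = median_self_ligation_span(res.self_ligation)
    clusters, significant, diag = call_interactions(
        res.intra_inter + res.inter_chrom, ext=ext, genome=ctx["genome_info"])
    return ctx, ext, clusters, significant, diag


def _loop_supported(cluster, sites, loops, radius):
    for ia, ib in loops:
        (chrom, pa), (_, pb) = sites[ia], sites[ib]
        if (cluster.anchor_a.chrom == chrom
                and cluster.anchor_a.start - radius <= pa <= cluster.anchor_a.end + radius
                and cluster.anchor_b.start - radius <= pb <= cluster.anchor_b.end + radius):
            return (ia, ib)
    return None


class TestCallInteractions:
    def test_planted_loops_recovered_without_false_pairs(self):
        ctx, ext, clusters, significant, _ = _recover(_loop_library(301))
        sites, loops = ctx["sites"], ctx["loops"]
        radius = 150 + ext
        found = {_loop_supported(c, sites, loops, radius) for c in significant}
        assert None not in found  # zero non-planted significant pairs
        assert len(found) == len(loops)  # every loop has significant support

    def test_every_pet_counted_once(self):
        ctx, _, clusters, _, diag = _recover(_loop_library(302))
        n_clustered = sum(c.count for c in clusters)
        assert n_clustered == diag["paired"]
        assert diag["dropped"] == 0

    def test_singletons_reported_but_untested(self):
        _, _, clusters, _, _ = _recover(_loop_library(303))
        singletons = [c for c in clusters if c.count == 1]
        assert singletons and all(c.pvalue is None for c in singletons)
        tested = [c for c in clusters if c.count >= 2]
        assert all(c.pvalue is not None and c.adjusted_p >= c.pvalue
                   for c in tested)

    def test_user_anchor_mode_equals_computed_on_same_regions(self):
        config = _loop_library(304)
        pets, _, ctx = generate_mapped_pets(config)
        exact, _ = merge_exact(pets)
        unique, _ = merge_similar(exact)
        res = categorize_pets(unique, 8000)
        inter = res.intra_inter + res.inter_chrom
        ext = median_self_ligation_span(res.self_ligation)
        anchors, _ = build_anchors(extend_tags(inter, ext, ctx["genome_info"]))
        computed = call_interactions(inter, ext=ext, genome=ctx["genome_info"])
        user = call_interactions(
            inter, ext=ext, genome=ctx["genome_info"],
            user_anchors=[(a.chrom, a.start, a.end) for a in anchors])
        key = lambda c: (c.anchor_a.chrom, c.anchor_a.start, c.anchor_b.chrom,
                         c.anchor_b.start, c.count)
        assert sorted(map(key, computed[0])) == sorted(map(key, user[0]))

    def test_shuffled_pairing_null_respects_fdr(self):
        """Random re-pairing of tags destroys loops; nothing should pass."""
        total_sig = 0
        for seed in (401, 402, 403):
            config = _loop_library(seed)
            pets, _, ctx = generate_mapped_pets(config)
            exact, _ = merge_exact(pets)
            unique, _ = merge_similar(exact)
            res = categorize_pets(unique, 8000)
            inter = res.intra_inter + res.inter_chrom
            rng = np.random.default_rng(seed)
            tags2 = [(p.chrom2, p.start2, p.end2, p.strand2) for p in inter]
            rng.shuffle(tags2)
            shuffled = []
            for p, t2 in zip(inter, tags2):
                try:
                    shuffled.append(MappedPET(p.chrom1, p.start1, p.end1,
                                              p.strand1, *t2).normalized())
                except ValueError:
                    continue
            _, significant, _ = call_interactions(
                shuffled, ext=500, genome=ctx["genome_info"])
            total_sig += len(significant)
        assert total_sig <= 1

    def test_cluster_spectrum_dominated_by_small_counts(self):
        _, _, clusters, significant, _ = _recover(_loop_library(305))
        tested = [c for c in clusters if c.count >= 2]
        spectrum = {}
        for c in tested:
            spectrum[c.count] = spectrum.get(c.count, 0) + 1
        assert spectrum.get(2, 0) > spectrum.get(3, 0) >= spectrum.get(4, 0)
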