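import pytest

from chiapet.io_core import GenomeInfo
from chiapet.linkerfilter import TaggedPET, run_linker_filter
from chiapet.mapping import (MULTI, UNMAPPED_TAG, MappingParams, ToyGenomeIndex,
                             extract_unique_pets, map_tagged_pets,
                             plan_alignment, reverse_complement, toy_map,
                             write_toy_sam)


def _fastq(path, reads):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


class TestPlanAlignment:
    def test_short_mode_uses_short_read_subcommand(self, tmp_path):
        fq1 = _fastq(tmp_path / "a.fq", ["ACGT" * 5] * 3)
        fq2 = _fastq(tmp_path / "b.fq", ["ACGT" * 5] * 3)
        plan = plan_alignment(fq1, fq2, MappingParams(
            genome_index="idx", engine="external-short"))
        assert plan.subcommand == "aln"
        assert any("bwa aln idx" in c for c in plan.commands)
        assert any("samse" in c for c in plan.commands)

    def test_long_reads_use_mem(self, tmp_path):
        fq1 = _fastq(tmp_path / "a.fq", ["A" * 120] * 3)
        fq2 = _fastq(tmp_path / "b.fq", ["C" * 120] * 3)
        plan = plan_alignment(fq1, fq2, MappingParams(
            genome_index="idx", engine="external-long"))
        assert plan.subcommand == "mem"

    def test_long_short_tags_use_aln(self, tmp_path):
        fq1 = _fastq(tmp_path / "a.fq", ["A" * 30] * 3)
        fq2 = _fastq(tmp_path / "b.fq", ["C" * 30] * 3)
        plan = plan_alignment(fq1, fq2, MappingParams(
            genome_index="idx", engine="external-long"))
        assert plan.subcommand == "aln"

    def test_dry_run_launches_nothing(self, tmp_path):
        fq1 = _fastq(tmp_path / "a.fq", ["ACGT" * 9])
        fq2 = _fastq(tmp_path / "b.fq", ["ACGT" * 9])
        plan = plan_alignment(fq1, fq2, MappingParams(
            genome_index="no_such_index", engine="external-short"), dry_run=True)
        assert not list(tmp_path.glob("*.sam"))
        assert plan.text().count("bwa") == 4

    def test_missing_index_fails_before_launch(self, tmp_path):
        fq1 = _fastq(tmp_path / "a.fq", ["ACGT" * 9])
        fq2 = _fastq(tmp_path / "b.fq", ["ACGT" * 9])
        with pytest.raises(FileNotFoundError):
            plan_alignment(fq1, fq2, MappingParams(
                genome_index=str(tmp_path / "missing"), engine="external-short"),
                dry_run=False)


class TestToyMap:
    GENOME = {
        "chr1": "ACGTACCTGGATCGATTACGGATCCGGAATTCCAAGGTTCGCGCGTATATACCGGTT",
        "chr2": "TTGGCCAATTGGCCAATTGGCCAATTGGCCAA",
    }

    def test_unique_plus_strand(self):
        tag = self.GENOME["chr1"][5:25]
        aln = toy_map(tag, self.GENOME)
        assert (aln.chrom, aln.start, aln.end, aln.strand) == ("chr1", 5, 25, "+")
        assert aln.mapq == 60

    def test_reverse_complement_maps_minus(self):
        tag = reverse_complement(self.GENOME["chr1"][5:25])
        aln = toy_map(tag, self.GENOME)
        assert (aln.chrom, aln.start, aln.end, aln.strand) == ("chr1", 5, 25, "-")

    def test_repeat_is_multi(self):
        assert toy_map("TTGGCCAATTGGCCAA", self.GENOME) == MULTI

    def test_absent_tag_unmapped(self):
        assert toy_map("A" * 30, self.GENOME) == UNMAPPED_TAG

    def test_index_matches_direct_scan(self):
        index = ToyGenomeIndex(self.GENOME)
        tag = self.GENOME["chr1"][10:30]
        assert index.occurrences(tag) == [("chr1", 10)]


class TestExtractUnique:
    def _sam(self, tmp_path, mapq2):
        text = ("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
                f"r1\t65\tchr1\t101\t60\t20M\t*\t0\t0\t{'A' * 20}\t*\n"
                f"r1\t129\tchr1\t301\t{mapq2}\t20M\t*\t0\t0\t{'C' * 20}\t*\n")
        path = tmp_path / "t.sam"
        path.write_text(text)
        return path

    def test_high_quality_pair_retained(self, tmp_path):
        pets, counts = extract_unique_pets(self._sam(tmp_path, 60), 30)
        assert counts == {"total": 1, "both_unique": 1}
        assert pets[0].start1 == 100 and pets[0].start2 == 300

    def test_low_mapq_mate_dropped(self, tmp_path):
        pets, counts = extract_unique_pets(self._sam(tmp_path, 12), 30)
        assert pets == [] and counts["both_unique"] == 0

    def test_retention_monotone_in_cutoff(self, tmp_path):
        path = self._sam(tmp_path, 40)
        kept = [len(extract_unique_pets(path, c)[0]) for c in (0, 30, 50, 70)]
        assert kept == sorted(kept, reverse=True)


class TestSyntheticRecovery:
    def test_coordinates_recovered_exactly(self, read_library):
        pairs, truth, ctx = read_library
        retained, _ = run_linker_filter(pairs, ctx["linkers"])
        pets, counts = map_tagged_pets(retained, ctx["genome"])
        assert counts["both_unique"] == counts["total"]  # no repeats planted
        tr = truth.set_index("pet_id")
        for pet in pets:
            row = tr.loc[pet.pet_id]
            want = sorted([(row.chrom1, row.start1, row.end1, row.strand1),
                           (row.chrom2, row.start2, row.end2, row.strand2)])
            got = sorted([(pet.chrom1, pet.start1, pet.end1, pet.strand1),
                          (pet.chrom2, pet.start2, pet.end2, pet.strand2)])
            assert want == got

    def test_toy_sam_round_trip(self, read_library, tmp_path):
        """SAM written by the toy mapper re-reads to the same MappedPETs."""
        pairs, _, ctx = read_library
        retained, _ = run_linker_filter(pairs, ctx["linkers"])
        retained = retained[:200]
        direct, _ = map_tagged_pets(retained, ctx["genome"])
        sam_path = tmp_path / "toy.sam"
        write_toy_sam(retained, ctx["genome"], ctx["genome_info"], sam_path)
        via_sam, _ = extract_unique_pets(sam_path, 30)
        key = lambda p: (p.chrom1, p.start1, p.end1, p.strand1,
                         p.chrom2, p.start2, p.end2, p.strand2, p.pet_id)
        assert sorted(map(key, via_sam)) == sorted(map(key, direct))

    def test_planted_repeats_become_multi(self):
        from chiapet.synth import SynthConfig, generate_pet_library

        config = SynthConfig(seed=77, n_molecules=300, chrom_length=150_000,
                             repeat_fraction=0.02, multi_fraction=0.15)
        pairs, truth, ctx = generate_pet_library(config)
        retained, _ = run_linker_filter(pairs, ctx["linkers"])
        _, counts = map_tagged_pets(retained, ctx["genome"])
        same = truth[truth.linker_class.isin(["A_A", "B_B"])]
        planted_multi = (same.site_id == -2).sum()
        assert counts["multi"] >= planted_multi > 0
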