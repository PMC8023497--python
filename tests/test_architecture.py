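import random

import pytest

from mitoarch import architecture as arch
from mitoarch.model import AnnotationError, GeneFeature, Mitogenome
from mitoarch.synthetic import SynthSpec, synth_genome

from oracles import hairpin_oracle


def _gap_map(genome):
    return {(r.upstream, r.downstream): r.gap for r in arch.intergenic_gaps(genome)}


class TestIntergenicGaps:
    def test_reference_examples(self, reference):
        gaps = _gap_map(reference)
        assert gaps[("cox1", "trnL2")] == 8
        assert gaps[("trnE", "trnS2")] == -16
        # circular wrap: the spacer before cox1 computes to 274, not the
        # published 273 — only 274 closes the conservation identity
        assert gaps[("trnF", "cox1")] == 274

    def test_record_count_is_circular(self, reference):
        assert len(arch.intergenic_gaps(reference)) == len(reference.features)

    def test_overlap_census(self, reference):
        gaps = arch.intergenic_gaps(reference)
        assert sum(1 for r in gaps if r.gap < 0) == 8
        big = arch.largest_overlap(reference)
        assert (big.upstream, big.downstream, big.gap) == ("trnE", "trnS2", -16)

    def test_conservation_identity(self, reference):
        assert arch.conservation_check(reference) == 17064

    def test_rotation_changes_no_gap(self, reference):
        base = {frozenset((r.upstream, r.downstream)): r.gap
                for r in arch.intergenic_gaps(reference)}
        for offset in (1, 2845, 11127, 17000):
            rot = reference.rotated(offset)
            rotated = {frozenset((r.upstream, r.downstream)): r.gap
                       for r in arch.intergenic_gaps(rot)}
            assert rotated == base
            assert arch.conservation_check(rot) == rot.length

    def test_triple_overlap_rejected(self):
        feats = [
            GeneFeature("a", "PCG", "+", 1, 100),
            GeneFeature("b", "tRNA", "+", 50, 60),
            GeneFeature("c", "tRNA", "+", 70, 200),
        ]
        g = Mitogenome("bad", 300, features=feats)
        with pytest.raises(AnnotationError, match="triple overlap"):
            arch.intergenic_gaps(g)


class TestNoncodingRegions:
    def test_reference_census(self, reference):
        nrs = arch.noncoding_regions(reference)
        assert len(nrs) == 25
        assert max(r[2] for r in nrs) == 1371

    def test_control_region_location(self, reference):
        start, end, length = arch.locate_control_region(reference)
        assert (start, end, length) == (11128, 12498, 1371)
        # flanked by nad2 (ends 11127) and trnK (starts 12499)
        assert reference.feature("nad2").end == start - 1
        assert reference.feature("trnK").start == end + 1

    def test_two_abutting_features_cover_circle(self):
        g = Mitogenome(
            "full", 100,
            features=[
                GeneFeature("a", "PCG", "+", 1, 60),
                GeneFeature("b", "PCG", "+", 61, 100),
            ],
        )
        assert arch.noncoding_regions(g) == []
        with pytest.raises(AnnotationError):
            arch.locate_control_region(g)

    def test_tie_breaks_to_lowest_start(self):
        g = Mitogenome(
            "tie", 100,
            features=[
                GeneFeature("a", "PCG", "+", 1, 20),
                GeneFeature("b", "PCG", "+", 31, 50),  # gap 21..30
                GeneFeature("c", "PCG", "+", 61, 100),  # gap 51..60
            ],
        )
        assert arch.locate_control_region(g) == (21, 30, 10)

    def test_single_gap(self):
        g = Mitogenome(
            "one", 100,
            features=[
                GeneFeature("a", "PCG", "+", 1, 40),
                GeneFeature("b", "PCG", "+", 51, 100),
            ],
        )
        assert arch.noncoding_regions(g) == [(41, 50, 10)]
        assert arch.locate_control_region(g) == (41, 50, 10)


class TestTerminalCodons:
    def _genome(self, coding, strand="+"):
        from mitoarch.model import reverse_complement

        insert = coding if strand == "+" else reverse_complement(coding)
        seq = insert + "C" * 10
        return Mitogenome(
            "t", len(seq), sequence=seq,
            features=[GeneFeature("nad3", "PCG", strand, 1, len(coding))],
        )

    def test_complete_stop(self):
        tc = arch.terminal_codons(self._genome("ATGAAATAA"))["nad3"]
        assert (tc.start_codon, tc.stop_codon, tc.incomplete) == ("ATG", "TAA", False)

    def test_incomplete_stop_t(self):
        tc = arch.terminal_codons(self._genome("ATGAAACCCT"))["nad3"]
        assert tc.stop_codon == "T(AA)" and tc.incomplete

    def test_incomplete_stop_ta(self):
        tc = arch.terminal_codons(self._genome("ATGAAACCCTA"))["nad3"]
        assert tc.stop_codon == "TA(A)" and tc.incomplete

    def test_light_strand_uses_coding_strand(self):
        tc = arch.terminal_codons(self._genome("ATAAAATAG", strand="-"))["nad3"]
        assert (tc.start_codon, tc.stop_codon) == ("ATA", "TAG")

    def test_too_short_pcg_raises(self):
        with pytest.raises(AnnotationError, match="shorter"):
            arch.terminal_codons(self._genome("ATGAA"))

    def test_synthetic_round_trip(self):
        g = synth_genome(SynthSpec(seed=13))
        for label, tc in arch.terminal_codons(g).items():
            assert tc.start_codon in ("ATG", "ATA", "ATT"), label
            if not tc.incomplete:
                assert tc.stop_codon in ("TAA", "TAG"), label
            else:
                assert tc.stop_codon in ("T(AA)", "TA(A)"), label


class TestFindHairpin:
    def test_perfect_palindrome(self):
        hp = arch.find_hairpin("ACGT", min_stem=2, min_loop=0)
        assert (hp.stem_pairs, hp.loop_len) == (2, 0)

    def test_no_complementarity(self):
        assert arch.find_hairpin("AAAAAAAA", min_stem=2, min_loop=0) is None

    def test_arms_are_reverse_complementary(self):
        from mitoarch.model import reverse_complement

        hp = arch.find_hairpin("GGGCCAAAATGGCCC", min_stem=3, min_loop=3)
        assert hp is not None
        assert reverse_complement(hp.arms[0]) == hp.arms[1]
        assert 2 * hp.stem_pairs + hp.loop_len <= hp.span[1] - hp.span[0] + 1

    @pytest.mark.parametrize("allow_gu", [False, True])
    def test_matches_oracle_on_random_sequences(self, allow_gu):
        rng = random.Random(99)
        for trial in range(60):
            n = rng.randint(12, 40)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            got = arch.find_hairpin(seq, min_stem=3, min_loop=3, max_loop=15,
                                    allow_gu=allow_gu)
            want = hairpin_oracle(seq, min_stem=3, min_loop=3, max_loop=15,
                                  allow_gu=allow_gu)
            if want is None:
                assert got is None, seq
            else:
                assert got is not None, seq
                assert (got.stem_pairs, got.loop_len, got.span[0]) == want, seq

    def test_planted_hairpin_recovered(self):
        g = synth_genome(SynthSpec(seed=17, hairpin=(9, 16)))
        start, end, _ = arch.locate_control_region(g)
        hp = arch.find_hairpin(g.subsequence(start, end))
        assert hp is not None and hp.stem_pairs >= 9


class TestReport:
    def test_report_summary_lines(self, reference):
        text = arch.architecture_report(reference)
        assert "# noncoding_regions=25" in text
        assert "# overlaps=8" in text
        assert "# largest_overlap=16\tbetween=trnE,trnS2" in text
        assert "# control_region=11128..12498\tcr_length=1371" in text
        assert "# conservation_check=17064\tcloses=True" in text
        assert text.count("\n") == 36 + 7  # rows + summary/header lines
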