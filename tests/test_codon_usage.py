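import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoarch import codon_usage as cu
from mitoarch.composition import round_half_away
from mitoarch.model import GeneFeature, Mitogenome
from mitoarch.synthetic import SynthSpec, synth_genome

from oracles import rscu_oracle


class TestGeneticCodeFamilies:
    def test_invertebrate_mito_reassignments(self):
        fams = cu.genetic_code_families(5)
        assert "UGA" in fams["W"] and len(fams["W"]) == 2
        assert set(fams["S"]) >= {"AGA", "AGG", "UCU", "AGU"}
        assert len(fams["S"]) == 8
        assert len(fams["L"]) == 6
        assert "AUA" in fams["M"]
        assert set(fams["*"]) == {"UAA", "UAG"}

    def test_families_partition_the_64_codons(self):
        fams = cu.genetic_code_families(5)
        seen = [c for codons in fams.values() for c in codons]
        assert sorted(seen) == sorted(cu.ALL_CODONS)

    def test_split_families(self):
        fams = cu.split_families(5)
        assert set(fams["Leu1"]) == {"CUU", "CUC", "CUA", "CUG"}
        assert set(fams["Leu2"]) == {"UUA", "UUG"}
        assert set(fams["Ser1"]) == {"AGU", "AGC", "AGA", "AGG"}
        assert set(fams["Ser2"]) == {"UCU", "UCC", "UCA", "UCG"}


class TestCodonCountTable:
    def test_from_counts_accepts_dna_alphabet(self):
        t = cu.CodonCountTable.from_counts({"TTT": 3, "UUU": 2})
        assert t.counts["UUU"] == 5 and t.total == 5

    def test_rejects_bad_codon(self):
        with pytest.raises(ValueError, match="not a codon"):
            cu.CodonCountTable.from_counts({"XYZ": 1})


class TestRscu:
    def test_leucine_family(self):
        t = cu.CodonCountTable.from_counts(
            {"UUA": 270, "UUG": 192, "CUU": 99, "CUC": 18, "CUA": 47, "CUG": 32}
        )
        values = cu.rscu(t).rounded(2)
        assert values["UUA"] == 2.46

    def test_serine_eight_codon_family(self):
        t = cu.CodonCountTable.from_counts(
            {"UCU": 121, "UCC": 38, "UCA": 45, "UCG": 26,
             "AGU": 110, "AGC": 38, "AGA": 100, "AGG": 111}
        )
        assert cu.rscu(t).rounded(2)["UCU"] == 1.64

    def test_tryptophan_family_code5(self):
        t = cu.CodonCountTable.from_counts({"UGA": 86, "UGG": 128})
        assert cu.rscu(t).rounded(2)["UGA"] == 0.80

    def test_equal_counts_give_unity(self):
        t = cu.CodonCountTable.from_counts({c: 7 for c in cu.ALL_CODONS})
        values = cu.rscu(t).rscu
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_zero_family_is_missing(self):
        t = cu.CodonCountTable.from_counts({"UUU": 5})
        values = cu.rscu(t).rscu
        assert values["GGG"] is None and values["UUU"] == pytest.approx(2.0)

    @given(factor=st.integers(2, 50))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_uniform_scaling(self, codon_counts, factor):
        base = cu.rscu(codon_counts).rscu
        scaled = cu.rscu(codon_counts.scaled(factor)).rscu
        for c in cu.ALL_CODONS:
            assert scaled[c] == pytest.approx(base[c])

    def test_family_sums_equal_family_sizes(self, codon_counts):
        values = cu.rscu(codon_counts).rscu
        for aa, codons in codon_counts.families.items():
            total = sum(values[c] for c in codons)
            assert total == pytest.approx(len(codons)), aa

    def test_matches_family_oracle(self, codon_counts):
        fams = codon_counts.families
        by_family = {
            aa: {c: codon_counts.counts[c] for c in codons}
            for aa, codons in fams.items()
        }
        want = rscu_oracle(by_family)
        got = cu.rscu(codon_counts).rscu
        for c in cu.ALL_CODONS:
            assert got[c] == pytest.approx(want[c])

    def test_whole_published_table_regression(self, codon_counts, codon_table_df):
        """Recomputing every published RSCU from its published count matches
        the printed 2-decimal value for all 64 codons."""
        got = cu.rscu(codon_counts).rounded(2)
        for codon, printed in zip(codon_table_df.codon, codon_table_df.rscu):
            assert got[codon] == pytest.approx(printed, abs=5e-3), codon


class TestAminoAcidComposition:
    def test_published_percentages(self, codon_counts):
        aa = cu.amino_acid_composition(codon_counts)
        assert round_half_away(aa["Phe"], 2) == 11.66
        assert round_half_away(aa["Gly"], 2) == 8.64

    def test_split_families_reported_separately(self, codon_counts):
        aa = cu.amino_acid_composition(codon_counts)
        assert {"Leu1", "Leu2", "Ser1", "Ser2"} <= set(aa)
        assert "Leu" not in aa and "Ser" not in aa

    def test_percentages_sum_to_100(self, codon_counts):
        assert sum(cu.amino_acid_composition(codon_counts).values()) == pytest.approx(100.0)

    def test_single_codon_table(self):
        t = cu.CodonCountTable.from_counts({"UUU": 10})
        assert cu.amino_acid_composition(t)["Phe"] == 100.0

    def test_stop_exclusion_changes_denominator(self, codon_counts):
        with_stops = cu.amino_acid_composition(codon_counts, exclude_stops=False)
        assert "*" in with_stops
        without = cu.amino_acid_composition(codon_counts)
        assert without["Phe"] > with_stops["Phe"]

    def test_empty_table_raises(self):
        t = cu.CodonCountTable.from_counts({})
        with pytest.raises(ValueError):
            cu.amino_acid_composition(t)


class TestExtractCodons:
    def _genome(self, coding):
        seq = coding + "G" * 9
        return Mitogenome(
            "t", len(seq), sequence=seq,
            features=[GeneFeature("nad3", "PCG", "+", 1, len(coding))],
        )

    def test_simple_stream(self):
        assert cu.extract_codons(self._genome("ATGAAATAA"))["nad3"] == [
            "AUG", "AAA", "UAA"
        ]

    def test_incomplete_stop_trimmed(self):
        streams = cu.extract_codons(self._genome("ATGAAACCCT"))
        assert streams["nad3"] == ["AUG", "AAA", "CCC"]

    def test_synthetic_stream_recovered(self):
        """Counting a generated genome equals the histogram of its streams."""
        g = synth_genome(SynthSpec(seed=23))
        streams = cu.extract_codons(g)
        assert set(streams) == {f.label for f in g.features_of("PCG")}
        t = cu.CodonCountTable.from_genome(g)
        flat = [c for s in streams.values() for c in s]
        assert t.total == len(flat)
        assert t.counts["AUG"] == flat.count("AUG")


class TestCodonReport:
    def test_64_rows_and_columns(self, codon_counts):
        df = cu.codon_report(codon_counts)
        assert len(df) == 64
        assert list(df.columns) == ["codon", "amino_acid", "count", "rscu"]
        assert df["count"].sum() == codon_counts.total

    def test_empty_counts(self):
        df = cu.codon_report(cu.CodonCountTable.from_counts({}))
        assert len(df) == 64
        assert (df["count"] == 0).all()
        assert df.rscu.isna().all()

    def test_round_trip_tsv(self, codon_counts, tmp_path):
        p = cu.write_codon_report(codon_counts, tmp_path / "codons.tsv")
        back = cu.read_codon_counts(p)
        assert back.counts == codon_counts.counts
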