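import random

import pytest

from mitoarch import gene_order as go
from mitoarch.model import PCG, RRNA, TRNA
from mitoarch.synthetic import permute_order

from oracles import breakpoint_oracle, shared_blocks_oracle

HIATELLIDAE = tuple("nad3 nad1 nad5 nad6 cytb rrnL atp6 rrnS cox3".split())
SOLENIDAE = tuple("nad3 nad1 nad6 nad5 cytb rrnL atp6 rrnS cox3".split())


def order(labels, circular=False, signs=None):
    return go.GeneOrder(
        labels=tuple(labels),
        signs=tuple(signs) if signs else (),
        circular=circular,
    )


class TestLinearize:
    def test_full_complement_starts_at_cox1(self, reference):
        o = go.linearize(reference)
        assert len(o) == 36
        assert o.labels[:7] == ("cox1", "trnL2", "nad1", "trnL1", "trnV", "trnN", "nad5")
        assert all(s == 1 for s in o.signs)  # all genes on the heavy strand

    def test_trna_exclusion(self, reference):
        o = go.linearize(reference, include={PCG, RRNA})
        assert len(o) == 14
        assert o.labels[:7] == ("cox1", "nad1", "nad5", "cytb", "nad6", "rrnL", "atp6")

    def test_missing_start_gene_lists_available(self, reference):
        with pytest.raises(KeyError, match="atp8"):
            go.linearize(reference, start_gene="atp8")

    def test_single_gene_genome(self):
        from mitoarch.model import GeneFeature, Mitogenome

        g = Mitogenome("m", 100, features=[GeneFeature("cox1", "PCG", "+", 1, 90)])
        assert go.linearize(g).labels == ("cox1",)


class TestSharedBlocks:
    def test_identical_orders_one_full_block(self):
        a = order("abcdef", circular=True)
        blocks = go.shared_blocks(a, a.rotated(2))
        assert len(blocks) == 1
        assert blocks[0].length == 6

    def test_published_family_comparison(self):
        """Hiatellidae vs Solenidae PCG+rRNA strings: two conserved blocks,
        with nad5/nad6 swapped between them falling in neither."""
        blocks = go.shared_blocks(order(HIATELLIDAE), order(SOLENIDAE))
        gene_sets = sorted(b.genes for b in blocks)
        assert gene_sets == [
            ("cytb", "rrnL", "atp6", "rrnS", "cox3"),
            ("nad3", "nad1"),
        ]
        covered = {g for b in blocks for g in b.genes}
        assert "nad5" not in covered and "nad6" not in covered

    def test_breakpoint_of_published_pair(self):
        assert go.breakpoint_distance(order(HIATELLIDAE), order(SOLENIDAE)) == 2

    def test_disjoint_label_sets_empty(self):
        assert go.shared_blocks(order("abc"), order("xyz")) == []

    def test_unequal_label_sets_restricted_to_common(self):
        # atp8 present only in b; blocks computed on the common set
        a = order(["cox1", "cox2", "nad1"])
        b = order(["cox1", "cox2", "atp8", "nad1"])
        blocks = go.shared_blocks(a, b)
        assert [b_.genes for b_ in blocks] == [("cox1", "cox2", "nad1")]

    def test_symmetry(self):
        rng = random.Random(5)
        labels = list("abcdefgh")
        for _ in range(20):
            pa, pb = labels[:], labels[:]
            rng.shuffle(pa)
            rng.shuffle(pb)
            ab = {b.genes for b in go.shared_blocks(order(pa), order(pb))}
            ba = {b.genes for b in go.shared_blocks(order(pb), order(pa))}
            assert ab == ba

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(41)
        for trial in range(50):
            n = rng.randint(3, 10)
            labels = [f"g{i}" for i in range(n)]
            pa, pb = labels[:], labels[:]
            rng.shuffle(pa)
            rng.shuffle(pb)
            got = sorted(
                b.genes for b in go.shared_blocks(order(pa), order(pb))
            )
            want = sorted(shared_blocks_oracle(pa, pb))
            assert got == want, (pa, pb)

    def test_signed_reversed_block(self):
        a = order("abcd", signs=[1, 1, 1, 1])
        b = order(["a", "c", "b", "d"], signs=[1, -1, -1, 1])
        blocks = go.shared_blocks(a, b, signed=True)
        rev = [blk for blk in blocks if blk.orientation == "reversed"]
        assert len(rev) == 1 and rev[0].genes == ("b", "c")
        # unsigned mode must not count the reversed block
        unsigned = go.shared_blocks(a, order(["a", "c", "b", "d"]))
        assert all(blk.orientation == "same" for blk in unsigned)
        assert ("b", "c") not in {blk.genes for blk in unsigned}

    def test_rotation_invariance_circular(self):
        a = order("abcdefg", circular=True)
        b = permute_order(a, 1, seed=3)
        base = {blk.genes for blk in go.shared_blocks(a, b)}
        for k in range(1, 7):
            rot = {blk.genes for blk in go.shared_blocks(a.rotated(k), b)}
            # block contents are rotation-invariant up to the cyclic cut
            assert {g for blk in rot for g in blk} == {g for blk in base for g in blk}
            assert go.breakpoint_distance(a.rotated(k), b) == go.breakpoint_distance(a, b)


class TestConservedFragments:
    def test_identical_orders(self):
        a = order("abcdef", circular=True)
        frags = go.conserved_fragments([a, a.rotated(1), a.rotated(3)])
        assert len(frags) == 1 and frags[0].length == 6

    def test_constructed_conserved_segment(self):
        """A 3-gene segment untouched by each genome's rearrangement is
        recovered as a conserved fragment."""
        ref = tuple("abcxyzpqr")
        v1 = tuple("xyzabcpqr")  # move abc after xyz; pqr intact
        v2 = tuple("abcpqrxyz")  # move xyz to the end; pqr intact
        frags = go.conserved_fragments(
            [order(ref), order(v1), order(v2)], min_len=2
        )
        assert ("p", "q", "r") in {f.genes for f in frags}
        for f in frags:
            for other in (v1, v2):
                s = "".join(other)
                assert "".join(f.genes) in s

    def test_no_common_adjacency(self):
        a = order("abcd")
        b = order("acbd")
        c = order("adbc")
        assert go.conserved_fragments([a, b, c]) == []


class TestBreakpointDistance:
    def test_identical_zero(self):
        a = order("abcdef", circular=True)
        assert go.breakpoint_distance(a, a) == 0
        assert go.breakpoint_distance(a, a.rotated(4)) == 0

    def test_unequal_label_sets_error(self):
        with pytest.raises(ValueError, match="label sets differ"):
            go.breakpoint_distance(order("abc"), order("abd"))

    def test_matches_oracle(self):
        rng = random.Random(7)
        for trial in range(100):
            n = rng.randint(2, 8)
            labels = [f"g{i}" for i in range(n)]
            pa, pb = labels[:], labels[:]
            rng.shuffle(pa)
            rng.shuffle(pb)
            circular = trial % 2 == 0
            got = go.breakpoint_distance(
                order(pa, circular=circular), order(pb, circular=circular)
            )
            assert got == breakpoint_oracle(pa, pb, circular=circular), (pa, pb)

    def test_bounded_by_three_per_transposition(self):
        base = order([f"g{i}" for i in range(12)], circular=True)
        for k in (1, 2, 3):
            for seed in range(10):
                moved = permute_order(base, k, seed=seed)
                assert go.breakpoint_distance(base, moved) <= 3 * k


class TestOrderFiles:
    def test_round_trip(self, tmp_path):
        a = order(["cox1", "nad2", "rrnS"], signs=[1, -1, 1], circular=True)
        b = order("abc", circular=True)
        p = go.write_orders([a, b], tmp_path / "orders.tsv")
        back = go.read_orders(p)
        assert back[0].labels == a.labels and back[0].signs == a.signs
        assert back[1].labels == b.labels
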