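"""Gene-order extraction and rearrangement comparison.

A mitogenome's gene order is its sequence of gene labels around the
circle, optionally signed by strand. Because every label occurs once,
two orders can be compared through their adjacencies: maximal runs of
genes that are contiguous in both orders are *shared blocks* (conserved
synteny fragments), and the number of adjacencies of one order missing
from the other is the *breakpoint distance* (0 for identical circular
orders up to rotation).

The default comparison is unsigned — appropriate for taxa whose genes
all sit on the heavy strand — and then a block only counts when it runs
in the same direction in both orders. In signed mode a block appearing
reversed with flipped signs also counts, flagged orientation="reversed".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import CATEGORIES, GeneFeature, Mitogenome


@dataclass(frozen=True)
class GeneOrder:
    """An ordered tuple of unique gene labels with per-gene orientation."""

    labels: tuple[str, ...]
    signs: tuple[int, ...] = ()
    circular: bool = True
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty gene order")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValueError(f"duplicate labels in gene order: {dupes}")
        if not self.signs:
            object.__setattr__(self, "signs", tuple(1 for _ in self.labels))
        if len(self.signs) != len(self.labels):
            raise ValueError("signs and labels differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    def rotated(self, k: int) -> "GeneOrder":
        """Start the circular order ``k`` positions later."""
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        k %= len(self.labels)
        return replace(
            self,
            labels=self.labels[k:] + self.labels[:k],
            signs=self.signs[k:] + self.signs[:k],
        )

    def restricted(self, keep: Iterable[str]) -> "GeneOrder":
        """Drop labels not in ``keep``, preserving relative order."""
        keep = set(keep)
        pairs = [(l, s) for l, s in zip(self.labels, self.signs) if l in keep]
        if not pairs:
            raise ValueError("restriction removes every label")
        return replace(
            self,
            labels=tuple(l for l, _ in pairs),
            signs=tuple(s for _, s in pairs),
        )

    def adjacencies(self, signed: bool = False) -> set:
        """Canonical adjacency set: n pairs for circular, n-1 for linear.

        Unsigned adjacencies are unordered label pairs; signed adjacencies
        are canonicalized so that reading the molecule from the other
        strand gives the same set.
        """
        n = len(self.labels)
        out = set()
        last = n if self.circular else n - 1
        for i in range(last):
            x, y = self.labels[i], self.labels[(i + 1) % n]
            if signed:
                sx, sy = self.signs[i], self.signs[(i + 1) % n]
                fwd = (x, sx, y, sy)
                rev = (y, -sy, x, -sx)
                out.add(min(fwd, rev))
            else:
                out.add(frozenset((x, y)))
        return out


@dataclass(frozen=True)
class SharedBlock:
    """A maximal run of genes contiguous (and co-oriented) in two orders."""

    genes: tuple[str, ...]
    pos_a: int
    pos_b: int
    orientation: str  # "same" | "reversed"

    @property
    def length(self) -> int:
        return len(self.genes)


def linearize(
    genome: Mitogenome,
    start_gene: str = "cox1",
    include: Optional[Iterable[str]] = None,
) -> GeneOrder:
    """Read the gene order off an annotated genome, rotated to ``start_gene``.

    ``include`` restricts to a set of feature categories (e.g. exclude the
    tRNAs and compare by protein-coding and rRNA genes only).
    """
    cats = set(include) if include is not None else set(CATEGORIES)
    feats = [f for f in genome.features if f.category in cats]
    labels = tuple(f.label for f in feats)
    signs = tuple(1 if f.strand == "+" else -1 for f in feats)
    order = GeneOrder(
        labels=labels, signs=signs, circular=genome.circular, source=genome.identifier
    )
    if start_gene not in labels:
        raise KeyError(
            f"{genome.identifier}: start gene {start_gene!r} not present; "
            f"available: {', '.join(labels)}"
        )
    if genome.circular:
        order = order.rotated(labels.index(start_gene))
    return order


# ---------------------------------------------------------------------------
# Shared blocks


def shared_blocks(
    a: GeneOrder, b: GeneOrder, min_len: int = 2, signed: bool = False
) -> list[SharedBlock]:
    """All maximal common contiguous blocks of length >= min_len.

    Orders over unequal label sets are first restricted to their common
    labels (contiguity is then contiguity-after-restriction, the usual
    convention when e.g. tRNAs are ignored); disjoint label sets give an
    empty list. Blocks are returned sorted by (length desc, position in
    ``a`` asc). Circular wrap is honoured when both orders are circular;
    two circular orders that are plain rotations of one another yield one
    full-length block.
    """
    common = set(a.labels) & set(b.labels)
    if not common:
        return []
    ra = a.restricted(common) if set(a.labels) != common else a
    rb = b.restricted(common) if set(b.labels) != common else b

    # index positions in the original (unrestricted) orders for reporting
    pos_in_a = {l: i for i, l in enumerate(a.labels)}
    pos_in_b = {l: i for i, l in enumerate(b.labels)}

    n, m = len(ra), len(rb)
    posb = {l: i for i, l in enumerate(rb.labels)}
    signa = dict(zip(ra.labels, ra.signs))
    signb = dict(zip(rb.labels, rb.signs))

    def fwd_preserved(x: str, y: str) -> bool:
        ix, iy = posb[x], posb[y]
        nxt = (ix + 1) % m if rb.circular else ix + 1
        if nxt != iy or (not rb.circular and ix + 1 >= m):
            return False
        if signed and (signa[x] != signb[x] or signa[y] != signb[y]):
            return False
        return True

    def rev_preserved(x: str, y: str) -> bool:
        if not signed:
            return False
        ix, iy = posb[x], posb[y]
        nxt = (iy + 1) % m if rb.circular else iy + 1
        if nxt != ix or (not rb.circular and iy + 1 >= m):
            return False
        return signa[x] == -signb[x] and signa[y] == -signb[y]

    blocks: list[SharedBlock] = []
    for orientation, preserved in (("same", fwd_preserved), ("reversed", rev_preserved)):
        if orientation == "reversed" and not signed:
            continue
        adj_last = n if (ra.circular and rb.circular) else n - 1
        ok = [
            preserved(ra.labels[i], ra.labels[(i + 1) % n]) for i in range(adj_last)
        ]
        if adj_last == n and all(ok):
            anchor = ra.labels[0] if orientation == "same" else ra.labels[-1]
            blocks.append(
                SharedBlock(
                    genes=ra.labels,
                    pos_a=pos_in_a[ra.labels[0]],
                    pos_b=pos_in_b[anchor],
                    orientation=orientation,
                )
            )
            continue
        blocks.extend(
            _runs_to_blocks(ra, ok, adj_last, orientation, pos_in_a, pos_in_b)
        )
    blocks = [blk for blk in blocks if blk.length >= min_len]
    blocks.sort(key=lambda blk: (-blk.length, blk.pos_a, blk.orientation))
    return blocks


def _runs_to_blocks(ra, ok, adj_last, orientation, pos_in_a, pos_in_b):
    """Maximal runs of preserved adjacencies -> blocks."""
    n = len(ra)
    circular_scan = adj_last == n
    # run starts: adjacency i preserved while its predecessor is not
    starts = []
    for i in range(adj_last):
        prev = (i - 1) % n if circular_scan else i - 1
        prev_ok = ok[prev] if (circular_scan or prev >= 0) else False
        if ok[i] and not prev_ok:
            starts.append(i)
    out = []
    for s in starts:
        length = 1
        while length < n:
            nxt = s + length
            if circular_scan:
                nxt %= n
            elif nxt >= adj_last:
                break
            if not ok[nxt]:
                break
            length += 1
        genes = tuple(ra.labels[(s + t) % n] for t in range(length + 1))
        out.append(
            SharedBlock(
                genes=genes,
                pos_a=pos_in_a[genes[0]],
                pos_b=pos_in_b[genes[0] if orientation == "same" else genes[-1]],
                orientation=orientation,
            )
        )
    return out


def conserved_fragments(
    orders: Sequence[GeneOrder], min_len: int = 2, signed: bool = False
) -> list[SharedBlock]:
    """Maximal blocks present contiguously in *every* order.

    Computed by intersecting, over all non-reference orders, the set of
    reference adjacencies each one preserves; within a run the orientation
    must be consistent per order (a fragment cannot be half-forward,
    half-reversed in any single genome).
    """
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    ref = orders[0]
    common = set(ref.labels)
    for o in orders[1:]:
        common &= set(o.labels)
    if len(common) < min_len:
        return []
    ra = ref.restricted(common) if set(ref.labels) != common else ref
    n = len(ra)
    circular_all = all(o.circular for o in orders)
    adj_last = n if circular_all else n - 1

    # orientation of each reference adjacency in each other order:
    # "same", "reversed", or None
    states = []
    for o in orders[1:]:
        ro = o.restricted(common) if set(o.labels) != common else o
        m = len(ro)
        posb = {l: i for i, l in enumerate(ro.labels)}
        signb = dict(zip(ro.labels, ro.signs))
        signa = dict(zip(ra.labels, ra.signs))
        st = []
        for i in range(adj_last):
            x, y = ra.labels[i], ra.labels[(i + 1) % n]
            ix, iy = posb[x], posb[y]
            fwd = ((ix + 1) % m if ro.circular else ix + 1) == iy and (
                ro.circular or ix + 1 < m
            )
            rev = ((iy + 1) % m if ro.circular else iy + 1) == ix and (
                ro.circular or iy + 1 < m
            )
            if signed:
                fwd = fwd and signa[x] == signb[x] and signa[y] == signb[y]
                rev = rev and signa[x] == -signb[x] and signa[y] == -signb[y]
            else:
                rev = False
            st.append("same" if fwd else ("reversed" if rev else None))
        states.append(st)

    ok = [all(st[i] is not None for st in states) for i in range(adj_last)]

    def compatible(run_start: int, length: int) -> bool:
        # orientation constant within the run, for every order
        for st in states:
            vals = {st[(run_start + t) % n if adj_last == n else run_start + t]
                    for t in range(length)}
            if len(vals) > 1:
                return False
        return True

    if adj_last == n and all(ok) and compatible(0, n):
        return [SharedBlock(genes=ra.labels, pos_a=0, pos_b=0, orientation="same")]

    pos_in_ref = {l: i for i, l in enumerate(ref.labels)}
    out = []
    circular_scan = adj_last == n
    starts = []
    for i in range(adj_last):
        prev = (i - 1) % n if circular_scan else i - 1
        prev_ok = ok[prev] if (circular_scan or prev >= 0) else False
        if ok[i] and not prev_ok:
            starts.append(i)
    for s in starts:
        length = 1
        while True:
            nxt = (s + length) % n if circular_scan else s + length
            if (s + length < adj_last or circular_scan) and ok[nxt] and length < n:
                length += 1
            else:
                break
        # shrink from the right until orientation-consistent everywhere
        while length >= 1 and not compatible(s, length):
            length -= 1
        if length < 1:
            continue
        genes = tuple(ra.labels[(s + t) % n] for t in range(length + 1))
        if len(genes) >= min_len:
            out.append(
                SharedBlock(
                    genes=genes, pos_a=pos_in_ref[genes[0]], pos_b=-1, orientation="same"
                )
            )
    out.sort(key=lambda blk: (-blk.length, blk.pos_a))
    return out


# ---------------------------------------------------------------------------
# Breakpoint distance


def breakpoint_distance(a: GeneOrder, b: GeneOrder, signed: bool = False) -> int:
    """Number of adjacencies of ``a`` absent from ``b``.

    Requires identical label sets (restrict first when comparing taxa with
    unequal gene content). Zero iff the circular orders are rotations of
    one another (up to whole-molecule reflection, which unsigned circular
    adjacencies cannot distinguish).
    """
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        only_a, only_b = sorted(sa - sb), sorted(sb - sa)
        raise ValueError(
            f"label sets differ: only in a: {only_a or '-'}; only in b: {only_b or '-'}"
        )
    return len(a.adjacencies(signed=signed) - b.adjacencies(signed=signed))


# ---------------------------------------------------------------------------
# Order-file I/O: one genome per line, "id<TAB>gene1,gene2,-gene3,..."


def read_orders(path: Union[str, Path], circular: bool = True) -> list[GeneOrder]:
    orders = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ident, _, genes = line.partition("\t")
        if not genes:
            raise ValueError(f"{path}: malformed line {line!r}")
        labels, signs = [], []
        for token in genes.split(","):
            token = token.strip()
            if token.startswith("-"):
                labels.append(token[1:])
                signs.append(-1)
            else:
                labels.append(token)
                signs.append(1)
        orders.append(
            GeneOrder(
                labels=tuple(labels), signs=tuple(signs),
                circular=circular, source=ident,
            )
        )
    return orders


def write_orders(orders: Sequence[GeneOrder], path: Union[str, Path]) -> Path:
    p = Path(path)
    lines = []
    for o in orders:
        genes = ",".join(
            ("-" if s < 0 else "") + l for l, s in zip(o.labels, o.signs)
        )
        lines.append(f"{o.source or 'order'}\t{genes}")
    p.write_text("\n".join(lines) + "\n")
    return p
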