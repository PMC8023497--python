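"""Circular genome architecture: spacers, overlaps, control region,
terminal codons, and stem-loop (hairpin) detection.

The gap after gene *i* is ``start(i+1) - end(i) - 1`` with the downstream
start lifted by the genome length on the wrap-around adjacency. Positive
gaps are intergenic spacers (noncoding regions), negative gaps are
overlaps of neighbouring genes, zero means abutting. Over a fully
annotated circular genome the identity

    sum(feature lengths) + sum(signed gaps) == genome length

always closes exactly; it is the principal self-check of an annotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

from .model import PCG, AnnotationError, GeneFeature, Mitogenome, reverse_complement


@dataclass(frozen=True)
class GapRecord:
    """Signed spacing between two consecutive features on the circle."""

    upstream: str
    downstream: str
    gap: int


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop: ``stem_pairs`` paired bases closing a ``loop_len`` loop.

    ``span`` is the (start, end) of the whole element within the query,
    1-based inclusive; ``arms`` are the two paired substrings (5' arm in
    reading direction, 3' arm as written in the query).
    """

    stem_pairs: int
    loop_len: int
    span: tuple[int, int]
    arms: tuple[str, str]


# ---------------------------------------------------------------------------
# Gap accounting


def intergenic_gaps(genome: Mitogenome) -> list[GapRecord]:
    """One signed gap per adjacency; N features give N records on a circle
    (N - 1 on a linear molecule).

    Only pairwise-consecutive overlaps are supported: a feature reaching
    past the *next* feature's end (a triple overlap) raises.
    """
    feats = genome.features
    if not feats:
        raise AnnotationError(f"{genome.identifier}: no features")
    L = genome.length
    records = []
    n = len(feats)

    def lifted_end(f: GeneFeature) -> int:
        # a feature wrapping the origin ends at end + L on the unrolled circle
        return f.end + L if f.wraps else f.end

    last = n if genome.circular else n - 1
    for i in range(last):
        cur, nxt = feats[i], feats[(i + 1) % n]
        nxt_start = nxt.start + L if i == n - 1 else nxt.start
        gap = nxt_start - lifted_end(cur) - 1
        records.append(GapRecord(upstream=cur.label, downstream=nxt.label, gap=gap))
        if i + 2 < n or (genome.circular and n > 2):
            after = feats[(i + 2) % n]
            after_start = after.start + L if i + 2 >= n else after.start
            if after_start <= lifted_end(cur):
                raise AnnotationError(
                    f"{genome.identifier}: triple overlap around "
                    f"{cur.label}/{nxt.label}/{after.label}"
                )
    return records


def conservation_check(genome: Mitogenome) -> int:
    """sum(feature lengths) + sum(signed gaps); equals the genome length
    on any consistent circular annotation."""
    total = sum(f.length(genome.length) for f in genome.features)
    total += sum(r.gap for r in intergenic_gaps(genome))
    return total


def noncoding_regions(genome: Mitogenome) -> list[tuple[int, int, int]]:
    """Intervals (start, end, length) of every strictly positive gap.

    Coordinates are 1-based inclusive; an interval crossing the origin has
    end < start.
    """
    feats = genome.features
    L = genome.length
    out = []
    n = len(feats)
    for i, rec in enumerate(intergenic_gaps(genome)):
        if rec.gap <= 0:
            continue
        cur, nxt = feats[i], feats[(i + 1) % n]
        start = cur.end % L + 1
        end = (nxt.start - 2) % L + 1
        out.append((start, end, rec.gap))
    return out


def locate_control_region(genome: Mitogenome) -> tuple[int, int, int]:
    """The largest noncoding interval (start, end, length); the putative
    control region. Ties break to the lowest start."""
    regions = noncoding_regions(genome)
    if not regions:
        raise AnnotationError(f"{genome.identifier}: no noncoding positions")
    return max(regions, key=lambda r: (r[2], -r[0]))


def largest_overlap(genome: Mitogenome) -> Optional[GapRecord]:
    """The most negative gap, or None when no genes overlap."""
    overlaps = [r for r in intergenic_gaps(genome) if r.gap < 0]
    if not overlaps:
        return None
    return min(overlaps, key=lambda r: r.gap)


# ---------------------------------------------------------------------------
# Terminal codons


@dataclass(frozen=True)
class TerminalCodons:
    start_codon: str
    stop_codon: str
    incomplete: bool


def terminal_codons(genome: Mitogenome) -> dict[str, TerminalCodons]:
    """Start and stop codons of every protein-coding gene.

    The start codon is the first triplet of the coding strand. A gene whose
    length is a multiple of 3 ends in a complete stop; a trailing T (length
    mod 3 == 1) or TA (mod 3 == 2) is an incomplete stop completed to TAA
    by polyadenylation, reported as "T(AA)" / "TA(A)".
    """
    out = {}
    for f in genome.features_of(PCG):
        seq = genome.feature_sequence(f)
        if len(seq) < 6:
            raise AnnotationError(f"{genome.identifier}: PCG {f.label} shorter than 6 nt")
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            out[f.label] = TerminalCodons(start, seq[-3:], incomplete=False)
        elif rem == 1 and seq.endswith("T"):
            out[f.label] = TerminalCodons(start, "T(AA)", incomplete=True)
        elif rem == 2 and seq.endswith("TA"):
            out[f.label] = TerminalCodons(start, "TA(A)", incomplete=True)
        else:
            out[f.label] = TerminalCodons(start, seq[-rem:] + "?", incomplete=True)
    return out


# ---------------------------------------------------------------------------
# Hairpin (stem-loop) search

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in _WC or (allow_gu and (x, y) in _GU)


def find_hairpin(
    seq: str,
    min_stem: int = 6,
    min_loop: int = 3,
    max_loop: int = 30,
    allow_gu: bool = False,
) -> Optional[Hairpin]:
    """Exhaustive combinatorial stem-loop search (no thermodynamics).

    Every placement of a hairpin — outermost pair at positions (i, j),
    stem extended inward while bases pair — is scored; the hairpin with
    the most stem pairs wins, ties broken by smaller loop, then by 5'-most
    position. Pairing is Watson-Crick, with wobble G.T admitted when
    ``allow_gu``. Returns None when no placement satisfies the thresholds.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    best: Optional[Hairpin] = None
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            span = j - i + 1
            # deepest stem allowed before the loop would shrink below min_loop
            p_cap = (span - min_loop) // 2
            p = 0
            while p < p_cap and _pairs(s[i + p], s[j - p], allow_gu):
                p += 1
            loop = span - 2 * p
            if p < min_stem or loop > max_loop:
                continue
            cand = Hairpin(
                stem_pairs=p,
                loop_len=loop,
                span=(i + 1, j + 1),
                arms=(s[i : i + p], s[j - p + 1 : j + 1]),
            )
            if best is None or _better(cand, best):
                best = cand
    return best


def _better(a: Hairpin, b: Hairpin) -> bool:
    ka = (a.stem_pairs, -a.loop_len, -a.span[0], -a.span[1])
    kb = (b.stem_pairs, -b.loop_len, -b.span[0], -b.span[1])
    return ka > kb


# ---------------------------------------------------------------------------
# Report


def architecture_report(genome: Mitogenome) -> str:
    """TSV report: per-gene rows plus a '#'-prefixed summary block."""
    gaps = intergenic_gaps(genome)
    gap_after = {r.upstream: r.gap for r in gaps}
    codons: dict[str, TerminalCodons] = {}
    if genome.sequence is not None:
        codons = terminal_codons(genome)

    nrs = noncoding_regions(genome)
    overlaps = [r for r in gaps if r.gap < 0]
    lines = [
        f"# genome={genome.identifier}\tlength={genome.length}",
        f"# noncoding_regions={len(nrs)}\tnoncoding_total_bp={sum(r[2] for r in nrs)}",
        f"# overlaps={len(overlaps)}",
    ]
    big = largest_overlap(genome)
    if big is not None:
        lines.append(
            f"# largest_overlap={-big.gap}\tbetween={big.upstream},{big.downstream}"
        )
    try:
        cr = locate_control_region(genome)
        lines.append(f"# control_region={cr[0]}..{cr[1]}\tcr_length={cr[2]}")
    except AnnotationError:
        pass
    check = conservation_check(genome)
    lines.append(f"# conservation_check={check}\tcloses={check == genome.length}")
    lines.append("gene\tstart\tend\tlength\tstart_codon\tstop_codon\tgap_after")
    for f in genome.features:
        tc = codons.get(f.label)
        lines.append(
            "\t".join(
                [
                    f.label,
                    str(f.start),
                    str(f.end),
                    str(f.length(genome.length)),
                    tc.start_codon if tc else "",
                    tc.stop_codon if tc else "",
                    str(gap_after.get(f.label, "")),
                ]
            )
        )
    return "\n".join(lines) + "\n"
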