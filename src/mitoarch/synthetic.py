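"""Seeded generator of annotated circular mitogenomes.

The generator emulates the architecture of a bivalve-style mitogenome —
a ~17 kb circle tiled by protein-coding genes, tRNAs, rRNAs, short
spacers, occasional small overlaps, and one large control region hiding
a stem-loop — with controlled base composition, strand skews and codon
usage, so that every analysis stage of the package can be tested without
real data. All randomness flows from a single integer seed through one
numpy Generator; generation order is fixed, so outputs are reproducible.

Defaults mirror the reference genome this package ships: the 36-gene
complement and gene sizes of the *S. minima* annotation, ~17 kb, A+T 66.4%
with AT-skew -0.235 and GC-skew 0.367, a 1,371 bp control region, and
overlaps only at tRNA-adjacent junctions, capped at 20 bp (the largest
observed is 16 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_usage import ALL_CODONS, genetic_code_families
from .gene_order import GeneOrder
from .model import (
    OTHER_NONCODING,
    PCG,
    RRNA,
    TRNA,
    GeneFeature,
    Mitogenome,
    classify_label,
    reverse_complement,
)

START_CODONS = ("ATG", "ATA", "ATT")
STOP_CODONS = ("TAA", "TAG")


class InfeasibleSpec(ValueError):
    """The requested genome cannot be laid out (e.g. genes exceed length)."""


def _default_gene_lengths() -> dict[str, int]:
    from .fixtures import reference_annotation  # deferred: fixtures import io

    ref = reference_annotation()
    return {f.label: f.length(ref.length) for f in ref.features}


def _default_gene_order() -> tuple[str, ...]:
    from .fixtures import reference_annotation

    return tuple(f.label for f in reference_annotation().features)


@dataclass
class SynthSpec:
    """Parameters of one synthetic genome.

    ``genome_length`` is an approximate target: gene lengths and the
    control region are laid out first and the remaining budget is spread
    over the spacers, so the realized length matches the target exactly
    unless rounding in the spacer draw moves it by a few nucleotides.
    Skews are dimensionless in (-1, 1); ``at_pct`` in (0, 100).
    """

    seed: int = 0
    genome_length: int = 17_000
    gene_set: Optional[Sequence[str]] = None  # default: the 36-gene complement
    gene_lengths: Optional[dict[str, int]] = None
    k_block_moves: int = 0
    at_pct: float = 66.4
    at_skew: float = -0.235
    gc_skew: float = 0.367
    codon_weights: Optional[dict[str, float]] = None
    cr_length: int = 1371
    cr_after: Optional[str] = "nad2"
    hairpin: tuple[int, int] = (10, 14)  # (stem pairs, loop nt)
    overlap_prob: float = 0.2
    max_overlap: int = 20
    light_strand_genes: frozenset[str] = frozenset()

    def base_probs(self) -> dict[str, float]:
        """Per-base sampling probabilities realizing the composition targets."""
        if not 0.0 < self.at_pct < 100.0:
            raise InfeasibleSpec(f"at_pct must be in (0, 100), got {self.at_pct}")
        for name, skew in (("at_skew", self.at_skew), ("gc_skew", self.gc_skew)):
            if not -1.0 < skew < 1.0:
                raise InfeasibleSpec(f"{name} must be in (-1, 1), got {skew}")
        at = self.at_pct / 100.0
        gc = 1.0 - at
        return {
            "A": at * (1 + self.at_skew) / 2,
            "T": at * (1 - self.at_skew) / 2,
            "G": gc * (1 + self.gc_skew) / 2,
            "C": gc * (1 - self.gc_skew) / 2,
        }

    def effective_codon_weights(self) -> dict[str, float]:
        """Codon sampling weights for internal PCG positions.

        Defaults to a product of per-position base probabilities with stop
        codons excluded. Because excluding UAA/UAG removes A/T-rich mass,
        the position probabilities are calibrated by a fixed-point
        iteration so that the *marginal* base distribution of the emitted
        codons still equals the composition targets; skews and A+T% then
        carry through to coding sequence. Explicit ``codon_weights``
        bypass the calibration (stops are still zeroed).
        """
        if self.codon_weights is not None:
            w = {
                c.upper().replace("T", "U"): float(v)
                for c, v in self.codon_weights.items()
            }
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise InfeasibleSpec("codon_weights must be non-negative, not all zero")
        else:
            w = _calibrated_codon_weights(self.base_probs())
        stops = set(genetic_code_families(5)["*"])
        for c in stops:
            w[c] = 0.0
        total = sum(w.values())
        return {c: w.get(c, 0.0) / total for c in ALL_CODONS}


# ---------------------------------------------------------------------------

_RNA_OF_DNA = {"A": "A", "C": "C", "G": "G", "T": "U"}
_DNA_OF_RNA = {v: k for k, v in _RNA_OF_DNA.items()}


def _calibrated_codon_weights(
    target: dict[str, float], iterations: int = 200
) -> dict[str, float]:
    """Product-form codon weights whose stop-excluded marginal base
    distribution matches ``target`` (DNA alphabet probabilities).

    Fixed-point scheme: start every codon position at the target
    distribution, compute the realized marginal after dropping UAA/UAG,
    multiply all three positions by target/realized, renormalize, repeat.
    """
    stops = {"UAA", "UAG"}
    q = dict(target)
    for _ in range(iterations):
        w = {
            c: q[_DNA_OF_RNA[c[0]]] * q[_DNA_OF_RNA[c[1]]] * q[_DNA_OF_RNA[c[2]]]
            for c in ALL_CODONS
            if c not in stops
        }
        total = sum(w.values())
        realized = {b: 0.0 for b in "ACGT"}
        for c, v in w.items():
            for ch in c:
                realized[_DNA_OF_RNA[ch]] += v / total / 3.0
        if all(abs(realized[b] - target[b]) < 1e-12 for b in "ACGT"):
            break
        q = {b: q[b] * (target[b] / realized[b]) for b in "ACGT"}
        norm = sum(q.values())
        q = {b: v / norm for b, v in q.items()}
    w = {
        c: q[_DNA_OF_RNA[c[0]]] * q[_DNA_OF_RNA[c[1]]] * q[_DNA_OF_RNA[c[2]]]
        for c in ALL_CODONS
    }
    return w


def _draw_bases(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    bases = np.array(list(probs.keys()))
    p = np.array(list(probs.values()), dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(bases, size=n, p=p)) if n > 0 else ""


def sample_codons(
    rng: np.random.Generator, n: int, weights: dict[str, float]
) -> list[str]:
    """Draw ``n`` RNA codons i.i.d. from normalized ``weights``."""
    codons = np.array([c for c in ALL_CODONS if weights.get(c, 0.0) > 0])
    p = np.array([weights[c] for c in codons], dtype=float)
    p = p / p.sum()
    return list(rng.choice(codons, size=n, p=p)) if n > 0 else []


def _pcg_sequence(
    rng: np.random.Generator, length: int, weights: dict[str, float]
) -> str:
    """A DNA coding sequence of exactly ``length`` nt: start codon, internal
    codons from ``weights``, then a stop codon.

    A length that is not a multiple of 3 truncates the stop to its first
    1-2 nt — an incomplete stop codon, as annotated in real mitogenomes.
    """
    if length < 6:
        raise InfeasibleSpec(f"PCG length {length} < 6")
    stop_len = length % 3 or 3
    n_internal = (length - 3 - stop_len) // 3
    start = START_CODONS[rng.integers(len(START_CODONS))]
    internal = "".join(sample_codons(rng, n_internal, weights)).replace("U", "T")
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))][:stop_len]
    seq = start + internal + stop
    assert len(seq) == length
    return seq


def _hairpin_sequence(
    rng: np.random.Generator, stem: int, loop: int, probs: dict[str, float]
) -> str:
    arm = _draw_bases(rng, stem, probs)
    return arm + _draw_bases(rng, loop, probs) + reverse_complement(arm)


def synth_genome(spec: SynthSpec) -> Mitogenome:
    """Generate one annotated genome with sequence; deterministic under seed.

    Layout: genes in (optionally block-permuted) reference order starting
    at position 1, separated by spacers; one spacer is the control region
    of ``cr_length`` containing the requested hairpin; the closing spacer
    before the first gene absorbs the residual length budget so the
    annotation exactly tiles the circle.
    """
    rng = np.random.default_rng(spec.seed)
    order = list(spec.gene_set) if spec.gene_set is not None else list(_default_gene_order())
    if spec.k_block_moves > 0:
        perm = permute_order(
            GeneOrder(labels=tuple(order), circular=True),
            spec.k_block_moves,
            seed=int(rng.integers(2**31 - 1)),
        )
        order = list(perm.labels)

    lengths = dict(_default_gene_lengths())
    if spec.gene_lengths:
        lengths.update(spec.gene_lengths)
    missing = [g for g in order if g not in lengths]
    if missing:
        raise InfeasibleSpec(f"no length known for genes: {missing}")

    stem, loop = spec.hairpin
    if 2 * stem + loop > spec.cr_length:
        raise InfeasibleSpec(
            f"hairpin ({stem} bp stem, {loop} nt loop) does not fit in a "
            f"{spec.cr_length} bp control region"
        )

    n = len(order)
    cr_junction = n - 1  # after the last gene, unless cr_after is present
    if spec.cr_after in order:
        cr_junction = order.index(spec.cr_after)

    # -- draw gaps per junction (gap[i] follows gene i) ---------------------
    gene_total = sum(lengths[g] for g in order)
    budget = spec.genome_length - gene_total - spec.cr_length
    if budget < 0:
        raise InfeasibleSpec(
            f"genes ({gene_total} bp) + control region ({spec.cr_length} bp) "
            f"exceed genome_length {spec.genome_length}"
        )
    gaps = np.zeros(n, dtype=int)
    free = [i for i in range(n) if i != cr_junction]
    mean_spacer = max(budget / max(len(free), 1), 1.0)
    for i in free:
        nxt = order[(i + 1) % n]
        tRNA_junction = classify_label(order[i]) == TRNA or classify_label(nxt) == TRNA
        if tRNA_junction and rng.random() < spec.overlap_prob:
            cap = min(spec.max_overlap, lengths[order[i]] - 1, lengths[nxt] - 1)
            if cap >= 1:
                gaps[i] = -int(rng.integers(1, cap + 1))
                continue
        gaps[i] = int(rng.geometric(1.0 / mean_spacer)) - 1
    gaps[cr_junction] = spec.cr_length
    # absorb the residual into the closing junction (wrap before gene 0)
    residual = budget - int(gaps[free].sum())
    wrap_j = free[-1] if free[-1] != cr_junction else free[0]
    gaps[wrap_j] += residual
    if gaps[wrap_j] < 0:
        gaps[wrap_j] = 0  # genome comes out slightly longer than targeted

    genome_length = gene_total + int(gaps.sum())

    # -- place features -----------------------------------------------------
    features: list[GeneFeature] = []
    pos = 1
    cr_span = None
    for i, g in enumerate(order):
        start = pos
        end = start + lengths[g] - 1
        cat = classify_label(g)
        features.append(
            GeneFeature(
                label=g,
                category=cat,
                strand="-" if g in spec.light_strand_genes else "+",
                start=start,
                end=end,
            )
        )
        if i == cr_junction:
            cr_span = (end + 1, end + spec.cr_length)
        pos = end + 1 + int(gaps[i])

    # -- sequence: noncoding background, then tRNA/rRNA, then PCGs ----------
    probs = spec.base_probs()
    weights = spec.effective_codon_weights()
    seq = list(_draw_bases(rng, genome_length, probs))

    def write(start: int, s: str) -> None:
        for k, ch in enumerate(s):
            seq[(start - 1 + k) % genome_length] = ch

    for f in features:
        if f.category in (TRNA, RRNA, OTHER_NONCODING):
            s = _draw_bases(rng, f.end - f.start + 1, probs)
            if f.strand == "-":
                s = reverse_complement(s)
            write(f.start, s)
    for f in features:
        if f.category == PCG:
            s = _pcg_sequence(rng, f.end - f.start + 1, weights)
            if f.strand == "-":
                s = reverse_complement(s)
            write(f.start, s)

    # plant the hairpin inside the control region, after everything else
    assert cr_span is not None
    hp = _hairpin_sequence(rng, stem, loop, probs)
    slack = spec.cr_length - len(hp)
    offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
    write(cr_span[0] + offset, hp)

    return Mitogenome(
        identifier=f"synth-{spec.seed}",
        length=genome_length,
        features=features,
        sequence="".join(seq),
        circular=True,
        genetic_code=5,
    )


# ---------------------------------------------------------------------------


def permute_order(order: GeneOrder, k: int, seed: int) -> GeneOrder:
    """Apply ``k`` uniformly random block transpositions.

    Each move cuts a contiguous segment and reinserts it at a random
    position among the remaining genes. One transposition changes at most
    3 adjacencies, so breakpoint_distance(original, permuted) <= 3k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    labels = list(order.labels)
    signs = list(order.signs)
    n = len(labels)
    for _ in range(k):
        if n < 2:
            break
        i = int(rng.integers(0, n))
        j = int(rng.integers(i, n))
        seg_l = labels[i : j + 1]
        seg_s = signs[i : j + 1]
        rest_l = labels[:i] + labels[j + 1 :]
        rest_s = signs[:i] + signs[j + 1 :]
        p = int(rng.integers(0, len(rest_l) + 1))
        labels = rest_l[:p] + seg_l + rest_l[p:]
        signs = rest_s[:p] + seg_s + rest_s[p:]
    return GeneOrder(
        labels=tuple(labels), signs=tuple(signs),
        circular=order.circular, source=order.source,
    )
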