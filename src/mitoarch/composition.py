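"""Base composition and strand-skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) measure the
asymmetry of base usage between the two strands of the mitochondrial
duplex. Both are scale-invariant (counts and percentages give the same
value) and antisymmetric in their arguments. Statistics can be computed
for the whole molecule, for a single gene, or for a category of genes
concatenated in genome order (light-strand genes are reverse-complemented
before concatenation).

Internal arithmetic is kept at full precision; printed values follow the
field's convention of 2-decimal percentages and 3-decimal skews, rounded
half away from zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import CONTROL_REGION, PCG, RRNA, TRNA, GeneFeature, Mitogenome

BASES = ("A", "C", "G", "T")

#: Region-spec aliases for concatenated categories.
_CATEGORY_ALIASES = {
    "pcg": PCG, "pcgs": PCG,
    "trna": TRNA, "trnas": TRNA,
    "rrna": RRNA, "rrnas": RRNA,
    "cr": CONTROL_REGION, "control-region": CONTROL_REGION,
}


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (0.61605 -> 0.616, -0.0775 -> -0.078)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def at_skew(a: float, t: float) -> Optional[float]:
    """(A - T)/(A + T) from counts or percentages; None when A + T == 0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> Optional[float]:
    """(G - C)/(G + C) from counts or percentages; None when G + C == 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


@dataclass
class RegionStats:
    """Composition of one region: counts, percentages and skews.

    Percentages are taken over unambiguous bases only; ``size`` counts all
    positions including ambiguous ones.
    """

    region: str
    size: int
    counts: dict[str, int]
    ambiguous: int
    pct: dict[str, float]
    at_pct: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def rounded(self) -> dict[str, float]:
        """Values at printed precision: 2 dp percentages, 3 dp skews."""
        out = {f"{b}_pct": round_half_away(self.pct[b], 2) for b in BASES}
        out["AT_pct"] = round_half_away(self.at_pct, 2)
        out["AT_skew"] = None if self.at_skew is None else round_half_away(self.at_skew, 3)
        out["GC_skew"] = None if self.gc_skew is None else round_half_away(self.gc_skew, 3)
        return out


def base_composition(seq: str, region: str = "sequence") -> RegionStats:
    """Count bases and derive percentages, A+T% and both skews.

    U is accepted as T; N (and any other IUPAC ambiguity) is excluded from
    every percentage and skew but still counted in ``size``.
    """
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in BASES}
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    pct = {b: counts[b] / unambiguous * 100.0 for b in BASES}
    return RegionStats(
        region=region,
        size=len(s),
        counts=counts,
        ambiguous=len(s) - unambiguous,
        pct=pct,
        at_pct=pct["A"] + pct["T"],
        at_skew=at_skew(counts["A"], counts["T"]),
        gc_skew=gc_skew(counts["G"], counts["C"]),
    )


def region_sequence(genome: Mitogenome, region: str) -> str:
    """Extract the nucleotides of a named region.

    ``region`` may be "mitogenome" (the full molecule), a feature label, or
    a category name ("PCGs", "tRNAs", "rRNAs", "CR"). Category regions
    concatenate their features' coding-strand sequences in genome order
    (starting at the first feature after the origin); "CR" resolves to the
    annotated control region or, failing that, to the largest noncoding
    interval.
    """
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: genome carries no sequence")
    key = region.strip()
    if key.lower() in ("mitogenome", "genome", "whole"):
        return genome.sequence
    cat = _CATEGORY_ALIASES.get(key.lower())
    if cat == CONTROL_REGION:
        cr = [f for f in genome.features if f.category == CONTROL_REGION]
        if cr:
            return genome.feature_sequence(cr[0])
        from .architecture import locate_control_region  # deferred: avoids cycle

        start, end, _ = locate_control_region(genome)
        return genome.subsequence(start, end)
    if cat is not None:
        feats = genome.features_of(cat)
        if not feats:
            raise KeyError(f"{genome.identifier}: no {cat} features")
        return "".join(genome.feature_sequence(f) for f in feats)
    for f in genome.features:
        if f.label == key:
            return genome.feature_sequence(f)
    raise KeyError(f"{genome.identifier}: unknown region {region!r}")


REPORT_COLUMNS = (
    "genome", "region", "size_bp",
    "A_pct", "T_pct", "G_pct", "C_pct", "AT_pct", "AT_skew", "GC_skew",
)


def composition_report(
    genomes: Sequence[Mitogenome],
    regions: Sequence[str] = ("mitogenome", "PCGs", "tRNAs", "rRNAs"),
) -> pd.DataFrame:
    """One row per genome x region at printed precision (Table-style output).

    Regions absent from a genome produce a row of missing values and a
    warning instead of aborting the whole report.
    """
    rows = []
    for g in genomes:
        for region in regions:
            try:
                stats = base_composition(region_sequence(g, region), region=region)
            except (KeyError, ValueError) as exc:
                warnings.warn(f"{g.identifier}: region {region!r} skipped: {exc}")
                rows.append(
                    {"genome": g.identifier, "region": region, "size_bp": None,
                     **{c: None for c in REPORT_COLUMNS[3:]}}
                )
                continue
            rows.append(
                {"genome": g.identifier, "region": region, "size_bp": stats.size,
                 **stats.rounded()}
            )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
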