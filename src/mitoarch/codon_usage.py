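"""Codon counting, relative synonymous codon usage (RSCU), and amino-acid
composition under the invertebrate mitochondrial genetic code.

RSCU of a codon c in a synonymous family F is

    RSCU(c) = n_c * |F| / sum(n_c' for c' in F)

so that a family with no usage bias has RSCU 1.00 for every member and
family RSCU values always sum to |F|. Under translation table 5, UGA
codes Trp, AGA/AGG code Ser (making Ser an 8-codon family), AUA codes
Met, and Leu is a 6-codon family; the two stop codons UAA/UAG form
their own family. Amino-acid composition is reported with the split
families conventional in mitogenomics: Leu1 = CUN, Leu2 = UUA/UUG,
Ser1 = AGN, Ser2 = UCN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio.Data import CodonTable

from .composition import round_half_away
from .model import PCG, Mitogenome

RNA_BASES = "UCAG"

#: All 64 RNA codons in classical table order (first base slowest, U C A G).
ALL_CODONS = tuple(
    a + b + c for a, b, c in itertools.product(RNA_BASES, RNA_BASES, RNA_BASES)
)

_AA1_TO_3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

STOP = "*"


def genetic_code_families(code: int = 5) -> dict[str, tuple[str, ...]]:
    """Synonymous codon families of an NCBI translation table.

    Keys are one-letter amino acids plus "*" for the stop family; values
    are codon tuples (RNA alphabet). Families partition the 64 codons.
    """
    table = CodonTable.unambiguous_rna_by_id[code]
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = STOP if codon in table.stop_codons else table.forward_table[codon]
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(codons) for aa, codons in fams.items()}


def split_families(code: int = 5) -> dict[str, tuple[str, ...]]:
    """Families for amino-acid composition, with Leu and Ser split.

    Leu1 = CUN, Leu2 = UUA/UUG; Ser1 = AGN members, Ser2 = UCN members.
    Other amino acids keep their full synonymous family, named by
    three-letter code.
    """
    merged = genetic_code_families(code)
    out: dict[str, tuple[str, ...]] = {}
    for aa, codons in merged.items():
        if aa == STOP:
            out[STOP] = codons
        elif aa == "L":
            out["Leu1"] = tuple(c for c in codons if c.startswith("CU"))
            out["Leu2"] = tuple(c for c in codons if not c.startswith("CU"))
        elif aa == "S":
            out["Ser1"] = tuple(c for c in codons if c.startswith("AG"))
            out["Ser2"] = tuple(c for c in codons if not c.startswith("AG"))
        else:
            out[_AA1_TO_3[aa]] = codons
    return out


@dataclass
class CodonCountTable:
    """Counts over all 64 codons plus the genetic-code id behind them."""

    counts: dict[str, int]
    code: int = 5

    @classmethod
    def from_counts(cls, counts: dict[str, int], code: int = 5) -> "CodonCountTable":
        norm = {}
        for codon, n in counts.items():
            c = codon.upper().replace("T", "U")
            if c not in ALL_CODONS:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            norm[c] = norm.get(c, 0) + int(n)
        full = {c: norm.get(c, 0) for c in ALL_CODONS}
        return cls(counts=full, code=code)

    @classmethod
    def from_codons(cls, codons: Iterable[str], code: int = 5) -> "CodonCountTable":
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        return cls.from_counts(counts, code=code)

    @classmethod
    def from_genome(cls, genome: Mitogenome) -> "CodonCountTable":
        streams = extract_codons(genome)
        return cls.from_codons(
            itertools.chain.from_iterable(streams.values()), code=genome.genetic_code
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        return genetic_code_families(self.code)

    def scaled(self, factor: int) -> "CodonCountTable":
        return CodonCountTable(
            counts={c: n * factor for c, n in self.counts.items()}, code=self.code
        )


@dataclass
class RscuTable:
    """Per-codon RSCU values; None for codons of families with zero usage."""

    rscu: dict[str, Optional[float]]
    code: int = 5

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        return {
            c: (None if v is None else round_half_away(v, ndigits))
            for c, v in self.rscu.items()
        }


def rscu(table: CodonCountTable) -> RscuTable:
    """RSCU(c) = n_c * |F| / total(F) within each synonymous family."""
    values: dict[str, Optional[float]] = {}
    for aa, codons in table.families.items():
        fam_total = sum(table.counts[c] for c in codons)
        for c in codons:
            values[c] = None if fam_total == 0 else table.counts[c] * len(codons) / fam_total
    return RscuTable(rscu={c: values[c] for c in ALL_CODONS}, code=table.code)


def amino_acid_composition(
    table: CodonCountTable, exclude_stops: bool = True
) -> dict[str, float]:
    """Percentage of each amino acid among all counted codons.

    Leu and Ser are reported split (Leu1/Leu2, Ser1/Ser2). Stops are
    excluded from the denominator by default; pass ``exclude_stops=False``
    to include them as a "*" entry.
    """
    fams = split_families(table.code)
    if exclude_stops:
        fams = {aa: codons for aa, codons in fams.items() if aa != STOP}
    denom = sum(table.counts[c] for codons in fams.values() for c in codons)
    if denom == 0:
        raise ValueError("no codons counted")
    return {
        aa: sum(table.counts[c] for c in codons) / denom * 100.0
        for aa, codons in fams.items()
    }


# ---------------------------------------------------------------------------
# Codon extraction from annotated genomes


def extract_codons(genome: Mitogenome) -> dict[str, list[str]]:
    """Per-PCG codon streams (RNA alphabet) from the coding strand.

    Each gene's coding-strand sequence is split into consecutive triplets;
    the 1-2 trailing nucleotides of an incomplete stop codon are dropped.
    """
    out: dict[str, list[str]] = {}
    for f in genome.features_of(PCG):
        seq = genome.feature_sequence(f)
        usable = len(seq) - len(seq) % 3
        if usable == 0:
            raise ValueError(f"{genome.identifier}: PCG {f.label} has no complete codon")
        rna = seq[:usable].replace("T", "U")
        out[f.label] = [rna[i : i + 3] for i in range(0, usable, 3)]
    return out


# ---------------------------------------------------------------------------
# Tabular I/O


def codon_report(table: CodonCountTable) -> pd.DataFrame:
    """64-row table: codon, amino acid (one-letter, '*' for stops), count, RSCU."""
    fams = table.families
    aa_of = {c: aa for aa, codons in fams.items() for c in codons}
    values = rscu(table).rounded(2)
    return pd.DataFrame(
        {
            "codon": list(ALL_CODONS),
            "amino_acid": [aa_of[c] for c in ALL_CODONS],
            "count": [table.counts[c] for c in ALL_CODONS],
            "rscu": [values[c] for c in ALL_CODONS],
        }
    )


def read_codon_counts(path: Union[str, Path], code: int = 5) -> CodonCountTable:
    """Read a codon-count TSV with columns ``codon`` and ``count``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "codon" not in cols or "count" not in cols:
        raise ValueError(f"{path}: need 'codon' and 'count' columns")
    return CodonCountTable.from_counts(
        dict(zip(df[cols["codon"]], df[cols["count"]])), code=code
    )


def write_codon_report(table: CodonCountTable, path: Union[str, Path]) -> Path:
    p = Path(path)
    codon_report(table).to_csv(p, sep="\t", index=False)
    return p
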