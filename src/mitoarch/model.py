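"""Domain types for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive on both ends (GenBank convention).
A feature whose ``end`` is smaller than its ``start`` spans the origin of
the circular molecule (it wraps across position 1).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

# ---------------------------------------------------------------------------
# Feature categories

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control-region"
OTHER_NONCODING = "other-noncoding"

CATEGORIES = (PCG, TRNA, RRNA, CONTROL_REGION, OTHER_NONCODING)

#: The 13 canonical protein-coding gene labels of animal mitogenomes.
#: Many bivalves (including all Pharidae) lack atp8; gene content is not
#: enforced anywhere, only naming.
PCG_LABELS = frozenset(
    {
        "cox1",
        "cox2",
        "cox3",
        "cytb",
        "nad1",
        "nad2",
        "nad3",
        "nad4",
        "nad4l",
        "nad5",
        "nad6",
        "atp6",
        "atp8",
    }
)

RRNA_LABELS = frozenset({"rrnS", "rrnL"})

#: One-letter amino-acid code -> canonical tRNA suffix.
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

#: Anticodon (DNA, 5'->3' as annotated) disambiguates the duplicated
#: leucine and serine tRNA isoacceptors.
ANTICODON_ISOACCEPTOR = {
    ("trnL", "TAG"): "trnL1",
    ("trnL", "TAA"): "trnL2",
    ("trnS", "TCT"): "trnS1",
    ("trnS", "TGA"): "trnS2",
}

_SYNONYMS = {
    # cytochrome oxidase subunits
    "co1": "cox1", "coi": "cox1", "cox1": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "cox2": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "cox3": "cox3", "coxiii": "cox3",
    # cytochrome b
    "cob": "cytb", "cytb": "cytb", "cyb": "cytb", "cyt b": "cytb",
    # NADH dehydrogenase subunits
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nd5": "nad5", "nad5": "nad5",
    "nd6": "nad6", "nad6": "nad6",
    # ATP synthase subunits
    "atp6": "atp6", "atpase6": "atp6", "atpase 6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpase 8": "atp8",
    # ribosomal RNAs
    "rrns": "rrnS", "12s": "rrnS", "12s rrna": "rrnS", "12s ribosomal rna": "rrnS",
    "srrna": "rrnS", "s-rrna": "rrnS", "rrn12": "rrnS",
    "small subunit ribosomal rna": "rrnS",
    "rrnl": "rrnL", "16s": "rrnL", "16s rrna": "rrnL", "16s ribosomal rna": "rrnL",
    "lrrna": "rrnL", "l-rrna": "rrnL", "rrn16": "rrnL",
    "large subunit ribosomal rna": "rrnL",
    # control region
    "cr": CONTROL_REGION, "d-loop": CONTROL_REGION, "control region": CONTROL_REGION,
}

_TRNA_RE = re.compile(r"^trna?[-_ ]?(?P<rest>.+)$", re.IGNORECASE)


class AnnotationError(ValueError):
    """Raised when an annotation cannot be interpreted (bad coordinates etc.)."""


def canonical_label(name: str, anticodon: Optional[str] = None) -> str:
    """Map a gene name (case-insensitive, many synonyms) to its canonical form.

    Canonical names are lowercase (cox1..3, cytb, nad1..6, nad4l, atp6, atp8,
    trnX / trnL1 / trnL2 / trnS1 / trnS2) except rrnS and rrnL. tRNA names
    given generically as trnL / trnS are split into isoacceptors by their
    anticodon when one is supplied. Unknown names are returned stripped and
    lowercased, unmodified otherwise; canonicalization is idempotent.
    """
    raw = name.strip()
    key = raw.lower().replace("*", "").strip()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = _TRNA_RE.match(key)
    if m:
        rest = m.group("rest").strip().strip("()-_ ")
        # strip an embedded anticodon such as "leu(tag)" / "l-tag"
        emb = re.match(r"^(?P<aa>[a-z]{1,4})\s*[-_( ]*\s*(?P<ac>[acgtu]{3})?\)?(?P<iso>\d)?$", rest)
        aa_part, ac_part, iso = rest, None, None
        if emb:
            aa_part = emb.group("aa")
            ac_part = emb.group("ac")
            iso = emb.group("iso")
        if aa_part in _AA3_TO_1:
            letter = _AA3_TO_1[aa_part]
        elif len(aa_part) >= 1 and aa_part[0].upper() in _AA3_TO_1.values():
            letter = aa_part[0].upper()
            if len(aa_part) > 1 and aa_part[1] in "12":
                iso = aa_part[1]
        else:
            return key
        base = f"trn{letter}"
        if iso in ("1", "2") and letter in ("L", "S"):
            return f"{base}{iso}"
        ac = (anticodon or ac_part or "").upper().replace("U", "T")
        return ANTICODON_ISOACCEPTOR.get((base, ac), base)
    return key


def classify_label(label: str) -> str:
    """Infer the feature category from a canonical label."""
    if label in PCG_LABELS:
        return PCG
    if label in RRNA_LABELS:
        return RRNA
    if label.startswith("trn"):
        return TRNA
    if label == CONTROL_REGION:
        return CONTROL_REGION
    return OTHER_NONCODING


# ---------------------------------------------------------------------------
# Features and genomes


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a circular genome.

    ``end < start`` encodes a feature spanning the origin. ``strand`` is
    "+" for the heavy strand and "-" for the light strand.
    """

    label: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.label}: strand must be '+' or '-', got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise AnnotationError(f"{self.label}: unknown category {self.category!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.label}: coordinates must be >= 1 ({self.start}..{self.end})")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        """Feature length in nucleotides; wrapping features add the genome length."""
        n = self.end - self.start + 1
        if self.wraps:
            n += genome_length
        return n


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length of ``f`` on a circular genome of ``genome_length`` nucleotides."""
    return f.length(genome_length)


@dataclass
class Mitogenome:
    """A circular (by default) mitochondrial genome with ordered annotation.

    ``genetic_code`` is the NCBI translation-table id; 5 is the invertebrate
    mitochondrial code (UGA=Trp, AGA/AGG=Ser, AUA=Met).
    """

    identifier: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = True
    genetic_code: int = 5

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"{self.identifier}: genome length must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.length:
                raise AnnotationError(
                    f"{self.identifier}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise AnnotationError(
                    f"{self.identifier}: feature {f.label} coordinates "
                    f"{f.start}..{f.end} exceed genome length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    # -- queries ------------------------------------------------------------

    def feature(self, label: str) -> GeneFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"{self.identifier}: no feature named {label!r}")

    def features_of(self, *categories: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category in categories]

    def counts_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.category] = out.get(f.category, 0) + 1
        return out

    # -- sequence access ----------------------------------------------------

    def subsequence(self, start: int, end: int) -> str:
        """Nucleotides from ``start`` to ``end`` inclusive, wrapping if end < start."""
        if self.sequence is None:
            raise ValueError(f"{self.identifier}: genome carries no sequence")
        if end >= start:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise AnnotationError(f"wrapping interval {start}..{end} on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Coding-strand sequence of a feature (light-strand features are
        reverse-complemented)."""
        s = self.subsequence(f.start, f.end)
        return reverse_complement(s) if f.strand == "-" else s

    # -- transformations ----------------------------------------------------

    def rotated(self, offset: int) -> "Mitogenome":
        """Move the origin forward by ``offset`` nucleotides (circular only).

        Old position ``offset + 1`` becomes position 1. Gap values, region
        lengths and all per-region statistics are invariant under rotation.
        """
        if not self.circular:
            raise AnnotationError("cannot rotate a linear genome")
        L = self.length
        off = offset % L

        def shift(p: int) -> int:
            return (p - 1 - off) % L + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in self.features]
        seq = None
        if self.sequence is not None:
            seq = self.sequence[off:] + self.sequence[:off]
        return Mitogenome(
            identifier=self.identifier,
            length=L,
            features=feats,
            sequence=seq,
            circular=True,
            genetic_code=self.genetic_code,
        )

    def validate(self, reference_sizes: Optional[dict[str, int]] = None) -> list[str]:
        """Run consistency checks; return human-readable warnings.

        ``reference_sizes`` optionally maps gene labels to externally
        reported sizes (bp); mismatches with the annotated coordinates are
        flagged rather than resolved.
        """
        notes: list[str] = []
        seen: dict[str, int] = {}
        for f in self.features:
            seen[f.label] = seen.get(f.label, 0) + 1
        for label, n in seen.items():
            if n > 1:
                notes.append(f"duplicate feature label {label!r} ({n} copies)")
        if reference_sizes:
            for label, size in reference_sizes.items():
                try:
                    f = self.feature(label)
                except KeyError:
                    continue
                got = f.length(self.length)
                if got != size:
                    notes.append(
                        f"{label}: annotated length {got} bp differs from "
                        f"reported size {size} bp"
                    )
        return notes


# ---------------------------------------------------------------------------
# Small sequence helpers

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
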