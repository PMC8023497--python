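"""Readers and writers for annotated mitogenomes.

Three external formats are supported:

* a TSV annotation dialect with columns ``gene  category  strand  start
  end  anticodon`` (header row required, ``#`` comments allowed; only
  gene/strand/start/end are mandatory),
* a subset of the GenBank flat-file grammar (LOCUS/FEATURES/ORIGIN with
  gene, CDS, tRNA, rRNA, D-loop and misc_feature keys; ``complement()``
  and origin-spanning ``join()`` locations), parsed and written through
  Biopython,
* FASTA for bare sequences.

Gene labels are canonicalized on input (COI -> cox1, 12S -> rrnS, ...);
unknown labels are retained as category ``other-noncoding`` with a warning
rather than aborting the parse.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    CONTROL_REGION,
    OTHER_NONCODING,
    PCG,
    RRNA,
    TRNA,
    AnnotationError,
    GeneFeature,
    Mitogenome,
    canonical_label,
    classify_label,
)

PathLike = Union[str, Path]

TSV_COLUMNS = ("gene", "category", "strand", "start", "end", "anticodon")

_GENBANK_TYPE_FOR_CATEGORY = {
    PCG: "CDS",
    TRNA: "tRNA",
    RRNA: "rRNA",
    CONTROL_REGION: "D-loop",
    OTHER_NONCODING: "misc_feature",
}
_CATEGORY_FOR_GENBANK_TYPE = {
    "CDS": PCG,
    "tRNA": TRNA,
    "rRNA": RRNA,
    "D-loop": CONTROL_REGION,
    "misc_feature": OTHER_NONCODING,
}


# ---------------------------------------------------------------------------
# dispatch


def read_annotation(
    source: PathLike,
    fmt: Optional[str] = None,
    sequence: Optional[str] = None,
    length: Optional[int] = None,
    identifier: Optional[str] = None,
) -> Mitogenome:
    """Read an annotated genome from a GenBank flat file or the TSV dialect.

    ``fmt`` is "genbank" or "tsv"; when omitted it is inferred from the file
    suffix (.gb/.gbk/.genbank vs anything else) and, failing that, from the
    leading bytes. For TSV input, ``length`` gives the genome length (when
    omitted it defaults to the largest coordinate seen, with a warning) and
    ``sequence`` optionally attaches nucleotides.
    """
    path = Path(source)
    if fmt is None:
        if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
            fmt = "genbank"
        elif path.suffix.lower() in (".tsv", ".txt"):
            fmt = "tsv"
        else:
            head = path.read_text(errors="replace")[:5]
            fmt = "genbank" if head.startswith("LOCUS") else "tsv"
    if fmt == "genbank":
        return read_genbank(path)
    if fmt == "tsv":
        return read_annotation_tsv(path, sequence=sequence, length=length, identifier=identifier)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_annotation(genome: Mitogenome, dest: PathLike, fmt: Optional[str] = None) -> Path:
    """Write a genome as TSV or GenBank; read(write(g)) round-trips."""
    path = Path(dest)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank") else "tsv"
    if fmt == "genbank":
        return write_genbank(genome, path)
    if fmt == "tsv":
        return write_annotation_tsv(genome, path)
    raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# TSV dialect


def read_annotation_tsv(
    source: PathLike,
    sequence: Optional[str] = None,
    length: Optional[int] = None,
    identifier: Optional[str] = None,
) -> Mitogenome:
    path = Path(source)
    rows = []
    meta: dict[str, str] = {}
    with path.open(newline="") as fh:
        lines = []
        for ln in fh:
            if not ln.strip():
                continue
            if ln.lstrip().startswith("#"):
                # metadata comments of the form "# key=value\tkey=value"
                for token in ln.lstrip("# \t").split("\t"):
                    if "=" in token:
                        k, _, v = token.strip().partition("=")
                        meta.setdefault(k.strip().lower(), v.strip())
                continue
            lines.append(ln)
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        raise AnnotationError(f"{path}: empty annotation table")
    cols = [c.strip().lower() for c in reader.fieldnames]
    required = {"gene", "start", "end", "strand"}
    if not required.issubset(cols):
        raise AnnotationError(
            f"{path}: header must name at least gene, start, end, strand (got {cols})"
        )
    for raw in reader:
        row = {k.strip().lower(): (v.strip() if v else "") for k, v in raw.items() if k}
        rows.append(row)

    features = []
    for row in rows:
        name = row["gene"]
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise AnnotationError(f"{path}: feature {name!r}: bad coordinates") from exc
        anticodon = row.get("anticodon") or None
        label = canonical_label(name, anticodon)
        category = row.get("category") or ""
        if category:
            category = _normalize_category(category)
        else:
            category = classify_label(label)
        if category == OTHER_NONCODING and classify_label(label) == OTHER_NONCODING \
                and label not in (CONTROL_REGION,):
            warnings.warn(f"{path}: unknown gene label {name!r} kept as other-noncoding")
        features.append(
            GeneFeature(
                label=label,
                category=category,
                strand=row["strand"] or "+",
                start=start,
                end=end,
                anticodon=anticodon,
            )
        )

    if length is None:
        if "length" in meta:
            length = int(meta["length"])
        elif sequence is not None:
            length = len(sequence)
        else:
            length = max((max(f.start, f.end) for f in features), default=1)
            warnings.warn(
                f"{path}: no genome length given; using largest coordinate {length}"
            )
    circular = meta.get("circular", "true").lower() != "false"
    try:
        return Mitogenome(
            identifier=identifier or meta.get("genome") or path.stem,
            length=length,
            features=features,
            sequence=sequence,
            circular=circular,
        )
    except AnnotationError as exc:
        raise AnnotationError(f"{path}: {exc}") from exc


def _normalize_category(cat: str) -> str:
    c = cat.strip().lower()
    aliases = {
        "pcg": PCG, "cds": PCG, "protein": PCG,
        "trna": TRNA, "rrna": RRNA,
        "cr": CONTROL_REGION, "control-region": CONTROL_REGION,
        "control region": CONTROL_REGION, "d-loop": CONTROL_REGION,
        "other-noncoding": OTHER_NONCODING, "noncoding": OTHER_NONCODING,
        "other": OTHER_NONCODING, "misc": OTHER_NONCODING,
    }
    if c not in aliases:
        raise AnnotationError(f"unknown feature category {cat!r}")
    return aliases[c]


def write_annotation_tsv(genome: Mitogenome, dest: PathLike) -> Path:
    path = Path(dest)
    with path.open("w", newline="") as fh:
        fh.write(f"# genome={genome.identifier}\tlength={genome.length}\t"
                 f"circular={str(genome.circular).lower()}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for f in genome.features:
            writer.writerow(
                [f.label, f.category, f.strand, f.start, f.end, f.anticodon or ""]
            )
    return path


# ---------------------------------------------------------------------------
# GenBank (via Biopython)


def read_genbank(source: PathLike) -> Mitogenome:
    path = Path(source)
    record = SeqIO.read(str(path), "genbank")
    length = len(record.seq)
    seq = str(record.seq).upper()
    has_real_seq = bool(seq) and set(seq) != {"N"}

    features: list[GeneFeature] = []
    claimed: set[tuple[int, int]] = set()
    typed = [f for f in record.features if f.type in _CATEGORY_FOR_GENBANK_TYPE]
    genes = [f for f in record.features if f.type == "gene"]
    for f in typed + genes:
        start, end, strand = _span_from_location(f, length, path)
        if f.type == "gene" and (start, end) in claimed:
            continue  # the typed sibling (CDS/tRNA/rRNA) already covers it
        claimed.add((start, end))
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("product", [None])[0]
            or f.qualifiers.get("note", [None])[0]
            or f.type
        )
        anticodon = None
        if "anticodon" in f.qualifiers:
            ac = f.qualifiers["anticodon"][0]
            anticodon = ac.split(":")[-1].strip("() ").upper().replace("U", "T")[-3:]
        label = canonical_label(name, anticodon)
        if f.type in ("CDS", "tRNA", "rRNA", "D-loop"):
            category = _CATEGORY_FOR_GENBANK_TYPE[f.type]
        else:
            category = classify_label(label)
        if category == OTHER_NONCODING and label == CONTROL_REGION:
            category = CONTROL_REGION
        if category == OTHER_NONCODING and classify_label(label) == OTHER_NONCODING:
            warnings.warn(f"{path}: unknown gene label {name!r} kept as other-noncoding")
        if start > length or end > length:
            raise AnnotationError(
                f"{path}: feature {label} coordinates {start}..{end} exceed length {length}"
            )
        features.append(
            GeneFeature(label=label, category=category, strand=strand,
                        start=start, end=end, anticodon=anticodon)
        )

    topology = record.annotations.get("topology", "circular")
    return Mitogenome(
        identifier=record.id if record.id != "<unknown id>" else path.stem,
        length=length,
        features=features,
        sequence=seq if has_real_seq else None,
        circular=topology != "linear",
    )


def _span_from_location(f: SeqFeature, length: int, path: Path) -> tuple[int, int, str]:
    """1-based inclusive span; a join across the origin becomes a wrap."""
    loc = f.location
    strand = "-" if loc.strand == -1 else "+"
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(loc.start) + 1, int(loc.end), strand
    first, last = parts[0], parts[-1]
    if int(first.start) == 0 and int(last.end) == length:
        # join(x..length, 1..y): single feature wrapping the origin
        return int(last.start) + 1, int(first.end), strand
    raise AnnotationError(
        f"{path}: cannot interpret compound location {loc} as a circular wrap"
    )


def write_genbank(genome: Mitogenome, dest: PathLike) -> Path:
    path = Path(dest)
    seq = genome.sequence if genome.sequence is not None else "N" * genome.length
    record = SeqRecord(
        Seq(seq),
        id=genome.identifier[:20] or "genome",
        name=(genome.identifier[:16] or "genome").replace(" ", "_"),
        description="annotated mitochondrial genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, genome.length, strand=strand),
                    SimpleLocation(0, f.end, strand=strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        qualifiers: dict = {"gene": [f.label]}
        if f.anticodon:
            qualifiers["anticodon"] = [f.anticodon]
        record.features.append(
            SeqFeature(loc, type=_GENBANK_TYPE_FOR_CATEGORY[f.category], qualifiers=qualifiers)
        )
    with path.open("w") as fh:
        SeqIO.write([record], fh, "genbank")
    return path


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: PathLike) -> tuple[str, str]:
    """Return (identifier, sequence) of the first record."""
    record = next(SeqIO.parse(str(source), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(identifier: str, sequence: str, dest: PathLike, width: int = 70) -> Path:
    path = Path(dest)
    record = SeqRecord(Seq(sequence), id=identifier, description="")
    with path.open("w") as fh:
        SeqIO.write([record], fh, "fasta")
    return path
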