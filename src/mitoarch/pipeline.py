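"""End-to-end report generation over one or more annotated genomes.

``run`` reads every input, emits the requested per-genome reports
(composition, architecture, codon usage) plus cross-genome tables
(a combined composition table and, with two or more inputs, a gene-order
comparison), and collects all warnings into a run log. A genome that
fails to parse is reported and skipped; it does not abort the others.
Reports use fixed column orders and fixed rounding, so re-running a
config produces byte-identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import architecture, codon_usage, composition, gene_order, io
from .model import PCG, RRNA, TRNA, Mitogenome

logger = logging.getLogger("mitoarch")

ALL_REPORTS = ("composition", "architecture", "codons", "order")


@dataclass
class RunConfig:
    inputs: list[str]
    reports: Sequence[str] = ALL_REPORTS
    counts: Optional[str] = None  # codon-count TSV when genomes lack sequence
    output_dir: str = "."
    regions: Sequence[str] = ("mitogenome", "PCGs", "tRNAs", "rRNAs", "CR")
    order_exclude: Sequence[str] = ()  # categories to drop before comparison
    order_start: str = "cox1"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input is required")
        bad = set(self.reports) - set(ALL_REPORTS)
        if bad:
            raise ValueError(f"unknown reports: {sorted(bad)}; choose from {ALL_REPORTS}")


@dataclass
class RunResult:
    written: list[Path] = field(default_factory=list)
    genomes: list[Mitogenome] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)


def run(config: RunConfig) -> RunResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.setLevel(config.log_level.upper())
    result = RunResult()

    for src in config.inputs:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                g = io.read_annotation(src)
            except Exception as exc:  # noqa: BLE001 - reported, not swallowed
                result.failures[src] = str(exc)
                result.messages.append(f"ERROR {src}: {exc}")
                continue
            for w in caught:
                result.messages.append(f"WARN {src}: {w.message}")
        result.genomes.append(g)

    for g in result.genomes:
        for note in g.validate():
            result.messages.append(f"WARN {g.identifier}: {note}")
        prefix = out / _safe(g.identifier)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if "architecture" in config.reports:
                p = Path(f"{prefix}.architecture.tsv")
                p.write_text(architecture.architecture_report(g))
                result.written.append(p)
            if "composition" in config.reports and g.sequence is not None:
                p = Path(f"{prefix}.composition.tsv")
                composition.composition_report([g], config.regions).to_csv(
                    p, sep="\t", index=False
                )
                result.written.append(p)
            if "codons" in config.reports:
                table = None
                if g.sequence is not None:
                    table = codon_usage.CodonCountTable.from_genome(g)
                elif config.counts is not None:
                    table = codon_usage.read_codon_counts(config.counts)
                if table is not None:
                    p = Path(f"{prefix}.codon_usage.tsv")
                    codon_usage.write_codon_report(table, p)
                    result.written.append(p)
        for w in caught:
            result.messages.append(f"WARN {g.identifier}: {w.message}")

    with_seq = [g for g in result.genomes if g.sequence is not None]
    if "composition" in config.reports and with_seq:
        p = out / "composition.all.tsv"
        composition.composition_report(with_seq, config.regions).to_csv(
            p, sep="\t", index=False
        )
        result.written.append(p)

    if "order" in config.reports and len(result.genomes) >= 2:
        p = out / "order_comparison.tsv"
        p.write_text(order_comparison(result.genomes, config))
        result.written.append(p)

    log = out / "run.log"
    log.write_text("".join(m + "\n" for m in result.messages))
    result.written.append(log)
    return result


def order_comparison(genomes: Sequence[Mitogenome], config: RunConfig) -> str:
    """Pairwise shared blocks and breakpoint distances as one TSV."""
    include = tuple(c for c in (PCG, TRNA, RRNA) if c not in set(config.order_exclude))
    orders = []
    for g in genomes:
        try:
            orders.append(gene_order.linearize(g, config.order_start, include))
        except KeyError:
            orders.append(gene_order.linearize(g, g.features[0].label, include))
    lines = ["a\tb\tkind\tvalue\tgenes"]
    for i in range(len(orders)):
        for j in range(i + 1, len(orders)):
            a, b = orders[i], orders[j]
            common = set(a.labels) & set(b.labels)
            ra = a.restricted(common)
            rb = b.restricted(common)
            d = gene_order.breakpoint_distance(ra, rb)
            lines.append(f"{a.source}\t{b.source}\tbreakpoint_distance\t{d}\t")
            if common != set(a.labels) | set(b.labels):
                dropped = sorted((set(a.labels) | set(b.labels)) - common)
                lines.append(
                    f"{a.source}\t{b.source}\trestricted_to_common\t"
                    f"{len(common)}\tdropped:{','.join(dropped)}"
                )
            for blk in gene_order.shared_blocks(a, b):
                lines.append(
                    f"{a.source}\t{b.source}\tshared_block\t{blk.length}\t"
                    + ",".join(blk.genes)
                )
    return "\n".join(lines) + "\n"


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)
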