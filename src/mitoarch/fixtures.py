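"""Packaged reference tables for the *Siliqua minima* mitogenome (MT375556).

Three small TSVs transcribed from the published study travel with the
package so that every analysis stage can be exercised and regression-tested
without network access: the 36-feature annotation (17,064 bp), the
per-region composition/skew table, and the codon-count/RSCU table for the
12 protein-coding genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_usage import CodonCountTable
from .io import read_annotation_tsv
from .model import Mitogenome

#: Length of the reference mitogenome in nucleotides.
REFERENCE_LENGTH = 17_064

#: The published 34-nt origin-of-light-strand-replication (OL) element found
#: inside the control region; it folds into a stem-loop hairpin.
OL_SEQUENCE = "CCTTCCCCCTTCTACGATAGTTGGAGGGGGAAGG"


def _data_path(name: str):
    return resources.files("mitoarch.data").joinpath(name)


def reference_annotation() -> Mitogenome:
    """The 36-gene annotation (12 PCG + 22 tRNA + 2 rRNA), no sequence."""
    with resources.as_file(_data_path("sminima_annotation.tsv")) as p:
        return read_annotation_tsv(p, length=REFERENCE_LENGTH, identifier="MT375556")


def reference_region_table() -> pd.DataFrame:
    """Published per-region composition: size, base %, A+T%, printed skews."""
    with resources.as_file(_data_path("sminima_regions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_codon_counts() -> CodonCountTable:
    """Published codon counts for the 12 PCGs (invertebrate mito code)."""
    df = reference_codon_table()
    return CodonCountTable.from_counts(dict(zip(df["codon"], df["count"])), code=5)


def reference_codon_table() -> pd.DataFrame:
    """The raw codon table: codon, count, printed RSCU (2 dp)."""
    with resources.as_file(_data_path("sminima_codons.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_pcg_sizes() -> dict[str, int]:
    """Published per-PCG sizes (bp) from the region table.

    Note these are the *published* sizes; cox2 is printed as 948 bp there
    while the annotation coordinates give 685 bp. ``Mitogenome.validate``
    surfaces the conflict.
    """
    df = reference_region_table()
    pcg_rows = df[~df["region"].isin(["mitogenome", "CR", "tRNAs", "rRNAs", "PCGs"])]
    return dict(zip(pcg_rows["region"], pcg_rows["size_bp"].astype(int)))
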