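"""Relative synonymous codon usage and amino-acid composition from the
packaged codon-count table (12 protein-coding genes, invertebrate
mitochondrial code).

RSCU(c) = count(c) * |family| / total(family): 1.00 means no bias within
the synonymous family; >1 means the codon is over-used.
"""

from mitoarch import amino_acid_composition, rscu
from mitoarch.composition import round_half_away
from mitoarch.fixtures import reference_codon_counts

counts = reference_codon_counts()
values = rscu(counts).rounded(2)

print(f"codons counted: {counts.total}")
print()
print("selected RSCU values (family sizes under code 5 in brackets):")
for codon, note in [
    ("UUA", "Leu  [6] - most over-used codon"),
    ("UCU", "Ser  [8] - AGA/AGG join the serine family"),
    ("UGA", "Trp  [2] - UGA is tryptophan, not stop"),
    ("GCU", "Ala  [4]"),
    ("CGC", "Arg  [4] - rarest codon"),
]:
    print(f"  {codon}  RSCU={values[codon]:<5} {note}")

aa = amino_acid_composition(counts, exclude_stops=True)
top = sorted(aa.items(), key=lambda kv: -kv[1])[:4]
print()
print("most frequent amino acids (stops excluded; Leu/Ser split as Leu1=CUN,")
print("Leu2=UUA/UUG, Ser1=AGN, Ser2=UCN):")
for name, pct in top:
    print(f"  {name:<5} {round_half_away(pct, 2):.2f}%")
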