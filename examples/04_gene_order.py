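"""Gene-order comparison: shared blocks and breakpoint distance.

Compares the protein-coding + rRNA gene strings of two razor-clam
families that differ only by a swap of nad5 and nad6: two conserved
blocks remain, and the breakpoint distance is 2.
"""

from mitoarch import GeneOrder, breakpoint_distance, linearize, shared_blocks
from mitoarch.fixtures import reference_annotation
from mitoarch.model import PCG, RRNA

hiatellidae = GeneOrder(
    labels=tuple("nad3 nad1 nad5 nad6 cytb rrnL atp6 rrnS cox3".split()),
    circular=False,
)
solenidae = GeneOrder(
    labels=tuple("nad3 nad1 nad6 nad5 cytb rrnL atp6 rrnS cox3".split()),
    circular=False,
)

print("shared blocks (unsigned, same direction):")
for blk in shared_blocks(hiatellidae, solenidae):
    print(f"  {'-'.join(blk.genes)}  (length {blk.length})")
d = breakpoint_distance(hiatellidae, solenidae)
print(f"breakpoint distance: {d} "
      "(the nad1-nad5 and nad6-cytb adjacencies are broken by the swap)")

print()
ref = reference_annotation()
order = linearize(ref, start_gene="cox1", include={PCG, RRNA})
print(f"reference PCG+rRNA order ({len(order)} genes, rotated to cox1):")
print("  " + "-".join(order.labels))
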