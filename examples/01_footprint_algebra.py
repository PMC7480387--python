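"""Footprint interval algebra on the bundled protected-region table.

Loads the ten DNase-I protected regions of the sfb cluster promoters
(anchored to each gene's translation start) and prints, per promoter, the
protection length on each strand, the displacement between the two strands'
regions, and their overlap.  A displacement of {0} means the two strands
were protected over exactly the same stretch; a small displacement with a
large overlap is the classic signature of a protein sitting on one face of
the double helix.
"""

from gblreg.operator_model import (
    interval_length,
    sfb_footprints,
    strand_displacement,
    strand_overlap,
)

for pair in sfb_footprints():
    up, down, summary = strand_displacement(pair)
    print(
        f"{pair.promoter:8s} top {pair.top.from_pos}..{pair.top.to_pos} "
        f"({interval_length(pair.top)} nt), bottom {pair.bottom.from_pos}.."
        f"{pair.bottom.to_pos} ({interval_length(pair.bottom)} nt), "
        f"displacement {sorted(summary)}, overlap {strand_overlap(pair)} nt"
    )
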