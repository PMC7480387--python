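"""Bipartite promoter scanning with a variable spacer.

Implants a −35 box (TTGACA) and a −10 box (TATAAT) separated by 17 nt into
GC-rich random background, then scans every (position, spacer) combination
with the combined two-block matrix.  The top hit should land exactly on the
implant with the right spacer; the score is the sum of the two 13-column
window scores (null spacer columns contribute nothing).
"""

import numpy as np

from gblreg.promoter_scan import default_model, scan_bipartite
from gblreg.synthetic_data import random_sequence

rng = np.random.default_rng(7)
upstream = (
    random_sequence(rng, 60, 0.72)
    + "TTGACA" + random_sequence(rng, 17, 0.72) + "TATAAT"
    + random_sequence(rng, 40, 0.72)
)

model = default_model("consensus")
hits = scan_bipartite(upstream, model, gene="demo")
best = hits[0]
m35, m10 = best.hexamers(upstream)
print(f"top hit: -35 {m35} ... {best.hexamer_spacer} nt ... -10 {m10}")
print(f"windows (anchored): -35 {best.minus35_window.from_pos}..{best.minus35_window.to_pos}, "
      f"-10 {best.minus10_window.from_pos}..{best.minus10_window.to_pos}")
print(f"score = {best.score35:.1f} + {best.score10:.1f} = {best.score_total:.1f}")
print(f"(anchored positions count backwards from the start codon: -1 is the "
      "base just 5' of it)")
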