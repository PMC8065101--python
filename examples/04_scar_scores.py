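"""Score the three HR-deficiency genomic scars on hand-built segments.

One 100 Mb chromosome (centromere at 45-55 Mb) is given three archetypal
lesions: an interior 20 Mb LOH region, a 15 Mb telomeric allelic imbalance,
and a large-scale copy-number transition between two >=10 Mb segments.
"""

import pandas as pd

from hrdscape.io import ASCNSegment, ChromosomeMap
from hrdscape.scars import score_sample

M = 1_000_000
chrom_map = ChromosomeMap(pd.DataFrame([{
    "chrom": "demo", "length": 100 * M,
    "centromere_start": 45 * M, "centromere_end": 55 * M}]))

segments = [
    ASCNSegment("S", "demo", 1, 15 * M, 2, 1),            # telomeric imbalance
    ASCNSegment("S", "demo", 20 * M, 40 * M, 2, 0),       # interior LOH
    ASCNSegment("S", "demo", 56 * M, 70 * M, 1, 1),
    ASCNSegment("S", "demo", 70 * M + 1, 85 * M, 2, 2),   # q-arm LST breakpoint
]

scores = score_sample(segments, chrom_map)
print(f"LOH score: {scores.loh_score}   (minor-copy-0 runs > 15 Mb, "
      "not whole-chromosome)")
print(f"TAI score: {scores.tai_score}   (imbalanced runs >= 11 Mb reaching a "
      "telomere, not crossing the centromere)")
print(f"LST score: {scores.lst_score}   (breakpoints between >= 10 Mb states "
      "after 3 Mb smoothing)")
print(f"HRD-sum:   {scores.hrd_sum}   (the sum of the three, the usual "
      "HR-deficiency readout)")
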