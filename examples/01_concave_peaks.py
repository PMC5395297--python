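"""Split a broad peak into two sharp concave peaks.

Two binding events 300 bp apart are planted inside one broad interval; the
smoothed-second-derivative refinement recovers them as separate peaks, each
scored by |curvature index| (more negative curvature = sharper peak).
"""

import numpy as np

from hetchrom.intervals import GenomicInterval
from hetchrom.peaks import find_concave_regions, smooth_second_derivative
from hetchrom.synth import PlantedBump, make_coverage

track = make_coverage(
    {"chr1": 20_000},
    [PlantedBump("chr1", 9_850, height=400, width=320),
     PlantedBump("chr1", 10_150, height=400, width=320)],
    baseline=10,
    seed=0,
)
broad_peak = GenomicInterval("chr1", 8_000, 12_000, score=500.0)

d2 = smooth_second_derivative(track, kernel_bp=250)
regions = find_concave_regions(d2, [broad_peak], curvature_threshold=-500.0)

print(f"broad peak: {broad_peak.name} ({broad_peak.width} bp)")
print(f"concave peaks found: {len(regions)}")
for r in regions:
    print(f"  {r.interval.name}  curvature_index={r.curvature_index:.0f}")
print(
    "\nTwo sub-threshold-curvature regions inside one broad call means the\n"
    "two planted binding events were resolved instead of being reported as\n"
    "a single wide peak."
)
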