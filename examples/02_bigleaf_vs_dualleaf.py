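"""Where the big-leaf conductance model errs, and by how much.

Sweeps incident PAR at two leaf area indices with no VPD or soil-water
stress and compares the big-leaf canopy conductance (mean light times
effective LAI) against the dual-leaf sum of sunlit and shaded
contributions.
"""

import numpy as np

from canopyflux import RunConfig, compare_gsc

config = RunConfig()
grid = np.arange(10.0, 1001.0, 10.0)

for lai in (2.0, 5.0):
    table = compare_gsc(config, [lai], grid, zenith_deg=35.0)
    peak = table.loc[table["rel_error_pct"].abs().idxmax()]
    print(f"LAI = {lai}: largest big-leaf error {peak['rel_error_pct']:+.1f}% "
          f"at Q_o = {peak['q_o']:.0f} W m-2")

print("\nBecause stomata respond to light along a saturating curve, feeding the "
      "canopy-mean irradiance to one big leaf overestimates conductance in a "
      "moderate canopy, while in a dense canopy the halved effective LAI turns "
      "the bias into underestimation.")
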