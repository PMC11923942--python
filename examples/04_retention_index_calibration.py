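"""Retention-index conversion and data-driven threshold calibration.

Run:  python examples/04_retention_index_calibration.py
"""

import numpy as np

import hocscreen as h

# Kovats (n-alkane) indices from an electron-ionisation library are mapped
# onto the Fiehn (FAME) scale with a linear fit over shared compounds...
mapping = h.KovatsFiehnMap.fit(
    [(900.0, 1010.0), (1200.0, 1325.0), (1500.0, 1640.0), (2400.0, 2590.0)]
)
ri_kovats = 1500.0
ri_fiehn = h.kovats_to_fiehn(ri_kovats, mapping)
print(f"Kovats RI {ri_kovats:.0f} -> Fiehn RI {ri_fiehn:.1f} "
      f"(slope {mapping.slope:.4f}, intercept {mapping.intercept:.1f})")

# ...and Fiehn indices become retention times via a FAME anchor table.
cal = h.RICalibration(
    anchors=((800.0, 5.0), (1000.0, 10.0), (1400.0, 18.0), (2000.0, 30.0)),
)
rt, extrapolated = h.ri_to_rt(ri_fiehn, cal)
print(f"Fiehn RI {ri_fiehn:.1f} -> RT {rt:.2f} min"
      + (" (extrapolated)" if extrapolated else ""))

# RT matching thresholds are calibrated from measured-minus-reference
# residuals: mean ± SD bounds full confidence, mean ± 2 SD bounds exclusion.
rng = np.random.default_rng(0)
residuals = rng.normal(0.15, 0.69, size=36)
high, low = h.calibrate_rt_thresholds(residuals)
print(f"\ncalibrated RT intervals from {len(residuals)} residuals:")
print(f"  high confidence: [{high[0]:+.3f}, {high[1]:+.3f}] min")
print(f"  low  confidence: [{low[0]:+.3f}, {low[1]:+.3f}] min")
# The intervals keep any systematic bias of the reference source; a
# deviation inside the high interval scores 100%, outside the low one 0%.
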