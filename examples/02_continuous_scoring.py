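"""Continuous RT/CCS scoring and weighted fusion at the default operating point.

Run:  python examples/02_continuous_scoring.py
"""

import hocscreen as h

thresholds = h.default_thresholds()
ct_high, ct_low = thresholds.ccs_literature
print(f"literature-CCS thresholds: CT_high ±{ct_high}%, CT_low ±{ct_low}%")
for delta in (0.0, 1.5, 2.5, 3.5):
    score = h.continuous_score(delta, ct_high, ct_low)
    print(f"  ΔCCS {delta:+.1f}% -> score {score * 100:5.1f}%")
# 1.5% is inside the high-confidence band (100%); 2.5% sits midway between
# the bands (50%); 3.5% is beyond the low-confidence band (0%, excluded).

rt_high, rt_low = thresholds.rt_bounds("literature_converted")
print(f"\nliterature-RT intervals: high {rt_high} min, low {rt_low} min")
for delta in (0.0, 1.0, 2.0):
    score = h.continuous_score(delta, rt_high, rt_low)
    print(f"  ΔRT {delta:+.2f} min -> score {score * 100:5.1f}%")
# The RT intervals are asymmetric: the mean bias of the reference values is
# kept, so the decay starts and ends at different distances on each side.

cfg = h.ScoringConfig()
print(f"\nweights (RT, CCS, MS2) = {cfg.weights}, cutoff = {cfg.cutoff}")
for rt, ccs, ms2 in ((1.0, 1.0, 0.9), (1.0, 1.0, None), (0.5, 1.0, None)):
    fused = h.fuse_scores(rt, ccs, ms2, cfg)
    label = "retained" if fused >= cfg.cutoff else "rejected"
    ms2_text = "absent" if ms2 is None else f"{ms2:.2f}"
    print(f"  S_RT={rt:.2f} S_CCS={ccs:.2f} S_MS2={ms2_text} "
          f"-> {fused * 100:5.1f}%  ({label})")
# Without an MS2 score the fused score of a perfect RT+CCS match lands
# exactly on the 60% cutoff: fragmentation evidence is optional only when
# chromatography and mobility agree perfectly.
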