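"""Dominance dynamics of spine pairs: DiffIndex trends and class comparison.

Samples measured integrated-density series for MSB and single-bouton (SSB)
spine pairs at the default conditions, fits each pair's dominance rate, and
compares the two classes.
"""

import numpy as np

import msbdyn as m
import msbdyn.dynamics as dyn

cfg = m.SceneConfig(seed=3)  # 16 hourly frames, 5% intensity noise

fitted = {}
for cls in ("msb", "ssb"):
    fitted[cls] = [dyn.pair_dynamics(s.pair_id, cls, s.times, s.intden_a,
                                     s.intden_b, truth_rate=s.truth_rate)
                   for s in m.sample_pair_dynamics(cfg, 50, cls)]

one = fitted["msb"][0]
print("one MSB pair, first frames (time, IntDen_Dom, IntDen_Nondom, DiffIndex):")
for row in one.to_frame().head(4).itertuples(index=False):
    print(f"  {row.time_h:4.1f}  {row.intden_dom:8.0f}  {row.intden_nondom:8.0f}"
          f"  {row.diff_index:+.3f}")
print(f"  fitted rate {one.dominance_rate:+.4f} ΔDiffIndex/h "
      f"(truth {one.truth_rate:+.4f}), R² {one.r_squared:.3f}")

report = dyn.compare_classes(fitted["msb"], fitted["ssb"])
print(dyn.comparison_table(report).to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"))
print(f"rate fold (MSB/SSB): {report['rate_fold']:.1f}; "
      f"one-tailed t p = {report['rate_p_one_tailed']:.2g}")
# MSB pairs diverge steadily (one spine wins volume at the partner's
# expense) while SSB neighbor pairs drift around zero: the dominance rate
# separates the two classes by more than an order of magnitude.
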