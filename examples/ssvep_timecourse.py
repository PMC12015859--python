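"""SSVEP amplitude time courses for a small synthetic cohort.

Both the attended and the ignored plane carry a -30% post-cue amplitude
modulation (the study's central finding), which the Gabor-filter pipeline
recovers as percent change against the pre-cue baseline.

Run: python examples/ssvep_timecourse.py   (~1 minute)
"""

import numpy as np

from stereoattn import GroundTruth, generate_trial_schedule
from stereoattn.pipeline import ssvep_cohort
from stereoattn.ssvep import ssvep_inference

schedule = generate_trial_schedule(80, (80, 0, 0), n_blocks=4, seed=2)
gt = GroundTruth()                      # both envelopes dip to 0.70
att, ign, times = ssvep_cohort(12, schedule, gt, seed=7)
res = ssvep_inference(att, ign, times)

print(f"electrode cluster: {len(res.cluster)} posterior channels")
print(f"summary window {res.window_ms[0]:.0f}-{res.window_ms[1]:.0f} ms:")
print(f"  attended mean: {res.window_means[:, 0].mean():6.1f} % change")
print(f"  ignored mean : {res.window_means[:, 1].mean():6.1f} % change")
t = res.window_test
print(f"  attended vs ignored: t({t.df:.0f}) = {t.statistic:.3f}, "
      f"p = {t.p:.3f}, BF10 = {t.bf10:.3f}")
print("  -> both conditions drop ~30% below baseline with no difference "
      "between them: a non-selective modulation.")
sig = res.mask_attended_vs_baseline
if sig.any():
    print(f"attended course deviates from baseline from "
          f"{times[sig][0]:.0f} ms to {times[sig][-1]:.0f} ms "
          "(running FDR-corrected t-tests)")
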