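"""Windowed nonlinear Granger causality around one model discharge.

Computes prediction-improvement (PI) curves for the six directed pairs
among Cortex, VPM and RTN in 1 s moving windows, flags values above the
95th percentile of the interictal baseline, and summarizes the ictal
coupling increase.
"""
import numpy as np

from swdnet.experiments import build_pair, reference_pair_specs, seizure_trial
from swdnet.granger import GCParams, sliding_pi

full = build_pair(reference_pair_specs()[0])
trial = seizure_trial(full, trial_seed=3, duration_s=22.0)
ev = trial.discharge
print(f"discharge {ev.onset_s:.2f}-{ev.offset_s:.2f} s at {ev.dominant_frequency_hz:.0f} Hz\n")

params = GCParams(f_samp=trial.lfp.f_samp, step_s=0.25)
res = sliding_pi(
    trial.lfp, params, events=[ev], span=(1.5, 21.5), baseline_span=(2.0, 7.5)
)
t = res.times
print(f"{'pair':>14}  PI_baseline  PI_ictal  sig. ictal windows")
for (src, dst), pis in res.pi.items():
    base = pis[(t > 3.0) & (t < 7.5)].mean()
    ict = pis[(t > ev.onset_s + 1.0) & (t < ev.offset_s)].mean()
    flags = res.flags[(src, dst)]
    frac = flags[(t > ev.onset_s + 1.0) & (t < ev.offset_s)].mean()
    print(f"{src + '->' + dst:>14}  {base:10.3f}  {ict:8.3f}  {100 * frac:9.0f}%")
print(
    "\nPI rises during the discharge for most directed pairs: the "
    "synchronized rhythm makes each channel predictable from the others."
)
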