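"""Simulate a joint longitudinal-survival cohort with known ground truth.

Each subject carries a random intercept/slope pair driving both their
biomarker trajectory and their hazard of the event (association alpha).
"""
import numpy as np

from bigjm import SimulationConfig, simulate_joint_dataset

config = SimulationConfig(n_subjects=300, alpha=0.6, seed=42)
long, surv, truth = simulate_joint_dataset(config)

n_events = int(surv.records["event"].sum())
print(f"subjects:            {config.n_subjects}")
print(f"longitudinal records:{long.n_records:6d}")
print(f"events / censored:   {n_events} / {config.n_subjects - n_events}")
print(f"median follow-up:    {np.median(surv.records['observed_time']):.2f}")
print(f"true association:    alpha = {truth.alpha}")
# A positive alpha means subjects whose biomarker runs high are at elevated
# hazard, so their follow-up times are shorter on average.
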