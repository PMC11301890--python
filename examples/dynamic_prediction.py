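"""Dynamic subject-level prediction from a fitted joint model.

Given one subject's biomarker history up to a landmark time s, draw their
random effects from p(b | history, T > s) and convert each draw into a
conditional survival curve S(u | s) and a trajectory band.
"""
import numpy as np

from bigjm import (
    McmcConfig,
    ModelSpec,
    SimulationConfig,
    SubjectHistory,
    fit_big,
    predict_survival,
    predict_trajectory,
    simulate_joint_dataset,
)
from bigjm.data_io import validate_join

long, surv, _ = simulate_joint_dataset(SimulationConfig(n_subjects=200, seed=1))
pooled = fit_big(long, surv, mcmc=McmcConfig(n_iter=2000, n_burnin=500),
                 chunk_size=200, seed=1)
ds = validate_join(long, surv)

# pick a subject still at risk at the landmark s = 1.0
s = 1.0
alive = ds.survival.records.query("observed_time > @s").iloc[0]
sid = alive.subject_id
rec = ds.longitudinal.records.query("subject_id == @sid and time <= @s")
hist = SubjectHistory(
    subject_id=sid,
    times=rec["time"].to_numpy(),
    outcomes=rec["outcome"].to_numpy(),
    covariates=np.array([alive.w1]),
    landmark=s,
)

horizons = np.linspace(s, 2.5, 7)
sp = predict_survival(hist, pooled, ModelSpec(), pooled.basis, horizons,
                      n_draws=1000, seed=7)
tp = predict_trajectory(hist, pooled, ModelSpec(), pooled.basis, horizons,
                        n_draws=1000, seed=7)

print(f"subject {sid}: {len(rec)} biomarker records up to s = {s}")
print(f"{'horizon u':>9}  {'S(u|s)':>7}  {'95% band':>15}  {'biomarker':>9}")
for u, m, lo, hi, y in zip(horizons, sp.survival_mean, sp.survival_lower,
                           sp.survival_upper, tp.trajectory_mean):
    print(f"{u:>9.2f}  {m:>7.3f}  [{lo:.3f}, {hi:.3f}]  {y:>9.3f}")
# S(u|s) starts at 1 by construction and decreases with the horizon; the
# trajectory column is the expected biomarker value given the history.
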