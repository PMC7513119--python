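"""Entropy decay across the pre-shock pause and the crossing-time question.

Simulates two groups of records — 'successful' (large, irregular VF) and
'unsuccessful' (small, regular VF) — both with a slow amplitude decay
across a 22 s compression-free pause.  Slides a 3 s FuzzyEn window every
0.5 s across each pause, pools the points per group, fits entropy-vs-time
lines, compares their coefficients, and extrapolates how long a pause
would have to be for the successful-group level to decay to the
unsuccessful-group level.
"""

from vfshock import (
    EntropyParams,
    VfGenParams,
    compare_regressions,
    entropy_trajectory,
    fit_group_regression,
    generate_vf,
    time_to_cross,
)

params = EntropyParams(m=3, r=80.0)


def trajectories(amplitude, irregularity, label, n=10):
    out = []
    for seed in range(n):
        record = generate_vf(VfGenParams(
            seed=seed + (1000 if label else 0), amplitude=amplitude,
            irregularity=irregularity, decay_rate=1.5, pause_s=22.0))
        out.append(entropy_trajectory(record, record.shocks[0], params))
    return out


good = trajectories(300.0, 0.7, True)
poor = trajectories(110.0, 0.35, False)

fit_good = fit_group_regression(good)
fit_poor = fit_group_regression(poor)
comp = compare_regressions(fit_good, fit_poor)

print("group         intercept (nats)   slope (nats/min)   points")
print(f"successful    {fit_good.intercept:16.3f}   {fit_good.slope:16.3f}"
      f"   {fit_good.n:6d}")
print(f"unsuccessful  {fit_poor.intercept:16.3f}   {fit_poor.slope:16.3f}"
      f"   {fit_poor.n:6d}")
print(f"\ncoefficient comparison: intercept p = {comp.p_intercept:.2g}, "
      f"slope p = {comp.p_slope:.2g}")

if fit_good.slope < 0:
    t_cross = time_to_cross(fit_good.intercept, fit_poor.intercept,
                            fit_good.slope)
    print(f"\nAt the fitted decay, dropping from the successful level to the "
          f"unsuccessful level\nwould take {t_cross:.0f} s of untreated "
          "pause — the groups stay separated throughout\nany realistic "
          "pre-shock pause (10-30 s).")
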