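"""Verify analyzer precision from a 5-day × 5-replicate QC experiment.

Simulates a QC material measured five times a day for five days, then
decomposes the variance into repeatability (within-run) and
within-laboratory (between-run) components and applies a CV threshold.
"""

import numpy as np

import urised as u

rng = np.random.default_rng(0)
true_mean, sigma_within, sigma_between = 50.0, 2.0, 1.5
day_effects = rng.normal(0.0, sigma_between, size=5)
data = true_mean + day_effects[:, None] + rng.normal(0.0, sigma_within, (5, 5))

exp = u.PrecisionExperiment("RBC", "Level I", data, declared_interval=(35.0, 65.0))
result = u.ep15_precision(exp)
verdict = u.precision_verdict(result, threshold_pct=15.0,
                              declared_interval=exp.declared_interval,
                              measurements=exp.data)

print(f"grand mean        : {result.grand_mean:.2f} particles/µL")
print(f"s_r (within-run)  : {result.s_r:.3f}   CV {result.cv_within_run:.1f}%")
print(f"s_b (between-day) : {result.s_b:.3f}")
print(f"s_wl (within-lab) : {result.s_wl:.3f}   CV {result.cv_between_run:.1f}%")
print(f"pass at 15% CV    : {verdict.passed}")

print(
    "\ns_wl² = s_r² + s_b²: total within-laboratory imprecision combines "
    "repeatability and day-to-day drift; both CVs must stay within the "
    "declared threshold and all raw values inside the declared interval."
)
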