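"""Kaplan-Meier comparison of an altered vs unaltered cohort.

Simulates exponential overall-survival times for a genomically altered
group (median 87.7 months) and an unaltered group (median 163.5
months) with 30% independent censoring, fits product-limit curves with
Greenwood variance and log-log confidence bands, and compares the
groups with a log-rank test.
"""

from gemmomics import survival as sv
from gemmomics import synthdata as sd

cfg = sd.SynthConfig(
    seed=5,
    survival_medians={"altered": 87.7, "unaltered": 163.5},
    censor_rate=0.3,
    n_survival_per_group=500,
)
records = sd.gen_survival(cfg)
stat, p, curves = sv.km_compare(records, "altered", "unaltered")

for group, curve in curves.items():
    lo, hi = curve.median_ci
    print(f"{group:10s} median OS {curve.median:6.1f} months "
          f"(95% CI {lo:.1f}-{hi:.1f})")
print(f"log-rank chi2 = {stat:.1f}, p = {p:.3g}")

# The estimated medians should bracket the generating 87.7 / 163.5
# month medians, and the log-rank test should be decisive at n = 500
# per arm.
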