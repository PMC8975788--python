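"""Bootstrap-then-impute inference with BCa confidence intervals.

Runs a scaled-down stratified bootstrap (resampling within study x arm strata)
on data with MAR missingness; each replicate is completed by multivariate-normal
multiple imputation before fitting, and intervals are bias-corrected and
accelerated (acceleration from a leave-one-study-out jackknife). A full-scale
analysis would use B=5000 replicates and m=10 imputations.
"""

import ipdmed as im
from ipdmed.bootstrap import BootstrapConfig, run_bootstrap

design = im.preset_integrate_like()
ds, truth = im.generate_multistudy(design, seed=1)
masked = im.apply_mar_missingness(ds, design, rng=1)

cfg = BootstrapConfig(B=100, m=3, seed=7)
boot = run_bootstrap(masked, config=cfg)

print(f"replicates kept: {boot.estimates.shape[0]}  discarded: {boot.n_discarded}")
for name in ("std_a_PF", "std_b_med_per_sd", "std_indirect_PF", "std_total_PF"):
    r = boot[name]
    print(f"{name:>18}: {r['estimate']:+.4f}  95% BCa [{r['lo']:+.4f}, {r['hi']:+.4f}]")
print(f"true raw indirect (PF): {truth.indirect[im.Arm.PF]:+.5f}")
# 'estimate' is the mean over bootstrap replicates; the interval excludes zero
# when the mediated pathway is statistically credible at the 5% level.
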