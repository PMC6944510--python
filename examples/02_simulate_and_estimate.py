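"""Simulate a two-sample study with a known effect and run every estimator.

The generator produces three partially overlapping exposure GWAS sources,
two case-control outcome samples and an LD reference panel, with a true
causal log-OR of 0.37 per SD of exposure (OR ~ 1.45).  The pipeline steps
are: merge sources (largest-n wins), harmonize to the outcome, estimate.
"""

import numpy as np

from cismr import (
    SimulationConfig,
    egger,
    harmonize,
    ivw,
    merge_exposure_sources,
    pc_givw,
    simulate_two_sample,
    weighted_median,
)

cfg = SimulationConfig(seed=7, theta_true=0.37, ld_rho=0.3)
study = simulate_two_sample(cfg)

exposure = merge_exposure_sources(study.exposure_sources)
print("merged exposure sources ->", exposure.n_variants, "variants")
for label, kept in exposure.provenance:
    print(f"  {label}: {kept} records retained")

h = harmonize(exposure, study.outcome_samples[0])
print("harmonized:", h.audit)

est_ivw = ivw(h)
est_egger, diag = egger(h)
est_wm = weighted_median(h, n_boot=500, seed=cfg.seed)
est_pc = pc_givw(h, study.ld, kappa=0.99)

print(f"\ntrue log-OR per SD exposure: {cfg.theta_true} (OR {np.exp(cfg.theta_true):.2f})")
for est in (est_ivw, est_egger, est_wm, est_pc):
    extra = f" (k={est.n_components})" if est.n_components else ""
    print(
        f"{est.method:15s} theta={est.theta:+.3f} se={est.se:.3f} "
        f"OR={np.exp(est.theta):.2f} p={est.pvalue:.2g}{extra}"
    )
print(
    f"Egger intercept {diag.intercept:+.4f} (p={diag.intercept_p:.2f}), "
    f"I2_GX={100 * diag.i2_gx:.1f}%"
)
# With no pleiotropy in the generator all estimators agree within sampling
# error of the truth and the Egger intercept is consistent with zero.
# I2_GX well below 100% warns that the Egger slope (which regresses on the
# noisy exposure effects around their mean) is attenuated; the IVW and
# median estimates are much less affected at this instrument strength.
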