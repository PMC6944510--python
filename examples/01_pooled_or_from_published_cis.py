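"""Pool two published per-study odds ratios by fixed-effects meta-analysis.

Per-study MR odds ratios are often reported only as an OR with a 95% CI.
Back-transforming to the log scale (theta = ln OR, se from the CI width)
lets them be pooled with inverse-variance weights and tested for
heterogeneity with Cochran's Q.
"""

from cismr import meta_fixed, or_from_ci, present_or

# two case-control samples' IVW estimates for the same exposure-outcome pair
igap = or_from_ci(1.10, 0.85, 1.43)
pgc = or_from_ci(1.98, 1.02, 3.81)

pooled = meta_fixed([("IGAP", igap), ("PGC", pgc)])
por = present_or(pooled.theta_meta, pooled.se_meta, "per_unit_higher")

print(f"study 1: theta={igap.theta:.4f} se={igap.se:.4f}")
print(f"study 2: theta={pgc.theta:.4f} se={pgc.se:.4f}")
print(
    f"pooled OR {por.or_point:.2f} (95% CI {por.or_low:.2f}-{por.or_high:.2f}), "
    f"p={pooled.pvalue:.2f}"
)
print(f"heterogeneity Q={pooled.q_statistic:.2f} (df={pooled.q_df}, p={pooled.q_pvalue:.2f})")
# The pooled OR weights each study by its precision: the wide-CI second
# study contributes little, so the pooled estimate sits near the first.
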