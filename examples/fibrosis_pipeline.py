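"""End-to-end hidden-fibrosis comparison on a synthetic cohort.

Simulates the four-group infarct study (sham/infarct x close/far
section, n = 5 each), quantifies every sample by AFM stiffness, PSR and
SHG, and runs the group statistics.
"""

from cardioafm.pipeline import FibrosisConfig, run_fibrosis_pipeline

report = run_fibrosis_pipeline(FibrosisConfig(seed=11))

print(report.per_sample.groupby("group").mean(numeric_only=True).round(3))
print()
for metric, cmp in report.comparisons.items():
    far_close = cmp.pair("mi_far", "sham_close")
    far_far = cmp.pair("mi_far", "sham_far")
    print(f"{metric:15s} [{cmp.branch}] mi_far vs sham: "
          f"p_adj = {far_close.p_adjusted:.4f} / {far_far.p_adjusted:.4f}")
print()
print("hidden fibrosis detected:", report.hidden_fibrosis_detected())
# The far-infarct sections separate from sham on the stiffness metric but
# not on either collagen stain: ECM remodeling that stiffens the tissue
# without extra collagen I/III is invisible to the stains yet measurable
# by AFM -- the hidden-fibrosis signature.
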