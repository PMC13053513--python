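"""Run the full lesion-level evaluation pipeline on a synthetic cohort.

Per-feature discrimination is scored with leave-pair-out cross-validated
AUC; the combined 11-feature model's AUC above chance is attributed to
features with Shapley values; the index is dichotomized at the Youden-J
cutoff and the two groups compared with Kaplan-Meier / log-rank.
"""

from cvikit import CohortConfig, evaluate_cohort, sample_cohort

df = sample_cohort(CohortConfig(n_lesions=300, seed=11))
report = evaluate_cohort(df, n_boot=200, seed=11)

print("Single-feature LPOCV AUC ranking:")
for f in report["ranking"]:
    print(f"  {f:<10s} {report['per_feature_auc'][f]['auc']:.3f}")

print("\nShapley attribution of the combined model's AUC above 0.5:")
shap = report["shapley_delta_auc"]
for f in sorted(shap, key=shap.get, reverse=True):
    print(f"  {f:<10s} {shap[f]:+.4f}")

for b in report["bootstrap"]:
    print(f"\nModel '{b['model']}': AUC {b['auc']:.3f} "
          f"(95% bootstrap CI {b['ci_low']:.3f}-{b['ci_high']:.3f})")

cut = report["cutoff"]
km = report["km_logrank"]
print(f"\nYouden cutoff on cvi: {cut['threshold']:.3f} "
      f"(sens {cut['sensitivity']:.2f}, spec {cut['specificity']:.2f})")
print(f"Log-rank between index-high and index-low groups: "
      f"chi2 = {km['statistic']:.1f}, p = {km['p_value']:.2e}")
print("\nA mechanistically informative index should top both rankings and")
print("stratify event risk; chance-level AUC is 0.5.")
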