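"""Eye-clustered group comparison and diagnostic ROC on a simulated cohort.

Simulates a two-eye cohort with the reference study's group means (49 PD
subjects, 40 controls, inter-eye correlation 0.5), compares groups with
exchangeable-GEE models adjusted for age/sex/hypertension, and fits a
logistic-GEE diagnostic model for the strongest descriptor.
"""

import warnings

warnings.filterwarnings("ignore")

from octaquant.simulate import generate_cohort, reference_cohort_spec
from octaquant.stats import adjusted_comparison, diagnostic_model

df = generate_cohort(reference_cohort_spec(rho=0.5), seed=42)
print(f"{len(df)} eyes from {df.subject_id.nunique()} subjects")
print()
print(f"{'descriptor':24} {'PD':>14} {'control':>14} {'d':>5} {'p':>7} {'p adj':>7}")
for m in ("faz_area_mm2_dvc", "lacunarity_dvc", "fractal_dimension_svc",
          "perfusion_density_dvc"):
    r = adjusted_comparison(df, m)
    print(f"{m:24} {r['mean1']:7.3f}±{r['sd1']:5.3f} {r['mean2']:7.3f}±{r['sd2']:5.3f} "
          f"{r['cohens_d']:5.2f} {r['univariate_p']:7.4f} {r['multivariate_p']:7.4f}")

print()
fit, roc, summary = diagnostic_model(df, ["lacunarity_dvc"])
print(f"null model AUC (age+sex+hypertension): {summary['auc_null']:.3f}")
print(f"+ DVC lacunarity                     : {summary['auc_full']:.3f} "
      f"(95% CI {roc.ci_low:.2f}-{roc.ci_high:.2f})")
print(f"Wald test vs null: chi2={summary['wald_chi2']:.1f}, p={summary['wald_p']:.2g}")
print("the added descriptor carries diagnostic information beyond demographics")
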