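"""Cluster a dye cohort into six ordered sensitivity classes.

Generates a literature-compilation-shaped cohort (115 dyes, 10-30 solvents
each, sensitivities spanning negative to positive) and partitions it on the
fitted A.  Cluster 1 holds the most positively solvatochromic dyes.
"""

from solvachrom import cluster_by_A, cluster_summary, fit_sensitivity, generate_cohort

cohort, truth = generate_cohort(n_dyes=115, noise_sd=30.0, seed=7)
results = [fit_sensitivity(s) for s in cohort]
assignments = cluster_by_A(results, k=6, strategy="quantile")
summary = cluster_summary(assignments, results, cohort)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# each row is one sensitivity class: cluster 1 = strong positive
# solvatochromism (emission red-shifts fastest with polarity), cluster 6 =
# strong negative; the Stokes and quantum-yield columns show the pooled
# photophysical range of each class.
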