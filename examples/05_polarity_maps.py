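"""Build the diagnostic map tables and rank probe candidates.

Three scatter datasets summarise a clustered cohort — absorption vs
emission, Stokes shift vs -(nu_abs + nu_em), and quantum yield vs Stokes
shift — and two rankings select probes: large-|A| dyes for polarity
mapping, near-zero-A dyes with a wide quantum-yield swing for viscosity
(molecular-rotor) sensing.
"""

from solvachrom import (
    build_map,
    cluster_by_A,
    fit_sensitivity,
    frequency_diagram,
    generate_cohort,
    map_to_frame,
    select_probes,
)

cohort, _ = generate_cohort(n_dyes=40, noise_sd=30.0, seed=21)
results = [fit_sensitivity(s) for s in cohort]
assignments = cluster_by_A(results, k=6)

points = build_map("stokes_vs_negsum", cohort, results, assignments=assignments)
df = map_to_frame(points)
print(f"stokes_vs_negsum map: {len(df)} points, axes in 1000/cm")
print(df[["dye_id", "solvent", "cluster", "x", "y"]].head(4).to_string(index=False))

hist = frequency_diagram([r.A_stokes for r in results], bin_width=0.2)
print("\nfrequency diagram of fitted A (bin width 0.2):")
print(hist.to_string(index=False))

polarity, viscosity = select_probes(results, cohort)
print("\ntop polarity-mapping candidates (by |A|):")
print(polarity.head(3).to_string(index=False))
print("\ntop viscosity/rotor candidates (near-zero A, widest QY range):")
print(viscosity.head(3).to_string(index=False))
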