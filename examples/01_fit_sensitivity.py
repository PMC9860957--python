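"""Fit the solvatochromic parameters of a single dye series.

A dye measured in three solvents with exactly collinear band shifts:
the Stokes shift grows linearly as -(nu_abs + nu_em) increases, so the
three regressions determine A, B, C, D, E, F in closed form.
"""

from solvachrom import DyeSeries, SpectralRecord, fit_sensitivity, predict_emission

# band maxima chosen so nu_abs = 20.0, 19.8, 19.6 kK and
# nu_em = 19.0, 18.6, 18.2 kK
records = [
    SpectralRecord("demo", f"solvent{i}", 1e7 / (a * 1000), 1e7 / (e * 1000))
    for i, (a, e) in enumerate([(20.0, 19.0), (19.8, 18.6), (19.6, 18.2)], 1)
]
result = fit_sensitivity(DyeSeries("demo", records))

print(f"A (Stokes slope)      = {result.A_stokes:.6f}")
print(f"B (Stokes intercept)  = {result.B / 1000:.3f} kK")
print(f"C, E (abs/em slopes)  = {result.C:.6f}, {result.E:.6f}")
print(f"A from C - E          = {result.A_ce:.6f}")
print(f"E/C = mu_e/mu_g       = {result.ec_ratio:.6f}")
nu_em = predict_emission(result.A_stokes, result.B, 20000.0)
print(f"predicted nu_em at nu_abs = 20 kK: {nu_em / 1000:.3f} kK")

# A = 1/3 means the emission band red-shifts with solvent polarity three
# times faster than the absorption/emission mid-point moves; E/C = 2 says
# the excited-state dipole moment is twice the ground-state one.
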