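# Methods

## Model

The analysis rests on a semiempirical linearisation of continuum
solvation theory: across a solvent series, a dye's Stokes shift
(ν_abs − ν_em) and its band wavenumber sum (ν_abs + ν_em) are linearly
related, with the slope of

    ν_abs − ν_em = A·[−(ν_abs + ν_em)] + B

defining the solvatochromic sensitivity A.  No solvent polarity function
enters: the wavenumber sum itself plays the role of the (unknown,
monotone) solvent coordinate, which is what makes the method applicable
to heterogeneous literature data where only band maxima are reported.

Two companion regressions on the same regressor,
ν_abs = C·x + D and ν_em = E·x + F with x = −(ν_abs + ν_em), satisfy
C = −(1 − A)/2 and E = −(1 + A)/2 identically, giving two consistency
relations that hold exactly on noiseless data and approximately
otherwise: A = C − E, and E/C = (1 + A)/(1 − A).  For coplanar dipole
moments the theory reduces to scalars: A = (μe − μg)/(μe + μg) and
E/C = μe/μg.  The general vector form is
A = |μe − μg|² / (|μe|² − |μg|²), undefined when the magnitudes coincide
while the vectors differ; `sensitivity_from_dipoles` raises in that case.

Sign conventions, stated once and enforced by tests: the regressor is the
*negated* wavenumber sum, so slopes carry the conventional signs
(positive solvatochromism ⇒ A > 0, C and E both negative); Stokes shift
is ν_abs − ν_em > 0 for red-shifted emission; ν(cm⁻¹) = 10⁷/λ(nm) with
no refractive-index or vacuum correction.  The internal unit is cm⁻¹
everywhere; 1000/cm (kK) appears only at reporting boundaries
(`series_to_frame(units="kK")`, map tables).

## Estimation and diagnostics

All three fits are plain OLS (scipy's `linregress` for the point
estimates; standard errors computed from residuals with the classical
formulas, because the r-based error propagation loses precision near
exact fits).  No robust or weighted variant is offered: the method's
outputs are defined as plain regression coefficients.  When the response
has zero total variance the fit is a perfect constant and r² is reported
as 1 by convention (avoids 0/0).  Fewer than 3 points, or a regressor
with zero spread (all solvents giving the same ν_abs + ν_em), raise typed
errors naming the dye.

The primary reported sensitivity is the Stokes-line slope `A_stokes`;
`A_ce` = C − E is carried alongside as a consistency diagnostic.  The
`near_zero` flag marks dyes where the Stokes route is unreliable:
|A_stokes| < 0.1 or stderr(A) > |A_stokes|.  The 0.1 threshold is this
package's choice of where "A ≈ 0" begins; the flag is a heuristic —
under exactly flat bands with measurement noise, roughly a quarter of
replicate series still produce a nominally "significant" A by chance,
which is precisely why E/C (which stays near 1 there) is the better
near-zero diagnostic.  |A| ≥ 1 is reported but flagged `out_of_theory`:
the scalar dipole relation maps it to no physical ratio.  Observed
literature values slightly beyond ±1 can arise from regression noise or
non-coplanar dipole geometry; the package takes no position and simply
flags them.

Outlier solvents are never removed automatically (hydrogen-bonding
solvents are the usual suspects); `fit_sensitivity(exclude_solvents=...)`
and the duplicate-dispersion `exclude` list put that decision in the
user's hands.

## Clustering

The taxonomy is one-dimensional by design: A is the sole coordinate.
Because no authoritative interval-construction rule exists for this kind
of taxonomy, three are offered and the choice is explicit: `quantile`
(equal-frequency, the default — robust to the strong central peak of
near-zero dyes), `equal_width`, and `kmeans1d` (exact dynamic-programming
1-D k-means, O(k·n²), deterministic — implemented in-house because
library k-means is heuristic and seed-dependent).  Labels are 1-based
and descending in A.  Ties break on dye_id, so assignments are invariant
to input order.  All-equal A collapses to a single cluster with a
warning rather than an error.  Exact per-dye memberships therefore
depend on the chosen strategy; only the partition/order/stability
invariants are contractual.

## Duplicates

Structural identity uses standard InChI (stereo-aware, default layers)
computed from RDKit-parsed structures; SMILES from any writing of the
same molecule key identically.  Groups keep all members — their spread is
the measurement, not a defect — and the dispersion statistics are sample
SD (n − 1 denominator; a flag switches to population SD) and SD/√n.
Short series (6–9 solvents) excluded from the main fits may still join
duplicate groups; member solvent counts are carried through to the
output.

## Synthetic generator

The generator emulates the reaction-field mechanism: a solvent
coordinate f ∈ [0, 1] shifts the band origins linearly,
ν_abs = ν₀_abs − g·μg·(μe − μg)·f and ν_em = ν₀_em − g·μe·(μe − μg)·f,
with additive Gaussian band noise.  Under this model the fitted A equals
(μe − μg)/(μe + μg) exactly at zero noise, so recovery tests have 1e-9
oracles.  Defaults: band origins 20.5/19.5 kK (green-emitting dyes),
coupling g = 40 cm⁻¹ per unit dipole²·polarity (giving realistic
1000–2000 cm⁻¹ full-range shifts for μ ≈ 4–9), band noise 30 cm⁻¹
(≈ 1 nm reading error at 500 nm), quantum yield 0.9·exp(−3·10⁻⁴·Stokes)
clamped to [0, 1] — encoding the empirical tendency of yield to fall as
the Stokes shift grows.  Cohorts default to 115 dyes in 10–30 solvents
with A spanning −0.9…0.9 (requests beyond the open interval (−1, 1) are
clipped: scalar dipoles cannot produce them).  Duplicate injection
clones dyes under new ids with jittered band origins and fresh noise.

What the generator does *not* emulate: specific solvation
(hydrogen-bonding outliers), non-coplanar dipole geometry, band-shape
changes, temperature effects, or digitisation/rounding structure of
literature tables.  Passing recovery tests therefore demonstrate
correctness of the estimator under the linear-response model, not
robustness to every pathology of real compiled data.

## Numerical choices

- Wavenumber round-trips are exact to 1e-9 relative over 5–50 kK.
- Histogram bins are left-closed right-open, origin at the data minimum
  unless given; counts always conserve n.
- Random streams: one `numpy.random.default_rng` per generator call,
  seeded explicitly; cohort members draw child seeds from the parent
  stream, so any subset regenerates identically.
- Duplicate (dye, solvent) rows in input tables are kept and flagged;
  rows lacking either band maximum are skipped with a logged line
  number; quantum yield is optional and never blocks a row.
- Solvent names match case-insensitively after trimming; no synonym
  dictionary is attempted.

## Problem sizes

The test suite runs the estimator on series of 3–30 solvents, replicate
ensembles of 25–200 for noise-scaling and bias checks, and cohorts of
up to 120 series; `scripts/acceptance.py` uses a 115-dye cohort with 5
injected duplicate groups and 200-replicate recovery ensembles.  These
sizes match the scale of the literature compilations the package
targets.

## Known limitations

- The E/C ratio is numerically fragile when C → 0 (strongly negative A
  is fine; the pathological case is near A ≈ −1 where C → −1 and E → 0,
  harmless, versus C → 0 which cannot occur for |A| < 1 on-model but can
  on noisy data); it is reported as None when C = 0 exactly.
- OLS standard errors treat the regressor as fixed; since
  ν_abs + ν_em carries the same measurement noise as the response, the
  reported errors understate uncertainty for weakly solvatochromic dyes
  (see the near-zero flag discussion above).
- Dataset-level counts and duplicate-group statistics for any specific
  deposited compilation require that compilation's files; the pipeline
  reads them through `read_series_table`/`attach_structures` but ships
  no copy of third-party data.
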