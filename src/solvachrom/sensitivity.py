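"""Semiempirical solvatochromic-sensitivity regressions.

For a dye measured across solvents, three ordinary-least-squares lines are
fitted against the common regressor x = -(nu_abs + nu_em):

    nu_abs - nu_em = A * x + B        (Stokes-shift line)
    nu_abs         = C * x + D        (absorption line)
    nu_em          = E * x + F        (emission line)

so each slope is read directly with its conventional sign: A is the
solvatochromic sensitivity, and C, E relate to A as C = -(1 - A)/2,
E = -(1 + A)/2, hence A = C - E and E/C = (1 + A)/(1 - A).  For coplanar
ground/excited-state dipole moments mu_g, mu_e the theory gives
A = (mu_e - mu_g)/(mu_e + mu_g) and E/C = mu_e/mu_g, so the fitted E/C is a
direct estimate of the excited-to-ground dipole-magnitude ratio.

Sign hazard: the regressor is the *negated* wavenumber sum.  Regressing on
+(nu_abs + nu_em) flips every slope's sign and is the single most common
implementation error with this method.

The Stokes regression carries parameter A best when |A| is appreciable;
near A = 0 the Stokes shift is almost solvent-independent and the
absorption/emission lines (through E/C ~ 1) are the sharper diagnostic,
which the ``near_zero`` flag records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    SingularityError,
    UndefinedRatioError,
    UndefinedSensitivityError,
)
from .spectra_io import DyeSeries

#: |A_stokes| below this, or a slope standard error exceeding |A_stokes|,
#: marks a dye as near-zero-solvatochromic.
NEAR_ZERO_THRESHOLD = 0.1


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary: y = slope * x + intercept over n_points."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class DipolePair:
    """Ground/excited-state dipole moments, as magnitudes or 3-vectors."""

    mu_g: float | tuple[float, float, float]
    mu_e: float | tuple[float, float, float]


@dataclass(frozen=True)
class SensitivityResult:
    """Fitted solvatochromic parameters for one dye (wavenumbers in cm^-1).

    ``A_stokes`` is the primary sensitivity (Stokes-line slope); ``A_ce``
    = C - E is the consistency diagnostic from the absorption/emission
    lines — the two agree exactly on noiseless data.  ``ec_ratio`` = E/C
    estimates mu_e/mu_g.  ``out_of_theory`` flags |A| >= 1, which maps
    outside physical dipole ratios.
    """

    dye_id: str
    A_stokes: float
    B: float
    C: float
    D: float
    E: float
    F: float
    A_ce: float
    ec_ratio: float | None
    near_zero: bool
    out_of_theory: bool
    n_solvents: int
    fit_stokes: RegressionFit
    fit_abs: RegressionFit
    fit_em: RegressionFit


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares with classical standard errors.

    Requires >= 3 points and non-constant x.  When y has zero total
    variance the fit is a perfect constant and r^2 is reported as 1
    (avoids 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in regressor")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # perfect fit of a constant: slope 0, r2 = 1 by convention,
        # zero standard errors (linregress yields NaNs here)
        return RegressionFit(
            slope=0.0,
            intercept=float(y.mean()),
            stderr_slope=0.0,
            stderr_intercept=0.0,
            r2=1.0,
            n_points=n,
        )
    res = stats.linregress(x, y)
    # standard errors from residuals rather than from r: the r-based route
    # loses precision catastrophically near exact fits
    resid = y - res.slope * x - res.intercept
    ss_res = float(np.sum(resid**2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    s2 = ss_res / (n - 2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=math.sqrt(s2 / sxx),
        stderr_intercept=math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)),
        r2=1.0 - ss_res / ss_tot,
        n_points=n,
    )


def fit_sensitivity(
    series: DyeSeries, exclude_solvents: Sequence[str] | None = None
) -> SensitivityResult:
    """Fit the three solvatochromic regressions for one dye series.

    Parameters
    ----------
    series
        Dye series with >= 3 records carrying both band maxima.
    exclude_solvents
        Optional solvent names (case-insensitive) to drop before fitting,
        e.g. hydrogen-bonding outliers the user has identified.
    """
    excl = {s.strip().lower() for s in exclude_solvents} if exclude_solvents else set()
    points = [
        pt
        for rec, pt in zip(series.records, series.wavenumber_points())
        if rec.solvent.strip().lower() not in excl
    ]
    if len(points) < 3:
        raise InsufficientDataError(
            f"{series.dye_id}: only {len(points)} usable solvents (need >= 3)"
        )
    x = np.array([-p.nu_sum for p in points])
    if np.ptp(x) == 0:
        raise DegenerateDesignError(
            f"{series.dye_id}: all solvents give identical nu_abs + nu_em"
        )
    stokes = np.array([p.stokes for p in points])
    nu_abs = np.array([p.nu_abs for p in points])
    nu_em = np.array([p.nu_em for p in points])

    fit_st = fit_line(x, stokes)
    fit_ab = fit_line(x, nu_abs)
    fit_em_ = fit_line(x, nu_em)

    A = fit_st.slope
    C, E = fit_ab.slope, fit_em_.slope
    ec = E / C if C != 0 else None
    near_zero = abs(A) < NEAR_ZERO_THRESHOLD or fit_st.stderr_slope > abs(A)
    return SensitivityResult(
        dye_id=series.dye_id,
        A_stokes=A,
        B=fit_st.intercept,
        C=C,
        D=fit_ab.intercept,
        E=E,
        F=fit_em_.intercept,
        A_ce=C - E,
        ec_ratio=ec,
        near_zero=near_zero,
        out_of_theory=abs(A) >= 1.0,
        n_solvents=len(points),
        fit_stokes=fit_st,
        fit_abs=fit_ab,
        fit_em=fit_em_,
    )


def sensitivity_from_dipoles(d: DipolePair, tol: float = 1e-12) -> float:
    """Theoretical A from ground/excited dipole moments.

    Scalar inputs: A = (mu_e - mu_g)/(mu_e + mu_g).
    Vector inputs: A = |mu_e - mu_g|^2 / (|mu_e|^2 - |mu_g|^2); undefined
    when the magnitudes are equal but the vectors differ.
    """
    scalar_g = np.isscalar(d.mu_g)
    scalar_e = np.isscalar(d.mu_e)
    if scalar_g and scalar_e:
        mu_g, mu_e = float(d.mu_g), float(d.mu_e)
        if mu_g < 0 or mu_e < 0:
            raise UndefinedSensitivityError("dipole magnitudes must be >= 0")
        if abs(mu_e + mu_g) <= tol:
            raise UndefinedSensitivityError("both dipole moments are zero")
        return (mu_e - mu_g) / (mu_e + mu_g)
    g = np.asarray(d.mu_g, dtype=float)
    e = np.asarray(d.mu_e, dtype=float)
    num = float(np.dot(e - g, e - g))
    den = float(np.dot(e, e) - np.dot(g, g))
    if abs(den) <= tol:
        if num <= tol:
            raise UndefinedSensitivityError("both dipole moments are zero")
        raise UndefinedSensitivityError(
            "|mu_e| == |mu_g| with mu_e != mu_g: A undefined (division by zero)"
        )
    return num / den


def dipole_ratio(result: SensitivityResult) -> float:
    """Estimated mu_e/mu_g ratio, i.e. the fitted E/C."""
    if result.ec_ratio is None:
        raise UndefinedRatioError(f"{result.dye_id}: C = 0, E/C undefined")
    return result.ec_ratio


def predict_emission(A: float, B: float, nu_abs: float) -> float:
    """Predicted emission wavenumber from the fitted Stokes line.

    nu_em = ((1 + A)/(1 - A)) * nu_abs - B/(1 - A); singular at A = 1.
    """
    if math.isclose(A, 1.0, rel_tol=0.0, abs_tol=1e-15):
        raise SingularityError("prediction undefined at A = 1")
    return (1 + A) / (1 - A) * nu_abs - B / (1 - A)


def results_to_frame(results: Sequence[SensitivityResult]):
    """One row per dye with parameters, standard errors and r^2 values."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "dye_id": r.dye_id,
                "A_stokes": r.A_stokes,
                "B_cm1": r.B,
                "C": r.C,
                "D_cm1": r.D,
                "E": r.E,
                "F_cm1": r.F,
                "A_ce": r.A_ce,
                "ec_ratio": r.ec_ratio,
                "near_zero": r.near_zero,
                "out_of_theory": r.out_of_theory,
                "n_solvents": r.n_solvents,
                "stderr_A": r.fit_stokes.stderr_slope,
                "stderr_B_cm1": r.fit_stokes.stderr_intercept,
                "r2_stokes": r.fit_stokes.r2,
                "r2_abs": r.fit_abs.r2,
                "r2_em": r.fit_em.r2,
            }
        )
    return pd.DataFrame(rows)
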