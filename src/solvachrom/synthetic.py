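"""Physics-grounded synthetic dye-solvent series with known sensitivity.

The generator produces band maxima from a reaction-field picture: a solvent
coordinate f in [0, 1] (an empirical stand-in for any of the usual polarity
functions) shifts the absorption and emission origins linearly,

    nu_abs(f) = nu0_abs - coupling * mu_g * (mu_e - mu_g) * f + eps
    nu_em(f)  = nu0_em  - coupling * mu_e * (mu_e - mu_g) * f + eps'

with mu_g, mu_e the ground/excited-state dipole magnitudes and eps Gaussian
measurement noise.  Under this model the Stokes shift regressed on
-(nu_abs + nu_em) has slope exactly (mu_e - mu_g)/(mu_e + mu_g) — the
solvatochromic sensitivity A — and E/C = mu_e/mu_g, so every fitted
parameter has a known ground truth.  Negative solvatochromism arises from
mu_e < mu_g; no separate mechanism is modelled.

The quantum yield follows the empirical trend that larger Stokes shifts
accompany lower yields: QY = clamp(qy0 * exp(-qy_decay * stokes), 0, 1).

Structures for synthetic dyes come from a short internal list of valid
SMILES (a boron-dipyrromethene core among simple molecules) so that
structure-dependent code paths run; the chemistry is placeholder by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectra_io import DyeSeries, SpectralRecord, wavenumber_to_nm

#: Valid placeholder SMILES; index 0 is a BODIPY (dipyrrin-BF2) core.
SYNTHETIC_SMILES = (
    "[B-]1(F)(F)n2cccc2C=C2C=CC=[N+]12",  # unsubstituted BODIPY core
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "c1ccc2ccccc2c1",
    "CN(C)c1ccc(C=O)cc1",
    "Oc1ccc2ccccc2c1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic dye series.

    Parameters
    ----------
    mu_g, mu_e
        Ground/excited-state dipole magnitudes (arbitrary consistent
        units; Debye-like scale).
    nu0_abs, nu0_em
        Zero-polarity band origins, cm^-1.  Defaults sit in the green
        (~500 nm) region typical of small fluorophores.
    coupling
        Reaction-field scale, cm^-1 per (dipole^2 * polarity unit).
    polarity_values
        Solvent coordinates f_i in [0, 1]; one synthetic solvent each.
    noise_sd
        Gaussian noise on each band position, cm^-1 (~1 nm reading error
        at 500 nm is ~40 cm^-1).
    qy0, qy_decay
        Zero-Stokes quantum yield and its exponential decay per cm^-1 of
        Stokes shift.
    seed
        Seed for the per-call random generator.
    """

    mu_g: float
    mu_e: float
    polarity_values: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 12))
    nu0_abs: float = 20500.0
    nu0_em: float = 19500.0
    coupling: float = 40.0
    noise_sd: float = 0.0
    qy0: float = 0.9
    qy_decay: float = 3e-4
    seed: int = 0
    dye_id: str = "SYN-1"
    structure: str | None = SYNTHETIC_SMILES[0]

    def __post_init__(self) -> None:
        if self.mu_g < 0 or self.mu_e < 0:
            raise ValidationError("dipole magnitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if len(self.polarity_values) < 3:
            raise ValidationError("need >= 3 polarity values")
        if not 0 < self.qy0 <= 1:
            raise ValidationError("qy0 must be in (0, 1]")

    @property
    def true_A(self) -> float:
        """Ground-truth sensitivity (mu_e - mu_g)/(mu_e + mu_g)."""
        return (self.mu_e - self.mu_g) / (self.mu_e + self.mu_g)


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    table: pd.DataFrame  # dye_id, mu_g, mu_e, true_A, n_solvents, dup_group
    seed: int


def generate_series(spec: SyntheticSpec) -> DyeSeries:
    """Generate one dye series from a :class:`SyntheticSpec`.

    Deterministic for a fixed spec (one seeded generator per call).
    Solvent names are "S01".."Sn" in polarity order.
    """
    rng = np.random.default_rng(spec.seed)
    dmu = spec.mu_e - spec.mu_g
    records = []
    for i, f in enumerate(spec.polarity_values, start=1):
        nu_abs = spec.nu0_abs - spec.coupling * spec.mu_g * dmu * f
        nu_em = spec.nu0_em - spec.coupling * spec.mu_e * dmu * f
        if spec.noise_sd > 0:
            nu_abs += rng.normal(0.0, spec.noise_sd)
            nu_em += rng.normal(0.0, spec.noise_sd)
        stokes = nu_abs - nu_em
        qy = min(max(spec.qy0 * math.exp(-spec.qy_decay * stokes), 0.0), 1.0)
        records.append(
            SpectralRecord(
                dye_id=spec.dye_id,
                solvent=f"S{i:02d}",
                lambda_abs=wavenumber_to_nm(nu_abs),
                lambda_em=wavenumber_to_nm(nu_em),
                quantum_yield=qy,
                source_ref="synthetic",
            )
        )
    return DyeSeries(dye_id=spec.dye_id, records=records, structure=spec.structure)


def _dipoles_for_A(A: float, mu_sum: float = 10.0) -> tuple[float, float]:
    """Dipole pair with the requested sensitivity and fixed mu_g + mu_e."""
    mu_e = mu_sum * (1 + A) / 2
    mu_g = mu_sum * (1 - A) / 2
    return mu_g, mu_e


def generate_cohort(
    n_dyes: int = 115,
    A_range: tuple[float, float] = (-0.9, 0.9),
    solvents_per_dye_range: tuple[int, int] = (10, 30),
    noise_sd: float = 30.0,
    seed: int = 0,
) -> tuple[list[DyeSeries], CohortTruth]:
    """Generate a cohort of dye series spanning a sensitivity range.

    Defaults emulate the shape of a literature compilation: ~115 dyes,
    each measured in 10-30 solvents, with sensitivities from strongly
    negative to strongly positive.  Requested A bounds outside the scalar
    theory's open codomain (-1, 1) are clipped to +/-0.99 with a warning.
    """
    import logging

    lo, hi = A_range
    if lo > hi:
        raise ValidationError("A_range must be (low, high)")
    clipped = (max(lo, -0.99), min(hi, 0.99))
    if clipped != (lo, hi):
        logging.getLogger(__name__).warning(
            "A range %s clipped to %s: |A| >= 1 cannot arise from scalar dipoles",
            A_range,
            clipped,
        )
    lo, hi = clipped
    rng = np.random.default_rng(seed)
    series: list[DyeSeries] = []
    truth_rows = []
    if n_dyes > 0:
        A_targets = np.linspace(lo, hi, n_dyes) if n_dyes > 1 else [0.5 * (lo + hi)]
        for i, A in enumerate(A_targets, start=1):
            mu_g, mu_e = _dipoles_for_A(float(A))
            n_solv = int(rng.integers(solvents_per_dye_range[0],
                                      solvents_per_dye_range[1] + 1))
            spec = SyntheticSpec(
                mu_g=mu_g,
                mu_e=mu_e,
                polarity_values=tuple(np.linspace(0.0, 1.0, n_solv)),
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                dye_id=f"SYN-{i:03d}",
                # unique placeholder structure per dye (homologous alkanes)
                # so accidental duplicate groups cannot arise
                structure=SYNTHETIC_SMILES[0] if i == 1 else "C" * i,
            )
            series.append(generate_series(spec))
            truth_rows.append(
                {
                    "dye_id": spec.dye_id,
                    "mu_g": mu_g,
                    "mu_e": mu_e,
                    "true_A": spec.true_A,
                    "n_solvents": n_solv,
                    "dup_group": None,
                }
            )
    truth = CohortTruth(
        table=pd.DataFrame(
            truth_rows,
            columns=["dye_id", "mu_g", "mu_e", "true_A", "n_solvents", "dup_group"],
        ),
        seed=seed,
    )
    return series, truth


def inject_duplicates(
    cohort: Sequence[DyeSeries],
    truth: CohortTruth,
    n_groups: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[DyeSeries], CohortTruth]:
    """Clone dyes under new ids with identical structures to form duplicates.

    Each selected dye gains one clone whose measurements are re-generated
    with band origins jittered by ``jitter_sd`` (cm^-1), emulating an
    independent study of the same compound.  Truth table gains a
    ``dup_group`` label shared by each original/clone pair.
    """
    if n_groups < 0 or n_groups > len(cohort) // 2:
        raise ValidationError("n_groups must be in [0, n_dyes/2]")
    if n_groups == 0:
        return list(cohort), truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cohort), size=n_groups, replace=False)
    out = list(cohort)
    table = truth.table.copy()
    for g_idx, c in enumerate(sorted(chosen), start=1):
        orig = cohort[c]
        row = table.loc[table["dye_id"] == orig.dye_id].iloc[0]
        clone_id = f"{orig.dye_id}-dup"
        spec = SyntheticSpec(
            mu_g=float(row["mu_g"]),
            mu_e=float(row["mu_e"]),
            polarity_values=tuple(
                np.linspace(0.0, 1.0, int(row["n_solvents"]))
            ),
            nu0_abs=20500.0 + rng.normal(0.0, jitter_sd),
            nu0_em=19500.0 + rng.normal(0.0, jitter_sd),
            noise_sd=jitter_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            dye_id=clone_id,
            structure=orig.structure,
        )
        clone = generate_series(spec)
        out.append(clone)
        table.loc[table["dye_id"] == orig.dye_id, "dup_group"] = f"G{g_idx}"
        clone_row = {
            "dye_id": clone_id,
            "mu_g": row["mu_g"],
            "mu_e": row["mu_e"],
            "true_A": row["true_A"],
            "n_solvents": row["n_solvents"],
            "dup_group": f"G{g_idx}",
        }
        table = pd.concat([table, pd.DataFrame([clone_row])], ignore_index=True)
    return out, CohortTruth(table=table, seed=truth.seed)


def series_with_seed(spec: SyntheticSpec, seed: int) -> DyeSeries:
    """Regenerate a spec's series under a different noise seed."""
    return generate_series(replace(spec, seed=seed))
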