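"""Duplicate-structure detection and reproducibility statistics.

Literature datasets often contain the same dye measured independently by
different groups under different dye_ids.  Grouping by canonical structure
(standard InChI) identifies these duplicates, and the dispersion of their
fitted sensitivities A — sample SD and SD/sqrt(n) — gives an empirical
estimate of the method's reproducibility across laboratories.  Unlike a
conventional deduplication, members are retained: their spread is the
signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import InsufficientDataError, ValidationError
from .sensitivity import SensitivityResult
from .spectra_io import DyeSeries, to_wavenumber_point

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit warnings go through our logger instead


@dataclass(frozen=True)
class DuplicateGroup:
    """Dyes sharing one canonical structure, with their A dispersion."""

    group_key: str
    member_ids: tuple[str, ...]
    A_values: tuple[float, ...]
    solvent_counts: tuple[int, ...]
    sd: float
    sem: float

    @property
    def n(self) -> int:
        return len(self.member_ids)


def canonical_key(structure: str) -> str:
    """Canonical, input-order-independent key for a structure (standard InChI).

    Two SMILES of the same molecule map to the same key; stereo-aware.
    """
    mol = Chem.MolFromSmiles(structure) if structure else None
    if mol is None:
        raise ValidationError(f"unparsable structure {structure!r}")
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise ValidationError(f"InChI generation failed for {structure!r}")
    return inchi


def _dispersion(values: Sequence[float], population: bool = False) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    ddof = 0 if population else 1
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    sd = math.sqrt(var)
    return sd, sd / math.sqrt(n)


def find_duplicates(
    series: Sequence[DyeSeries],
    results: Mapping[str, SensitivityResult] | Sequence[SensitivityResult],
    population_sd: bool = False,
) -> list[DuplicateGroup]:
    """Group structurally identical dyes and quantify their A dispersion.

    Parameters
    ----------
    series
        Dye series with structures attached; series without a parsable
        structure are excluded (logged).
    results
        Fitted sensitivities, keyed by dye_id (a sequence is accepted and
        keyed automatically).  Members without a fit are dropped from the
        dispersion but their presence is still logged.
    population_sd
        Use the n denominator instead of the default sample (n-1) one.

    Returns
    -------
    list of DuplicateGroup with >= 2 members, sorted by group size then key.
    """
    if not isinstance(results, Mapping):
        results = {r.dye_id: r for r in results}
    by_key: dict[str, list[DyeSeries]] = {}
    for s in series:
        if not s.structure:
            continue
        try:
            key = canonical_key(s.structure)
        except ValidationError as exc:
            logger.warning("%s excluded from duplicate analysis: %s", s.dye_id, exc)
            continue
        by_key.setdefault(key, []).append(s)

    groups: list[DuplicateGroup] = []
    for key, members in by_key.items():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda s: s.dye_id)
        fitted = [m for m in members if m.dye_id in results]
        if len(fitted) < 2:
            logger.warning(
                "duplicate group %s: fewer than 2 fitted members; skipped", key
            )
            continue
        A_vals = [results[m.dye_id].A_stokes for m in fitted]
        sd, sem = _dispersion(A_vals, population=population_sd)
        groups.append(
            DuplicateGroup(
                group_key=key,
                member_ids=tuple(m.dye_id for m in fitted),
                A_values=tuple(A_vals),
                solvent_counts=tuple(m.n_solvents for m in fitted),
                sd=sd,
                sem=sem,
            )
        )
    groups.sort(key=lambda g: (-g.n, g.group_key))
    return groups


def group_dispersion(
    group: DuplicateGroup,
    exclude: Sequence[str] = (),
    population_sd: bool = False,
) -> tuple[float, float]:
    """Sample SD and SD/sqrt(n) of the group's A values after exclusions.

    ``exclude`` names member dye_ids to drop (e.g. a known outlier study);
    at least two values must remain.
    """
    retained = [
        a for m, a in zip(group.member_ids, group.A_values) if m not in set(exclude)
    ]
    if len(retained) < 2:
        raise InsufficientDataError(
            f"group {group.group_key}: fewer than 2 values after exclusion"
        )
    return _dispersion(retained, population=population_sd)


def per_solvent_comparison(
    group: DuplicateGroup, series: Sequence[DyeSeries]
) -> pd.DataFrame:
    """Cross-study spread per shared solvent for one duplicate group.

    For each solvent measured by >= 2 members, reports the spread of
    nu_abs, nu_em, Stokes shift (cm^-1) and quantum yield.  Empty when the
    members' solvent sets are disjoint.
    """
    by_id = {s.dye_id: s for s in series}
    per_solvent: dict[str, list[tuple[str, float, float, float, float | None]]] = {}
    for dye_id in group.member_ids:
        s = by_id.get(dye_id)
        if s is None:
            continue
        for rec in s.records:
            pt = to_wavenumber_point(rec)
            per_solvent.setdefault(rec.solvent.strip().lower(), []).append(
                (dye_id, pt.nu_abs, pt.nu_em, pt.stokes, rec.quantum_yield)
            )
    rows = []
    for solvent, entries in sorted(per_solvent.items()):
        if len(entries) < 2:
            continue
        nu_abs = [e[1] for e in entries]
        nu_em = [e[2] for e in entries]
        stokes = [e[3] for e in entries]
        qy = [e[4] for e in entries if e[4] is not None]
        rows.append(
            {
                "group_key": group.group_key,
                "solvent": solvent,
                "n_studies": len(entries),
                "members": ";".join(e[0] for e in entries),
                "delta_nu_abs_cm1": max(nu_abs) - min(nu_abs),
                "delta_nu_em_cm1": max(nu_em) - min(nu_em),
                "delta_stokes_cm1": max(stokes) - min(stokes),
                "delta_qy": (max(qy) - min(qy)) if len(qy) >= 2 else None,
            }
        )
    if not rows:
        logger.info("group %s: no solvent shared by >= 2 members", group.group_key)
    return pd.DataFrame(
        rows,
        columns=[
            "group_key",
            "solvent",
            "n_studies",
            "members",
            "delta_nu_abs_cm1",
            "delta_nu_em_cm1",
            "delta_stokes_cm1",
            "delta_qy",
        ],
    )


def groups_to_frame(groups: Sequence[DuplicateGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_key": g.group_key,
                "n": g.n,
                "members": ";".join(g.member_ids),
                "solvent_counts": ";".join(map(str, g.solvent_counts)),
                "A_values": ";".join(f"{a:.6g}" for a in g.A_values),
                "sd_A": g.sd,
                "sem_A": g.sem,
            }
            for g in groups
        ]
    )
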