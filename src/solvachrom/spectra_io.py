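"""Reading, validation and unit conversion for dye-solvent spectral tables.

A measurement campaign for a solvatochromic dye produces one row per
(dye, solvent) pair: the absorption and emission band maxima in nm and,
when reported, the fluorescence quantum yield.  This module turns such
delimited-text tables into validated :class:`DyeSeries` objects and converts
band positions to wavenumbers (cm^-1), the energy-linear unit in which the
solvatochromic regressions are carried out.

Internal unit is cm^-1 throughout; tables destined for plotting are emitted
in 1000/cm (kilokayser, kK) only at the reporting boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: cm^-1 per kK; applied only when emitting plot tables.
CM1_PER_KK = 1000.0

MANDATORY_COLUMNS = ("dye_id", "solvent", "lambda_abs_nm", "lambda_em_nm")
OPTIONAL_COLUMNS = ("quantum_yield", "smiles", "ref")


def nm_to_wavenumber(lambda_nm: float) -> float:
    """Convert a wavelength in nm to a wavenumber in cm^-1 (nu = 1e7 / lambda)."""
    if not lambda_nm > 0:
        raise ValidationError(f"wavelength must be positive, got {lambda_nm!r}")
    return 1e7 / lambda_nm


def wavenumber_to_nm(nu_cm1: float) -> float:
    """Convert a wavenumber in cm^-1 to a wavelength in nm."""
    if not nu_cm1 > 0:
        raise ValidationError(f"wavenumber must be positive, got {nu_cm1!r}")
    return 1e7 / nu_cm1


@dataclass(frozen=True)
class SpectralRecord:
    """One dye-in-one-solvent measurement.

    Parameters
    ----------
    dye_id
        Opaque identifier of the dye (e.g. "2009 Aroyo-1").
    solvent
        Solvent name as reported.
    lambda_abs, lambda_em
        Absorption and emission band maxima, nm.
    quantum_yield
        Fluorescence quantum yield in [0, 1], or None when unreported.
    source_ref
        Free-text literature citation tag.
    """

    dye_id: str
    solvent: str
    lambda_abs: float
    lambda_em: float
    quantum_yield: float | None = None
    source_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.lambda_abs > 0:
            raise ValidationError(
                f"{self.dye_id}/{self.solvent}: lambda_abs must be > 0"
            )
        if not self.lambda_em > 0:
            raise ValidationError(
                f"{self.dye_id}/{self.solvent}: lambda_em must be > 0"
            )
        if self.quantum_yield is not None and not 0 <= self.quantum_yield <= 1:
            raise ValidationError(
                f"{self.dye_id}/{self.solvent}: quantum yield "
                f"{self.quantum_yield} outside [0, 1]"
            )


@dataclass(frozen=True)
class WavenumberPoint:
    """Wavenumber-space view of one measurement (all fields cm^-1).

    ``nu_sum = nu_abs + nu_em`` is the regressor of the solvatochromic fits
    (negated); ``stokes = nu_abs - nu_em`` is the Stokes shift, positive
    whenever emission lies to the red of absorption.
    """

    nu_abs: float
    nu_em: float
    nu_sum: float = field(init=False)
    stokes: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nu_sum", self.nu_abs + self.nu_em)
        object.__setattr__(self, "stokes", self.nu_abs - self.nu_em)


def to_wavenumber_point(rec: SpectralRecord) -> WavenumberPoint:
    """Convert a record's band maxima to a :class:`WavenumberPoint`."""
    return WavenumberPoint(
        nu_abs=nm_to_wavenumber(rec.lambda_abs),
        nu_em=nm_to_wavenumber(rec.lambda_em),
    )


@dataclass
class DyeSeries:
    """A dye's measurements across solvents, plus an optional structure.

    Solvent names must be unique within a series; structure is a SMILES
    string or None.
    """

    dye_id: str
    records: list[SpectralRecord]
    structure: str | None = None

    @property
    def n_solvents(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.dye_id != self.dye_id:
                raise ValidationError(
                    f"record dye_id {rec.dye_id!r} != series {self.dye_id!r}"
                )

    def wavenumber_points(self) -> list[WavenumberPoint]:
        return [to_wavenumber_point(r) for r in self.records]


@dataclass
class TableReadResult:
    """Partition of a spectral table: included, excluded (short) and skipped rows.

    ``included`` + rows of ``excluded`` + ``n_skipped`` always accounts for
    every data row of the file.
    """

    included: list[DyeSeries]
    excluded: list[DyeSeries]
    n_skipped: int
    skipped_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def all_series(self) -> list[DyeSeries]:
        return self.included + self.excluded


def _normalise_solvent(name: str) -> str:
    return str(name).strip().lower()


def read_series_table(
    path: str | Path,
    min_solvents: int = 10,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TableReadResult:
    """Read a delimited dye-solvent table and group rows into series.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header.  Mandatory columns:
        ``dye_id, solvent, lambda_abs_nm, lambda_em_nm``; optional:
        ``quantum_yield, smiles, ref``.
    min_solvents
        Series with fewer distinct measurements go to ``excluded`` (kept,
        not dropped: short six-to-nine-solvent series still feed the
        duplicate-dispersion analysis).
    sep
        Field separator; None auto-detects comma vs tab from the header.
    column_map
        Optional mapping from the canonical column names to the names used
        in the file, for deposited tables with a different layout.

    Returns
    -------
    TableReadResult
        Included series, excluded (short) series, and skipped-row count.
    """
    path = Path(path)
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    rename = dict(column_map) if column_map else {}
    actual = {canon: rename.get(canon, canon) for canon in MANDATORY_COLUMNS}
    missing = [col for col in actual.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    opt_actual = {c: rename.get(c, c) for c in OPTIONAL_COLUMNS}

    if df.empty:
        logger.warning("%s: empty table", path)
        return TableReadResult(included=[], excluded=[], n_skipped=0)

    records_by_dye: dict[str, list[SpectralRecord]] = {}
    smiles_by_dye: dict[str, str] = {}
    skipped: list[tuple[int, str]] = []
    seen_pairs: set[tuple[str, str]] = set()

    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        dye_id = str(row[actual["dye_id"]]).strip()
        solvent = str(row[actual["solvent"]]).strip()
        try:
            lam_abs = float(row[actual["lambda_abs_nm"]])
            lam_em = float(row[actual["lambda_em_nm"]])
        except (TypeError, ValueError):
            reason = "unparsable band maximum"
            logger.warning("%s line %d: %s; row skipped", path, line_no, reason)
            skipped.append((line_no, reason))
            continue
        qy: float | None = None
        qy_col = opt_actual["quantum_yield"]
        if qy_col in df.columns and str(row[qy_col]).strip():
            try:
                qy = float(row[qy_col])
            except ValueError:
                qy = None  # QY is optional; a bad cell does not kill the row
        ref_col = opt_actual["ref"]
        ref = str(row[ref_col]).strip() or None if ref_col in df.columns else None
        try:
            rec = SpectralRecord(
                dye_id=dye_id,
                solvent=solvent,
                lambda_abs=lam_abs,
                lambda_em=lam_em,
                quantum_yield=qy,
                source_ref=ref,
            )
        except ValidationError as exc:
            logger.warning("%s line %d: %s; row skipped", path, line_no, exc)
            skipped.append((line_no, str(exc)))
            continue
        pair = (dye_id, _normalise_solvent(solvent))
        if pair in seen_pairs:
            # Repeated literature measurements are kept and flagged; the
            # regression uses all rows.
            logger.warning(
                "%s line %d: duplicate (dye, solvent) pair %s", path, line_no, pair
            )
        seen_pairs.add(pair)
        records_by_dye.setdefault(dye_id, []).append(rec)
        sm_col = opt_actual["smiles"]
        if sm_col in df.columns and str(row[sm_col]).strip():
            smiles_by_dye.setdefault(dye_id, str(row[sm_col]).strip())

    included: list[DyeSeries] = []
    excluded: list[DyeSeries] = []
    for dye_id, recs in records_by_dye.items():
        series = DyeSeries(
            dye_id=dye_id, records=recs, structure=smiles_by_dye.get(dye_id)
        )
        (included if series.n_solvents >= min_solvents else excluded).append(series)
    return TableReadResult(
        included=included,
        excluded=excluded,
        n_skipped=len(skipped),
        skipped_rows=skipped,
    )


def attach_structures(
    series: Sequence[DyeSeries],
    structures: str | Path | Mapping[str, str],
    id_property: str | None = None,
) -> list[DyeSeries]:
    """Annotate series with structures from an SDF file or a SMILES map.

    SDF molecules are keyed by the molecule title, or by ``id_property``
    when given.  Unmatched series keep ``structure=None`` and are logged;
    unparsable structures are skipped per-record.
    """
    from rdkit import Chem

    smiles_map: dict[str, str] = {}
    if isinstance(structures, Mapping):
        smiles_map = {str(k): str(v) for k, v in structures.items()}
    else:
        supplier = Chem.SDMolSupplier(str(structures), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("SDF molecule %d unparsable; skipped", i)
                continue
            if id_property and mol.HasProp(id_property):
                key = mol.GetProp(id_property)
            else:
                key = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            if not key:
                logger.warning("SDF molecule %d has no identifier; skipped", i)
                continue
            smiles_map[key.strip()] = Chem.MolToSmiles(mol)

    out: list[DyeSeries] = []
    matched_keys: set[str] = set()
    for s in series:
        smi = smiles_map.get(s.dye_id)
        if smi is not None:
            if Chem.MolFromSmiles(smi) is None:
                logger.warning("%s: invalid SMILES %r; structure omitted", s.dye_id, smi)
                out.append(replace_structure(s, None))
                continue
            matched_keys.add(s.dye_id)
            out.append(replace_structure(s, smi))
        else:
            logger.info("%s: no structure supplied", s.dye_id)
            out.append(replace_structure(s, s.structure))
    for key in set(smiles_map) - matched_keys:
        logger.warning("structure key %r matches no series; ignored", key)
    return out


def replace_structure(series: DyeSeries, structure: str | None) -> DyeSeries:
    return DyeSeries(
        dye_id=series.dye_id, records=list(series.records), structure=structure
    )


def series_to_frame(series: Iterable[DyeSeries], units: str = "cm1") -> pd.DataFrame:
    """Flatten series into a table with computed wavenumber columns.

    ``units='cm1'`` (internal) or ``'kK'`` (1000/cm, the plotting unit).
    """
    if units not in ("cm1", "kK"):
        raise ValidationError(f"unknown units {units!r}")
    scale = 1.0 if units == "cm1" else 1.0 / CM1_PER_KK
    suffix = "cm1" if units == "cm1" else "kk"
    rows = []
    for s in series:
        for rec in s.records:
            pt = to_wavenumber_point(rec)
            rows.append(
                {
                    "dye_id": rec.dye_id,
                    "solvent": rec.solvent,
                    "lambda_abs_nm": rec.lambda_abs,
                    "lambda_em_nm": rec.lambda_em,
                    "quantum_yield": rec.quantum_yield,
                    "ref": rec.source_ref,
                    f"nu_abs_{suffix}": pt.nu_abs * scale,
                    f"nu_em_{suffix}": pt.nu_em * scale,
                    f"nu_sum_{suffix}": pt.nu_sum * scale,
                    f"stokes_{suffix}": pt.stokes * scale,
                }
            )
    return pd.DataFrame(rows)


def write_series_table(series: Iterable[DyeSeries], path: str | Path) -> None:
    """Write series plus computed wavenumber columns as CSV."""
    series_to_frame(series).to_csv(path, index=False)
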