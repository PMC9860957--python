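"""Diagnostic map tables and frequency diagrams for probe selection.

Three scatter-map kinds summarise a clustered dye set:

- ``abs_vs_em``: emission maximum against absorption maximum, in nm or in
  1000/cm (kK) depending on the units flag;
- ``stokes_vs_negsum``: Stokes shift against -(nu_abs + nu_em), both in kK —
  the plane in which each dye's points fall on a line of slope A;
- ``qy_vs_stokes``: quantum yield against Stokes shift (cm^-1); rows
  without a quantum yield are dropped from this map only.

Every point carries a tooltip record mirroring its source measurement, so
a plotted mark can be traced back to the literature row that produced it.
Probe selection ranks dyes for two applications: polarity mapping (large
|A| — band positions track solvent polarity strongly) and viscosity /
molecular-rotor sensing (near-zero A with a wide quantum-yield range
across solvents).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .clustering import ClusterAssignment
from .sensitivity import SensitivityResult
from .spectra_io import CM1_PER_KK, DyeSeries, to_wavenumber_point

logger = logging.getLogger(__name__)

MAP_KINDS = ("abs_vs_em", "stokes_vs_negsum", "qy_vs_stokes")


@dataclass(frozen=True)
class MapPoint:
    """One plotted mark: coordinates plus a full provenance tooltip."""

    dye_id: str
    solvent: str
    cluster_index: int | None
    x: float
    y: float
    tooltip: dict


def build_map(
    kind: str,
    series: Sequence[DyeSeries],
    results: Mapping[str, SensitivityResult] | Sequence[SensitivityResult],
    assignments: Sequence[ClusterAssignment] | None = None,
    units: str = "nm",
    clusters: Sequence[int] | None = None,
) -> list[MapPoint]:
    """Build one of the three diagnostic map datasets.

    Parameters
    ----------
    kind
        One of ``abs_vs_em``, ``stokes_vs_negsum``, ``qy_vs_stokes``.
    units
        For ``abs_vs_em`` only: ``'nm'`` or ``'kK'``.  The Stokes map is
        always kK/kK and the QY map dimensionless vs cm^-1.
    clusters
        Optional cluster-index filter (requires ``assignments``).
    """
    if kind not in MAP_KINDS:
        raise ValidationError(f"unknown map kind {kind!r}; choose {MAP_KINDS}")
    if units not in ("nm", "kK"):
        raise ValidationError(f"unknown units {units!r}")
    if not isinstance(results, Mapping):
        results = {r.dye_id: r for r in results}
    cluster_of: dict[str, int] = (
        {a.dye_id: a.cluster_index for a in assignments} if assignments else {}
    )
    keep = set(clusters) if clusters is not None else None

    points: list[MapPoint] = []
    for s in series:
        res = results.get(s.dye_id)
        cl = cluster_of.get(s.dye_id)
        if keep is not None and cl not in keep:
            continue
        for rec in s.records:
            pt = to_wavenumber_point(rec)
            tooltip = {
                "dye_id": rec.dye_id,
                "solvent": rec.solvent,
                "A": res.A_stokes if res else None,
                "ec_ratio": res.ec_ratio if res else None,
                "lambda_abs_nm": rec.lambda_abs,
                "lambda_em_nm": rec.lambda_em,
                "stokes_cm1": pt.stokes,
                "quantum_yield": rec.quantum_yield,
            }
            if kind == "abs_vs_em":
                if units == "nm":
                    x, y = rec.lambda_abs, rec.lambda_em
                else:
                    x, y = pt.nu_abs / CM1_PER_KK, pt.nu_em / CM1_PER_KK
            elif kind == "stokes_vs_negsum":
                x = -pt.nu_sum / CM1_PER_KK
                y = pt.stokes / CM1_PER_KK
            else:  # qy_vs_stokes
                if rec.quantum_yield is None:
                    continue
                x, y = pt.stokes, rec.quantum_yield
            points.append(
                MapPoint(
                    dye_id=rec.dye_id,
                    solvent=rec.solvent,
                    cluster_index=cl,
                    x=x,
                    y=y,
                    tooltip=tooltip,
                )
            )
    return points


def map_to_frame(points: Sequence[MapPoint]) -> pd.DataFrame:
    """Flatten map points to a table; tooltip fields become columns."""
    rows = []
    for p in points:
        row = {"dye_id": p.dye_id, "solvent": p.solvent, "cluster": p.cluster_index,
               "x": p.x, "y": p.y}
        row.update({f"tt_{k}": v for k, v in p.tooltip.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frequency_diagram(
    values: Sequence[float], bin_width: float, origin: float | None = None
) -> pd.DataFrame:
    """Histogram with left-closed right-open bins of fixed width.

    The bin origin defaults to the data minimum.  Counts always sum to the
    number of input values.  Empty input yields an empty table.
    """
    if not bin_width > 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = float(v.min()) if origin is None else float(origin)
    if lo > v.min():
        raise ValidationError("origin must not exceed the data minimum")
    n_bins = int(np.floor((v.max() - lo) / bin_width)) + 1
    idx = np.minimum(((v - lo) / bin_width).astype(int), n_bins - 1)
    # floor can land an exact right-edge value in the next bin; clip handles
    # only the max — recompute exactly for left-closed semantics:
    idx = np.floor((v - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=idx.max() + 1)
    rows = [
        {
            "bin_left": lo + i * bin_width,
            "bin_right": lo + (i + 1) * bin_width,
            "count": int(c),
        }
        for i, c in enumerate(counts)
    ]
    return pd.DataFrame(rows)


def select_probes(
    results: Sequence[SensitivityResult],
    series: Sequence[DyeSeries] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank dyes for polarity mapping and for viscosity (rotor) sensing.

    Returns ``(polarity, viscosity)`` tables.  Polarity candidates are all
    dyes ranked by |A| descending — strong solvatochromism makes band
    positions informative about medium polarity.  Viscosity candidates are
    the near-zero-A dyes ranked by their quantum-yield range across
    solvents descending — a wide QY swing at fixed band position is the
    molecular-rotor signature.  Without any QY data the viscosity ranking
    is empty (warned).
    """
    polarity = pd.DataFrame(
        [
            {"dye_id": r.dye_id, "A": r.A_stokes, "abs_A": abs(r.A_stokes),
             "ec_ratio": r.ec_ratio, "near_zero": r.near_zero}
            for r in results
        ]
    )
    if not polarity.empty:
        polarity = polarity.sort_values(
            ["abs_A", "dye_id"], ascending=[False, True]
        ).reset_index(drop=True)

    series_by_id = {s.dye_id: s for s in series} if series else {}
    visc_rows = []
    for r in results:
        if not r.near_zero:
            continue
        s = series_by_id.get(r.dye_id)
        qys = [rec.quantum_yield for rec in s.records if rec.quantum_yield is not None] if s else []
        if len(qys) < 2:
            continue
        visc_rows.append(
            {
                "dye_id": r.dye_id,
                "A": r.A_stokes,
                "qy_min": min(qys),
                "qy_max": max(qys),
                "qy_range": max(qys) - min(qys),
            }
        )
    viscosity = pd.DataFrame(
        visc_rows,
        columns=["dye_id", "A", "qy_min", "qy_max", "qy_range"],
    )
    if viscosity.empty:
        logger.warning("no quantum-yield coverage: viscosity ranking is empty")
    else:
        viscosity = viscosity.sort_values(
            ["qy_range", "dye_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return polarity, viscosity


def plot_map(points: Sequence[MapPoint], path: str, kind: str = "") -> None:
    """Optional static rendering of a map dataset (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = map_to_frame(points)
    fig, ax = plt.subplots(figsize=(6, 5))
    if df.empty:
        ax.set_title(f"{kind} (empty)")
    else:
        clusters = df["cluster"].fillna(-1)
        sc = ax.scatter(df["x"], df["y"], c=clusters, s=12, cmap="viridis")
        if df["cluster"].notna().any():
            fig.colorbar(sc, ax=ax, label="cluster")
        ax.set_title(kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
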