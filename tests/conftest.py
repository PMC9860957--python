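import numpy as np
import pytest

from solvachrom import DyeSeries, SpectralRecord, SyntheticSpec, generate_series


def series_from_kk(dye_id, nu_abs_kk, nu_em_kk, qy=None, structure=None):
    """Build a DyeSeries from wavenumbers given in 1000/cm."""
    records = []
    for i, (a, e) in enumerate(zip(nu_abs_kk, nu_em_kk), start=1):
        records.append(
            SpectralRecord(
                dye_id=dye_id,
                solvent=f"solv{i}",
                lambda_abs=1e7 / (a * 1000.0),
                lambda_em=1e7 / (e * 1000.0),
                quantum_yield=None if qy is None else qy[i - 1],
            )
        )
    return DyeSeries(dye_id=dye_id, records=records, structure=structure)


@pytest.fixture
def collinear_series():
    """Exactly collinear three-solvent series with A = 1/3, B = 14 kK."""
    return series_from_kk("COLL-1", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2])


@pytest.fixture
def noiseless_49():
    """Noiseless synthetic series, mu_g=4, mu_e=9 (A = 5/13, E/C = 2.25)."""
    return generate_series(
        SyntheticSpec(
            mu_g=4.0,
            mu_e=9.0,
            polarity_values=tuple(np.linspace(0, 1, 12)),
            noise_sd=0.0,
            seed=1,
        )
    )


@pytest.fixture
def simple_table(tmp_path):
    path = tmp_path / "table.csv"
    lines = ["dye_id,solvent,lambda_abs_nm,lambda_em_nm,quantum_yield,smiles,ref"]
    # dye X: 3 solvents (short); dye Y: 12 solvents
    for i in range(3):
        lines.append(f"X,sx{i},500,{520 + i},0.5,CCO,refX")
    for i in range(12):
        lines.append(f"Y,sy{i},{500 + i},{530 + 2 * i},0.{i % 9 + 1},c1ccccc1,refY")
    path.write_text("\n".join(lines) + "\n")
    return path
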