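import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvachrom import (
    canonical_key,
    find_duplicates,
    group_dispersion,
    per_solvent_comparison,
)
from solvachrom.duplicates import DuplicateGroup
from solvachrom.errors import InsufficientDataError, ValidationError
from conftest import series_from_kk
from test_clustering import make_result


class TestCanonicalKey:
    def test_same_molecule_different_smiles(self):
        assert canonical_key("OCC") == canonical_key("CCO")

    def test_different_molecules(self):
        assert canonical_key("CCO") != canonical_key("CCN")

    def test_empty_string_rejected(self):
        with pytest.raises(ValidationError):
            canonical_key("")

    def test_garbage_rejected(self):
        with pytest.raises(ValidationError):
            canonical_key("this is not a molecule")

    @pytest.mark.parametrize(
        "smi", ["CCO", "c1ccccc1", "C/C=C/C", "C[C@H](N)C(=O)O"]
    )
    def test_idempotent_and_kekule_invariant(self, smi):
        """Keying is stable under re-canonicalisation round trips,
        including stereo-bearing inputs."""
        from rdkit import Chem

        canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        assert canonical_key(smi) == canonical_key(canon)

    def test_stereo_distinguished(self):
        assert canonical_key("C/C=C/C") != canonical_key("C/C=C\\C")


def two_member_setup(A1=0.5, A2=0.6, smiles=("CCO", "OCC")):
    s1 = series_from_kk("d1", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                        structure=smiles[0])
    s2 = series_from_kk("d2", [20.1, 19.9, 19.7], [19.1, 18.7, 18.3],
                        structure=smiles[1])
    results = [make_result("d1", A1), make_result("d2", A2)]
    return [s1, s2], results


class TestFindDuplicates:
    def test_same_structure_grouped(self):
        series, results = two_member_setup()
        groups = find_duplicates(series, results)
        assert len(groups) == 1
        assert groups[0].n == 2
        assert groups[0].member_ids == ("d1", "d2")
        assert groups[0].solvent_counts == (3, 3)

    def test_disjoint_structures_no_groups(self):
        series, results = two_member_setup(smiles=("CCO", "CCN"))
        assert find_duplicates(series, results) == []

    def test_three_study_dispersion(self):
        """A = 0.50, 0.60, 0.55 across three studies: sample SD = 0.05,
        SEM = 0.05/sqrt(3)."""
        series = [
            series_from_kk(f"d{i}", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                           structure="CCO")
            for i in range(3)
        ]
        results = [make_result("d0", 0.50), make_result("d1", 0.60),
                   make_result("d2", 0.55)]
        (g,) = find_duplicates(series, results)
        assert g.sd == pytest.approx(0.05, abs=1e-12)
        assert g.sem == pytest.approx(0.05 / math.sqrt(3), abs=1e-12)

    def test_shuffle_invariance(self):
        series, results = two_member_setup()
        a = find_duplicates(series, results)
        b = find_duplicates(series[::-1], results[::-1])
        assert a == b

    def test_unparsable_structure_excluded(self, caplog):
        import logging

        series, results = two_member_setup()
        bad = series_from_kk("d3", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                             structure="((bad")
        with caplog.at_level(logging.WARNING):
            groups = find_duplicates(series + [bad], results + [make_result("d3", 0.4)])
        assert len(groups) == 1
        assert "d3" not in groups[0].member_ids

    @given(st.lists(st.sampled_from(["CCO", "CCN", "c1ccccc1", "CC(C)O"]),
                    min_size=2, max_size=8))
    @settings(deadline=None, max_examples=30)
    def test_key_count_bound(self, smiles_list):
        """Distinct keys <= dye count, equal iff no structural duplicates."""
        series = [
            series_from_kk(f"d{i}", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                           structure=s)
            for i, s in enumerate(smiles_list)
        ]
        keys = {canonical_key(s) for s in smiles_list}
        assert len(keys) <= len(series)
        groups = find_duplicates(
            series, [make_result(f"d{i}", 0.1 * i) for i in range(len(series))]
        )
        n_dupes = sum(g.n for g in groups)
        assert (len(keys) == len(series)) == (n_dupes == 0)


class TestGroupDispersion:
    def make_group(self, A_values, ids=None):
        ids = ids or tuple(f"m{i}" for i in range(len(A_values)))
        sd = statistics.stdev(A_values)
        return DuplicateGroup(
            group_key="k", member_ids=tuple(ids), A_values=tuple(A_values),
            solvent_counts=tuple([3] * len(A_values)), sd=sd,
            sem=sd / math.sqrt(len(A_values)),
        )

    def test_two_point(self):
        sd, sem = group_dispersion(self.make_group([0.5, 0.6]))
        assert sd == pytest.approx(0.1 / math.sqrt(2), abs=1e-12)
        assert sem == pytest.approx(sd / math.sqrt(2), abs=1e-12)

    def test_identical_values(self):
        sd, sem = group_dispersion(self.make_group([0.4, 0.4, 0.4]))
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_exclusion_to_one_value_errors(self):
        g = self.make_group([0.5, 0.6], ids=("keep", "drop"))
        with pytest.raises(InsufficientDataError):
            group_dispersion(g, exclude=["drop"])

    def test_exclusion_changes_dispersion(self):
        g = self.make_group([0.5, 0.6, 1.5], ids=("a", "b", "outlier"))
        sd_all, _ = group_dispersion(g)
        sd_excl, sem_excl = group_dispersion(g, exclude=["outlier"])
        assert sd_excl < sd_all
        assert sem_excl == pytest.approx(sd_excl / math.sqrt(2), abs=1e-12)

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=2, max_size=10))
    @settings(deadline=None, max_examples=100)
    def test_matches_two_pass_formula(self, values):
        """Module SD/SEM agree with textbook two-pass sample statistics."""
        g = self.make_group(values)
        sd, sem = group_dispersion(g)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert sd == pytest.approx(math.sqrt(var), abs=1e-12)
        assert sem == pytest.approx(math.sqrt(var / len(values)), abs=1e-12)

    def test_population_sd_flag(self):
        g = self.make_group([0.0, 1.0])
        sd_pop, _ = group_dispersion(g, population_sd=True)
        assert sd_pop == pytest.approx(0.5, abs=1e-12)


class TestPerSolventComparison:
    def test_shared_solvents(self):
        series, results = two_member_setup()
        (g,) = find_duplicates(series, results)
        table = per_solvent_comparison(g, series)
        # conftest names solvents solv1..solv3 for both members
        assert len(table) == 3
        assert (table["n_studies"] == 2).all()
        # 0.1 kK offset between members in every solvent
        assert table["delta_nu_abs_cm1"].iloc[0] == pytest.approx(100.0, rel=1e-9)

    def test_disjoint_solvents_empty(self):
        s1 = series_from_kk("d1", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                            structure="CCO")
        s2 = series_from_kk("d2", [20.0, 19.8, 19.6], [19.0, 18.6, 18.2],
                            structure="OCC")
        for rec in s2.records:
            object.__setattr__(rec, "solvent", rec.solvent + "_other")
        (g,) = find_duplicates([s1, s2], [make_result("d1", 0.1),
                                          make_result("d2", 0.2)])
        assert per_solvent_comparison(g, [s1, s2]).empty

    def test_wavelength_delta_in_wavenumbers(self):
        """A 2 nm band difference in one solvent appears as its exact
        wavenumber difference."""
        from solvachrom import SpectralRecord, DyeSeries

        r1 = [SpectralRecord("d1", "ethanol", 500.0, 520.0),
              SpectralRecord("d1", "water", 505.0, 525.0),
              SpectralRecord("d1", "hexane", 495.0, 515.0)]
        r2 = [SpectralRecord("d2", "ethanol", 502.0, 520.0),
              SpectralRecord("d2", "water", 505.0, 525.0),
              SpectralRecord("d2", "hexane", 495.0, 515.0)]
        s1 = DyeSeries("d1", r1, structure="CCO")
        s2 = DyeSeries("d2", r2, structure="OCC")
        (g,) = find_duplicates([s1, s2], [make_result("d1", 0.1),
                                          make_result("d2", 0.2)])
        table = per_solvent_comparison(g, [s1, s2])
        row = table[table["solvent"] == "ethanol"].iloc[0]
        assert row["delta_nu_abs_cm1"] == pytest.approx(
            1e7 / 500 - 1e7 / 502, abs=1e-9
        )
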