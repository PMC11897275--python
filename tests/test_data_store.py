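"""Configuration I/O, packaged tables, and profile round-trips."""

import numpy as np
import pytest
from pydantic import ValidationError

from pbpkddi import data_store
from pbpkddi.pk_engine import ConcTimeProfile


class TestDrugModelConfig:
    def test_rifampicin_fixture_carries_published_parameters(self, rif):
        assert rif.induction.emax == 14.6
        assert rif.induction.ec50 == 0.8
        assert rif.compound.fup == 0.16
        assert rif.compound.rbp == 0.52
        assert rif.compound.molecular_weight == 822.96
        assert rif.disposition.vc == 0.15145
        assert rif.clearance.cl_cyp3a4_hepatic == 0.0179
        assert rif.clearance.cl_other_hepatic == 0.0623
        assert rif.clearance.cl_renal == 0.0169
        assert rif.clearance.km == 0.028

    @pytest.mark.parametrize(
        "patch",
        [
            {"compound": {"fup": 0.0}},
            {"compound": {"fup": 1.5}},
            {"disposition": {"vc": -1.0}},
            {"disposition": {"k13": 0.5}},  # k13 without k31
            {"clearance": {"vmax_mode": "michaelis_menten", "km": None}},
            {"clearance": {"fg": 0.0}},
        ],
    )
    def test_invariant_violations_raise(self, rif, patch):
        payload = rif.model_dump()
        for section, fields in patch.items():
            payload[section].update(fields)
        with pytest.raises(ValidationError):
            data_store.DrugModel.model_validate(payload)

    def test_missing_field_names_the_field(self, rif, tmp_path):
        payload = rif.model_dump()
        del payload["compound"]["molecular_weight"]
        path = tmp_path / "broken.json"
        import json

        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="molecular_weight"):
            data_store.load_drug_model(path)

    def test_yaml_config_loads(self, rif, tmp_path):
        import yaml

        path = tmp_path / "rif.yaml"
        path.write_text(yaml.safe_dump(rif.model_dump()))
        assert data_store.load_drug_model(path) == rif


class TestInteractionTable:
    def test_has_28_records_in_table_order(self):
        records = data_store.load_ddi_table()
        assert len(records) == 28
        assert records[0].victim == "Abiraterone"
        assert records[-1].victim == "Istradefylline"

    def test_spot_values_match_printed_table(self):
        by_name = {r.victim: r for r in data_store.load_ddi_table()}
        abi = by_name["Abiraterone"]
        assert (abi.observed_aucr, abi.predicted_aucr_static, abi.predicted_aucr_pbpk) == (
            0.42,
            0.04,
            0.22,
        )
        vor = by_name["Vorapaxar"]
        assert vor.observed_aucr == 1.08
        assert all(
            r.observed_aucr <= 1.0 for r in by_name.values() if r.victim != "Vorapaxar"
        )

    def test_two_steady_state_victims(self):
        records = data_store.load_ddi_table()
        qd = [r.victim for r in records if r.is_steady_state]
        assert sorted(qd) == ["Macitentan", "Vorapaxar"]
        assert sum(1 for r in records if not r.is_steady_state) == 26

    def test_fixture_checksums_are_frozen(self):
        assert data_store.fixture_checksums() == data_store._CHECKSUMS


class TestPKValidationTable:
    def test_iv_rows(self):
        records = data_store.load_pk_validation_table()
        iv = {r.parameter: r for r in records if "IV" in r.regimen_label}
        assert (iv["Cmax"].predicted, iv["Cmax"].observed) == (31.9, 37.6)
        assert (iv["T1/2"].predicted, iv["T1/2"].observed) == (2.22, 2.21)

    def test_oral_auc_row(self):
        records = data_store.load_pk_validation_table()
        (row,) = [
            r
            for r in records
            if r.regimen_label == "200 mg oral, SD" and r.parameter == "AUC"
        ]
        assert (row.predicted, row.observed) == (49.6, 60.0)

    def test_day_tags_attached(self):
        records = data_store.load_pk_validation_table()
        qd1 = [r.parameter for r in records if r.regimen_label == "600 mg oral, QD-1"]
        assert "AUC-Day 6" in qd1


class TestProfileRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        profile = ConcTimeProfile(
            times=[0.0, 0.5, 1.0, 7.25],
            concentrations=[0.0, 5.123456789012345, 2.5, 1e-9],
            dose_events=[(0.0, 100.0, "oral")],
            cumulative_eliminated={"renal": 12.5, "unabsorbed": 3.25},
        )
        path = tmp_path / "profile.csv"
        data_store.write_profile(profile, path)
        back = data_store.read_profile(path)
        np.testing.assert_allclose(back.times, profile.times, rtol=1e-12)
        np.testing.assert_allclose(back.concentrations, profile.concentrations, rtol=1e-12)
        assert back.dose_events == profile.dose_events
        assert back.cumulative_eliminated == profile.cumulative_eliminated

    def test_header_format(self, tmp_path, rif_model):
        from pbpkddi import pk_engine

        regimen = pk_engine.DoseRegimen(route="oral", dose=600.0)
        profile = pk_engine.simulate(rif_model, regimen, t_end=4.0, autoinduction=False)
        path = tmp_path / "rif.csv"
        data_store.write_profile(profile, path)
        lines = path.read_text().splitlines()
        header = [l for l in lines if not l.startswith("#")][0]
        assert header == "time_h,conc_mg_per_L"

    def test_empty_profile_rejected(self, tmp_path):
        profile = ConcTimeProfile(times=[], concentrations=[])
        with pytest.raises(ValueError):
            data_store.write_profile(profile, tmp_path / "empty.csv")

    def test_non_monotone_times_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_h,conc_mg_per_L\n0,1\n2,2\n1,3\n")
        with pytest.raises(ValueError):
            data_store.read_profile(path)
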