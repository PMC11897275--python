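"""DDI orchestration: design parsing, null cases, analytic-oracle consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkddi import data_store, ddi_simulation
from pbpkddi.ddi_simulation import (
    aucr_analytic,
    default_design,
    invert_fm,
    parse_dosing,
    run_ddi,
)


class TestDesign:
    @pytest.mark.parametrize(
        "dosing,expected",
        [
            ("10 mg, SD", (10.0, "SD")),
            ("1,000 mg, SD", (1000.0, "SD")),
            ("500 ug, SD", (0.5, "SD")),
            ("20 mg, QD", (20.0, "QD")),
        ],
    )
    def test_dosing_strings_parse(self, dosing, expected):
        assert parse_dosing(dosing) == expected

    def test_unparseable_dosing_rejected(self):
        with pytest.raises(ValueError):
            parse_dosing("abc")

    def test_single_dose_design_layout(self):
        design = default_design("10 mg, SD")
        assert design.victim_regimen.n_doses == 1
        assert design.victim_regimen.start_time == 7 * 24.0  # dosed on day 8
        assert design.perpetrator_regimen.dose == 600.0
        assert design.perpetrator_regimen.interval == 24.0
        # perpetrator covers wash-in plus the victim observation window
        assert design.perpetrator_regimen.n_doses * 24.0 >= design.t_end

    def test_steady_state_design_for_qd_victims(self):
        design = default_design("10 mg, QD")
        assert design.steady_state_victim
        assert design.victim_regimen.n_doses >= 5
        assert design.victim_regimen.interval == 24.0


class TestNullCases:
    def test_non_inducing_perpetrator_gives_unity_aucr(self, oracle_victim, rif, phys):
        inert = rif.model_copy(deep=True)
        inert.induction.emax = 0.0
        design = default_design("100 mg, SD", washin_days=3, victim_window=96.0)
        result = run_ddi(oracle_victim, rif.model_copy(update={"induction": inert.induction}),
                         design, phys)
        assert result.aucr == pytest.approx(1.0, abs=1e-3)
        assert result.cmaxr == pytest.approx(1.0, abs=1e-3)

    def test_non_substrate_victim_unaffected(self, rif, phys):
        victim = data_store.DrugModel(
            name="non_substrate",
            compound=data_store.CompoundProperties(
                molecular_weight=400.0, log_d=2.0, aqueous_solubility=10.0,
                peff=3.0, rbp=1.0, fup=0.1,
            ),
            disposition=data_store.DispositionParams(vc=1.0),
            clearance=data_store.ClearanceParams(
                cl_cyp3a4_hepatic=0.0, cl_other_hepatic=0.1, fm_cyp3a4=0.0, fg=1.0
            ),
        )
        design = default_design("100 mg, SD", washin_days=3, victim_window=96.0)
        result = run_ddi(victim, rif, design, phys)
        assert result.aucr == pytest.approx(1.0, abs=1e-3)

    def test_perpetrator_without_induction_rejected(self, oracle_victim, rif, phys):
        bare = rif.model_copy(update={"induction": None})
        with pytest.raises(ValueError):
            run_ddi(oracle_victim, bare, default_design("10 mg, SD"), phys)


class TestOracleConsistency:
    def test_dynamic_aucr_matches_clearance_scaling_oracle(self, oracle_ddi_result):
        """A linear fg=1 victim at near-steady induction must follow
        AUCR = 1/((1-fm) + fm*fold)."""
        res = oracle_ddi_result
        expected = aucr_analytic(0.8, 1.0, res.fold_liver_weighted, 1.0)
        assert res.aucr == pytest.approx(expected, rel=0.15)

    def test_aucr_below_unity_for_pure_inducer(self, oracle_ddi_result):
        assert oracle_ddi_result.aucr < 1.0
        assert oracle_ddi_result.cmaxr < 1.0

    def test_shorter_washin_moves_aucr_toward_unity(self, oracle_victim, rif, phys,
                                                    oracle_ddi_result):
        short = run_ddi(oracle_victim, rif, default_design("100 mg, SD", washin_days=2), phys)
        assert short.aucr > oracle_ddi_result.aucr
        assert short.fold_liver_at_victim_dose < oracle_ddi_result.fold_liver_at_victim_dose


class TestAnalyticOracle:
    @pytest.mark.parametrize(
        "fm,fg,fold_l,fold_g,expected",
        [
            (0.0, 1.0, 5.0, 5.0, 1.0),
            (1.0, 1.0, 2.0, 1.0, 0.5),
            (0.8, 1.0, 4.0, 1.0, 1 / (0.2 + 0.8 * 4.0)),  # 0.294
            (0.9, 0.5, 5.0, 5.0, (1 / 6.0 / 0.5) / (0.1 + 4.5)),  # 0.0725
        ],
    )
    def test_hand_computed_values(self, fm, fg, fold_l, fold_g, expected):
        assert aucr_analytic(fm, fg, fold_l, fold_g) == pytest.approx(expected, rel=1e-6)

    @given(
        fm=st.floats(0.0, 1.0),
        fg=st.floats(0.05, 1.0),
        fold=st.floats(1.0, 15.6),
    )
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_monotonicity_in_fm(self, fm, fg, fold):
        aucr = aucr_analytic(fm, fg, fold, fold)
        assert 0.0 < aucr <= 1.0 + 1e-12
        if fm < 1.0:
            assert aucr_analytic(min(fm + 0.1, 1.0), fg, fold, fold) <= aucr + 1e-12

    def test_inversion_recovers_fm(self):
        for fm in (0.05, 0.4, 0.85):
            target = aucr_analytic(fm, 0.7, 4.2, 2.5)
            assert invert_fm(target, 0.7, 4.2, 2.5) == pytest.approx(fm, abs=1e-8)

    def test_inversion_rejects_unattainable_target(self):
        with pytest.raises(ValueError):
            invert_fm(1.5, 1.0, 4.0, 1.0)
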