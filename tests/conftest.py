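"""Shared fixtures; expensive co-simulations are session-scoped."""

import pytest

from pbpkddi import data_store, ddi_simulation, pk_engine, synthetic_data


@pytest.fixture(scope="session")
def rif():
    return data_store.load_rifampicin()


@pytest.fixture(scope="session")
def phys():
    return pk_engine.Physiology()


@pytest.fixture(scope="session")
def rif_model(rif, phys):
    return pk_engine.build_model(rif, phys)


@pytest.fixture(scope="session")
def exemplar_victims():
    return data_store.load_exemplar_victims()


@pytest.fixture(scope="session")
def qd_profile(rif_model):
    """600 mg oral once daily for 7 days with autoinduction enabled."""
    regimen = pk_engine.DoseRegimen(route="oral", dose=600.0, n_doses=7, interval=24.0)
    return pk_engine.simulate(rif_model, regimen, t_end=7 * 24.0)


@pytest.fixture(scope="session")
def oracle_victim():
    """Linear, low-extraction, fg=1 victim for the clearance-scaling oracle."""
    return synthetic_data.DrugModel(
        name="oracle_victim",
        description="synthetic low-extraction victim, fm=0.8, fg=1",
        compound=data_store.CompoundProperties(
            molecular_weight=400.0,
            log_d=2.0,
            aqueous_solubility=10.0,
            peff=3.0,
            rbp=1.0,
            fup=0.1,
        ),
        disposition=data_store.DispositionParams(vc=1.0),
        clearance=data_store.ClearanceParams(
            cl_cyp3a4_hepatic=0.08,
            cl_other_hepatic=0.02,
            fm_cyp3a4=0.8,
            fg=1.0,
        ),
    )


@pytest.fixture(scope="session")
def oracle_ddi_result(oracle_victim, rif, phys):
    """run_ddi at near-steady enzyme (14-day wash-in) for the oracle victim."""
    design = ddi_simulation.default_design("100 mg, SD", washin_days=14)
    return ddi_simulation.run_ddi(oracle_victim, rif, design, phys)


@pytest.fixture(scope="session")
def exemplar_ddi_results(exemplar_victims, rif, phys):
    """Default-design DDI runs for the three packaged exemplar victims."""
    design = ddi_simulation.default_design("100 mg, SD", washin_days=7)
    return {
        v.name: ddi_simulation.run_ddi(v, rif, design, phys) for v in exemplar_victims
    }


@pytest.fixture(scope="session")
def cohort_report(rif, phys):
    """End-to-end recovery experiment on a 20-victim synthetic cohort."""
    spec = synthetic_data.SyntheticCohortSpec(n_victims=20, seed=7)
    return synthetic_data.recovery_experiment(
        spec, phys=phys, perpetrator=rif, noise_gsds=(1.0, 1.8, 2.5)
    )
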