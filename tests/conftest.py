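import numpy as np
import pandas as pd
import pytest

import phenowater as pw
from phenowater.pipeline import run_analysis


@pytest.fixture(scope="session")
def trait_table() -> pd.DataFrame:
    """Packaged genotype x treatment trait table as a frame."""
    return pw.records_to_frame(pw.reference_trait_table())


@pytest.fixture(scope="session")
def default_sim() -> pw.SimulatedExperiment:
    """One synthetic experiment under the default configuration."""
    return pw.simulate_experiment(pw.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_sim) -> pw.AnalysisResult:
    return run_analysis(default_sim.pots, default_sim.gas_exchange,
                        default_sim.harvest)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def recovery_study():
    """Replicated simulated experiments analysed end to end.

    Ten independent experiments under the default configuration; each
    seed is one full greenhouse run. Estimates averaged over the runs
    are compared against the generating truth in recovery tests.
    """
    from phenowater.pipeline import et0_residual_regression

    out = {"evap_control": [], "evap_stress": [], "te_slope": [],
           "class_accuracy": [], "et0_resid_r2": []}
    for seed in range(10):
        sim = pw.simulate_experiment(pw.SimConfig(seed=seed))
        res = run_analysis(sim.pots, sim.gas_exchange, sim.harvest)
        out["evap_control"].append(res.partitions["control"].evaporation)
        out["evap_stress"].append(res.partitions["stress"].evaporation)
        out["te_slope"].append(res.te.slope)
        truth = {g: v["type"] for g, v in sim.truth["genotypes"].items()}
        out["class_accuracy"].append(float(np.mean(
            [truth[r.genotype_id] == r.type
             for r in res.types.itertuples()])))
        out["et0_resid_r2"].append(
            et0_residual_regression(res.flux, sim.climate).r2)
    return out
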