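import numpy as np
import pandas as pd
import pytest

from promcoupling import synthetic

LN2 = np.log(2.0)


def make_kinetics(genes, k_syn_1, k_deg_1, k_syn_2=None, k_deg_2=None):
    """Hand-built kinetics table for noiseless closed-form checks."""
    k_syn_1 = np.broadcast_to(np.asarray(k_syn_1, dtype=float), (len(genes),))
    k_deg_1 = np.broadcast_to(np.asarray(k_deg_1, dtype=float), (len(genes),))
    k_syn_2 = k_syn_1 if k_syn_2 is None else np.broadcast_to(
        np.asarray(k_syn_2, dtype=float), (len(genes),))
    k_deg_2 = k_deg_1 if k_deg_2 is None else np.broadcast_to(
        np.asarray(k_deg_2, dtype=float), (len(genes),))
    return pd.DataFrame(
        {
            "gene": list(genes),
            "k_syn_1": k_syn_1,
            "k_deg_1": k_deg_1,
            "k_syn_2": k_syn_2,
            "k_deg_2": k_deg_2,
            "delta_syn_true": np.log2(k_syn_2 / k_syn_1),
            "delta_deg_true": np.log2(k_deg_2 / k_deg_1),
        }
    )


@pytest.fixture(scope="session")
def coupled_cohort():
    """One medium labeling cohort under the coupled model (shared across tests)."""
    scen = synthetic.CouplingScenario(
        model="coupled", n_genes=2000, beta=2.0, seed=42
    )
    kin = synthetic.simulate_kinetics(scen)
    data = synthetic.simulate_labeling(
        kin, 60.0, sd_noise=0.1, sd_assay=scen.sd_noise, capture_sd=0.5,
        seed=scen.seed,
    )
    return scen, kin, data
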