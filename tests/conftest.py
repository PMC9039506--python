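import pandas as pd
import pytest

import graftmobile as gm
from graftmobile import delta


@pytest.fixture(scope="session")
def small_dataset() -> gm.GraftDataset:
    """Modest end-to-end dataset with planted mobility, DEG/DIM effects and correlations."""
    cfg = gm.SimulationConfig(n_pairs=12, transcript_length=400, depth=15.0, seed=11)
    plan = [
        gm.MobilePlanEntry("Csa_0001", "Csa", "Cmo", "root", "chilling", 30),
        gm.MobilePlanEntry("Cmo_0002", "Csa", "Cmo", "leaf", "chilling", 25),
        gm.MobilePlanEntry("Csa_0003", "Cmo", "Csa", "leaf", "control", 20),
        gm.MobilePlanEntry("Cmo_0004", "Cmo", "Csa", "root", "chilling", 15),
    ]
    return gm.generate_dataset(
        cfg,
        mobility_plan=plan,
        planted_effects=[
            ("Csa_0005", "leaf", 3.0),
            ("Cmo_0006", "root", -3.0),
            ("Csa_0007", "leaf", 1.0),
        ],
        planted_dims=[("met_0001", "leaf", 4.0), ("met_0002", "root", -3.0)],
        planted_correlations=[("Csa_0005", "met_0003", 1), ("Cmo_0006", "met_0004", -1)],
        n_metabolites=20,
    )


@pytest.fixture(scope="session")
def chain_dataset() -> gm.GraftDataset:
    """A single planted mobile -> ortholog-DEG -> correlated-DIM chain, noiseless."""
    from graftmobile.scenarios import chain_scenario

    return chain_scenario(seed=23)


@pytest.fixture(scope="session")
def gene_contrasts(small_dataset) -> pd.DataFrame:
    return pd.concat(
        [delta.contrast_log2fc(t) for _, t in sorted(small_dataset.expression.items())]
    )


@pytest.fixture(scope="session")
def metabolite_contrasts(small_dataset) -> pd.DataFrame:
    return delta.contrast_log2fc(small_dataset.intensity)
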