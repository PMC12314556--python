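import numpy as np
import pandas as pd
import pytest

from hippoprofiler.synthetic import SyntheticConfig, Treatment


def tiny_config_obj():
    """Small but complete study design: two inhibitor families, two doses."""
    return SyntheticConfig(
        seed=7,
        n_features=40,
        n_blocks=8,
        block_rho=0.95,
        treatments=(
            Treatment("VT-107", "selective-TEAD", (1.1, 10.0)),
            Treatment("dasatinib", "non-selective", (1.1, 10.0)),
        ),
        n_replicate_wells=3,
        n_technical_wells=2,
        cells_per_well=60,
    )


@pytest.fixture
def tiny_config():
    return tiny_config_obj()


@pytest.fixture
def single_drug_config():
    """One treatment at one dose, 8 wells/arm — the planted-recovery design."""
    return SyntheticConfig(
        seed=0,
        n_features=40,
        n_blocks=8,
        block_rho=0.5,
        treatments=(Treatment("drug", "selective-TEAD", (10.0,)),),
        n_replicate_wells=8,
        effect_size=6.0,
        affected_fraction=0.3,
        dependent_fraction=0.5,
        outlier_well_rate=0.0,
    )


def make_matrix(values, genotype="WT", treatment="DMSO", concentration=0.0, start=1):
    """Small well x feature frame from a 2D list, one row per well."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    df = pd.DataFrame({
        "Metadata_Plate": "P1",
        "Metadata_Well": [f"W{start + i:03d}" for i in range(n)],
        "Metadata_Genotype": genotype,
        "Metadata_Treatment": treatment,
        "Metadata_Family": "vehicle" if treatment == "DMSO" else "selective-TEAD",
        "Metadata_Concentration": concentration,
        "Metadata_Replicate": list(range(1, n + 1)),
    })
    feats = pd.DataFrame(values, columns=[f"feat_{j:04d}" for j in range(p)])
    return pd.concat([df, feats], axis=1)
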