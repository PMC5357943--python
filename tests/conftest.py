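import warnings

import numpy as np
import pandas as pd
import pytest

from switchnet import ExpressionMatrix, SwitchMiner, generate_modular_expression

# degenerate-module and empty-category warnings are expected on planted data
warnings.filterwarnings("ignore", message="module .*zero degree sd")
warnings.filterwarnings("ignore", message="no nodes in category")

PLANTED_SEED = 1
PLANTED_PARAMS = dict(
    n_modules=4, genes_per_module=50, n_samples=100, intra_corr=0.8,
    n_switch=10, switch_strength=0.8, noise_sd=0.3,
)
PLANTED_CUTOFF = 0.6
PLANTED_K = 4


@pytest.fixture(scope="session")
def planted():
    """Planted-switch dataset at the generator's default study conditions."""
    return generate_modular_expression(**PLANTED_PARAMS, seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def planted_results(planted):
    em, _ = planted
    model = SwitchMiner(em, cutoff=PLANTED_CUTOFF, k=PLANTED_K, seed=7)
    return model.fit()


def make_expression(values, genes=None, samples=None, conditions=None, patients=None):
    """Small helper assembling an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    sheet = None
    if conditions is not None:
        sheet = pd.DataFrame(
            {
                "patient_id": patients or [f"p{j}" for j in range(len(samples))],
                "condition": conditions,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    return ExpressionMatrix(df, sheet)


@pytest.fixture
def paired_em():
    """4 genes x 8 samples, 4 patients with matched tumor/normal."""
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 5, size=(4, 8))
    conditions = ["tumor", "normal"] * 4
    patients = [f"p{j // 2}" for j in range(8)]
    return make_expression(vals, conditions=conditions, patients=patients)
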