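import numpy as np
import pandas as pd
import pytest

from mrlipid import simulate_harmonized


@pytest.fixture
def harmonized_20():
    """20 clean instruments under a causal effect of ln(1.1) per SD."""
    h, truth = simulate_harmonized(20, float(np.log(1.1)), seed=42)
    return h, truth


@pytest.fixture
def assoc_table():
    """Small hand-written association table (exposure-style, per-SD betas)."""
    return pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3", "rs4"],
            "effect_allele": ["A", "C", "G", "A"],
            "other_allele": ["G", "T", "A", "T"],
            "eaf": [0.30, 0.55, 0.70, 0.25],
            "beta": [0.10, -0.08, 0.05, 0.12],
            "se": [0.01, 0.012, 0.009, 0.015],
            "pvalue": [1e-20, 1e-12, 1e-8, 1e-14],
        }
    )


def random_instrument_frame(rng, j=10):
    """Random harmonized-style frame for oracle equivalence tests."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(j)],
            "effect_allele": ["A"] * j,
            "beta_exposure": rng.uniform(0.02, 0.2, j),
            "se_exposure": rng.uniform(0.002, 0.01, j),
            "beta_outcome": rng.normal(0, 0.05, j),
            "se_outcome": rng.uniform(0.005, 0.05, j),
            "eaf_exposure": rng.uniform(0.05, 0.95, j),
            "eaf_outcome": rng.uniform(0.05, 0.95, j),
            "exclusion_flag": ["none"] * j,
        }
    )
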