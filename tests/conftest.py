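import numpy as np
import pandas as pd
import pytest

from polymr import (
    SimConfig,
    SummaryStatsSet,
    harmonize,
    simulate_panel,
    simulate_two_sample_gwas,
)


def make_sumstats(rows, trait_name="trait"):
    """Build a SummaryStatsSet from a list of dicts with defaults filled in."""
    defaults = {
        "chromosome": "1",
        "eaf": 0.3,
        "n": 10_000,
    }
    records = pd.DataFrame([{**defaults, **r} for r in rows])
    return SummaryStatsSet(trait_name=trait_name, records=records)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def panel(sim_config):
    return simulate_panel(sim_config)


@pytest.fixture(scope="session")
def gwas_pair(sim_config, panel):
    return simulate_two_sample_gwas(sim_config, panel)


@pytest.fixture(scope="session")
def harmonized_gwas(gwas_pair):
    exposure, outcome, truth = gwas_pair
    table, _ = harmonize(exposure, outcome)
    return table, truth


def harmonized_frame(bx, by, se_out, se_exp=None, positions=None):
    """A minimal harmonized instrument table from arrays."""
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(k)],
            "chromosome": "1",
            "position": positions if positions is not None else np.arange(k) * 1000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exposure": bx,
            "se_exposure": se_exp if se_exp is not None else np.full(k, 0.01),
            "beta_outcome": np.asarray(by, dtype=float),
            "se_outcome": np.asarray(se_out, dtype=float),
            "pvalue_exposure": np.full(k, 1e-10),
            "eaf_exposure": 0.3,
            "eaf_outcome": 0.3,
        }
    )
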