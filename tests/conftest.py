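import numpy as np
import pytest

from catbank.bank import Item, ItemBank
from catbank.synthetic import SimulationConfig, generate_bank, simulate_responses, study_like_config


@pytest.fixture(scope="session")
def dichotomous_bank():
    """One two-category item centred at zero: the logistic midpoint case."""
    return ItemBank([Item("i1", 2, 1.0, [0.0])])


@pytest.fixture(scope="session")
def symmetric_bank():
    """Five-item bank with thresholds symmetric about zero."""
    items = [
        Item(f"s{i+1}", 4, a, [-c, 0.0, c])
        for i, (a, c) in enumerate([(1.0, 1.0), (1.5, 0.8), (0.8, 1.4),
                                    (2.0, 0.6), (1.2, 1.1)])
    ]
    return ItemBank(items)


@pytest.fixture(scope="session")
def study_data():
    """Study-like cohort: 458 persons x 24 five-point items with redundancy,
    reverse coding, grouping variables and missingness."""
    cfg = study_like_config(seed=11)
    params, bank = generate_bank(cfg)
    responses, groups = simulate_responses(params, cfg)
    return cfg, params, bank, responses, groups


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete (no missing/NA) 21-item cohort from a known bank."""
    cfg = SimulationConfig(n_persons=1000, n_items=21, n_categories=5, seed=29)
    params, bank = generate_bank(cfg)
    responses, groups = simulate_responses(params, cfg)
    return cfg, params, bank, responses, groups
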