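import numpy as np
import pandas as pd
import pytest

from brainasym import (
    EffectSpec,
    SiteSpec,
    build_ai_table,
    default_catalog,
    default_sites,
    generate_cohort,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def null_cohort(catalog):
    """Small multi-site cohort with no effects and no artifacts."""
    sites = default_sites(n_sites=6, cases_per_site=60, controls_per_site=60)
    table, effects = generate_cohort(catalog, sites, EffectSpec.null(), seed=11)
    return table, effects


@pytest.fixture(scope="session")
def null_ai(null_cohort, catalog):
    table, _ = null_cohort
    return build_ai_table(table, catalog)


@pytest.fixture(scope="session")
def effect_cohort(catalog):
    """Cohort with a sizeable diagnosis effect on one thickness AI."""
    sites = default_sites(n_sites=8, cases_per_site=80, controls_per_site=80)
    effects = EffectSpec(d_true={"thick_middletemporal": -0.5})
    table, eff = generate_cohort(catalog, sites, effects, seed=21)
    return table, eff


@pytest.fixture(scope="session")
def effect_ai(effect_cohort, catalog):
    table, _ = effect_cohort
    return build_ai_table(table, catalog)


@pytest.fixture
def two_group_frame():
    """One dataset, two balanced groups, simple normal response."""
    rng = np.random.default_rng(7)
    n = 200
    dx = np.repeat([0, 1], n // 2)
    return pd.DataFrame(
        {
            "dataset_id": "d0",
            "scanner_id": "s0",
            "diagnosis": dx,
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(35, 9, n).round(1),
            "handedness": np.where(rng.random(n) < 0.9, "R", "L"),
            "icv": rng.normal(1.4e6, 1e5, n),
            "y": rng.normal(0, 1, n) + 0.3 * dx,
        }
    )
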