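"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

import episig as E
from helpers import cohort_groups as groups


@pytest.fixture(scope="session")
def strong_cohort():
    """A desk-scale cohort with strong planted effects: 500 sites, 40-site
    signature, 19 controls + 7 cases + 28 candidates + 30 held-out controls."""
    cfg = E.CohortConfig(
        n_sites=500, n_signature_sites=40, effect_delta=3.0,
        n_independent_controls=30, seed=11,
    )
    bm, sheet, truth = E.generate_cohort(cfg)
    return cfg, bm, sheet, truth


@pytest.fixture(scope="session")
def strong_m(strong_cohort):
    _, bm, _, _ = strong_cohort
    return E.beta_to_m(bm)


@pytest.fixture(scope="session")
def insilico(strong_cohort):
    """Leave-2-out in-silico mosaic cohort, models and band on the strong
    cohort's planted signature (controls double as the unaffected pool)."""
    cfg, bm, sheet, truth = strong_cohort
    g = groups(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, models = E.generate_insilico_cohort(
            bm.values, truth.signature_site_ids, g["case_initial"], g["control"],
            g["case_initial"], g["control"], per_combo=60, seed=7,
        )
        band = E.build_band(table, seed=7)
    return table, models, band


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_beta():
    """10 probes × 6 samples with crafted flags/detection-p for QC tests."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(0.05, 0.95, (10, 6)),
        index=[f"cg{i:02d}" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
    det = pd.DataFrame(0.001, index=vals.index, columns=vals.columns)
    flags = pd.DataFrame(False, index=vals.index, columns=["sex_chromosome"])
    return vals, det, flags
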