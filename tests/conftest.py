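import numpy as np
import pandas as pd
import pytest

import staplecea as sc


@pytest.fixture(scope="session")
def default_params():
    return sc.default_params()


@pytest.fixture(scope="session")
def pool2000():
    """Confounded synthetic pool large enough for matching diagnostics."""
    return sc.generate_cohort(sc.default_params(n_pool=2000), seed=42)


@pytest.fixture(scope="session")
def matched_pool(pool2000):
    scores, _ = sc.fit_propensity(pool2000)
    pairs = sc.match_one_to_one(pool2000, scores)
    return sc.matching.matched_cohort(pool2000, pairs)


def make_ten_patient_cohort() -> pd.DataFrame:
    """Hand-countable cohort: MCS 5 patients (2 leaks: one A|B no stoma, one C
    with stoma), ECPS 5 patients (1 grade-C leak, no stoma; 1 leak-free
    stoma)."""
    rows = [
        # arm, leak, grade, stoma, cost
        ("MCS", False, "none", False, 1000.0),
        ("MCS", False, "none", False, 2000.0),
        ("MCS", False, "none", False, 3000.0),
        ("MCS", True, "AB", False, 10000.0),
        ("MCS", True, "C", True, 30000.0),
        ("ECPS", False, "none", False, 1500.0),
        ("ECPS", False, "none", False, 2500.0),
        ("ECPS", False, "none", True, 4000.0),
        ("ECPS", False, "none", False, 2000.0),
        ("ECPS", True, "C", False, 20000.0),
    ]
    return pd.DataFrame(
        {
            "patient_id": [f"H{i}" for i in range(10)],
            "arm": [r[0] for r in rows],
            "leak": [r[1] for r in rows],
            "leak_grade": [r[2] for r in rows],
            "definitive_stoma": [r[3] for r in rows],
            "total_cost": [r[4] for r in rows],
        }
    )


@pytest.fixture()
def ten_patient_cohort():
    return make_ten_patient_cohort()


def binom99(count: int, n: int, p: float) -> bool:
    """Is `count` inside the exact binomial 99% central interval at (n, p)?"""
    from scipy.stats import binom

    return binom.ppf(0.005, n, p) <= count <= binom.ppf(0.995, n, p)
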