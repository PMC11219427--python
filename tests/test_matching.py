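"""Propensity model, caliper matching and balance diagnostics, checked
against brute-force likelihood and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import staplecea as sc
from staplecea.matching import MatchConfig, standardized_mean_differences


def _cohort_from_scores(treated_logits, control_logits):
    ids = [f"t{i}" for i in range(len(treated_logits))] + [
        f"c{i}" for i in range(len(control_logits))
    ]
    arms = ["ECPS"] * len(treated_logits) + ["MCS"] * len(control_logits)
    cohort = pd.DataFrame({"patient_id": ids, "arm": arms})
    scores = pd.Series(expit(np.r_[treated_logits, control_logits]), index=ids)
    return cohort, scores


def brute_force_best_pairing(treated_logits, control_logits, width):
    """Enumerate all injective pairings; return (max #pairs, min total
    distance among maximal pairings)."""
    nt, nc = len(treated_logits), len(control_logits)
    best = (0, 0.0)
    for k in range(min(nt, nc), 0, -1):
        feasible = []
        for t_sub in itertools.combinations(range(nt), k):
            for c_perm in itertools.permutations(range(nc), k):
                d = [abs(treated_logits[t] - control_logits[c]) for t, c in zip(t_sub, c_perm)]
                if all(x <= width for x in d):
                    feasible.append(sum(d))
        if feasible:
            return k, min(feasible)
    return best


# --- propensity model ------------------------------------------------------

def test_null_model_scores_near_arm_proportion():
    """With a covariate independent of the arm, fitted scores collapse to the
    arm proportion (null-model limit)."""
    rng = np.random.default_rng(0)
    n = 2000
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "arm": np.where(rng.random(n) < 0.5, "ECPS", "MCS"),
            "sex": np.where(rng.random(n) < 0.4, "F", "M"),
        }
    )
    scores, _ = sc.fit_propensity(df, covariates=("sex",))
    prop = (df["arm"] == "ECPS").mean()
    assert np.abs(scores.to_numpy() - prop).max() < 0.05


def test_logistic_fit_matches_grid_search_oracle():
    """6-patient fit equals a brute-force likelihood search to 1e-4."""
    df = pd.DataFrame(
        {
            "patient_id": list("abcdef"),
            "arm": ["ECPS"] * 3 + ["MCS"] * 3,
            "x": [1, 1, 0, 1, 0, 0],
        }
    )
    _, coefs = sc.fit_propensity(df, covariates=("x",))

    y = np.array([1, 1, 1, 0, 0, 0])
    x = np.array([1, 1, 0, 1, 0, 0])

    def nll(b0, b1):
        eta = b0 + b1 * x
        return -np.sum(y * eta - np.logaddexp(0, eta))

    # coarse-to-fine grid search
    b0, b1, span = 0.0, 0.0, 4.0
    for _ in range(18):
        g0 = np.linspace(b0 - span, b0 + span, 21)
        g1 = np.linspace(b1 - span, b1 + span, 21)
        vals = [(nll(a, b), a, b) for a in g0 for b in g1]
        _, b0, b1 = min(vals)
        span /= 3
    assert coefs["const"] == pytest.approx(b0, abs=1e-4)
    assert coefs["x"] == pytest.approx(b1, abs=1e-4)
    # analytic check on the saturated model
    assert coefs["const"] == pytest.approx(np.log(0.5), abs=1e-4)


def test_single_arm_cohort_is_an_error():
    df = pd.DataFrame({"patient_id": ["a", "b"], "arm": ["MCS", "MCS"], "age": [50, 60]})
    with pytest.raises(ValueError, match="both arms"):
        sc.fit_propensity(df, covariates=("age",))


def test_perfect_separation_is_an_explicit_error():
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(40)],
            "arm": ["ECPS"] * 20 + ["MCS"] * 20,
            "x": [1.0] * 20 + [0.0] * 20,
        }
    )
    with pytest.raises(ValueError, match="separation"):
        sc.fit_propensity(df, covariates=("x",))


def test_label_swap_symmetry(pool2000):
    """Swapping arm labels negates coefficients and maps scores to 1 - p."""
    scores, coefs = sc.fit_propensity(pool2000)
    swapped = pool2000.copy()
    swapped["arm"] = np.where(swapped["arm"] == "ECPS", "MCS", "ECPS")
    scores2, coefs2 = sc.fit_propensity(swapped)
    assert np.allclose(coefs.to_numpy(), -coefs2.to_numpy(), atol=1e-6)
    assert np.allclose(scores.to_numpy(), 1 - scores2.to_numpy(), atol=1e-8)


# --- matching --------------------------------------------------------------

def test_caliper_matching_equals_enumeration_on_spec_instance():
    """Treated logits {0, 1, 2} vs controls {0.1, 0.9, 5.0} under an absolute
    logit caliper of 0.3: two pairs, third treated unmatched."""
    t_logits, c_logits = [0.0, 1.0, 2.0], [0.1, 0.9, 5.0]
    cohort, scores = _cohort_from_scores(t_logits, c_logits)
    cfg = MatchConfig(caliper=0.3, caliper_scale="logit")
    res = sc.match_one_to_one(cohort, scores, cfg)
    got = {(t, c) for t, c in res.pairs}
    assert got == {("t0", "c0"), ("t1", "c1")}
    assert "t2" in res.unmatched
    n_best, _ = brute_force_best_pairing(t_logits, c_logits, 0.3)
    assert res.n_pairs == n_best


def greedy_policy_oracle(t_logits, c_logits, width):
    """Transparent re-implementation of the matching policy: treated in
    descending logit (ties by id), nearest available control, caliper bound."""
    treated = sorted(range(len(t_logits)), key=lambda i: (-t_logits[i], f"t{i}"))
    available = set(range(len(c_logits)))
    pairs = []
    for t in treated:
        if not available:
            break
        best = min(sorted(available), key=lambda c: abs(c_logits[c] - t_logits[t]))
        if abs(c_logits[best] - t_logits[t]) <= width:
            pairs.append((f"t{t}", f"c{best}"))
            available.remove(best)
    return set(pairs)


@pytest.mark.parametrize("seed", range(8))
def test_greedy_matches_policy_oracle_on_tiny_instances(seed):
    """On random <= 6-patient instances the pairing is feasible, injective,
    no larger than the enumeration optimum, and equals an independent
    re-implementation of the greedy policy pair for pair."""
    rng = np.random.default_rng(seed)
    t_logits = list(np.round(rng.normal(0, 1, 3), 3))
    c_logits = list(np.round(rng.normal(0.3, 1, 3), 3))
    width = 0.8
    cohort, scores = _cohort_from_scores(t_logits, c_logits)
    res = sc.match_one_to_one(cohort, scores, MatchConfig(caliper=width, caliper_scale="logit"))
    pos = {pid: logit(scores[pid]) for pid in scores.index}
    assert all(abs(pos[t] - pos[c]) <= width + 1e-9 for t, c in res.pairs)
    flat = [pid for pair in res.pairs for pid in pair]
    assert len(flat) == len(set(flat))
    n_best, _ = brute_force_best_pairing(t_logits, c_logits, width)
    assert res.n_pairs <= n_best
    assert set(res.pairs) == greedy_policy_oracle(t_logits, c_logits, width)


def test_identical_score_multisets_match_fully():
    cohort, scores = _cohort_from_scores([0.2, 0.5, 0.9], [0.2, 0.5, 0.9, 1.4])
    res = sc.match_one_to_one(cohort, scores, MatchConfig(caliper=0.1, caliper_scale="logit"))
    assert res.n_pairs == 3
    assert all(scores[t] == scores[c] for t, c in res.pairs)


def test_empty_arm_yields_no_pairs():
    cohort = pd.DataFrame({"patient_id": ["a", "b"], "arm": ["MCS", "MCS"]})
    scores = pd.Series([0.5, 0.5], index=["a", "b"])
    res = sc.match_one_to_one(cohort, scores)
    assert res.n_pairs == 0
    assert set(res.unmatched) == {"a", "b"}


def test_pairs_obey_caliper_and_injectivity(pool2000):
    scores, _ = sc.fit_propensity(pool2000)
    res = sc.match_one_to_one(pool2000, scores)
    lg = pd.Series(logit(scores.to_numpy()), index=scores.index)
    assert all(abs(lg[t] - lg[c]) <= res.caliper_width + 1e-12 for t, c in res.pairs)
    flat = [pid for pair in res.pairs for pid in pair]
    assert len(flat) == len(set(flat))
    assert res.n_pairs <= min((pool2000["arm"] == a).sum() for a in ("MCS", "ECPS"))


# --- balance ---------------------------------------------------------------

def test_smd_hand_example():
    """Treated {1, 3} vs control {0, 2}: SMD = 1/sqrt(2)."""
    df = pd.DataFrame(
        {
            "patient_id": list("abcd"),
            "arm": ["ECPS", "ECPS", "MCS", "MCS"],
            "x": [1.0, 3.0, 0.0, 2.0],
        }
    )
    smd = standardized_mean_differences(df, covariates=("x",))
    assert smd["x"] == pytest.approx(1 / np.sqrt(2))


def test_identical_arms_have_zero_smd():
    df = pd.DataFrame(
        {
            "patient_id": list("abcd"),
            "arm": ["ECPS", "ECPS", "MCS", "MCS"],
            "x": [1.0, 3.0, 1.0, 3.0],
        }
    )
    assert standardized_mean_differences(df, covariates=("x",))["x"] == 0.0


def test_matching_improves_balance_on_confounded_pool(pool2000):
    scores, _ = sc.fit_propensity(pool2000)
    pairs = sc.match_one_to_one(pool2000, scores)
    bal = sc.balance_diagnostics(pool2000, pairs)
    assert bal["smd_after"].abs().max() < bal["smd_before"].abs().max()


def test_median_post_matching_smd_below_threshold():
    """Over 20 confounded pools (n = 2000), the median post-matching |SMD| is
    <= 0.1 for every matched covariate."""
    after = []
    for seed in range(20):
        pool = sc.generate_cohort(sc.default_params(n_pool=2000), seed=100 + seed)
        scores, _ = sc.fit_propensity(pool)
        pairs = sc.match_one_to_one(pool, scores)
        after.append(sc.balance_diagnostics(pool, pairs)["smd_after"].abs())
    med = pd.concat(after, axis=1).median(axis=1)
    assert (med <= 0.1).all(), med.sort_values()
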