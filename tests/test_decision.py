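"""Decision tree: validation, rollback against counting oracles, ICER and
dominance logic, serialization."""

import numpy as np
import pytest

import staplecea as sc
from staplecea import defaults
from staplecea.decision import (
    ChanceBranch,
    ChanceNode,
    DecisionTree,
    TerminalNode,
    tree_to_dict,
)

from conftest import make_ten_patient_cohort


def _leaf(cost, eff=1.0):
    return TerminalNode(cost=cost, effectiveness=eff)


def test_validate_flags_bad_probability_sum():
    tree = DecisionTree(
        strategies={
            "MCS": ChanceNode(
                [ChanceBranch(0.6, _leaf(1)), ChanceBranch(0.3, _leaf(2))], label="leak?"
            )
        }
    )
    violations = sc.validate_tree(tree)
    assert any("sum to 0.9" in v for v in violations)


def test_validate_single_leaf_strategy_ok():
    assert sc.validate_tree(DecisionTree(strategies={"MCS": _leaf(100.0)})) == []


def test_validate_reference_tree_ok():
    assert sc.validate_tree(sc.reference_tree()) == []


def test_rollback_single_terminal():
    res = sc.rollback(DecisionTree(strategies={"S": _leaf(100.0, 1.0)}))
    assert res["S"].expected_cost == 100.0
    assert res["S"].expected_effectiveness == 1.0


def test_rollback_hand_computed_chance_node():
    node = ChanceNode(
        [ChanceBranch(0.25, _leaf(200.0, 0.0)), ChanceBranch(0.75, _leaf(100.0, 1.0))]
    )
    res = sc.rollback(DecisionTree(strategies={"S": node}))
    assert res["S"].expected_cost == pytest.approx(125.0)
    assert res["S"].expected_effectiveness == pytest.approx(0.75)


def test_rollback_degenerate_probabilities():
    node = ChanceNode([ChanceBranch(0.0, _leaf(999.0, 0.0)), ChanceBranch(1.0, _leaf(10.0, 1.0))])
    res = sc.rollback(DecisionTree(strategies={"S": node}))
    assert res["S"].expected_cost == 10.0


def test_rollback_rejects_invalid_tree():
    tree = DecisionTree(strategies={"S": ChanceNode([ChanceBranch(0.5, _leaf(1))])})
    with pytest.raises(ValueError, match="sum"):
        sc.rollback(tree)


# --- estimation from a cohort ---------------------------------------------

def test_estimated_probabilities_equal_hand_counts(ten_patient_cohort):
    tree = sc.estimate_tree_parameters(ten_patient_cohort)
    mcs = tree.strategies["MCS"]
    leak_br = {br.label: br for br in mcs.branches}
    assert leak_br["leak"].probability == pytest.approx(2 / 5)
    mgmt = {br.label: br for br in leak_br["leak"].node.branches}
    assert mgmt["conservative"].probability == pytest.approx(1 / 2)
    assert mgmt["surgical"].probability == pytest.approx(1 / 2)
    ecps = tree.strategies["ECPS"]
    ecps_br = {br.label: br for br in ecps.branches}
    assert ecps_br["leak"].probability == pytest.approx(1 / 5)
    # ECPS leaks are all grade C: management chance node collapses
    assert isinstance(ecps_br["leak"].node, TerminalNode)


def test_rollback_equals_counting_oracle(ten_patient_cohort):
    """Rollback of a tree estimated from a cohort returns exactly the arm
    mean cost and 1 - stoma proportion."""
    tree = sc.estimate_tree_parameters(ten_patient_cohort)
    res = sc.rollback(tree)
    for arm in ("MCS", "ECPS"):
        sub = ten_patient_cohort[ten_patient_cohort["arm"] == arm]
        assert res[arm].expected_cost == pytest.approx(sub["total_cost"].mean(), rel=1e-12)
        assert res[arm].expected_effectiveness == pytest.approx(
            1 - sub["definitive_stoma"].mean(), rel=1e-12
        )


def test_rollback_equals_counting_oracle_on_generated_cohort(default_params):
    df = sc.generate_cohort(default_params, seed=12)
    res = sc.rollback(sc.estimate_tree_parameters(df))
    for arm in ("MCS", "ECPS"):
        sub = df[df["arm"] == arm]
        assert res[arm].expected_cost == pytest.approx(sub["total_cost"].mean(), rel=1e-12)
        assert res[arm].expected_effectiveness == pytest.approx(
            1 - sub["definitive_stoma"].mean(), rel=1e-12
        )


def test_zero_leak_arm_collapses_leak_branch(ten_patient_cohort):
    df = ten_patient_cohort.copy()
    df.loc[df["arm"] == "ECPS", ["leak"]] = False
    df.loc[df["arm"] == "ECPS", "leak_grade"] = "none"
    tree = sc.estimate_tree_parameters(df)
    labels = {br.label for br in tree.strategies["ECPS"].branches} if isinstance(
        tree.strategies["ECPS"], ChanceNode
    ) else set()
    assert "leak" not in labels
    res = sc.rollback(tree)
    sub = df[df["arm"] == "ECPS"]
    assert res["ECPS"].expected_cost == pytest.approx(sub["total_cost"].mean())


def test_rollback_linearity(ten_patient_cohort):
    """Scaling all terminal costs by k scales expected cost by k and leaves
    effectiveness unchanged."""
    tree = sc.estimate_tree_parameters(ten_patient_cohort)
    base = sc.rollback(tree)
    from staplecea.psa import iter_nodes

    for _, node in iter_nodes(tree):
        if isinstance(node, TerminalNode):
            node.cost *= 3.0
    scaled = sc.rollback(tree)
    for arm in ("MCS", "ECPS"):
        assert scaled[arm].expected_cost == pytest.approx(3 * base[arm].expected_cost)
        assert scaled[arm].expected_effectiveness == base[arm].expected_effectiveness


# --- reference tree --------------------------------------------------------

def test_reference_tree_reproduces_scenario_aggregates():
    res = sc.rollback(sc.reference_tree())
    assert res["MCS"].expected_cost == pytest.approx(defaults.GROUP_MEAN_COST["MCS"])
    assert res["ECPS"].expected_cost == pytest.approx(defaults.GROUP_MEAN_COST["ECPS"])
    assert res["MCS"].expected_effectiveness == pytest.approx(1 - 11 / 165)
    assert res["ECPS"].expected_effectiveness == pytest.approx(1 - 5 / 165)


# --- ICER ------------------------------------------------------------------

def test_icer_on_reference_inputs():
    """Group means 6238.38 vs 9700.12 and effectiveness 98.27% vs 93.69%
    give ICER ~ -75,584 euros per patient free of complications."""
    inc = sc.icer(sc.StrategyResult(6238.38, 0.9827), sc.StrategyResult(9700.12, 0.9369))
    assert inc.delta_cost == pytest.approx(-3461.74)
    assert inc.delta_effectiveness == pytest.approx(0.0458)
    assert inc.icer == pytest.approx(-75_583.84, abs=0.5)
    assert inc.dominance == "dominant"


def test_icer_equivalent_strategies():
    inc = sc.icer(sc.StrategyResult(100.0, 0.5), sc.StrategyResult(100.0, 0.5))
    assert inc.icer is None
    assert inc.dominance == "equivalent"


def test_icer_dominated_quadrant():
    inc = sc.icer(sc.StrategyResult(100.0, 0.5), sc.StrategyResult(50.0, 1.0))
    assert inc.delta_cost == 50.0
    assert inc.delta_effectiveness == -0.5
    assert inc.dominance == "dominated"


def test_icer_trade_off_quadrants():
    assert sc.icer(sc.StrategyResult(100, 1.0), sc.StrategyResult(50, 0.5)).dominance == "trade-off_NE"
    assert sc.icer(sc.StrategyResult(50, 0.5), sc.StrategyResult(100, 1.0)).dominance == "trade-off_SW"


def test_icer_antisymmetry():
    a, b = sc.StrategyResult(6238.38, 0.9827), sc.StrategyResult(9700.12, 0.9369)
    fwd, rev = sc.icer(a, b), sc.icer(b, a)
    assert rev.delta_cost == -fwd.delta_cost
    assert rev.delta_effectiveness == -fwd.delta_effectiveness
    assert abs(rev.icer) == pytest.approx(abs(fwd.icer))
    assert (fwd.dominance, rev.dominance) == ("dominant", "dominated")


def test_icer_rejects_non_finite():
    with pytest.raises(ValueError, match="finite"):
        sc.icer(sc.StrategyResult(np.nan, 0.5), sc.StrategyResult(1.0, 0.5))


# --- serialization ---------------------------------------------------------

def test_tree_yaml_round_trip(tmp_path):
    tree = sc.reference_tree()
    path = tmp_path / "tree.yaml"
    sc.write_tree(tree, path)
    back = sc.read_tree(path)
    assert tree_to_dict(back) == tree_to_dict(tree)
    res_a, res_b = sc.rollback(tree), sc.rollback(back)
    for arm in ("MCS", "ECPS"):
        assert res_a[arm] == res_b[arm]
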