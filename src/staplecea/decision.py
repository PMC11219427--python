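"""Two-strategy decision tree, expected-value rollback, ICER and dominance.

The default topology per strategy (device arm) is: chance node on anastomotic
leak -> leak branch splits into conservative (grade A|B) vs surgical (grade C)
management -> each path ends in definitive-stoma / no-stoma terminals.
Terminal payoffs are a euro cost (the stratum mean) and an effectiveness
contribution of 1 for no definitive stoma, 0 otherwise, so strategy
effectiveness rolls up to 1 minus the definitive-stoma proportion.

Chance branches optionally carry the event count behind their probability and
terminals the (SD, n) behind their mean cost; the PSA module turns these into
uncertainty distributions.  Rollback is exact arithmetic (no sampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import defaults

log = logging.getLogger(__name__)

_PROB_TOL = 1e-9


@dataclass
class TerminalNode:
    cost: float
    effectiveness: float
    label: str = ""
    cost_sd: float = 0.0  # patient-level SD behind `cost` (0 = fixed)
    n: int = 0            # stratum size behind `cost` (0 = fixed)


@dataclass
class ChanceBranch:
    probability: float
    node: "ChanceNode | TerminalNode"
    label: str = ""
    count: float | None = None  # events behind `probability`, for the PSA


@dataclass
class ChanceNode:
    branches: list = field(default_factory=list)
    label: str = ""


@dataclass
class DecisionTree:
    """Root decision node: one subtree per strategy."""

    strategies: dict = field(default_factory=dict)  # name -> node


@dataclass
class StrategyResult:
    expected_cost: float
    expected_effectiveness: float


@dataclass
class ICERResult:
    delta_cost: float
    delta_effectiveness: float
    icer: float | None  # None when delta_effectiveness == 0
    dominance: str      # dominant | dominated | trade-off_NE | trade-off_SW | equivalent


# ---------------------------------------------------------------------------
# validation & rollback
# ---------------------------------------------------------------------------

def _walk(node, path, violations):
    if isinstance(node, TerminalNode):
        if not np.isfinite(node.cost):
            violations.append(f"{path}: terminal cost is not finite")
        if not 0.0 <= node.effectiveness <= 1.0:
            violations.append(f"{path}: terminal effectiveness outside [0, 1]")
        return
    if isinstance(node, ChanceNode):
        if not node.branches:
            violations.append(f"{path}: chance node has no branches")
            return
        total = 0.0
        for i, br in enumerate(node.branches):
            if not 0.0 <= br.probability <= 1.0:
                violations.append(
                    f"{path}/{br.label or i}: probability {br.probability} outside [0, 1]"
                )
            total += br.probability
            _walk(br.node, f"{path}/{br.label or i}", violations)
        if abs(total - 1.0) > _PROB_TOL:
            violations.append(f"{path}: probabilities sum to {total:.10g}")
        return
    violations.append(f"{path}: unknown node type {type(node).__name__}")


def validate_tree(tree: DecisionTree) -> list:
    """All invariant violations, each with the node path; empty list = ok."""
    violations: list = []
    if not tree.strategies:
        violations.append("root: no strategies")
    for name, node in tree.strategies.items():
        _walk(node, name, violations)
    return violations


def _rollback_node(node):
    if isinstance(node, TerminalNode):
        return node.cost, node.effectiveness
    cost = eff = 0.0
    for br in node.branches:
        c, e = _rollback_node(br.node)
        cost += br.probability * c
        eff += br.probability * e
    return cost, eff


def rollback(tree: DecisionTree) -> dict:
    """Probability-weighted expected (cost, effectiveness) per strategy."""
    violations = validate_tree(tree)
    if violations:
        raise ValueError("invalid tree: " + "; ".join(violations))
    return {
        name: StrategyResult(*_rollback_node(node)) for name, node in tree.strategies.items()
    }


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

def icer(result_ecps: StrategyResult, result_mcs: StrategyResult) -> ICERResult:
    """Incremental cost-effectiveness ratio, deltas as ECPS minus MCS.

    Dominance by quadrant of (delta_effectiveness, delta_cost): dominant when
    cheaper and more effective, dominated when costlier and less effective,
    otherwise a trade-off (NE: more effective and costlier; SW: less effective
    and cheaper); equivalent when both deltas are zero.
    """
    for res in (result_ecps, result_mcs):
        if not (np.isfinite(res.expected_cost) and np.isfinite(res.expected_effectiveness)):
            raise ValueError("strategy results must be finite")
    dc = result_ecps.expected_cost - result_mcs.expected_cost
    de = result_ecps.expected_effectiveness - result_mcs.expected_effectiveness
    ratio = dc / de if de != 0 else None
    if dc == 0 and de == 0:
        dom = "equivalent"
    elif de > 0 and dc < 0:
        dom = "dominant"
    elif de < 0 and dc > 0:
        dom = "dominated"
    elif de >= 0:
        dom = "trade-off_NE"
    else:
        dom = "trade-off_SW"
    return ICERResult(delta_cost=dc, delta_effectiveness=de, icer=ratio, dominance=dom)


# ---------------------------------------------------------------------------
# estimation from a cohort
# ---------------------------------------------------------------------------

def _stoma_subtree(stratum: pd.DataFrame, label: str):
    """Terminal pair (stoma / no-stoma) for one management stratum; empty
    stoma classes collapse to a single terminal."""
    n = len(stratum)
    stoma = stratum["definitive_stoma"].astype(bool)
    branches = []
    for has_stoma, tag in ((True, "stoma"), (False, "no_stoma")):
        sub = stratum[stoma] if has_stoma else stratum[~stoma]
        if len(sub) == 0:
            continue
        branches.append(
            ChanceBranch(
                probability=len(sub) / n,
                node=TerminalNode(
                    cost=float(sub["total_cost"].mean()),
                    effectiveness=0.0 if has_stoma else 1.0,
                    label=f"{label}/{tag}",
                    cost_sd=float(sub["total_cost"].std(ddof=1)) if len(sub) > 1 else 0.0,
                    n=len(sub),
                ),
                label=tag,
                count=len(sub),
            )
        )
    if len(branches) == 1:
        return branches[0].node
    return ChanceNode(branches=branches, label=f"{label}/stoma?")


def estimate_tree_parameters(cohort: pd.DataFrame, strategies=("MCS", "ECPS")) -> DecisionTree:
    """Build the default-topology tree from a matched cohort by counting.

    Branch probabilities are observed frequencies; terminal costs are stratum
    mean total costs.  Empty strata collapse with a logged warning (their
    probability is 0, so rollback is unaffected).
    """
    for col in ("arm", "leak", "leak_grade", "definitive_stoma", "total_cost"):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks required column {col!r}")
    tree = DecisionTree()
    for arm in strategies:
        sub = cohort[cohort["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no patients in arm {arm!r}")
        leak = sub["leak"].astype(bool)
        p_leak = float(leak.mean())
        no_leak_node = _stoma_subtree(sub[~leak], f"{arm}/no_leak") if (~leak).any() else None
        if leak.any():
            leakers = sub[leak]
            mgmt_branches = []
            for grade, tag in (("AB", "conservative"), ("C", "surgical")):
                grp = leakers[leakers["leak_grade"] == grade]
                if len(grp) == 0:
                    log.warning("%s: empty %s-management stratum collapsed", arm, tag)
                    continue
                mgmt_branches.append(
                    ChanceBranch(
                        probability=len(grp) / len(leakers),
                        node=_stoma_subtree(grp, f"{arm}/leak/{tag}"),
                        label=tag,
                        count=len(grp),
                    )
                )
            leak_node = (
                mgmt_branches[0].node
                if len(mgmt_branches) == 1
                else ChanceNode(branches=mgmt_branches, label=f"{arm}/management")
            )
        else:
            leak_node = None
        branches = []
        if leak_node is not None:
            branches.append(
                ChanceBranch(p_leak, leak_node, label="leak", count=int(leak.sum()))
            )
        if no_leak_node is not None:
            branches.append(
                ChanceBranch(1.0 - p_leak, no_leak_node, label="no_leak",
                             count=int((~leak).sum()))
            )
        tree.strategies[arm] = (
            branches[0].node if len(branches) == 1 else ChanceNode(branches, label=f"{arm}/leak?")
        )
    return tree


# ---------------------------------------------------------------------------
# reference tree from the bundled scenario
# ---------------------------------------------------------------------------

def _within_stratum_sd(arm: str, m_leak: float, m_no_leak: float) -> float:
    """Within-stratum cost SD by law-of-total-variance decomposition of the
    scenario's marginal SD (equal SD in both strata assumed)."""
    p = defaults.LEAK_EVENTS[arm] / defaults.ARM_N
    total_var = defaults.GROUP_SD_COST[arm] ** 2
    between = p * (1 - p) * (m_leak - m_no_leak) ** 2
    return float(np.sqrt(max(total_var - between, 0.0)))


def reference_tree() -> DecisionTree:
    """Fig-2-shaped tree parameterized from the bundled reference scenario.

    Leak probabilities, the management split and the stoma apportionment come
    from the scenario counts; all leak terminals carry the scenario's mean
    leak-patient cost, the no-leak terminals the complementary mean that
    reproduces the arm's overall mean cost.
    """
    n = defaults.ARM_N
    tree = DecisionTree()
    for arm in ("MCS", "ECPS"):
        leaks = defaults.LEAK_EVENTS[arm]
        grade_c = defaults.GRADE_C_EVENTS[arm]
        grade_ab = leaks - grade_c
        stoma_c = defaults.STOMA_AFTER_GRADE_C[arm]
        stoma_0 = defaults.STOMA_WITHOUT_LEAK[arm]
        p_leak = leaks / n
        m_leak = defaults.LEAK_MEAN_COST
        m_no_leak = (defaults.GROUP_MEAN_COST[arm] - p_leak * m_leak) / (1 - p_leak)
        sd_w = _within_stratum_sd(arm, m_leak, m_no_leak)

        def terminal(label, cost, eff, count):
            return TerminalNode(cost=cost, effectiveness=eff, label=f"{arm}/{label}",
                                cost_sd=sd_w, n=count)

        def stoma_node(label, n_stoma, n_total, cost):
            branches = []
            if n_stoma > 0:
                branches.append(ChanceBranch(n_stoma / n_total,
                                             terminal(f"{label}/stoma", cost, 0.0, n_stoma),
                                             label="stoma", count=n_stoma))
            if n_total - n_stoma > 0:
                branches.append(ChanceBranch((n_total - n_stoma) / n_total,
                                             terminal(f"{label}/no_stoma", cost, 1.0,
                                                      n_total - n_stoma),
                                             label="no_stoma", count=n_total - n_stoma))
            return branches[0].node if len(branches) == 1 else ChanceNode(
                branches, label=f"{arm}/{label}/stoma?")

        mgmt_branches = []
        if grade_ab > 0:
            mgmt_branches.append(ChanceBranch(grade_ab / leaks,
                                              stoma_node("leak/conservative", 0, grade_ab, m_leak),
                                              label="conservative", count=grade_ab))
        mgmt_branches.append(ChanceBranch(grade_c / leaks,
                                          stoma_node("leak/surgical", stoma_c, grade_c, m_leak),
                                          label="surgical", count=grade_c))
        leak_node = (mgmt_branches[0].node if len(mgmt_branches) == 1
                     else ChanceNode(mgmt_branches, label=f"{arm}/management"))
        no_leak_node = stoma_node("no_leak", stoma_0, n - leaks, m_no_leak)
        tree.strategies[arm] = ChanceNode(
            [
                ChanceBranch(p_leak, leak_node, label="leak", count=leaks),
                ChanceBranch(1 - p_leak, no_leak_node, label="no_leak", count=n - leaks),
            ],
            label=f"{arm}/leak?",
        )
    return tree


# ---------------------------------------------------------------------------
# serialization (lossless YAML round-trip)
# ---------------------------------------------------------------------------

def _node_to_dict(node):
    if isinstance(node, TerminalNode):
        return {
            "type": "terminal", "cost": node.cost, "effectiveness": node.effectiveness,
            "label": node.label, "cost_sd": node.cost_sd, "n": node.n,
        }
    return {
        "type": "chance", "label": node.label,
        "branches": [
            {"probability": br.probability, "label": br.label, "count": br.count,
             "node": _node_to_dict(br.node)}
            for br in node.branches
        ],
    }


def _node_from_dict(d):
    if d["type"] == "terminal":
        return TerminalNode(cost=d["cost"], effectiveness=d["effectiveness"],
                            label=d.get("label", ""), cost_sd=d.get("cost_sd", 0.0),
                            n=d.get("n", 0))
    return ChanceNode(
        branches=[
            ChanceBranch(probability=b["probability"], node=_node_from_dict(b["node"]),
                         label=b.get("label", ""), count=b.get("count"))
            for b in d["branches"]
        ],
        label=d.get("label", ""),
    )


def tree_to_dict(tree: DecisionTree) -> dict:
    return {"strategies": {k: _node_to_dict(v) for k, v in tree.strategies.items()}}


def tree_from_dict(d) -> DecisionTree:
    return DecisionTree(strategies={k: _node_from_dict(v) for k, v in d["strategies"].items()})


def write_tree(tree: DecisionTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(tree_to_dict(tree), fh, sort_keys=False)


def read_tree(path) -> DecisionTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_dict(yaml.safe_load(fh))
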