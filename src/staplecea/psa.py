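"""Probabilistic sensitivity analysis of the decision tree.

Parameter uncertainty follows the standard health-economics conventions:
branch probabilities get Beta(events, non-events) distributions (Dirichlet
over multi-way splits), terminal mean costs get gamma distributions by method
of moments, and fixed quantities stay point masses.  Each Monte Carlo draw
resamples every parameter independently, rebuilds the tree, rolls back both
strategies and records the incremental pair (delta effectiveness, delta cost);
the cloud is summarized on the cost-effectiveness plane and as a
cost-effectiveness acceptability curve (CEAC).

Zero-count branches (structural zeros, e.g. a management stratum no patient
occupied) keep their point probability: a Beta or Dirichlet with a zero
concentration is undefined, and resampling a branch no data supports would
invent events.  A single seeded generator samples parameters in a fixed
(path-sorted) order, so results are reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import ChanceNode, DecisionTree, TerminalNode, icer, rollback, validate_tree

QUADRANTS = ("I", "II", "III", "IV")


@dataclass
class ParameterDistribution:
    """Uncertainty distribution attached to one tree quantity.

    ``target`` is the node path (strategy name + branch labels).  ``kind`` is
    one of ``beta`` (two-way probability), ``dirichlet`` (multi-way split),
    ``gamma`` (terminal mean cost) or ``point`` (fixed).
    """

    kind: str
    target: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "beta":
            if self.params["alpha"] <= 0 or self.params["beta"] <= 0:
                raise ValueError(f"{self.target}: beta parameters must be > 0")
        elif self.kind == "dirichlet":
            if any(a <= 0 for a in self.params["alpha"]):
                raise ValueError(f"{self.target}: dirichlet concentrations must be > 0")
        elif self.kind == "gamma":
            if self.params["shape"] <= 0 or self.params["scale"] <= 0:
                raise ValueError(f"{self.target}: gamma parameters must be > 0")
        elif self.kind != "point":
            raise ValueError(f"{self.target}: unknown distribution kind {self.kind!r}")


def gamma_from_mean_sd(mean: float, sd: float) -> tuple:
    """Method-of-moments gamma: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0 for a gamma distribution")
    return (mean / sd) ** 2, sd**2 / mean


def iter_nodes(tree: DecisionTree):
    """Yield ``(path, node)`` depth-first; paths are strategy/branch-label
    chains (branch index where a label is missing)."""

    def walk(node, path):
        yield path, node
        if isinstance(node, ChanceNode):
            for i, br in enumerate(node.branches):
                yield from walk(br.node, f"{path}/{br.label or i}")

    for name, node in tree.strategies.items():
        yield from walk(node, name)


def assign_distributions(tree: DecisionTree, cost_uncertainty: str = "se") -> list:
    """Default uncertainty set for every tree parameter.

    Chance-node probabilities with positive counts on every branch become
    Beta (two branches) or Dirichlet (more); any zero or missing count keeps
    the node fixed (structural).  Terminal mean costs with a recorded
    ``(cost_sd, n)`` become gamma around the mean with SD equal to the
    standard error of the mean (``cost_uncertainty="se"``, the default) or
    the patient-level SD (``"sd"``); ``cost_sd`` 0 is a point mass.
    """
    if cost_uncertainty not in ("se", "sd"):
        raise ValueError("cost_uncertainty must be 'se' or 'sd'")
    dists = []
    for path, node in iter_nodes(tree):
        if isinstance(node, ChanceNode):
            counts = [br.count for br in node.branches]
            if any(c is None for c in counts):
                dists.append(ParameterDistribution("point", path))
                continue
            if sum(counts) == 0:
                raise ValueError(f"{path}: zero events and zero non-events")
            if any(c == 0 for c in counts):
                dists.append(ParameterDistribution("point", path))
            elif len(counts) == 2:
                dists.append(
                    ParameterDistribution(
                        "beta", path, {"alpha": float(counts[0]), "beta": float(counts[1])}
                    )
                )
            else:
                dists.append(
                    ParameterDistribution("dirichlet", path, {"alpha": [float(c) for c in counts]})
                )
        else:  # terminal
            sd = node.cost_sd if cost_uncertainty == "sd" else (
                node.cost_sd / np.sqrt(node.n) if node.n > 0 else 0.0
            )
            if node.cost > 0 and sd > 0:
                shape, scale = gamma_from_mean_sd(node.cost, sd)
                dists.append(
                    ParameterDistribution("gamma", path, {"shape": shape, "scale": scale})
                )
            else:
                dists.append(ParameterDistribution("point", path))
    return dists


@dataclass
class PSAResult:
    draws: pd.DataFrame  # columns: delta_effectiveness, delta_cost
    seed: int
    base_case: object    # ICERResult of the unperturbed tree

    @property
    def n(self) -> int:
        return len(self.draws)

    def quadrant_proportions(self) -> dict:
        return quadrant_proportions(self.draws)

    def summary(self) -> dict:
        q = self.quadrant_proportions()
        return {
            "n": self.n,
            "seed": self.seed,
            "mean_delta_effectiveness": float(self.draws["delta_effectiveness"].mean()),
            "mean_delta_cost": float(self.draws["delta_cost"].mean()),
            "quadrant_proportions": {k: q[k] for k in QUADRANTS},
            "dominant_fraction": q["II"],
            "base_case": {
                "delta_cost": self.base_case.delta_cost,
                "delta_effectiveness": self.base_case.delta_effectiveness,
                "icer": self.base_case.icer,
                "dominance": self.base_case.dominance,
            },
        }


def run_psa(tree: DecisionTree, distributions: list, n: int, seed: int) -> PSAResult:
    """Monte Carlo PSA: ``n`` independent parameter draws through the tree.

    Parameters are sampled in path-sorted order from one seeded generator, so
    equal ``(tree, distributions, n, seed)`` reproduces the result exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    violations = validate_tree(tree)
    if violations:
        raise ValueError("invalid tree: " + "; ".join(violations))
    work = copy.deepcopy(tree)
    index = dict(iter_nodes(work))
    for dist in distributions:
        if dist.target not in index:
            raise ValueError(f"distribution targets unknown node path {dist.target!r}")
    base = icer(*(rollback(tree)[a] for a in ("ECPS", "MCS")))

    rng = np.random.default_rng(seed)
    ordered = sorted(distributions, key=lambda d: d.target)
    samples = {}
    for dist in ordered:
        if dist.kind == "beta":
            samples[dist.target] = rng.beta(dist.params["alpha"], dist.params["beta"], size=n)
        elif dist.kind == "dirichlet":
            samples[dist.target] = rng.dirichlet(dist.params["alpha"], size=n)
        elif dist.kind == "gamma":
            samples[dist.target] = rng.gamma(
                dist.params["shape"], dist.params["scale"], size=n
            )

    de = np.empty(n)
    dc = np.empty(n)
    for i in range(n):
        for dist in ordered:
            if dist.kind == "point":
                continue
            node = index[dist.target]
            draw = samples[dist.target][i]
            if dist.kind == "beta":
                node.branches[0].probability = float(draw)
                node.branches[1].probability = 1.0 - float(draw)
            elif dist.kind == "dirichlet":
                for br, p in zip(node.branches, draw):
                    br.probability = float(p)
            else:
                node.cost = float(draw)
        res = rollback(work)
        inc = icer(res["ECPS"], res["MCS"])
        de[i] = inc.delta_effectiveness
        dc[i] = inc.delta_cost
    draws = pd.DataFrame({"delta_effectiveness": de, "delta_cost": dc})
    return PSAResult(draws=draws, seed=seed, base_case=base)


def quadrant_proportions(draws: pd.DataFrame) -> dict:
    """Fractions of draws per cost-effectiveness-plane quadrant.

    Orientation: effectiveness on x, cost on y.  Quadrant II (east-south:
    delta_effectiveness > 0, delta_cost < 0) is the dominant region.  Boundary
    convention, half-open: delta_effectiveness >= 0 counts east, delta_cost
    >= 0 counts north; boundary draws are also counted separately.
    """
    if len(draws) == 0:
        raise ValueError("no draws")
    de = draws["delta_effectiveness"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    east = de >= 0
    north = dc >= 0
    n = len(de)
    out = {
        "I": float((east & north).sum() / n),
        "II": float((east & ~north).sum() / n),
        "III": float((~east & ~north).sum() / n),
        "IV": float((~east & north).sum() / n),
        "n_boundary": int(((de == 0) | (dc == 0)).sum()),
    }
    return out


def ceac(draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay lambda, the fraction of draws with positive
    incremental net monetary benefit lambda * dE - dC.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if len(draws) == 0:
        raise ValueError("no draws")
    if np.any(wtp < 0):
        raise ValueError("willingness-to-pay values must be >= 0")
    de = draws["delta_effectiveness"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    frac = [(lam * de - dc > 0).mean() for lam in wtp]
    return pd.DataFrame({"wtp": wtp, "prob_cost_effective": frac})


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_ce_plane(draws: pd.DataFrame, path) -> None:
    """Scatter of the incremental cloud on the cost-effectiveness plane."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws["delta_effectiveness"], draws["delta_cost"], s=6, alpha=0.4)
    ax.axhline(0, color="0.3", lw=0.8)
    ax.axvline(0, color="0.3", lw=0.8)
    ax.set_xlabel("Incremental effectiveness (ECPS − MCS)")
    ax.set_ylabel("Incremental cost, € (ECPS − MCS)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["prob_cost_effective"])
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay, € per unit effectiveness")
    ax.set_ylabel("P(ECPS cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
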