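"""Per-patient direct-cost accounting and group cost summaries.

Turns per-resource utilization quantities and a unit-price table into euro
costs, aggregates per-arm totals / means / SDs per resource, and runs the
per-resource between-arm comparisons (two-sample t on z-score-standardized
costs; the t statistic is invariant under that affine standardization, which
is asserted in the tests).

Costs are kept at full floating precision internally; rounding to cents is a
presentation concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import defaults

log = logging.getLogger(__name__)


@dataclass
class PriceTable:
    """Unit prices in euros per resource; the circular stapler is priced per
    device arm."""

    prices: dict = field(default_factory=lambda: dict(defaults.UNIT_PRICES))
    stapler_prices: dict = field(default_factory=lambda: dict(defaults.STAPLER_PRICES))

    def __post_init__(self):
        for k, v in {**self.prices, **self.stapler_prices}.items():
            if v <= 0:
                raise ValueError(f"price for {k!r} must be > 0")

    def unit_price(self, resource: str, arm: str) -> float:
        if resource == "circular_stapler":
            return self.stapler_prices[arm]
        if resource not in self.prices:
            raise KeyError(f"unknown resource key: {resource!r}")
        return self.prices[resource]

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"prices": self.prices, "stapler_prices": self.stapler_prices}, fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PriceTable":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(prices=d["prices"], stapler_prices=d["stapler_prices"])


def patient_direct_cost(utilization, arm: str, prices: PriceTable | None = None) -> float:
    """Sum of quantity x unit price over a patient's utilization mapping.

    The stapler is priced by device arm.  Unknown resource keys raise a
    ``KeyError`` naming them.
    """
    prices = prices or PriceTable()
    unknown = [k for k in utilization if k != "circular_stapler" and k not in prices.prices]
    if unknown:
        raise KeyError(f"unknown resource keys: {sorted(unknown)}")
    return float(sum(q * prices.unit_price(r, arm) for r, q in utilization.items()))


def cohort_resource_costs(cohort: pd.DataFrame, prices: PriceTable | None = None) -> pd.DataFrame:
    """Per-patient per-resource euro costs (one column per resource plus
    ``total_cost``), with ``patient_id`` and ``arm`` carried along."""
    prices = prices or PriceTable()
    out = cohort[["patient_id", "arm"]].copy()
    total = np.zeros(len(cohort))
    for r in defaults.RESOURCES:
        if r not in cohort.columns:
            continue
        unit = np.where(
            cohort["arm"] == "ECPS", prices.unit_price(r, "ECPS"), prices.unit_price(r, "MCS")
        ) if r == "circular_stapler" else prices.unit_price(r, "MCS")
        out[r] = cohort[r].to_numpy(dtype=float) * unit
        total = total + out[r].to_numpy()
    out["total_cost"] = total
    return out


def group_cost_summary(costs: pd.DataFrame) -> pd.DataFrame:
    """Per-resource and overall totals / means / SDs per arm.

    ``costs`` is the output of :func:`cohort_resource_costs`.  Mean = total/n
    by construction; the overall row equals the sum of per-resource totals
    exactly (conservation, pre-rounding).
    """
    if len(costs) == 0:
        raise ValueError("empty cost table")
    resources = [c for c in costs.columns if c in defaults.RESOURCES] + ["total_cost"]
    rows = []
    for r in resources:
        row = {"resource": r}
        for arm in ("MCS", "ECPS"):
            x = costs.loc[costs["arm"] == arm, r].to_numpy(dtype=float)
            row[f"total_{arm}"] = float(x.sum())
            row[f"mean_{arm}"] = float(x.mean()) if len(x) else np.nan
            row[f"sd_{arm}"] = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("resource")


def zscore_standardize(x: np.ndarray) -> np.ndarray:
    """Pooled-sample z-score; zero-variance input is returned centered."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def per_resource_cost_tests(
    costs: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sample t test per resource (and for total cost) between arms on
    z-score-standardized euro costs.

    Equal-variance (Student) t by default; ``equal_var=False`` gives Welch.
    Columns with zero pooled variance are skipped with a warning unless the
    arm means differ with zero within-arm variance (a deterministic price
    difference, e.g. the stapler), reported as t = +-inf, p = 0 and flagged
    ``degenerate``.  Sign convention: t compares MCS - ECPS.
    """
    mcs = costs["arm"] == "MCS"
    if mcs.sum() < 2 or (~mcs).sum() < 2:
        raise ValueError("need >= 2 patients per arm")
    resources = [c for c in costs.columns if c in defaults.RESOURCES] + ["total_cost"]
    rows = []
    for r in resources:
        x = costs[r].to_numpy(dtype=float)
        z = zscore_standardize(x)
        a, b = z[mcs.to_numpy()], z[~mcs.to_numpy()]
        degenerate = False
        if np.ptp(a) == 0 and np.ptp(b) == 0:  # constant within each arm
            if a[0] == b[0]:
                log.warning("skipping zero-variance resource %s", r)
                continue
            t, p, degenerate = float(np.sign(a[0] - b[0]) * np.inf), 0.0, True
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"resource": r, "t": float(t), "p_value": float(p), "degenerate": degenerate})
    return pd.DataFrame(rows, columns=["resource", "t", "p_value", "degenerate"]).set_index(
        "resource"
    )


def reference_cost_summary() -> pd.DataFrame:
    """Cost summary of the bundled reference scenario: unit price, arm totals,
    mean computed as total/n, and the scenario's per-patient mean +- SD.

    Three rows of the scenario print per-patient moments that disagree with
    total/n (see docs/methods.md); both readings are reported side by side.
    """
    n = defaults.ARM_N
    rows = []
    for r in defaults.RESOURCES:
        row = {
            "resource": r,
            "price": defaults.STAPLER_PRICES if r == "circular_stapler" else defaults.UNIT_PRICES[r],
        }
        for arm in ("MCS", "ECPS"):
            total = defaults.RESOURCE_TOTALS[r][arm]
            row[f"total_{arm}"] = total
            row[f"mean_{arm}"] = total / n
            if r == "circular_stapler":
                row[f"scenario_mean_{arm}"] = total / n
                row[f"scenario_sd_{arm}"] = np.nan
            else:
                m, sd = defaults.COST_MOMENTS[r][arm]
                row[f"scenario_mean_{arm}"] = m
                row[f"scenario_sd_{arm}"] = sd
        rows.append(row)
    overall = {"resource": "overall", "price": np.nan}
    for arm in ("MCS", "ECPS"):
        total = sum(defaults.RESOURCE_TOTALS[r][arm] for r in defaults.RESOURCES)
        overall[f"total_{arm}"] = total
        overall[f"mean_{arm}"] = total / n
        overall[f"scenario_mean_{arm}"] = defaults.GROUP_MEAN_COST[arm]
        overall[f"scenario_sd_{arm}"] = defaults.GROUP_SD_COST[arm]
    rows.append(overall)
    return pd.DataFrame(rows).set_index("resource")
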