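"""Matched-cohort outcome statistics.

Arm-by-event contingency tables, the chi-square test for a 2x2 table (Pearson
or with the Yates continuity correction, both written out from the closed
form; Fisher's exact test delegated to scipy), the crude odds ratio with a
Wald confidence interval on the log scale, and the number needed to treat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TwoByTwoTable:
    """Counts with rows = exposure arm, columns = event yes/no.

    ``a`` events in row 1, ``b`` non-events in row 1, ``c``/``d`` likewise in
    row 2.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("exposed", "unexposed")
    col_labels: tuple = ("event", "no_event")

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class EffectEstimate:
    point: float
    ci_low: float
    ci_high: float
    method: str


def event_table(cohort: pd.DataFrame, event_field: str, exposed_arm: str = "MCS") -> TwoByTwoTable:
    """Arm x event counts, with ``exposed_arm`` as the first row."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if event_field not in cohort.columns:
        raise ValueError(f"unknown event field {event_field!r}")
    ev = cohort[event_field].astype(bool)
    exp = cohort["arm"] == exposed_arm
    other = sorted(set(cohort["arm"]) - {exposed_arm})
    return TwoByTwoTable(
        a=int((exp & ev).sum()),
        b=int((exp & ~ev).sum()),
        c=int((~exp & ev).sum()),
        d=int((~exp & ~ev).sum()),
        row_labels=(exposed_arm, other[0] if other else "other"),
        col_labels=(event_field, f"no_{event_field}"),
    )


def chi_square_test(table: TwoByTwoTable, correction: str = "yates"):
    """Chi-square test on 1 df.

    Pearson: n (ad - bc)^2 / (r1 r2 c1 c2).  Yates: |ad - bc| reduced by n/2
    (floored at 0) before squaring.  Returns ``(statistic, p_value)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("chi-square undefined: a marginal total is zero")
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(diff - n / 2.0, 0.0)
    elif correction != "pearson":
        raise ValueError("correction must be 'pearson' or 'yates'")
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def fisher_exact_test(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p-value (reported for transparency)."""
    return float(stats.fisher_exact(table.as_array())[1])


def odds_ratio(table: TwoByTwoTable, zero_cell_policy: str = "haldane") -> EffectEstimate:
    """Crude odds ratio ad/bc with 95% Wald CI on the log scale.

    With any zero cell, the Haldane–Anscombe correction adds 0.5 to every cell
    (``zero_cell_policy="haldane"``); ``"error"`` raises instead.  Two zero
    cells in the same row or column leave the OR undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: two zero cells share a row or column")
    method = "wald"
    if 0 in (a, b, c, d):
        if zero_cell_policy == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            method = "wald+haldane"
        else:
            raise ValueError("zero cell in table (set zero_cell_policy='haldane')")
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)
    return EffectEstimate(point=point, ci_low=lo, ci_high=hi, method=method)


def number_needed_to_treat(risk_control: float, risk_treated: float) -> int:
    """ceil(1 / absolute risk reduction); requires risk_control > risk_treated."""
    for name, r in (("risk_control", risk_control), ("risk_treated", risk_treated)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    arr = risk_control - risk_treated
    if arr <= 0:
        raise ValueError("NNT undefined: risk_control must exceed risk_treated")
    return math.ceil(round(1.0 / arr, 9))


def outcome_report(cohort: pd.DataFrame, correction: str = "yates") -> dict:
    """Leak / grade / stoma summary of a matched cohort, mirroring the
    standard outcome block: rates per arm, chi-square variants, crude OR for
    leak with ECPS as exposure, and the NNT."""
    out: dict = {"n": {arm: int((cohort["arm"] == arm).sum()) for arm in ("MCS", "ECPS")}}
    rates = {}
    for field_name in ("leak", "definitive_stoma"):
        rates[field_name] = {
            arm: float(cohort.loc[cohort["arm"] == arm, field_name].mean())
            for arm in ("MCS", "ECPS")
        }
    for grade in ("AB", "C"):
        rates[f"leak_grade_{grade}"] = {
            arm: float((cohort.loc[cohort["arm"] == arm, "leak_grade"] == grade).mean())
            for arm in ("MCS", "ECPS")
        }
    out["rates"] = rates
    table = event_table(cohort, "leak", exposed_arm="ECPS")
    stat, p = chi_square_test(table, correction=correction)
    out["leak_table"] = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    out["chi_square"] = {"correction": correction, "statistic": stat, "p_value": p}
    stat_p, p_p = chi_square_test(table, correction="pearson")
    out["chi_square_pearson"] = {"statistic": stat_p, "p_value": p_p}
    out["fisher_p"] = fisher_exact_test(table)
    est = odds_ratio(table)
    out["odds_ratio_ecps"] = {
        "point": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high, "method": est.method
    }
    r_mcs, r_ecps = rates["leak"]["MCS"], rates["leak"]["ECPS"]
    out["nnt"] = number_needed_to_treat(r_mcs, r_ecps) if r_mcs > r_ecps else None
    return out
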