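"""Propensity-score estimation and 1:1 caliper matching.

The propensity score — the probability of receiving the powered stapler given
baseline covariates — is fit by maximum-likelihood logistic regression
(statsmodels), with categorical covariates expanded to indicator contrasts
against the largest category.  Matching is greedy nearest-neighbour without
replacement on the logit of the score, processing treated patients in
descending score order (ties broken by patient id), with a caliper expressed
as a multiple of the SD of the logit scores (the dominant convention; absolute
logit- and probability-scale calipers are available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "charlson", "diagnosis", "procedure")
_CATEGORICAL = ("sex", "asa", "diagnosis", "procedure")


@dataclass
class MatchConfig:
    covariates: tuple = DEFAULT_COVARIATES
    caliper: float = 0.2
    caliper_scale: str = "logit-sd"  # or "logit" (absolute), "raw" (probability)
    ratio: int = 1
    replacement: bool = False
    order: str = "descending-score"

    def validate(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be > 0")
        if self.ratio != 1:
            raise ValueError("only 1:1 matching is supported")
        if self.replacement:
            raise ValueError("matching is without replacement")
        if self.caliper_scale not in ("logit-sd", "logit", "raw"):
            raise ValueError("caliper_scale must be 'logit-sd', 'logit' or 'raw'")


@dataclass
class MatchedPairs:
    pairs: list            # list of (treated_id, control_id)
    unmatched: list        # ids excluded (both arms)
    propensity: pd.Series  # per-patient score indexed by patient_id
    caliper_width: float   # realized absolute width on the matching scale

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix; categoricals become indicators with the largest
    category as reference."""
    cols = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort")
        col = cohort[cov]
        if cov in _CATEGORICAL or col.dtype == object:
            reference = col.value_counts().idxmax()
            dummies = pd.get_dummies(col, prefix=cov, dtype=float)
            dummies = dummies.drop(columns=f"{cov}_{reference}")
            cols.append(dummies)
        else:
            cols.append(col.astype(float).rename(cov))
    X = pd.concat(cols, axis=1)
    # drop single-valued columns (degenerate contrasts)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = set(X.columns) - set(keep)
    if dropped:
        log.warning("dropping degenerate covariate columns: %s", sorted(dropped))
    return X[keep]


def fit_propensity(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Fit P(arm = ECPS | covariates) by ML logistic regression.

    Returns ``(scores, coefficients)``: per-patient scores in (0, 1) indexed by
    patient_id, and the fitted coefficient Series (including the intercept).
    Perfect separation raises a ``ValueError`` recommending covariate
    reduction.
    """
    arms = cohort["arm"].unique()
    if len(arms) < 2:
        raise ValueError("cohort must contain patients in both arms")
    y = (cohort["arm"] == "ECPS").astype(float).to_numpy()
    X = sm.add_constant(_design_matrix(cohort, covariates), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise ValueError(
            "perfect separation in the propensity model; reduce or coarsen covariates"
        ) from exc
    p = np.asarray(res.predict(X.astype(float)))
    eps = 1e-12
    if np.any(p <= eps) or np.any(p >= 1 - eps):
        raise ValueError(
            "propensity scores at the boundary (quasi-separation); reduce covariates"
        )
    scores = pd.Series(p, index=cohort["patient_id"].to_numpy(), name="propensity")
    coefs = pd.Series(res.params.to_numpy() if hasattr(res.params, "to_numpy") else res.params,
                      index=X.columns, name="coef")
    return scores, coefs


def match_one_to_one(
    cohort: pd.DataFrame, scores: pd.Series, config: MatchConfig | None = None
) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbour matching on the logit of the score.

    Treated = ECPS.  Pairs obey ``|logit(p_t) - logit(p_c)| <= width`` where
    ``width`` is ``caliper * SD(logit scores)`` under the default scale,
    the raw caliper on the logit scale under ``"logit"``, or the caliper on
    the probability scale under ``"raw"`` (then distances are in probability
    units).  Deterministic: treated processed in descending score order, ties
    broken by patient id.
    """
    config = config or MatchConfig()
    config.validate()
    treated = cohort.loc[cohort["arm"] == "ECPS", "patient_id"].to_numpy()
    control = cohort.loc[cohort["arm"] == "MCS", "patient_id"].to_numpy()
    if len(treated) == 0 or len(control) == 0:
        log.warning("one arm is empty: no pairs formed")
        return MatchedPairs([], sorted(cohort["patient_id"]), scores, np.nan)

    if config.caliper_scale == "raw":
        pos = scores
        width = config.caliper
    else:
        pos = pd.Series(_logit(scores.to_numpy()), index=scores.index)
        width = (
            config.caliper * float(np.std(pos.to_numpy(), ddof=1))
            if config.caliper_scale == "logit-sd"
            else config.caliper
        )

    order = sorted(treated, key=lambda pid: (-pos[pid], pid))
    ctrl_ids = np.array(sorted(control))
    ctrl_pos = pos[ctrl_ids].to_numpy()
    available = np.ones(len(ctrl_ids), dtype=bool)

    pairs = []
    for t in order:
        if not available.any():
            break
        d = np.abs(ctrl_pos - pos[t])
        d[~available] = np.inf
        j = int(np.argmin(d))  # ties resolve to the lexicographically first id
        if d[j] <= width:
            pairs.append((t, str(ctrl_ids[j])))
            available[j] = False
    matched = {pid for pair in pairs for pid in pair}
    unmatched = sorted(set(cohort["patient_id"]) - matched)
    return MatchedPairs(pairs, unmatched, scores, width)


def matched_cohort(cohort: pd.DataFrame, pairs: MatchedPairs) -> pd.DataFrame:
    """Subset of the cohort containing only matched patients."""
    keep = {pid for pair in pairs.pairs for pid in pair}
    return cohort[cohort["patient_id"].isin(keep)].reset_index(drop=True)


def standardized_mean_differences(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.Series:
    """SMD per (indicator-expanded) covariate between arms:
    (mean_t - mean_c) / sqrt((s_t^2 + s_c^2)/2), sample variances (ddof=1)."""
    X = _design_matrix(cohort, covariates)
    t = cohort["arm"].to_numpy() == "ECPS"
    out = {}
    for col in X.columns:
        xt, xc = X.loc[t, col], X.loc[~t, col]
        pooled = np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2.0)
        diff = xt.mean() - xc.mean()
        if pooled == 0:
            if abs(diff) > 0:
                log.warning("zero pooled SD with unequal means for %s", col)
            out[col] = 0.0 if diff == 0 else np.inf
        else:
            out[col] = diff / pooled
    return pd.Series(out, name="smd")


def balance_diagnostics(
    cohort: pd.DataFrame, pairs: MatchedPairs, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Per-covariate SMD before and after matching."""
    before = standardized_mean_differences(cohort, covariates)
    after = standardized_mean_differences(matched_cohort(cohort, pairs), covariates)
    return pd.DataFrame({"smd_before": before, "smd_after": after})
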