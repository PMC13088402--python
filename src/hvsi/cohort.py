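"""Matched case-control construction and adjusted association models.

Propensity scores come from a logistic group-membership model (IRLS /
Newton via statsmodels); matching is greedy 1:1 nearest-neighbor without
replacement on the logit-propensity scale, with a caliper defaulting to
0.2 standard deviations of the logit score.  Adjusted odds ratios use a
multivariable logistic model with the sound index scaled per
``hvsi_step`` units (default 100) and Wald 95% intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from hvsi.diagnostics import reference_labels

__all__ = [
    "MatchResult",
    "AdjustedModelResult",
    "encode_covariates",
    "fit_propensity",
    "match_1to1",
    "match_cohort",
    "standardized_mean_differences",
    "fit_adjusted_or",
]


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (case_id, control_id)
    unmatched: list[int]
    propensity_scores: np.ndarray
    caliper: float
    balance_table: pd.DataFrame | None = None


@dataclass
class AdjustedModelResult:
    terms: list[dict] = field(default_factory=list)
    outcome_definition: str = ""
    hvsi_scaling: float = 100.0
    n: int = 0
    converged: bool = True

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)


def encode_covariates(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design columns: booleans to 0/1, sex to male=1, AVF type to
    wrist/snuffbox dummies with brachial as reference."""
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} not found in records")
        series = records[cov]
        if cov == "sex":
            cols["sex_male"] = (series.astype(str).str.lower() == "male").to_numpy(float)
        elif cov == "avf_type":
            s = series.astype(str).str.lower()
            unknown = set(s.unique()) - {"brachial", "wrist", "snuffbox"}
            if unknown:
                raise ValueError(f"unknown avf_type values: {sorted(unknown)}")
            cols["avf_wrist"] = (s == "wrist").to_numpy(float)
            cols["avf_snuffbox"] = (s == "snuffbox").to_numpy(float)
        elif series.dtype == bool:
            cols[cov] = series.to_numpy(float)
        elif series.dtype == object:
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(float)
        else:
            cols[cov] = series.to_numpy(float)
    return pd.DataFrame(cols, index=records.index)


def _fit_logit(X: pd.DataFrame, y: np.ndarray, context: str) -> sm.Logit:
    Xc = sm.add_constant(X, has_constant="add")
    try:
        # Separation/non-convergence is detected and raised below; silence
        # the advisory warnings statsmodels emits on the way there.
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            f"{context}: logistic fit failed ({exc}); covariate pattern "
            f"{list(X.columns)} may perfectly separate the groups"
        ) from exc
    if not res.mle_retvals.get("converged", False) or np.any(
        np.abs(res.params.to_numpy()) > 1e2
    ):
        raise ValueError(
            f"{context}: logistic fit did not converge; covariate pattern "
            f"{list(X.columns)} may perfectly separate the groups"
        )
    return res


def fit_propensity(
    records: pd.DataFrame, covariates: list[str], group_col: str = "group"
) -> np.ndarray:
    """Per-record probability of case-group membership."""
    y = (records[group_col].to_numpy() == "stenosis").astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both groups must be present to fit a propensity model")
    X = encode_covariates(records, covariates)
    res = _fit_logit(X, y, "propensity model")
    return np.asarray(res.predict())


def match_1to1(
    scores: np.ndarray,
    groups: np.ndarray,
    caliper: float | None = None,
    ids: np.ndarray | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Distances are on the logit-propensity scale.  Cases are processed in
    descending propensity order; ties between equidistant controls go to
    the lower id.  ``caliper=None`` uses 0.2 x SD of the logit scores;
    pairs farther apart than the caliper are discarded (the case is
    reported unmatched, not fatal).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if np.any((scores <= 0) | (scores >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    is_case = (groups == "stenosis") | (groups == True)  # noqa: E712
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("need at least one case and one control")
    ids = np.arange(scores.size) if ids is None else np.asarray(ids)

    logit = np.log(scores / (1 - scores))
    cal = 0.2 * float(np.std(logit, ddof=1)) if caliper is None else float(caliper)

    case_idx = np.flatnonzero(is_case)
    case_idx = case_idx[np.argsort(-scores[case_idx], kind="stable")]
    available = set(np.flatnonzero(~is_case))
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for ci in case_idx:
        best_j, best_d = None, np.inf
        for j in sorted(available):
            d = abs(logit[ci] - logit[j])
            if d < best_d - 1e-15:
                best_j, best_d = j, d
        if best_j is not None and best_d <= cal:
            pairs.append((int(ids[ci]), int(ids[best_j])))
            available.discard(best_j)
        else:
            unmatched.append(int(ids[ci]))
    unmatched.extend(int(ids[j]) for j in sorted(available))
    return MatchResult(
        pairs=pairs, unmatched=unmatched, propensity_scores=scores, caliper=cal
    )


def standardized_mean_differences(
    records: pd.DataFrame, covariates: list[str], group_col: str = "group"
) -> pd.Series:
    """Absolute standardized mean difference per encoded covariate column."""
    X = encode_covariates(records, covariates)
    is_case = records[group_col].to_numpy() == "stenosis"
    a, b = X[is_case], X[~is_case]
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    smd = (a.mean() - b.mean()).abs() / pooled_sd.replace(0.0, np.nan)
    return smd.fillna(0.0)


def match_cohort(
    records: pd.DataFrame,
    covariates: list[str],
    caliper: float | None = None,
    id_col: str = "id",
    group_col: str = "group",
) -> MatchResult:
    """Propensity fit + greedy matching + covariate balance in one call."""
    scores = fit_propensity(records, covariates, group_col=group_col)
    ids = records[id_col].to_numpy() if id_col in records.columns else None
    result = match_1to1(
        scores, records[group_col].to_numpy(), caliper=caliper, ids=ids
    )
    matched_ids = {i for pair in result.pairs for i in pair}
    key = records[id_col] if id_col in records.columns else pd.Series(
        np.arange(len(records)), index=records.index
    )
    matched = records[key.isin(matched_ids)]
    before = standardized_mean_differences(records, covariates, group_col)
    after = standardized_mean_differences(matched, covariates, group_col)
    result.balance_table = pd.DataFrame({"smd_before": before, "smd_after": after})
    return result


def fit_adjusted_or(
    records: pd.DataFrame,
    outcome_rule: str,
    covariates: list[str],
    hvsi_step: float = 100.0,
    score_col: str = "hvsi",
) -> AdjustedModelResult:
    """Multivariable logistic odds ratios with the score per ``hvsi_step`` units.

    The score coefficient is reported as the odds ratio per ``hvsi_step``
    score units (default: per 100); other terms as OR per unit/category.
    """
    y = reference_labels(records, outcome_rule).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"outcome {outcome_rule!r} has a single class")
    X = encode_covariates(records, covariates) if covariates else pd.DataFrame(
        index=records.index
    )
    X.insert(0, "hvsi", records[score_col].to_numpy(float) / hvsi_step)
    if len(records) <= X.shape[1] + 1:
        raise ValueError("need more records than model terms")
    res = _fit_logit(X, y, f"adjusted model for {outcome_rule!r}")
    z = 1.959963984540054  # Wald 95%
    terms = []
    for name in X.columns:
        beta = float(res.params[name])
        se = float(res.bse[name])
        terms.append(
            {
                "name": name,
                "odds_ratio": math.exp(beta),
                "ci_lo": math.exp(beta - z * se),
                "ci_hi": math.exp(beta + z * se),
                "p": float(res.pvalues[name]),
            }
        )
    return AdjustedModelResult(
        terms=terms,
        outcome_definition=outcome_rule,
        hvsi_scaling=hvsi_step,
        n=len(records),
        converged=True,
    )
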