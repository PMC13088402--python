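"""Diagnostic-accuracy engine for score-vs-reference evaluation.

Conventions
-----------
* Test positivity is ``score <= cutoff``: a *low* sound index signals
  disease (reduced flow / stenosis).  The orientation is recorded in every
  output so the convention is visible downstream.
* Reference rules are small expressions: ``"fv<400"`` (flow volume below a
  threshold, mL/min), ``"ri>0.6"``, or ``"group"`` (stenosis group label).
* Percentages are rounded half-up to one decimal.  Metrics with a zero
  denominator are reported as absent, never as 0 or 100.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "classify",
    "reference_labels",
    "confusion",
    "accuracy_metrics",
    "roc",
    "youden_cutoff",
    "concordance",
    "association",
    "round_percent",
]


def round_percent(x: float, decimals: int = 1) -> float:
    """Round half-up (0.05 -> 0.1), matching clinical-report formatting."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCResult:
    """Empirical ROC sweep plus summary statistics.

    ``thresholds[i]`` is a cutoff in original score units; a record is
    test-positive at that threshold when its score is <= the cutoff.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    youden_sens: float
    youden_spec: float
    n_pos: int
    n_neg: int
    orientation: str = "lower_is_positive"
    ci_method: str = "delong"


def classify(hvsi: float, cutoff: float) -> str:
    """``"positive"`` iff score <= cutoff (boundary inclusive)."""
    return "positive" if hvsi <= cutoff else "negative"


_FV_RULE = re.compile(r"^fv\s*<\s*([0-9.]+)$")
_RI_RULE = re.compile(r"^ri\s*>\s*([0-9.]+)$")


def reference_labels(records: pd.DataFrame, rule: str) -> np.ndarray:
    """Boolean reference-positive labels for a rule expression."""
    rule = rule.strip().lower()
    if m := _FV_RULE.match(rule):
        return records["flow_volume"].to_numpy(dtype=float) < float(m.group(1))
    if m := _RI_RULE.match(rule):
        return records["resistance_index"].to_numpy(dtype=float) > float(m.group(1))
    if rule == "group":
        return records["group"].to_numpy() == "stenosis"
    raise ValueError(
        f"unknown reference rule {rule!r}; expected 'fv<NNN', 'ri>X' or 'group'"
    )


def _test_positive(records: pd.DataFrame, cutoff: float, score_col: str) -> np.ndarray:
    return records[score_col].to_numpy(dtype=float) <= cutoff


def confusion(
    records: pd.DataFrame,
    cutoff: float,
    reference_rule: str,
    score_col: str = "hvsi",
) -> ConfusionCounts:
    """Cross-tabulate test positivity (score <= cutoff) against a reference."""
    if len(records) == 0:
        raise ValueError("empty input: no records to evaluate")
    test = _test_positive(records, cutoff, score_col)
    ref = reference_labels(records, reference_rule)
    return ConfusionCounts(
        tp=int(np.sum(test & ref)),
        fp=int(np.sum(test & ~ref)),
        fn=int(np.sum(~test & ref)),
        tn=int(np.sum(~test & ~ref)),
    )


def accuracy_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV in percent (1 decimal, half-up).

    Metrics whose denominator is zero are omitted from the result.
    """
    out: dict[str, float] = {}
    pairs = {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    for name, (num, den) in pairs.items():
        if den > 0:
            out[name] = round_percent(100.0 * num / den)
    return out


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count one half), on disease-oriented scores."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = ranks[: pos.size].sum()
    n1, n0 = pos.size, neg.size
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    # Structural components via midranks: V10_i = P(neg < pos_i) + ties/2
    # equals (combined midrank - within-class midrank) / n_other.
    n1, n0 = pos.size, neg.size
    combined = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (combined[:n1] - stats.rankdata(pos)) / n0
    v01 = 1.0 - (combined[n1:] - stats.rankdata(neg)) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def _bootstrap_auc_ci(
    pos: np.ndarray, neg: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, pos.size, replace=True)
        q = rng.choice(neg, neg.size, replace=True)
        aucs[b] = _auc_rank(p, q)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc(
    records: pd.DataFrame,
    reference_rule: str,
    score_col: str = "hvsi",
    orientation: str = "lower_is_positive",
    ci_seed: int = 0,
    ci: str = "auto",
) -> ROCResult:
    """Empirical ROC of a score against a reference rule.

    The AUC is computed by trapezoidal integration of the empirical curve,
    which coincides with the rank (Mann-Whitney) statistic with ties
    counting one half.  The 95% CI uses the DeLong asymptotic variance,
    falling back to a stratified bootstrap when either class has < 30
    records; ``ci="none"`` skips the interval (NaN bounds), which matters
    when sweeping thousands of small ROCs.
    """
    if len(records) == 0:
        raise ValueError("empty input: no records")
    scores = records[score_col].to_numpy(dtype=float)
    ref = reference_labels(records, reference_rule)
    n_pos, n_neg = int(ref.sum()), int((~ref).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"single-class input (positives={n_pos}, negatives={n_neg}); "
            "ROC needs both classes"
        )
    if orientation == "lower_is_positive":
        oriented = -scores
    elif orientation == "higher_is_positive":
        oriented = scores
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    # Threshold sweep in original score units: cutoffs between distinct
    # scores (midpoints), plus "none positive" and "all positive" ends.
    uniq = np.unique(scores)
    if orientation == "lower_is_positive":
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1]]])
        test_pos = scores[None, :] <= thresholds[:, None]
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[uniq[-1] + 1.0], mids[::-1], [uniq[0]]])
        test_pos = scores[None, :] >= thresholds[:, None]
    sens = (test_pos & ref).sum(axis=1) / n_pos
    spec = ((~test_pos) & ~ref).sum(axis=1) / n_neg

    pos, neg = oriented[ref], oriented[~ref]
    auc = _auc_rank(pos, neg)
    if ci == "none":
        ci_bounds, ci_method = (math.nan, math.nan), "none"
    elif min(n_pos, n_neg) >= 30:
        var = _delong_variance(pos, neg)
        half = stats.norm.ppf(0.975) * math.sqrt(var)
        ci_bounds = (max(0.0, auc - half), min(1.0, auc + half))
        ci_method = "delong"
    else:
        ci_bounds = _bootstrap_auc_ci(pos, neg, seed=ci_seed)
        ci_method = "bootstrap"

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # Sensitivity is nondecreasing along the sweep; ties in J are broken
    # toward higher sensitivity (screening favors catching disease).
    k = int(best[-1])

    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci=ci_bounds,
        youden_cutoff=float(thresholds[k]),
        youden_sens=float(sens[k]),
        youden_spec=float(spec[k]),
        n_pos=n_pos,
        n_neg=n_neg,
        orientation=orientation,
        ci_method=ci_method,
    )


def youden_cutoff(r: ROCResult) -> dict[str, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    return {"cutoff": r.youden_cutoff, "sens": r.youden_sens, "spec": r.youden_spec}


def concordance(
    records: pd.DataFrame,
    cutoff: float,
    reference_rule: str,
    score_col: str = "hvsi",
) -> dict[str, float]:
    """Agreement between score-based and reference-based classification."""
    if len(records) == 0:
        raise ValueError("empty input: no records")
    test = _test_positive(records, cutoff, score_col)
    ref = reference_labels(records, reference_rule)
    agree = int(np.sum(test == ref))
    total = int(len(records))
    return {
        "agree": agree,
        "total": total,
        "pct": round_percent(100.0 * agree / total),
    }


def association(records: pd.DataFrame, x: str, y: str) -> dict[str, float]:
    """Simple linear regression of ``y`` on ``x`` with Pearson correlation."""
    xv = records[x].to_numpy(dtype=float)
    yv = records[y].to_numpy(dtype=float)
    if xv.size < 3:
        raise ValueError("association needs n >= 3")
    if np.var(xv) == 0:
        raise ValueError(f"zero variance in {x!r}")
    fit = stats.linregress(xv, yv)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "pearson_r": float(fit.rvalue),
        "p": float(fit.pvalue),
    }
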