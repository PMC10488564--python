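"""Diagnostic statistics: cutoffs, 2x2 odds ratios, logistic models, ROC.

This stage mirrors how quantitative imaging features are turned into a
classifier in small diagnostic cohorts:

1. per feature, pick the Youden-optimal cutoff (max sensitivity +
   specificity − 1) over observed values, in both directions;
2. binarize cases at that cutoff and cross-tabulate score vs outcome;
3. estimate the odds ratio with Wald (asymptotic, no continuity
   correction) inference — this is the method whose CIs and p-values the
   printed study tables reproduce exactly;
4. run univariate logistic regression per binarized feature, then forward
   stepwise selection with backward pruning (score-test entry p <= 0.05,
   Wald removal p > 0.1) over the univariately significant candidates;
5. report sensitivity, specificity and the two-point ROC AUC of the
   selected predictor(s).

A zero cell in a 2x2 table means quasi-complete separation: the logistic
MLE diverges (the astronomic odds ratios sometimes seen in print are this
artifact), so such rows are flagged non-estimable rather than reported as
numbers.  An optional Haldane–Anscombe +0.5 correction is available behind
a flag.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CohortTable
from .types import FEATURE_NAMES, TumorGroup, TwoByTwoTable, ValidationError

_Z975 = float(stats.norm.ppf(0.975))


class Direction(str, enum.Enum):
    GREATER_THAN = "greater_than"
    LESS_OR_EQUAL = "less_or_equal"


class Contrast(str, enum.Enum):
    """The two diagnostic contrasts analyzed in the cohort."""

    CARCINOMA_VS_THYMOMA = "carcinoma_vs_thymoma"
    HIGH_VS_LOW_RISK = "high_vs_low_risk"


@dataclass(frozen=True)
class CutoffResult:
    feature_name: str
    cutoff: float
    direction: Direction
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    separation_flag: bool
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


@dataclass(frozen=True)
class PredictorEstimate:
    name: str
    coef: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFit:
    included_predictors: list[str]
    estimates: dict[str, PredictorEstimate]
    intercept: Optional[float]
    converged: bool
    separation_flags: dict[str, bool]
    selection_trace: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: float
    specificity: float
    auc: float
    table: TwoByTwoTable


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str  # "mann_whitney_u" | "kruskal_wallis"


# ---------------------------------------------------------------------------
# Cutoffs and binarization
# ---------------------------------------------------------------------------

def _check_binary_outcome(outcome: np.ndarray) -> np.ndarray:
    y = np.asarray(outcome).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both outcome classes must be present")
    return y


def youden_cutoff(
    values: Sequence[float], outcome: Sequence[int], feature_name: str = ""
) -> CutoffResult:
    """Youden-optimal threshold over observed values, both directions.

    Evaluates every rule ``value > c`` and ``value <= c`` with c ranging
    over the observed unique values and returns the rule maximizing
    J = sensitivity + specificity − 1.  Ties break toward higher
    specificity, then smaller ``|cutoff|``, then the greater-than
    direction, so the result is deterministic.
    """
    x = np.asarray(values, dtype=float)
    y = _check_binary_outcome(outcome)
    if x.shape != y.shape:
        raise ValidationError("values and outcome must have equal length")
    if np.isnan(x).any():
        raise ValidationError("missing values are not allowed in cutoff search")

    pos = y == 1
    neg = ~pos
    best: Optional[tuple] = None
    best_result: Optional[CutoffResult] = None
    for c in np.unique(x):
        for direction in (Direction.GREATER_THAN, Direction.LESS_OR_EQUAL):
            score = x > c if direction is Direction.GREATER_THAN else x <= c
            sens = float(score[pos].mean())
            spec = float((~score[neg]).mean())
            j = sens + spec - 1.0
            key = (j, spec, -abs(c), direction is Direction.GREATER_THAN)
            if best is None or key > best:
                best = key
                best_result = CutoffResult(
                    feature_name=feature_name,
                    cutoff=float(c),
                    direction=direction,
                    youden_j=j,
                    sens_at_cutoff=sens,
                    spec_at_cutoff=spec,
                )
    assert best_result is not None
    return best_result


def binarize_feature(values: Sequence[float], cutoff: CutoffResult) -> np.ndarray:
    """Score 1 iff the cutoff rule fires (boundary inclusive for <=)."""
    x = np.asarray(values, dtype=float)
    if cutoff.direction is Direction.GREATER_THAN:
        return (x > cutoff.cutoff).astype(int)
    return (x <= cutoff.cutoff).astype(int)


def crosstab(scores: Sequence[int], outcome: Sequence[int]) -> TwoByTwoTable:
    s = np.asarray(scores).astype(int)
    y = np.asarray(outcome).astype(int)
    if s.shape != y.shape:
        raise ValidationError("scores and outcome must have equal length")
    return TwoByTwoTable(
        a=int(((s == 1) & (y == 1)).sum()),
        b=int(((s == 1) & (y == 0)).sum()),
        c=int(((s == 0) & (y == 1)).sum()),
        d=int(((s == 0) & (y == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# Odds ratios and logistic models
# ---------------------------------------------------------------------------

def odds_ratio_wald(
    table: TwoByTwoTable, zero_cell_correction: bool = False
) -> OddsRatioResult:
    """Cross-product OR with asymptotic Wald CI and two-sided p.

    OR = ad/bc; SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d);
    CI = exp(ln OR ± z0.975 · SE); p from the normal tail of ln OR / SE.
    A zero cell makes the estimate non-estimable (separation flag) unless
    the Haldane–Anscombe +0.5 correction is explicitly requested.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    separated = table.has_zero_cell
    corrected = False
    if separated:
        if not zero_cell_correction:
            return OddsRatioResult(None, None, None, None, separation_flag=True)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # type: ignore[assignment]
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return OddsRatioResult(
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - _Z975 * se),
        ci_high=math.exp(log_or + _Z975 * se),
        p_value=p,
        separation_flag=separated,
        corrected=corrected,
    )


def _wald_estimate(name: str, coef: float, se: float) -> PredictorEstimate:
    z = coef / se
    return PredictorEstimate(
        name=name,
        coef=float(coef),
        or_value=math.exp(coef),
        ci_low=math.exp(coef - _Z975 * se),
        ci_high=math.exp(coef + _Z975 * se),
        p_value=2.0 * float(stats.norm.sf(abs(z))),
    )


class _FitFailure(Exception):
    """Logistic MLE failed or diverged (typically joint quasi-separation)."""


def _fit_logit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence is checked explicitly
        try:
            res = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise _FitFailure(str(exc)) from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise _FitFailure("non-finite estimates")
    if np.max(np.abs(res.params)) > 50.0:  # e^50: numerically divergent odds
        raise _FitFailure("divergent coefficients (separation)")
    return res


def univariate_logistic(score: Sequence[int], outcome: Sequence[int]) -> LogisticFit:
    """ML logistic fit of outcome on intercept + one binary score.

    On a saturated 2x2 with all cells positive the MLE odds ratio equals
    the cross-product ratio and the Wald SE equals sqrt(sum of reciprocal
    cells), so this agrees with :func:`odds_ratio_wald` to numerical
    precision.  A zero cell is quasi-complete separation: the fit is
    flagged instead of reporting the divergent MLE.
    """
    s = np.asarray(score).astype(int)
    y = _check_binary_outcome(outcome)
    if s.min() == s.max():
        raise ValidationError("constant predictor")
    table = crosstab(s, y)
    if table.has_zero_cell:
        return LogisticFit(
            included_predictors=["score"],
            estimates={},
            intercept=None,
            converged=False,
            separation_flags={"score": True},
        )
    X = np.column_stack([np.ones_like(s, dtype=float), s.astype(float)])
    res = _fit_logit(X, y.astype(float))
    est = _wald_estimate("score", res.params[1], res.bse[1])
    return LogisticFit(
        included_predictors=["score"],
        estimates={"score": est},
        intercept=float(res.params[0]),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flags={"score": False},
    )


def _score_test_p(
    X: np.ndarray, y: np.ndarray, phat: np.ndarray, x_new: np.ndarray
) -> float:
    """Rao score test p-value for adding x_new to a fitted logistic model."""
    w = phat * (1.0 - phat)
    u = float(x_new @ (y - phat))
    xtwx = X.T @ (X * w[:, None])
    xwx = (x_new * w) @ X
    try:
        v = float((x_new**2 * w).sum() - xwx @ np.linalg.solve(xtwx, xwx))
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 1e-10:
        return 1.0
    return float(stats.chi2.sf(u * u / v, df=1))


def stepwise_logistic(
    candidates: Mapping[str, Sequence[int]],
    outcome: Sequence[int],
    p_enter: float = 0.05,
    p_remove: float = 0.1,
) -> LogisticFit:
    """Forward selection with backward pruning over binary predictors.

    Entry: the not-yet-included candidate with the smallest score-test
    p-value enters if p <= ``p_enter``.  Removal: any included predictor
    with Wald p > ``p_remove`` is dropped (largest first).  Iterates to a
    fixed point; every step is recorded in ``selection_trace``.  Ties in
    p-value break lexicographically on the predictor name, so the result
    is deterministic for a given input.
    """
    if not candidates:
        raise ValidationError("at least one candidate predictor is required")
    y = _check_binary_outcome(outcome).astype(float)
    n = y.size
    cols: dict[str, np.ndarray] = {}
    separation: dict[str, bool] = {}
    for name, arr in candidates.items():
        s = np.asarray(arr).astype(float)
        if s.shape != y.shape:
            raise ValidationError(f"candidate {name!r} length mismatch")
        cols[name] = s
        separation[name] = crosstab(s.astype(int), y.astype(int)).has_zero_cell

    included: list[str] = []
    blocked: set[str] = set()  # candidates whose joint fit separated
    trace: list[dict] = []
    converged = True

    def design(names: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[m] for m in names])

    for _ in range(2 * len(cols) + 10):
        # current fit (intercept-only has closed-form probabilities)
        if included:
            res = _fit_logit(design(included), y)
            phat = np.asarray(res.predict())
            converged = bool(res.mle_retvals.get("converged", True))
        else:
            phat = np.full(n, y.mean())

        changed = False
        # entry step: best score-test p among eligible candidates; a
        # candidate that makes the joint MLE diverge is rolled back and
        # blocked from re-entry
        entry_p = {
            m: _score_test_p(design(included), y, phat, cols[m])
            for m in cols
            if m not in included and m not in blocked and not separation[m]
        }
        for best in sorted(entry_p, key=lambda m: (entry_p[m], m)):
            if entry_p[best] > p_enter:
                break
            try:
                _fit_logit(design(included + [best]), y)
            except _FitFailure as exc:
                blocked.add(best)
                trace.append(
                    {"action": "blocked", "name": best, "reason": str(exc)}
                )
                continue
            included.append(best)
            trace.append({"action": "enter", "name": best, "p": entry_p[best]})
            changed = True
            break

        # removal step(s)
        while included:
            res = _fit_logit(design(included), y)
            wald_p = {
                m: 2.0 * float(stats.norm.sf(abs(res.params[i + 1] / res.bse[i + 1])))
                for i, m in enumerate(included)
            }
            worst = max(sorted(wald_p), key=lambda m: wald_p[m])
            if wald_p[worst] > p_remove:
                included.remove(worst)
                trace.append({"action": "remove", "name": worst, "p": wald_p[worst]})
                changed = True
            else:
                break

        if not changed:
            break

    estimates: dict[str, PredictorEstimate] = {}
    intercept: Optional[float] = None
    if included:
        res = _fit_logit(design(included), y)
        converged = bool(res.mle_retvals.get("converged", True))
        intercept = float(res.params[0])
        for i, m in enumerate(included):
            estimates[m] = _wald_estimate(m, res.params[i + 1], res.bse[i + 1])
    return LogisticFit(
        included_predictors=list(included),
        estimates=estimates,
        intercept=intercept,
        converged=converged,
        separation_flags=separation,
        selection_trace=trace,
    )


# ---------------------------------------------------------------------------
# Performance and rank tests
# ---------------------------------------------------------------------------

def binary_performance(table: TwoByTwoTable) -> DiagnosticPerformance:
    """Sens/spec of the binarized rule and its two-point ROC AUC.

    For a binary predictor the empirical ROC has one interior operating
    point, so the trapezoidal area is (sensitivity + specificity) / 2.
    """
    if table.a + table.c < 1 or table.b + table.d < 1:
        raise ValidationError("both outcome arms must be nonempty")
    sens = table.a / (table.a + table.c)
    spec = table.d / (table.b + table.d)
    return DiagnosticPerformance(
        sensitivity=sens, specificity=spec, auc=(sens + spec) / 2.0, table=table
    )


def roc_auc_continuous(values: Sequence[float], outcome: Sequence[int]) -> float:
    """Rank-based AUC: P(random positive > random negative), ties count 1/2."""
    x = np.asarray(values, dtype=float)
    y = _check_binary_outcome(outcome)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _mann_whitney_exact(x: np.ndarray, y_vals: np.ndarray) -> tuple[float, float]:
    """Exact two-sided MWU p by enumerating all group-label assignments.

    Tie-safe (uses pooled midranks) and therefore gives p = 1 for two
    identical groups.  Intended for combined n <= 20.
    """
    pooled = np.concatenate([x, y_vals])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    n = pooled.size
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        u = float(ranks[list(idx)].sum() - offset)
        if abs(u - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def rank_tests(groups: Sequence[Sequence[float]], method: str) -> RankTestResult:
    """Mann–Whitney U (two groups) or Kruskal–Wallis (three or more).

    Mann–Whitney uses the exact permutation distribution when the combined
    sample size is <= 20, otherwise scipy's tie-corrected normal
    approximation.  Kruskal–Wallis uses the tie-corrected H statistic with
    a chi-square reference.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group must be nonempty")
    if method == "mann_whitney_u":
        if len(arrays) != 2:
            raise ValidationError("mann_whitney_u requires exactly 2 groups")
        x, y_vals = arrays
        if x.size + y_vals.size <= 20:
            u, p = _mann_whitney_exact(x, y_vals)
        else:
            res = stats.mannwhitneyu(x, y_vals, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        return RankTestResult(statistic=u, p_value=min(p, 1.0), method=method)
    if method == "kruskal_wallis":
        if len(arrays) < 3:
            raise ValidationError("kruskal_wallis requires >= 3 groups")
        res = stats.kruskal(*arrays)
        return RankTestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue), method=method
        )
    raise ValidationError(f"unknown rank test method {method!r}")


# ---------------------------------------------------------------------------
# Whole-cohort analysis
# ---------------------------------------------------------------------------

def outcome_for_contrast(
    frame: pd.DataFrame, contrast: Contrast
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subset the cohort and build the 0/1 outcome for a contrast.

    The high- vs low-risk contrast excludes carcinoma cases (it is a
    within-thymoma comparison).
    """
    contrast = Contrast(contrast)
    if contrast is Contrast.CARCINOMA_VS_THYMOMA:
        sub = frame
        y = (sub["group"] == TumorGroup.THYMIC_CARCINOMA.value).to_numpy().astype(int)
    else:
        sub = frame[frame["group"] != TumorGroup.THYMIC_CARCINOMA.value].reset_index(
            drop=True
        )
        y = (sub["group"] == TumorGroup.HIGH_RISK_THYMOMA.value).to_numpy().astype(int)
    if len(sub) == 0 or y.min() == y.max():
        raise ValidationError(
            f"contrast {contrast.value} needs both outcome classes in the cohort"
        )
    return sub, y


def analyze_cohort(
    table: CohortTable,
    contrast: Contrast,
    p_enter: float = 0.05,
    p_remove: float = 0.1,
    zero_cell_correction: bool = False,
) -> dict:
    """Full statistics stage for one contrast; returns a JSON-able report.

    Per feature: Youden cutoff, binarization, 2x2 table, Wald OR,
    univariate logistic, binary performance.  Univariately significant,
    non-separated features feed the stepwise model.  No multiple-testing
    correction is applied (the per-feature family size is echoed so readers
    can judge), matching common practice in small diagnostic cohorts.
    """
    frame = table.frame
    sub, y = outcome_for_contrast(frame, contrast)
    per_feature: dict[str, dict] = {}
    scores: dict[str, np.ndarray] = {}
    candidates: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        x = sub[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            per_feature[name] = {"skipped": True, "reason": "missing values"}
            continue
        cut = youden_cutoff(x, y, feature_name=name)
        score = binarize_feature(x, cut)
        tab = crosstab(score, y)
        orr = odds_ratio_wald(tab, zero_cell_correction=zero_cell_correction)
        perf = binary_performance(tab)
        uni = univariate_logistic(score, y) if score.min() != score.max() else None
        scores[name] = score
        uni_sig = (
            uni is not None
            and uni.converged
            and "score" in uni.estimates
            and uni.estimates["score"].p_value <= p_enter
        )
        if uni_sig:
            candidates[name] = score
        per_feature[name] = {
            "cutoff": cut.cutoff,
            "direction": cut.direction.value,
            "youden_j": cut.youden_j,
            "table": {"a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d},
            "odds_ratio": orr.or_value,
            "ci_low": orr.ci_low,
            "ci_high": orr.ci_high,
            "p_value": orr.p_value,
            "separation_flag": orr.separation_flag,
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "auc": perf.auc,
            "univariate_significant": bool(uni_sig),
            "feature_family_size": len(FEATURE_NAMES),
        }

    step: Optional[LogisticFit] = None
    if candidates:
        step = stepwise_logistic(candidates, y, p_enter=p_enter, p_remove=p_remove)
    report = {
        "contrast": Contrast(contrast).value,
        "n_cases": int(len(sub)),
        "n_positive": int(y.sum()),
        "p_enter": p_enter,
        "p_remove": p_remove,
        "features": per_feature,
        "stepwise": {
            "included": step.included_predictors if step else [],
            "estimates": {
                m: {
                    "odds_ratio": e.or_value,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                }
                for m, e in (step.estimates if step else {}).items()
            },
            "trace": step.selection_trace if step else [],
            "converged": step.converged if step else True,
        },
    }
    if "fibrosis_grade" in sub.columns and sub["fibrosis_grade"].notna().all():
        grades = sub["fibrosis_grade"].astype(int).to_numpy()
        pos_g = grades[y == 1]
        neg_g = grades[y == 0]
        test = rank_tests([pos_g, neg_g], "mann_whitney_u")
        report["fibrosis"] = {
            "mean_positive": float(pos_g.mean()),
            "mean_negative": float(neg_g.mean()),
            "mann_whitney_p": test.p_value,
        }
    return report
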