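"""ROC analysis and paired model comparison.

The area under the ROC curve is computed as the Mann-Whitney concordance
probability (ties counted 1/2), which equals the trapezoidal integral of the
empirical ROC curve.  Confidence intervals and the paired two-model
comparison use the DeLong asymptotic variance of the concordance statistic
(a nonparametric U-statistic argument); a bootstrap alternative sits behind
a switch.  Rows are treated as independent — with pooled per-minute
concentration sets this ignores within-patient correlation, a caveat
discussed in the methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "RocResult",
    "RocComparison",
    "mann_whitney_auc",
    "roc_auc",
    "auc_ci",
    "accuracy",
    "compare_roc",
    "evaluate_models",
    "EvaluationReport",
]


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.size != y.size:
        raise InvalidInputError("scores and labels must have equal length")
    if s.size == 0:
        raise InvalidInputError("empty input")
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("scores must be finite")
    if not np.all(np.isin(y, (0, 1))):
        raise InvalidInputError("labels must be binary 0/1")
    return s, y.astype(int)


def _require_both_classes(y):
    if y.min() == y.max():
        raise InvalidInputError("both classes must be present")


@dataclass
class RocResult:
    """ROC points, AUC with confidence interval, and threshold accuracy."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    accuracy: float
    threshold: float
    n: int


@dataclass
class RocComparison:
    """Paired comparison of two correlated ROC curves on the same labels."""

    auc_a: float
    auc_b: float
    diff: float
    z: float
    p_value: float


def _delong_components(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components via midranks.

    Returns ``(auc, v10, v01)`` where ``v10`` has one entry per positive and
    ``v01`` one per negative; ``var(auc) = var(v10)/m + var(v01)/n``.
    """
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v10, v01


def mann_whitney_auc(scores, labels) -> float:
    """Concordance probability P(score_pos > score_neg) + 0.5 P(tie)."""
    s, y = _check_scores_labels(scores, labels)
    _require_both_classes(y)
    auc, _, _ = _delong_components(s, y)
    return auc


def auc_ci(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` uses the asymptotic U-statistic variance;
    ``method="bootstrap"`` resamples rows with replacement (stratified by
    class so both classes persist).
    """
    if not (0 < level < 1):
        raise InvalidParameterError("confidence level must be in (0, 1)")
    s, y = _check_scores_labels(scores, labels)
    _require_both_classes(y)
    auc, v10, v01 = _delong_components(s, y)
    if method == "delong":
        var = 0.0
        if v10.size > 1:
            var += np.var(v10, ddof=1) / v10.size
        if v01.size > 1:
            var += np.var(v01, ddof=1) / v01.size
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return max(0.0, auc - half), min(1.0, auc + half)
    if method == "bootstrap":
        rng = np.random.default_rng() if rng is None else rng
        ipos = np.flatnonzero(y == 1)
        ineg = np.flatnonzero(y == 0)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ipos, ipos.size), rng.choice(ineg, ineg.size)]
            )
            stats[b], _, _ = _delong_components(s[idx], y[idx])
        lo, hi = np.quantile(stats, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return float(max(0.0, lo)), float(min(1.0, hi))
    raise InvalidParameterError(f"unknown CI method {method!r}")


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction correctly classified calling score >= threshold class 1."""
    s, y = _check_scores_labels(scores, labels)
    return float(np.mean((s >= threshold).astype(int) == y))


def roc_auc(
    scores,
    labels,
    level: float = 0.95,
    ci_method: str = "delong",
    threshold: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> RocResult:
    """Full ROC analysis of one score vector against binary labels."""
    s, y = _check_scores_labels(scores, labels)
    _require_both_classes(y)
    fpr, tpr, thr = roc_curve(y, s)
    auc = mann_whitney_auc(s, y)
    lo, hi = auc_ci(s, y, level=level, method=ci_method, rng=rng)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        accuracy=accuracy(s, y, threshold=threshold),
        threshold=threshold,
        n=int(s.size),
    )


def compare_roc(scores_a, scores_b, labels) -> RocComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be aligned to the same label vector.  The test
    statistic is the AUC difference over its paired standard error; swapping
    the inputs negates the difference and leaves the p-value unchanged.
    """
    sa, y = _check_scores_labels(scores_a, labels)
    sb, yb = _check_scores_labels(scores_b, labels)
    if sa.size != sb.size:
        raise InvalidInputError("score vectors must have equal length")
    _require_both_classes(y)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    diff = auc_a - auc_b
    var = 0.0
    if v10a.size > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / v10a.size
    if v01a.size > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / v01a.size
    if var <= 0 or not np.isfinite(var):
        # Identical (or perfectly coupled) scores: no evidence of a difference.
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if not np.isfinite(z) and diff == 0 else float(2.0 * norm.sf(abs(z)))
    if diff == 0:
        p = 1.0
    return RocComparison(auc_a=auc_a, auc_b=auc_b, diff=float(diff), z=float(z), p_value=p)


@dataclass
class EvaluationReport:
    """Side-by-side report of the surface model and the logistic comparator."""

    table: pd.DataFrame
    comparison: RocComparison
    roc_points: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [self.table.to_string(index=False)]
        c = self.comparison
        lines.append(
            f"paired AUC difference (surface - logistic): {c.diff:+.4f}  "
            f"z = {c.z:.3f}  p = {c.p_value:.4g}"
        )
        return "\n".join(lines)


def evaluate_models(
    dataset: pd.DataFrame,
    greco_model=None,
    logistic_model=None,
    level: float = 0.95,
    ci_method: str = "delong",
    threshold: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> EvaluationReport:
    """Score both predictors on a labeled dataset and compare their ROC curves.

    ``greco_model`` defaults to the shipped "oaas_lt4" surface preset;
    ``logistic_model`` defaults to a fresh forward-selection fit on the same
    dataset (internal validation, as is conventional for this design).
    """
    from .greco import GrecoResponseSurface
    from .logistic import fit_logistic

    needed = {"cep_ugml", "cer_ngml", "label", "patient_id"}
    missing = needed - set(dataset.columns)
    if missing:
        raise InvalidInputError(f"labeled dataset is missing columns: {sorted(missing)}")
    y = dataset["label"].to_numpy()
    X = dataset[["cep_ugml", "cer_ngml"]].to_numpy(dtype=float)

    if greco_model is None:
        greco_model = GrecoResponseSurface.from_preset("oaas_lt4").fit()
    if logistic_model is None:
        logistic_model = fit_logistic(dataset)

    scores_g = greco_model.predict_proba(X)[:, 1]
    scores_l = logistic_model.predict_proba(
        dataset[["cep_ugml", "cer_ngml"]].rename(
            columns={"cep_ugml": "propofol", "cer_ngml": "remifentanil"}
        )
    )[:, 1]

    rows = []
    points = {}
    for name, sc in (("greco_surface", scores_g), ("logistic", scores_l)):
        res = roc_auc(sc, y, level=level, ci_method=ci_method, threshold=threshold, rng=rng)
        rows.append(
            {
                "model": name,
                "auc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "accuracy": res.accuracy,
                "n_rows": res.n,
                "n_patients": int(dataset["patient_id"].nunique()),
            }
        )
        points[name] = res
    comp = compare_roc(scores_g, scores_l, y)
    return EvaluationReport(table=pd.DataFrame(rows), comparison=comp, roc_points=points)
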