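"""Forward-selection logistic regression on (propofol, remifentanil) concentration sets.

The comparator model for emergence prediction is a plain binomial logistic
regression of the binary response label (1 = responsive / regained response,
0 = no response / LOR) on the two effect-site concentrations.  Terms enter by
forward selection: starting from the intercept-only model, the candidate
with the smallest likelihood-ratio p-value is added while that p-value is
below the inclusion threshold (default 0.05).

The maximum-likelihood fit is iteratively reweighted least squares with
step-halving on the log-likelihood; convergence is declared when the score
(gradient) norm falls below ``tol``.  (Quasi-)complete separation is
surfaced as a flagged non-converged fit with a :class:`SeparationWarning`,
never a silent failure.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import (
    DegenerateFitError,
    InvalidInputError,
    InvalidParameterError,
    SeparationWarning,
)

__all__ = ["ForwardSelectionLogistic", "fit_logistic", "published_vats_model"]

# Any |coefficient| beyond this on standardized-ish clinical scales signals separation.
_SEPARATION_BOUND = 1e4


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(
    X: np.ndarray, y: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """Maximize the binomial log-likelihood; returns (beta, llf, cov, converged, n_iter)."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hess = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # Step-halving: back off until the log-likelihood does not decrease
        # (slack relative to |ll| so round-off at the optimum is accepted).
        step = 1.0
        slack = 1e-11 * (1.0 + abs(ll))
        for _ in range(30):
            cand = beta + step * delta
            eta_c = X @ cand
            ll_c = _log_likelihood(eta_c, y)
            if ll_c >= ll - slack:
                break
            step *= 0.5
        moved = np.linalg.norm(cand - beta)
        beta, eta, ll = cand, eta_c, ll_c
        if moved < 1e-10 * (1.0 + np.linalg.norm(beta)):
            # at the numerical optimum: the score cannot shrink further
            converged = np.linalg.norm(X.T @ (y - expit(eta))) < max(tol, 1e-6)
            break
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            break
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return beta, ll, cov, converged, it


class ForwardSelectionLogistic(BaseEstimator, ClassifierMixin):
    """Binomial logistic regression with forward selection of terms.

    Parameters
    ----------
    threshold : float
        Likelihood-ratio p-value below which a candidate term enters
        (default 0.05).  0 admits nothing; 1 admits every term that
        improves the likelihood.
    max_iter : int
        IRLS iteration cap per fit.
    tol : float
        Convergence tolerance on the score (gradient) norm.

    Attributes
    ----------
    intercept_ : ndarray of shape (1,)
    coef_ : ndarray of shape (1, n_features)
        Coefficients on the original feature scale; excluded terms are 0.
    included_terms_ : list of str
        Selected feature names in order of entry.
    pvalues_ : dict
        Likelihood-ratio entry p-value per candidate evaluated at its
        selection step (selected terms: the p-value at entry).
    se_ : dict
        Asymptotic standard errors of the final model's terms (and
        ``"intercept"``).
    llf_ : float
        Final maximized log-likelihood.
    converged_ : bool
        False flags separation or iteration-cap exhaustion.
    """

    def __init__(self, threshold: float = 0.05, max_iter: int = 100, tol: float = 1e-8):
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol

    def _resolve_names(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError("X must be 2-D")
        return arr, [f"x{i}" for i in range(arr.shape[1])]

    def fit(self, X, y):
        if not (0 <= self.threshold <= 1):
            raise InvalidParameterError("threshold must be in [0, 1]")
        Xa, names = self._resolve_names(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != Xa.shape[0]:
            raise InvalidInputError("X and y length mismatch")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise InvalidInputError("labels must be binary 0/1")
        if np.unique(y).size < 2:
            raise DegenerateFitError("both outcome classes must be present to fit")
        if not np.all(np.isfinite(Xa)):
            raise InvalidInputError("X must be finite")

        n, p = Xa.shape
        ones = np.ones((n, 1))

        def fit_cols(cols: Sequence[int]):
            design = np.hstack([ones, Xa[:, cols]]) if cols else ones
            return _irls(design, y, self.max_iter, self.tol)

        included: list[int] = []
        pvalues: dict[str, float] = {}
        beta, llf, cov, converged, _ = fit_cols(included)
        while len(included) < p:
            best = None
            for j in range(p):
                if j in included:
                    continue
                b_j, ll_j, cov_j, conv_j, _ = fit_cols(included + [j])
                stat = max(2.0 * (ll_j - llf), 0.0)
                pval = float(chi2.sf(stat, df=1))
                if best is None or pval < best[1]:
                    best = (j, pval, b_j, ll_j, cov_j, conv_j)
            j, pval, b_j, ll_j, cov_j, conv_j = best
            pvalues[names[j]] = pval
            if pval < self.threshold:
                included.append(j)
                beta, llf, cov, converged = b_j, ll_j, cov_j, conv_j
            else:
                break

        # Complete separation: every positive scored strictly above every
        # negative means the MLE diverges and the fit must be flagged.
        separated = False
        if included:
            design = np.hstack([ones, Xa[:, included]])
            eta = design @ beta
            if eta[y == 1].min() > eta[y == 0].max():
                separated = True
        if separated or not converged:
            converged = False
            warnings.warn(
                "logistic fit did not converge"
                + (" (complete separation detected)" if separated else "")
                + "; coefficients are unreliable",
                SeparationWarning,
                stacklevel=2,
            )

        coef = np.zeros(p)
        se = {"intercept": float(np.sqrt(max(cov[0, 0], 0.0)))}
        for slot, j in enumerate(included, start=1):
            coef[j] = beta[slot]
            se[names[j]] = float(np.sqrt(max(cov[slot, slot], 0.0)))

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.classes_ = np.array([0, 1])
        self.intercept_ = np.array([beta[0]])
        self.coef_ = coef.reshape(1, p)
        self.included_terms_ = [names[j] for j in included]
        self.pvalues_ = pvalues
        self.se_ = se
        self.llf_ = llf
        self.converged_ = bool(converged)
        return self

    def predict_proba(self, X):
        Xa, _ = self._resolve_names(X)
        if Xa.shape[1] != self.coef_.shape[1]:
            raise InvalidInputError(
                f"X has {Xa.shape[1]} features, model was fitted with {self.coef_.shape[1]}"
            )
        p1 = expit(self.intercept_[0] + Xa @ self.coef_.ravel())
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_dict(self) -> dict:
        """Flat serializable summary (terms, estimates, p-values, log-likelihood)."""
        out = {
            "intercept": float(self.intercept_[0]),
            "included_terms": list(self.included_terms_),
            "coefficients": {
                str(name): float(c)
                for name, c in zip(self.feature_names_in_, self.coef_.ravel())
            },
            "entry_p_values": {k: float(v) for k, v in self.pvalues_.items()},
            "standard_errors": {k: float(v) for k, v in self.se_.items()},
            "log_likelihood": float(self.llf_),
            "converged": bool(self.converged_),
        }
        return out


def fit_logistic(dataset: pd.DataFrame, threshold: float = 0.05) -> ForwardSelectionLogistic:
    """Fit the comparator on a labeled dataset (columns cep_ugml, cer_ngml, label).

    Feature names are mapped to ``propofol`` (cep) and ``remifentanil`` (cer).
    """
    needed = {"cep_ugml", "cer_ngml", "label"}
    missing = needed - set(dataset.columns)
    if missing:
        raise InvalidInputError(f"labeled dataset is missing columns: {sorted(missing)}")
    X = dataset[["cep_ugml", "cer_ngml"]].rename(
        columns={"cep_ugml": "propofol", "cer_ngml": "remifentanil"}
    )
    return ForwardSelectionLogistic(threshold=threshold).fit(X, dataset["label"])


def published_vats_model(
    intercept: float,
    beta_p: float = -3.403,
    beta_r: float = 2.652,
) -> ForwardSelectionLogistic:
    """Logistic model with the coefficients reported for a 29-patient VATS cohort.

    The published fit gives log-odds slopes of 2.652 per ng/mL remifentanil
    and -3.403 per µg/mL propofol for the probability of regained response;
    its intercept was not reported, so the caller must supply one (the model's
    absolute probabilities — though not its ROC ordering — depend on it).
    Feature order matches :func:`fit_logistic`: ``(propofol, remifentanil)``.
    """
    model = ForwardSelectionLogistic()
    model.feature_names_in_ = np.asarray(["propofol", "remifentanil"], dtype=object)
    model.n_features_in_ = 2
    model.classes_ = np.array([0, 1])
    model.intercept_ = np.array([float(intercept)])
    model.coef_ = np.array([[float(beta_p), float(beta_r)]])
    model.included_terms_ = ["propofol", "remifentanil"]
    model.pvalues_ = {}
    model.se_ = {}
    model.llf_ = float("nan")
    model.converged_ = True
    return model
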