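"""Greco propofol-remifentanil interaction surface.

The Greco response-surface model expresses the probability of loss of
response (LOR) to a stimulus as a sigmoid-Emax function of a combined drug
potency

    U = CeP/C50P + CeR/C50R + alpha * (CeP/C50P) * (CeR/C50R)

    P(LOR) = E0 + (Emax - E0) * U^N / (U^N + 1)

with CeP, CeR the propofol (µg/mL) and remifentanil (ng/mL) effect-site
concentrations, C50 the single-drug concentrations giving 50% of maximal
effect, N the steepness of the surface and alpha the interaction strength
(alpha > 0: synergy; alpha = 0: additivity).  The probability of regained
response is the complement, P(RR) = 1 - P(LOR).

The baseline effect E0 defaults to 0 and Emax to 1 so the sigmoid spans the
full probability range.  The shipped ``"oaas_lt4"`` preset carries published
volunteer-study parameters for the endpoint "OAA/S score < 4"
(C50P = 1.8 µg/mL, C50R = 12.5 ng/mL, N = 3.8, alpha = 5.1).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import InvalidInputError, InvalidParameterError
from .pk import ConcentrationTrajectory

__all__ = ["GrecoResponseSurface", "PRESETS", "predict_rr_time"]

#: Named parameter presets (c50p µg/mL, c50r ng/mL, n, alpha, emax).
PRESETS = {
    "oaas_lt4": {"c50p": 1.8, "c50r": 12.5, "n": 3.8, "alpha": 5.1, "emax": 1.0, "e0": 0.0},
}


def _as_nonneg(x, name):
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError(f"{name} must be finite and non-negative")
    return arr


class GrecoResponseSurface(BaseEstimator, ClassifierMixin):
    """Two-drug interaction surface scoring the probability of regained response.

    A *prefit* probabilistic classifier in the scikit-learn idiom: the
    parameters are fixed at construction (typically from a published
    volunteer fit), ``fit`` only validates them, and ``predict_proba``
    scores rows of ``(cep, cer)`` concentration pairs.  Class 1 is
    "responsive" (regained response), class 0 is "no response" (LOR).

    Parameters
    ----------
    c50p, c50r : float
        Single-drug effect-site concentrations at half-maximal effect
        (propofol µg/mL, remifentanil ng/mL).
    n : float
        Steepness of the response surface.
    alpha : float
        Interaction strength; 0 means additive, > 0 synergistic.
    emax, e0 : float
        Maximal and baseline effect on the probability scale.
    """

    def __init__(
        self,
        c50p: float = 1.8,
        c50r: float = 12.5,
        n: float = 3.8,
        alpha: float = 5.1,
        emax: float = 1.0,
        e0: float = 0.0,
    ):
        self.c50p = c50p
        self.c50r = c50r
        self.n = n
        self.alpha = alpha
        self.emax = emax
        self.e0 = e0

    @classmethod
    def from_preset(cls, name: str = "oaas_lt4") -> "GrecoResponseSurface":
        if name not in PRESETS:
            raise InvalidParameterError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return cls(**PRESETS[name])

    def _validate(self) -> None:
        if not (self.c50p > 0 and self.c50r > 0):
            raise InvalidParameterError("c50p and c50r must be positive")
        if not (self.n > 0):
            raise InvalidParameterError("steepness n must be positive")
        if self.alpha < 0:
            raise InvalidParameterError("alpha must be >= 0")
        if not (0 < self.emax <= 1):
            raise InvalidParameterError("emax must be in (0, 1]")
        if not (0 <= self.e0 < self.emax):
            raise InvalidParameterError("e0 must be in [0, emax)")

    # -- core surface ------------------------------------------------------

    def drive(self, cep, cer):
        """Combined dimensionless potency U of the drug pair."""
        self._validate()
        up = _as_nonneg(cep, "cep") / self.c50p
        ur = _as_nonneg(cer, "cer") / self.c50r
        out = up + ur + self.alpha * up * ur
        return float(out) if out.ndim == 0 else out

    def p_lor(self, cep, cer):
        """Probability of loss of response (no response to name calling)."""
        u = np.asarray(self.drive(cep, cer), dtype=float)
        # U^n/(U^n+1) = expit(n ln U); exact 0 at U = 0.
        with np.errstate(divide="ignore"):
            hill = np.where(u > 0, expit(self.n * np.log(np.where(u > 0, u, 1.0))), 0.0)
        out = self.e0 + (self.emax - self.e0) * hill
        return float(out) if out.ndim == 0 else out

    def p_rr(self, cep, cer):
        """Probability of regained response: exactly ``1 - p_lor``."""
        out = 1.0 - np.asarray(self.p_lor(cep, cer), dtype=float)
        return float(out) if out.ndim == 0 else out

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X=None, y=None):
        """Validate parameters; no estimation happens (the surface is prefit)."""
        self._validate()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X):
        """Columns of X are ``(cep, cer)``; returns ``[P(class 0), P(class 1)]``.

        Class 1 is "responsive", so its probability is ``p_rr``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidInputError("X must be 2-D with columns (cep, cer)")
        p1 = np.asarray(self.p_rr(X[:, 0], X[:, 1]), dtype=float)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- derived quantities ------------------------------------------------

    def axis_intercept(self, level: float, drug: str) -> float:
        """Single-drug concentration with ``p_lor == level`` (closed form)."""
        self._validate()
        if not (self.e0 < level < self.emax):
            raise InvalidInputError(f"level must lie in ({self.e0}, {self.emax}), got {level}")
        frac = (level - self.e0) / (self.emax - self.e0)
        u = (frac / (1.0 - frac)) ** (1.0 / self.n)
        return u * (self.c50p if drug == "propofol" else self.c50r)

    def isobole(self, level: float, cep_grid: Optional[np.ndarray] = None, n_points: int = 50):
        """Equal-effect contour: pairs ``(cep, cer)`` with ``p_lor == level``.

        Solved by bracketed root-finding in ``cer`` for each ``cep`` on the
        grid, to |p_lor - level| < 1e-9.  With alpha > 0 the contour bows
        inward below the straight additive line joining the axis intercepts.
        """
        self._validate()
        if not (self.e0 < level < self.emax):
            raise InvalidInputError(f"isobole level must lie in ({self.e0}, {self.emax})")
        cep_max = self.axis_intercept(level, "propofol")
        cer_max = self.axis_intercept(level, "remifentanil")
        if cep_grid is None:
            cep_grid = np.linspace(0.0, cep_max, n_points)
        else:
            cep_grid = _as_nonneg(cep_grid, "cep_grid")
            if np.any(cep_grid > cep_max):
                raise InvalidInputError("cep_grid exceeds the contour's propofol axis intercept")
        pairs = np.empty((cep_grid.size, 2))
        for i, cep in enumerate(cep_grid):
            f = lambda cer: self.p_lor(cep, cer) - level
            if abs(f(0.0)) <= 1e-15:
                cer = 0.0
            else:
                cer = brentq(f, 0.0, cer_max * (1 + 1e-12), xtol=1e-13, rtol=1e-15)
            pairs[i] = (cep, cer)
        return pairs

    def predict_rr_time(
        self, trajectory: ConcentrationTrajectory, threshold: float = 0.5
    ) -> Optional[float]:
        """Earliest time at which P(RR) reaches ``threshold`` along a trajectory.

        Linear interpolation between the bracketing grid samples refines the
        crossing below the grid resolution; a tie at exactly the threshold
        counts as crossed.  Returns None if the threshold is never reached.
        """
        return predict_rr_time(trajectory, self, threshold=threshold)


def predict_rr_time(
    trajectory: ConcentrationTrajectory,
    surface: GrecoResponseSurface,
    threshold: float = 0.5,
) -> Optional[float]:
    """Module-level form of :meth:`GrecoResponseSurface.predict_rr_time`."""
    if not isinstance(trajectory, ConcentrationTrajectory):
        raise InvalidInputError("trajectory must be a ConcentrationTrajectory")
    if not (0 < threshold < 1):
        raise InvalidParameterError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(surface.p_rr(trajectory.cep, trajectory.cer), dtype=float)
    hits = np.flatnonzero(p >= threshold)
    if hits.size == 0:
        return None
    i = int(hits[0])
    if i == 0:
        return float(trajectory.times[0])
    t0, t1 = trajectory.times[i - 1], trajectory.times[i]
    p0, p1 = p[i - 1], p[i]
    return float(t0 + (threshold - p0) / (p1 - p0) * (t1 - t0))
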