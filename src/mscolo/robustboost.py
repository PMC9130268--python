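"""RobustBoost: boosting with a Brownian-motion potential and an error goal.

Boost-by-majority style boosting on decision stumps.  The algorithm tracks
a virtual time t in [0, 1] and per-example margins m_i; examples are
weighted by a Gaussian weight centred on a drifting target margin

    mu(t)     = (theta - 2 rho) e^(1 - t) + 2 rho
    sigma2(t) = (sigma_f^2 + 1) e^(2 (1 - t)) - 1
    w(m, t)   = exp(-(m - mu(t))^2 / sigma2(t))

and the potential of an example is Phi(m, t) = (1 - erf((m - mu(t)) /
sigma(t))) / 2.  The drift rho is fixed by requiring the initial potential
of a zero-margin example to equal the error goal epsilon, so that driving
the average potential down to its final value bounds the training error by
roughly epsilon.  Each boosting step trains a stump on the current weights
and then solves simultaneously for a margin step alpha and a time advance
dt such that the stump decorrelates from the new weights and the average
potential does not increase; the run terminates when t reaches 1 or the
stump budget is exhausted.

If the per-step solve fails numerically the classifier falls back to
AdaBoost with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfinv
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array

logger = logging.getLogger(__name__)

__all__ = ["RobustBoostClassifier"]


class RobustBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boost-by-majority classifier on depth-1 trees.

    Parameters
    ----------
    n_estimators : stump budget (the run may stop earlier when t reaches 1).
    error_goal : target training error epsilon in (0, 0.5).
    theta : target margin at t = 1.
    sigma_f : final margin spread sigma_f > 0.
    """

    def __init__(self, n_estimators: int = 100, error_goal: float = 0.2,
                 theta: float = 0.0, sigma_f: float = 0.1,
                 max_alpha: float = 4.0, max_time_step: float = 0.05,
                 random_state=None):
        self.n_estimators = n_estimators
        self.error_goal = error_goal
        self.theta = theta
        self.sigma_f = sigma_f
        self.max_alpha = max_alpha
        # cap on the per-iteration time advance: without it a single strong
        # stump can satisfy the potential goal and end the run immediately,
        # leaving an ensemble of one; the cap spreads the run over >= 1/cap
        # stumps without changing the potential semantics
        self.max_time_step = max_time_step
        self.random_state = random_state

    # -- potential machinery -------------------------------------------------

    def _mu(self, t):
        return (self.theta - 2.0 * self._rho) * np.exp(1.0 - t) + 2.0 * self._rho

    def _sigma2(self, t):
        return (self.sigma_f ** 2 + 1.0) * np.exp(2.0 * (1.0 - t)) - 1.0

    def _weights(self, m, t):
        return np.exp(-((m - self._mu(t)) ** 2) / self._sigma2(t))

    def _potential(self, m, t):
        return 0.5 * (1.0 - erf((m - self._mu(t)) / np.sqrt(self._sigma2(t))))

    def _solve_rho(self):
        # initial potential of a zero-margin example equals the error goal:
        # Phi(0, 0) = eps  =>  mu(0) = -sigma(0) erfinv(1 - 2 eps)
        eps = self.error_goal
        if not 0.0 < eps < 0.5:
            raise ValueError("error_goal must lie in (0, 0.5)")
        sigma0 = np.sqrt(self._sigma2_nominal(0.0))
        mu0 = -sigma0 * erfinv(1.0 - 2.0 * eps)
        e = np.exp(1.0)
        return (self.theta * e - mu0) / (2.0 * (e - 1.0))

    def _sigma2_nominal(self, t):
        return (self.sigma_f ** 2 + 1.0) * np.exp(2.0 * (1.0 - t)) - 1.0

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RobustBoost is a binary classifier")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        self._rho = self._solve_rho()
        try:
            self._fit_robust(X, ypm)
            if not self.estimators_:
                raise RuntimeError("no usable stump found")
        except Exception as exc:  # numerical failure -> AdaBoost fallback
            logger.warning("RobustBoost solve failed (%s); falling back to AdaBoost", exc)
            self._fallback_ = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=self.n_estimators, learning_rate=0.1,
                random_state=self.random_state)
            self._fallback_.fit(X, (ypm > 0).astype(int))
            return self
        self._fallback_ = None
        return self

    def _fit_robust(self, X, ypm):
        n = len(ypm)
        m = np.zeros(n)
        t = 0.0
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        rs = np.random.RandomState(
            self.random_state if self.random_state is not None else 0)
        for _ in range(self.n_estimators):
            if t >= 1.0 - 1e-9:
                break
            w = self._weights(m, t)
            total = w.sum()
            if not np.isfinite(total) or total <= 1e-300:
                break  # every example far beyond the target margin
            stump = DecisionTreeClassifier(
                max_depth=1, random_state=rs.randint(0, 2 ** 31 - 1))
            stump.fit(X, (ypm > 0).astype(int), sample_weight=w / total)
            h = np.where(stump.predict(X) > 0.5, 1.0, -1.0)
            agree = ypm * h
            edge = float(np.sum(w * agree) / total)
            if edge <= 1e-12:
                # stump no better than chance on current weights: advance time
                t = min(1.0, t + 1.0 / self.n_estimators)
                continue
            dt, alpha = self._solve_step(m, agree, t)
            if alpha <= 0:
                t = min(1.0, t + 1.0 / self.n_estimators)
                continue
            m = m + alpha * agree
            t = t + dt
            self.estimators_.append(stump)
            self.alphas_.append(alpha)

    def _solve_step(self, m, agree, t):
        """Find (dt, alpha): zero stump/weight correlation at t + dt while the
        average potential does not increase; dt as large as feasible."""
        pot_now = self._potential(m, t).sum()

        def alpha_for(dt):
            tn = t + dt

            def corr(a):
                return float(np.sum(self._weights(m + a * agree, tn) * agree))

            lo, hi = 0.0, self.max_alpha
            c_lo = corr(lo)
            if c_lo <= 0.0:
                return 0.0
            c_hi = corr(hi)
            if c_hi > 0.0:
                return hi
            return brentq(corr, lo, hi, xtol=1e-6)

        def pot_gain(dt):
            a = alpha_for(dt)
            return float(self._potential(m + a * agree, t + dt).sum() - pot_now), a

        dt_max = min(1.0 - t, self.max_time_step)
        gain_max, a_max = pot_gain(dt_max)
        if gain_max <= 0.0:
            return dt_max, a_max  # can finish the run outright
        dt_min = min(1e-4, dt_max)
        gain_min, a_min = pot_gain(dt_min)
        if gain_min > 0.0:
            # even a tiny time step raises the potential: take the margin
            # step alone with a minimal time advance
            return dt_min, a_min
        lo, hi = dt_min, dt_max
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            gain_mid, _ = pot_gain(mid)
            if gain_mid <= 0.0:
                lo = mid
            else:
                hi = mid
        return lo, alpha_for(lo)

    # -- inference -----------------------------------------------------------

    def decision_function(self, X):
        X = check_array(X)
        if self._fallback_ is not None:
            return self._fallback_.decision_function(X)
        score = np.zeros(X.shape[0])
        for stump, alpha in zip(self.estimators_, self.alphas_):
            score += alpha * np.where(stump.predict(X) > 0.5, 1.0, -1.0)
        total = sum(self.alphas_)
        return score / total if total > 0 else score

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score >= 0, self.classes_[1], self.classes_[0])
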