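"""Logistic psychometric function fitting: PSE and JND.

The proportion of "group motion" reports as a function of SOA is fitted by
maximum likelihood with a two-parameter logistic,

    P(SOA) = 1 / (1 + exp(-(SOA - mu) / s)),

without lapse or guess rates.  The point of subjective equality (PSE) is
the 50% point, i.e. mu; the just noticeable difference (JND) is half the
span between the 25% and 75% points, which for this parameterization is
s * ln 3.  Fitting is deterministic: the optimizer is initialized from a
logit-linearized least-squares estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

LN3 = math.log(3.0)
#: SOA range of the Ternus designs; a PSE outside it is flagged extrapolated
TESTED_RANGE_MS = (80.0, 260.0)


@dataclass
class PsychometricFit:
    mu_ms: float
    s_ms: float
    converged: bool
    extrapolated: bool
    n_per_level: np.ndarray
    soa_levels_ms: np.ndarray

    @property
    def pse_ms(self) -> float:
        return pse(self)

    @property
    def jnd_ms(self) -> float:
        return jnd(self)

    def predict(self, soa_ms) -> np.ndarray:
        return expit((np.asarray(soa_ms, dtype=float) - self.mu_ms) / self.s_ms)


def _nll(theta, soa, k, n):
    mu, log_s = theta
    s = math.exp(log_s)
    z = (soa - mu) / s
    # stable log-likelihood: log p = -log1p(exp(-z)), log(1-p) = -log1p(exp(z))
    return float(np.sum(k * np.logaddexp(0.0, -z) + (n - k) * np.logaddexp(0.0, z)))


def fit_logistic(soa_levels_ms, k_group, n_trials) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the two-parameter logistic.

    Parameters
    ----------
    soa_levels_ms : SOA levels (ms)
    k_group : number of "group motion" responses per level
    n_trials : number of trials per level

    Degenerate data (all responses 0, all 1, or identical proportions at
    every level) are flagged non-converged with NaN estimates.
    """
    soa = np.asarray(soa_levels_ms, dtype=float)
    k = np.asarray(k_group, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    if soa.shape != k.shape or soa.shape != n.shape:
        raise ValueError("soa, k and n must have equal length")
    use = n > 0
    soa, k, n = soa[use], k[use], n[use]
    if len(np.unique(soa)) < 2:
        raise ValueError("need at least 2 distinct SOA levels with trials")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")

    p = k / n
    failed = PsychometricFit(np.nan, np.nan, False, False, n.copy(), soa.copy())
    if np.all(k == 0) or np.all(k == n) or np.allclose(p, p[0]):
        return failed

    # deterministic initialization: least squares on clipped logits
    pc = np.clip(p, 1.0 / (2.0 * n.max()), 1.0 - 1.0 / (2.0 * n.max()))
    y = np.log(pc / (1.0 - pc))
    slope, intercept = np.polyfit(soa, y, 1)
    if slope <= 0:
        slope = 1.0 / (soa.max() - soa.min())
    s0 = 1.0 / slope
    mu0 = -intercept * s0
    x0 = np.array([mu0, math.log(max(s0, 1e-3))])

    res = minimize(_nll, x0, args=(soa, k, n), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    mu, log_s = res.x
    s = math.exp(log_s)
    ok = bool(res.success) and np.isfinite(mu) and np.isfinite(s)
    # a scale blown past the data range means an unidentifiable fit
    if ok and s > 50.0 * (soa.max() - soa.min()):
        ok = False
    if not ok:
        return failed
    extrap = not (TESTED_RANGE_MS[0] <= mu <= TESTED_RANGE_MS[1])
    return PsychometricFit(float(mu), float(s), True, extrap, n.copy(), soa.copy())


def pse(fit: PsychometricFit) -> float:
    """SOA at which the fitted curve crosses 50% (= mu)."""
    if not fit.converged:
        raise ValueError("PSE undefined for a non-converged fit")
    return fit.mu_ms


def jnd(fit: PsychometricFit) -> float:
    """Half the span between the 25% and 75% points: s * ln 3."""
    if not fit.converged:
        raise ValueError("JND undefined for a non-converged fit")
    return fit.s_ms * LN3
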