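"""Four-parameter erf psychometric model of rightward-choice probability.

P(right | c) = gamma + (1 - gamma - lambda) * (erf((c - mu) / sigma) + 1) / 2

where gamma / lambda are the left / right lapse rates, mu the response bias
and sigma the contrast threshold (both in percent contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf

__all__ = [
    "PsychometricParams",
    "PsychFitResult",
    "psych_eval",
    "fit_psychometric",
    "aggregate_trials",
    "bias_shift",
    "DEFAULT_BOUNDS",
]

# Box constraints for maximum-likelihood fitting: (gamma, lambda, mu, sigma).
DEFAULT_BOUNDS = ((0.0, 0.5), (0.0, 0.5), (-100.0, 100.0), (0.5, 200.0))

_EPS = 1e-9


@dataclass(frozen=True)
class PsychometricParams:
    gamma: float  # left-lapse rate
    lambda_: float  # right-lapse rate
    mu: float  # bias, percent contrast
    sigma: float  # threshold, percent contrast

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 0.5 and 0.0 <= self.lambda_ <= 0.5):
            raise ValueError("lapse rates must lie in [0, 0.5]")
        if self.gamma + self.lambda_ >= 1.0:
            raise ValueError("gamma + lambda must be < 1")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma, self.lambda_, self.mu, self.sigma])


@dataclass(frozen=True)
class PsychFitResult:
    params: PsychometricParams
    nll: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    boundary: bool = False


def psych_eval(params: PsychometricParams, signed_contrast) -> np.ndarray:
    """Probability of a rightward choice at the given signed contrast(s)."""
    c = np.asarray(signed_contrast, dtype=float)
    p = params.gamma + (1.0 - params.gamma - params.lambda_) * (
        erf((c - params.mu) / params.sigma) + 1.0) / 2.0
    return p if p.ndim else float(p)


def _nll(theta: np.ndarray, c: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    gamma, lam, mu, sigma = theta
    p = gamma + (1.0 - gamma - lam) * (erf((c - mu) / sigma) + 1.0) / 2.0
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def aggregate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trials table to (signed_contrast, n_right, n_total) tuples.

    No-response trials (choice == 0) count toward n_total but not n_right.
    """
    g = trials.groupby("signed_contrast")["choice"]
    out = pd.DataFrame({
        "signed_contrast": np.asarray(sorted(g.groups)),
        "n_right": g.apply(lambda s: int((s == 1).sum())).values,
        "n_total": g.size().values,
    })
    return out


def fit_psychometric(aggregated: pd.DataFrame, *, n_restarts: int = 5,
                     bounds=DEFAULT_BOUNDS, seed: int = 0) -> PsychFitResult:
    """Binomial maximum-likelihood fit of the erf psychometric function.

    ``aggregated`` has columns signed_contrast, n_right, n_total.  Multi-start
    L-BFGS-B from jittered initial points inside the box; the best restart is
    returned.
    """
    c = np.asarray(aggregated["signed_contrast"], dtype=float)
    k = np.asarray(aggregated["n_right"], dtype=float)
    n = np.asarray(aggregated["n_total"], dtype=float)
    if len(np.unique(c)) < 2:
        raise ValueError("need at least 2 distinct contrasts to fit")
    if np.any(n < 1):
        raise ValueError("every contrast needs n_total >= 1")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("n_right must lie in [0, n_total]")

    frac = k.sum() / n.sum()
    base = np.array([0.05, 0.05, float(np.clip((0.5 - frac) * 50.0, -50, 50)), 15.0])
    rng = np.random.default_rng(seed)

    best = None
    n_used = 0
    for i in range(max(1, n_restarts)):
        theta0 = base if i == 0 else np.array([
            rng.uniform(0.0, 0.3), rng.uniform(0.0, 0.3),
            rng.uniform(-40.0, 40.0), rng.uniform(2.0, 60.0)])
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_nll, theta0, args=(c, k, n), method="L-BFGS-B", bounds=bounds)
        n_used += 1
        # jittered restarts must beat the incumbent by more than noise, so
        # that flat (under-determined) likelihoods keep the canonical start
        if best is None or res.fun < best.fun - 1e-6:
            best = res

    gamma, lam, mu, sigma = best.x
    # keep the invariant gamma + lambda < 1 even on a degenerate boundary fit
    if gamma + lam >= 1.0:
        scale = (1.0 - 1e-6) / (gamma + lam)
        gamma, lam = gamma * scale, lam * scale
    on_boundary = any(
        np.isclose(v, b[0]) or np.isclose(v, b[1])
        for v, b in zip(best.x, bounds))
    params = PsychometricParams(float(gamma), float(lam), float(mu), float(sigma))
    return PsychFitResult(params=params, nll=float(best.fun),
                          n_trials=int(n.sum()), converged=bool(best.success),
                          n_restarts_used=n_used, boundary=on_boundary)


def fit_psychometric_trials(trials: pd.DataFrame, **kwargs) -> PsychFitResult:
    """Convenience: aggregate a trials table, then fit."""
    return fit_psychometric(aggregate_trials(trials), **kwargs)


def bias_shift(frac_right_2080: pd.Series, frac_right_8020: pd.Series) -> pd.Series:
    """Per-contrast shift in rightward-choice fraction between block types.

    shift(c) = f_right^{20:80}(c) - f_right^{80:20}(c), in percentage points.
    Inputs are Series indexed by signed contrast on identical grids.
    """
    a = frac_right_2080.sort_index()
    b = frac_right_8020.sort_index()
    if not np.array_equal(a.index.values, b.index.values):
        raise ValueError("contrast grids of the two block types differ")
    return (a - b) * 100.0
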