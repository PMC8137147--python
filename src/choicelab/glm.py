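"""Trial-history logistic choice model.

The probability of a rightward choice is logistic(z) with

    z(i) = sum_c W_c I_c(i) + W_r r(i-1) + W_u u(i-1) + W_0  [+ W_b b(i)]

I_c is a signed indicator (+1 stimulus of contrast c on the right, -1 on the
left) for c in {6.25, 12.5, 25, 50, 100}; r / u encode the previous trial's
choice split by outcome (rewarded / unrewarded); b is the block label of the
full task (+1 in 20:80 blocks, -1 in 80:20, 0 unbiased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GLM_CONTRASTS",
    "GlmFit",
    "build_design",
    "fit_choice_glm",
    "glm_condition_number",
    "glm_predictive_accuracy",
    "glm_posterior_curves",
]

#: Contrast magnitudes with their own weight (0% is deliberately excluded).
GLM_CONTRASTS = (6.25, 12.5, 25.0, 50.0, 100.0)

_SESSION_KEYS = ["lab_id", "mouse_id", "session_day"]


@dataclass
class GlmFit:
    weights: pd.Series  # indexed by column name
    covariance: np.ndarray  # inverse Hessian of the unpenalized NLL at the optimum
    nll: float
    condition_number: float
    n_trials: int
    variant: str

    @property
    def names(self) -> list:
        return list(self.weights.index)


def _history_codes(choice: np.ndarray, correct: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r(i-1), u(i-1) for trials 1.. within one session; index 0 gets 0, 0."""
    r = np.zeros(len(choice))
    u = np.zeros(len(choice))
    prev_choice = choice[:-1]
    prev_correct = correct[:-1].astype(bool)
    responded = prev_choice != 0
    r[1:] = np.where(prev_correct & responded, prev_choice, 0.0)
    u[1:] = np.where(~prev_correct & responded, prev_choice, 0.0)
    return r, u


def build_design(trials: pd.DataFrame, variant: str = "basic"
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the design matrix and rightward-response vector.

    History never crosses a session boundary: the first trial of each session
    gets r = u = 0.  No-response trials (choice 0) are dropped as responses
    but still shape their successor's history codes (as unrewarded with no
    side, hence 0).
    """
    if variant not in ("basic", "full"):
        raise ValueError(f"unknown variant {variant!r}")
    mags = np.abs(trials["signed_contrast"].to_numpy(dtype=float))
    known = np.isin(mags, np.array((0.0,) + GLM_CONTRASTS))
    if not known.all():
        bad = sorted(set(mags[~known]))
        raise ValueError(f"unknown contrast magnitude(s) in trials: {bad}")

    keys = [k for k in _SESSION_KEYS if k in trials.columns]
    parts_r, parts_u = [], []
    if keys:
        for _, grp in trials.groupby(keys, sort=False):
            r, u = _history_codes(grp["choice"].to_numpy(dtype=float),
                                  grp["correct"].to_numpy())
            parts_r.append(pd.Series(r, index=grp.index))
            parts_u.append(pd.Series(u, index=grp.index))
        r = pd.concat(parts_r).reindex(trials.index).to_numpy()
        u = pd.concat(parts_u).reindex(trials.index).to_numpy()
    else:
        r, u = _history_codes(trials["choice"].to_numpy(dtype=float),
                              trials["correct"].to_numpy())

    c = trials["signed_contrast"].to_numpy(dtype=float)
    X = pd.DataFrame(index=trials.index)
    for m in GLM_CONTRASTS:
        X[f"c_{m:g}"] = np.where(np.abs(c) == m, np.sign(c), 0.0)
    X["prev_rewarded"] = r
    X["prev_unrewarded"] = u
    if variant == "full":
        p_left = trials["block_p_left"].to_numpy(dtype=float)
        X["block"] = np.where(p_left == 0.2, 1.0,
                              np.where(p_left == 0.8, -1.0, 0.0))
    X["intercept"] = 1.0

    responded = trials["choice"].to_numpy() != 0
    y = (trials["choice"].to_numpy() == 1).astype(float)
    return X.loc[responded], y[responded]


def glm_condition_number(design: pd.DataFrame) -> float:
    """2-norm condition number (largest / smallest singular value)."""
    X = np.asarray(design, dtype=float)
    if X.size == 0:
        raise ValueError("empty design")
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= s[0] * 1e-12 or not np.isfinite(s[-1]):
        warnings.warn("rank-deficient design; condition number is infinite")
        return np.inf
    return float(s[0] / s[-1])


def fit_choice_glm(design: pd.DataFrame, response: np.ndarray,
                   penalty_strength: float = 1e-4,
                   variant: Optional[str] = None) -> GlmFit:
    """Penalized maximum-likelihood fit of the logistic choice model.

    Maximizes the Bernoulli log-likelihood minus an L1 penalty of
    ``penalty_strength * n_trials * sum|W|`` (small by default, as a guard
    against separability).  The covariance is the inverse Hessian of the
    *unpenalized* negative log-likelihood at the optimum.
    """
    X = design.astype(float)
    y = np.asarray(response, dtype=float)
    zero_cols = [c for c in X.columns if (X[c] == 0).all()]
    if zero_cols:
        raise ValueError(f"design column(s) identically zero: {zero_cols}")

    n = len(y)
    alpha = penalty_strength * n
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(method="l1", alpha=alpha, disp=0,
                                    trim_mode="off", maxiter=500)
    w = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(w)) or np.abs(w).max() > 50:
        raise RuntimeError("divergent fit (separable data with near-zero penalty?)")

    p = 1.0 / (1.0 + np.exp(-(X.to_numpy() @ w)))
    eps = 1e-12
    nll = float(-np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    H = X.to_numpy().T @ (X.to_numpy() * (p * (1 - p))[:, None])
    cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2.0

    return GlmFit(weights=pd.Series(w, index=list(X.columns)),
                  covariance=cov, nll=nll,
                  condition_number=glm_condition_number(X),
                  n_trials=n,
                  variant=variant or ("full" if "block" in X.columns else "basic"))


def glm_predictive_accuracy(design: pd.DataFrame, response: np.ndarray, *,
                            k: int = 5, penalty_strength: float = 1e-4,
                            in_sample: bool = False) -> float:
    """Fraction of choices predicted correctly (p >= 0.5 rule).

    Default: k-fold cross-validation over contiguous blocks of trials
    (respecting trial order); ``in_sample=True`` fits once on everything.
    """
    X = design.astype(float)
    y = np.asarray(response, dtype=float)
    if in_sample:
        fit = fit_choice_glm(X, y, penalty_strength)
        p = 1.0 / (1.0 + np.exp(-(X.to_numpy() @ fit.weights.to_numpy())))
        return float(np.mean((p >= 0.5) == (y == 1)))
    n = len(y)
    folds = np.array_split(np.arange(n), k)
    correct = 0
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        fit = fit_choice_glm(X.iloc[train], y[train], penalty_strength)
        p = 1.0 / (1.0 + np.exp(-(X.iloc[fold].to_numpy() @ fit.weights.to_numpy())))
        correct += int(np.sum((p >= 0.5) == (y[fold] == 1)))
    return correct / n


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def glm_posterior_curves(fit: GlmFit, design: pd.DataFrame,
                         signed_contrast: np.ndarray, *,
                         n_samples: int = 10_000,
                         rng: Optional[np.random.Generator] = None
                         ) -> pd.DataFrame:
    """Laplace-approximation bands on per-contrast predicted choice fractions.

    Draws weight vectors from N(W-hat, covariance); for each draw computes the
    model's mean rightward-choice probability at every signed contrast in the
    data; returns the point prediction and pointwise 2.5% / 97.5% quantiles.
    """
    rng = rng if rng is not None else np.random.default_rng()
    cov = fit.covariance
    vals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if vals.min() < -1e-10:
        warnings.warn("covariance not PSD; projecting to the nearest PSD matrix")
        cov = _nearest_psd(cov)
    W = rng.multivariate_normal(fit.weights.to_numpy(), cov, size=n_samples,
                                method="eigh")
    X = design.to_numpy(dtype=float)
    c = np.asarray(signed_contrast, dtype=float)
    grid = np.unique(c)

    point_p = 1.0 / (1.0 + np.exp(-(X @ fit.weights.to_numpy())))
    rows = []
    for cc in grid:
        mask = c == cc
        P = 1.0 / (1.0 + np.exp(-(X[mask] @ W.T)))  # (n_cc, n_samples)
        frac = P.mean(axis=0)
        rows.append({
            "signed_contrast": cc,
            "point": float(point_p[mask].mean()),
            "lo": float(np.quantile(frac, 0.025)),
            "hi": float(np.quantile(frac, 0.975)),
        })
    return pd.DataFrame(rows)
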