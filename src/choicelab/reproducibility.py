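"""Cross-laboratory reproducibility assessment.

Per-mouse featurization from proficiency sessions, the subsample / leave-one-
out / shuffle-null lab-membership classification procedure, cross-lab
statistical tests with Benjamini-Hochberg FDR control, and the slow-learner
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from statsmodels.stats.multitest import multipletests

from .psychometrics import fit_psychometric_trials

__all__ = [
    "ClassificationReport",
    "featurize_mice",
    "classify_labs",
    "compare_labs_tests",
    "predict_slow_learners",
]

BASIC_FEATURES = ["perf_easy", "threshold", "bias"]
FULL_FEATURES = ["threshold_2080", "lapse_left_2080", "lapse_right_2080",
                 "bias_2080", "threshold_8020", "lapse_left_8020",
                 "lapse_right_8020", "bias_8020"]


@dataclass
class ClassificationReport:
    accuracies: np.ndarray  # one per subsample repeat
    null_accuracies: Optional[np.ndarray]
    confusion_matrix: pd.DataFrame  # rows = true lab (normalized), cols = predicted
    classifier_name: str
    mode: str

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def _mouse_sessions(cohort, mouse_id: str, days: list) -> pd.DataFrame:
    t = cohort.trials
    return t[(t["mouse_id"] == mouse_id) & (t["session_day"].isin(days))]


def featurize_mice(cohort, variant: str = "basic") -> pd.DataFrame:
    """One feature row per mouse, pooled over its three proficiency sessions.

    basic: easy-trial performance, contrast threshold, bias.
    full:  threshold, left/right lapse, bias — separately per block type.
    Mice lacking the required proficiency sessions are excluded.
    """
    rows = []
    for mouse_id in cohort.mouse_ids:
        st = cohort.statuses[mouse_id]
        lab_id = cohort.ground_truth[mouse_id]["lab_id"]
        tz = next(l.timezone_group for l in cohort.labs if l.lab_id == lab_id)
        if variant == "basic":
            days = st.get("proficiency_days") or []
            if not days:
                continue
            pooled = _mouse_sessions(cohort, mouse_id, days)
            if len(pooled) == 0:
                continue
            easy = np.abs(pooled["signed_contrast"]) >= 50.0
            fit = fit_psychometric_trials(pooled).params
            rows.append({
                "lab_id": lab_id, "mouse_id": mouse_id, "timezone_group": tz,
                "perf_easy": float(pooled.loc[easy, "correct"].mean()),
                "threshold": fit.sigma, "bias": fit.mu,
            })
        elif variant == "full":
            days = st.get("full_days") or []
            if not days:
                continue
            pooled = _mouse_sessions(cohort, mouse_id, days)
            if len(pooled) == 0:
                continue
            row = {"lab_id": lab_id, "mouse_id": mouse_id, "timezone_group": tz}
            for label, p_left in (("2080", 0.2), ("8020", 0.8)):
                blk = pooled[pooled["block_p_left"] == p_left]
                fit = fit_psychometric_trials(blk).params
                row[f"threshold_{label}"] = fit.sigma
                row[f"lapse_left_{label}"] = fit.gamma
                row[f"lapse_right_{label}"] = fit.lambda_
                row[f"bias_{label}"] = fit.mu
            rows.append(row)
        else:
            raise ValueError(f"unknown variant {variant!r}")
    return pd.DataFrame(rows)


_CLASSIFIERS = {
    "naive_bayes": lambda seed: GaussianNB(),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "logistic": lambda seed: LogisticRegression(max_iter=1000),
}


def _loo_accuracy(X: np.ndarray, y: np.ndarray, make_clf, seed: int,
                  standardize: bool, n_labs: int,
                  label_index: dict) -> tuple[float, np.ndarray]:
    n = len(y)
    confusion = np.zeros((n_labs, n_labs))
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte = X[mask], X[i:i + 1]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = make_clf(seed)
        clf.fit(Xtr, y[mask])
        pred = clf.predict(Xte)[0]
        if pred == y[i]:
            correct += 1
        confusion[label_index[y[i]], label_index[pred]] += 1
    return correct / n, confusion


def classify_labs(features: pd.DataFrame, classifier: str = "naive_bayes", *,
                  n_per_lab: int = 8, n_repeats: int = 2000,
                  mode: str = "data",
                  rng: Optional[np.random.Generator] = None,
                  standardize: bool = True,
                  feature_columns: Optional[list] = None,
                  shuffle_before_subsample: bool = False
                  ) -> ClassificationReport:
    """Lab-membership classification with subsampling and LOO cross-validation.

    Per repeat: subsample ``n_per_lab`` mice per lab, run leave-one-out over
    the pooled subsample; accuracy = correctly classified / total.
    mode="shuffle" permutes lab labels (within the subsample by default)
    before classification; mode="positive_control" appends the
    timezone-group feature.
    """
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    if mode not in ("data", "shuffle", "positive_control"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()

    labs = sorted(features["lab_id"].unique())
    label_index = {lab: i for i, lab in enumerate(labs)}
    for lab in labs:
        n_lab = int((features["lab_id"] == lab).sum())
        if n_lab < n_per_lab:
            raise ValueError(f"lab {lab!r} has only {n_lab} mice "
                             f"(< n_per_lab = {n_per_lab})")

    cols = list(feature_columns) if feature_columns is not None else [
        c for c in features.columns
        if c not in ("lab_id", "mouse_id", "timezone_group")]
    if mode == "positive_control":
        tz_codes = features["timezone_group"].astype("category").cat.codes
        features = features.assign(_tz=tz_codes.astype(float))
        cols = cols + ["_tz"]

    by_lab = {lab: features.index[features["lab_id"] == lab].to_numpy()
              for lab in labs}
    accuracies = np.empty(n_repeats)
    confusion = np.zeros((len(labs), len(labs)))
    make_clf = _CLASSIFIERS[classifier]

    for rep in range(n_repeats):
        idx = np.concatenate([
            rng.choice(by_lab[lab], size=n_per_lab, replace=False)
            for lab in labs])
        sub = features.loc[idx]
        y = sub["lab_id"].to_numpy().copy()
        if mode == "shuffle":
            if shuffle_before_subsample:
                # permute labels over the whole table, then re-read them
                perm = rng.permutation(len(features))
                relab = dict(zip(features["mouse_id"],
                                 features["lab_id"].to_numpy()[perm]))
                y = np.array([relab[m] for m in sub["mouse_id"]])
            else:
                y = rng.permutation(y)
        X = sub[cols].to_numpy(dtype=float)
        seed = int(rng.integers(2 ** 31 - 1))
        acc, conf = _loo_accuracy(X, y, make_clf, seed, standardize,
                                  len(labs), label_index)
        accuracies[rep] = acc
        confusion += conf

    row_sums = confusion.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    cm = pd.DataFrame(confusion / row_sums, index=labs, columns=labs)
    return ClassificationReport(accuracies=accuracies, null_accuracies=None,
                                confusion_matrix=cm,
                                classifier_name=classifier, mode=mode)


def compare_labs_tests(metrics_by_lab: dict, *,
                       paired_metrics: Optional[dict] = None) -> pd.DataFrame:
    """Cross-lab statistical tests with Benjamini-Hochberg FDR adjustment.

    ``metrics_by_lab`` maps metric name -> {lab_id: 1-D array of per-mouse
    values}.  For each metric: Kruskal-Wallis (medians), Brown-Forsythe
    Levene (variances), one-way ANOVA (means).  ``paired_metrics`` maps
    metric name -> (values_a, values_b) for Wilcoxon signed-rank tests on
    paired block-wise measures.  BH adjustment is applied within each test
    family.
    """
    if not metrics_by_lab and not paired_metrics:
        raise ValueError("no metrics supplied")
    rows = []
    for metric, groups in metrics_by_lab.items():
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
        if len(arrays) < 2:
            raise ValueError(f"metric {metric!r}: need >= 2 labs")
        if any(len(a) < 2 for a in arrays):
            raise ValueError(f"metric {metric!r}: need >= 2 values per lab")
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):  # degenerate: identical constants
            kw = lev = an = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            kw = stats.kruskal(*arrays)
            lev = stats.levene(*arrays, center="median")
            an = stats.f_oneway(*arrays)
        rows += [
            {"metric": metric, "test": "kruskal_wallis",
             "statistic": float(kw.statistic), "p": float(kw.pvalue)},
            {"metric": metric, "test": "levene",
             "statistic": float(lev.statistic), "p": float(lev.pvalue)},
            {"metric": metric, "test": "anova",
             "statistic": float(an.statistic), "p": float(an.pvalue)},
        ]
    for metric, (a, b) in (paired_metrics or {}).items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.allclose(a, b):
            rows.append({"metric": metric, "test": "wilcoxon",
                         "statistic": 0.0, "p": 1.0})
        else:
            w = stats.wilcoxon(a, b)
            rows.append({"metric": metric, "test": "wilcoxon",
                         "statistic": float(w.statistic), "p": float(w.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for test in out["test"].unique():
        mask = out["test"] == test
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def predict_slow_learners(perf_changes: pd.DataFrame,
                          days_to_proficiency: pd.Series,
                          rng: Optional[np.random.Generator] = None, *,
                          n_splits: int = 5) -> dict:
    """Predict bottom-quartile (slowest) learners from early performance.

    ``perf_changes``: one row per mouse, columns = session-to-session changes
    in easy-trial performance over the first five sessions.
    ``days_to_proficiency``: aligned Series; its top quartile of values (the
    slowest mice) defines the positive class.  Random-Forest classification
    under stratified-ish contiguous CV; reports the bottom-quartile accuracy
    (chance = 25% base rate) and the fast-as-slow misclassification rate.
    """
    rng = rng if rng is not None else np.random.default_rng()
    X = perf_changes.to_numpy(dtype=float)
    d = np.asarray(days_to_proficiency, dtype=float)
    n = len(d)
    if n < 8 or X.shape[0] != n:
        raise ValueError("need >= 8 mice with aligned features and labels")

    order = np.argsort(np.argsort(d))  # ranks: larger = slower
    quartile = np.minimum(order * 4 // n, 3)
    if min(np.bincount(quartile, minlength=4)) < 1 or n < 16:
        if n < 16:
            raise ValueError("need >= 4 mice per quartile (n >= 16)")
    slow = (quartile == 3).astype(int)  # slowest quartile
    fast = quartile == 0

    pred = np.zeros(n, dtype=int)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_splits)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        clf = RandomForestClassifier(random_state=int(rng.integers(2 ** 31 - 1)))
        clf.fit(X[train], slow[train])
        pred[fold] = clf.predict(X[fold])

    slow_mask = slow == 1
    slow_accuracy = float(pred[slow_mask].mean()) if slow_mask.any() else np.nan
    fast_as_slow = float(pred[fast].mean()) if fast.any() else np.nan
    return {
        "slow_quartile_accuracy": slow_accuracy,
        "fast_misclassified_as_slow": fast_as_slow,
        "chance": 0.25,
        "quartiles": quartile,
        "predictions": pred,
    }
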