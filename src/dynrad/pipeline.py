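"""Model building and evaluation: label dichotomization, z-scoring,
correlation-clustering feature reduction, ADASYN oversampling, three
classifiers (elastic-net logistic regression, random forest, XGBoost) tuned
by Gaussian-process Bayesian search over repeated 5-fold cross-validated
cross-entropy, a 1000-bootstrap evaluation with out-of-bag validation, a
metric battery with percentile 95% CIs, one-sided Wilcoxon comparisons of
test-AUC distributions with multiplicity correction, Shapley-value feature
attribution, and the Spearman screen of features against TBR_mean.

Training and test subjects come from different synthetic centers; every
fitted transform (harmonization, z-score, reduction, oversampling, tuning)
depends on training subjects only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr, wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, balanced_accuracy_score, f1_score,
                             log_loss, precision_score, roc_auc_score)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .harmonization import apply_combat, fit_combat

__all__ = [
    "CLINICAL_COLUMNS",
    "CLINICAL_CATEGORICAL",
    "HYPERPARAMETER_SPACES",
    "MetricSet",
    "BootstrapResult",
    "PipelineSettings",
    "ExperimentResult",
    "dichotomize_labels",
    "zscore",
    "reduce_by_clustering",
    "adasyn_oversample",
    "sample_hyperparameters",
    "make_estimator",
    "tune_hyperparameters",
    "bootstrap_evaluate",
    "compute_metrics",
    "compare_auc_wilcoxon",
    "correct_pvalues",
    "shap_importance",
    "provenance_shares",
    "correlate_with_reference",
    "features_from_cohort",
    "resolve_feature_set",
    "run_experiment",
    "compare_feature_sets",
    "metrics_json",
]

log = logging.getLogger("dynrad")

PFS_THRESHOLD_DAYS = 183

CLINICAL_COLUMNS = ["age", "sex", "who_grade", "idh", "codeletion_1p19q",
                    "prior_resection", "mri_contrast_enhancement"]
# all clinical features but age enter unscaled (binary indicators; WHO grade
# as ordinal integer)
CLINICAL_CATEGORICAL = CLINICAL_COLUMNS[1:]

FEATURE_SET_NAMES = ("clinical", "tbr_mean", "clinical+tbr_mean",
                     "static", "dynamic", "static+dynamic")


# --------------------------------------------------------------------------
# Labels and feature transforms
# --------------------------------------------------------------------------

def dichotomize_labels(pfs_days) -> np.ndarray:
    """Progression within six months: 1 iff PFS < 183 days (183 itself is
    censored progression-free, label 0)."""
    pfs = np.asarray(pfs_days, dtype=float)
    if np.any(~np.isfinite(pfs)):
        raise ValueError("missing PFS values cannot be dichotomized")
    if np.any(pfs < 0):
        raise ValueError("PFS days must be non-negative")
    return (pfs < PFS_THRESHOLD_DAYS).astype(int)


def zscore(train: pd.DataFrame, apply_to: pd.DataFrame | None = None,
           columns=None):
    """Z-score normalization fitted on the training table (population SD).

    Returns ``(train_t, apply_t, params)``; ``apply_t`` is None when no
    table to transform is given.  Zero-variance columns map to constant 0
    (logged).
    """
    columns = list(columns) if columns is not None else list(train.columns)
    mu = train[columns].mean()
    sd = train[columns].std(ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        log.warning("zscore: zero-variance columns set to 0: %s", flat)
    sd = sd.replace(0.0, 1.0)

    def _t(df):
        out = df.copy()
        out[columns] = (df[columns] - mu) / sd
        return out

    return _t(train), (_t(apply_to) if apply_to is not None else None), \
        {"mean": mu, "sd": sd}


def reduce_by_clustering(train: pd.DataFrame, threshold: float = 0.9,
                         linkage_method: str = "complete") -> list:
    """Hierarchical-clustering feature reduction on |Spearman| correlation.

    Distance is ``1 - |SCC|``; complete linkage cut at ``1 - threshold`` so
    merged clusters only contain pairs with |SCC| >= threshold.  One
    representative is kept per cluster: the feature with the highest mean
    |SCC| to its co-members (first in column order on ties); singletons keep
    themselves.  Constant features yield undefined correlations and are
    isolated into singleton clusters.
    """
    cols = list(train.columns)
    if len(cols) < 2:
        return cols
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = spearmanr(train.to_numpy(), axis=0)[0]
    rho = np.atleast_2d(rho)
    a = np.abs(rho)
    np.fill_diagonal(a, 1.0)
    a = np.where(np.isfinite(a), a, 0.0)  # constant feature -> no similarity
    dist = 1.0 - a
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")

    kept = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if len(members) == 1:
            kept.append(members[0])
            continue
        sub = a[np.ix_(members, members)]
        mean_sim = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        kept.append(members[int(np.argmax(mean_sim))])
    kept = sorted(kept)
    return [cols[i] for i in kept]


def adasyn_oversample(X, y, seed, k: int = 5, balance_tol: float = 0.0):
    """Adaptive synthetic oversampling of the minority class.

    Generation counts per minority sample are proportional to the fraction
    of majority neighbours among its k nearest neighbours (the adaptive
    density criterion); synthetic samples are drawn uniformly along segments
    to minority-class nearest neighbours.  The total generated count exactly
    balances the classes; original rows are preserved and come first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ADASYN requires both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    G = int(n_maj - n_min)
    if G == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    if n_min < k + 1:
        k = max(1, int(n_min) - 1)
        log.warning("ADASYN: minority class smaller than k+1, using k=%d", k)

    # adaptive weights: majority share of each minority point's k-NN
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn_all.kneighbors(Xmin)
    neigh_labels = y[idx[:, 1:]]
    r = (neigh_labels != minority).mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)  # isolated minority: spread generation uniformly
    r = r / r.sum()

    # largest-remainder allocation of exactly G synthetic samples
    raw = r * G
    g = np.floor(raw).astype(int)
    short = G - g.sum()
    if short > 0:
        order = np.argsort(-(raw - g), kind="stable")
        g[order[:short]] += 1

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(Xmin))).fit(Xmin)
    _, min_idx = nn_min.kneighbors(Xmin)
    synths = []
    for i, gi in enumerate(g):
        if gi == 0:
            continue
        choices = min_idx[i, 1:] if min_idx.shape[1] > 1 else min_idx[i, :1]
        picks = rng.choice(choices, size=gi)
        lam = rng.random((gi, 1))
        synths.append(Xmin[i] + lam * (Xmin[picks] - Xmin[i]))
    X_new = np.vstack([X] + synths) if synths else X.copy()
    y_new = np.concatenate([y, np.full(G, minority)])
    return X_new, y_new


# --------------------------------------------------------------------------
# Hyperparameter spaces and estimators
# --------------------------------------------------------------------------

# (low, high, prior, type) per parameter; priors: "uniform" | "log-uniform".
HYPERPARAMETER_SPACES = {
    "elasticnet_lr": {
        "l1_ratio": (0.0, 1.0, "uniform", float),
        "C": (0.001, 1000.0, "log-uniform", float),
    },
    "random_forest": {
        "n_estimators": (50, 1000, "uniform", int),
        "max_features": (0.001, 1.0, "uniform", float),
        "max_depth": (1, 20, "uniform", int),
        "min_samples_leaf": (0.001, 0.5, "uniform", float),
    },
    "xgboost": {
        "n_estimators": (50, 1000, "uniform", int),
        "max_depth": (1, 10, "uniform", int),
        "min_child_weight": (1.0, 10.0, "uniform", float),
        "max_delta_step": (0.0, 20.0, "uniform", float),
        "learning_rate": (0.001, 1.0, "log-uniform", float),
        "gamma": (1e-9, 0.5, "log-uniform", float),
        "subsample": (0.01, 1.0, "uniform", float),
        "colsample_bytree": (0.01, 1.0, "uniform", float),
        "colsample_bylevel": (0.01, 1.0, "uniform", float),
        "reg_alpha": (1e-9, 1.0, "log-uniform", float),
        "reg_lambda": (1e-9, 1e3, "log-uniform", float),
        "scale_pos_weight": (1e-6, 500.0, "log-uniform", float),
    },
}

ALGORITHMS = tuple(HYPERPARAMETER_SPACES)


def _space_items(algorithm):
    try:
        return list(HYPERPARAMETER_SPACES[algorithm].items())
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}") from None


def _unit_to_params(algorithm, u) -> dict:
    params = {}
    for (name, (lo, hi, prior, typ)), x in zip(_space_items(algorithm), u):
        x = float(np.clip(x, 0.0, 1.0))
        if prior == "log-uniform":
            v = np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo)))
        else:
            v = lo + x * (hi - lo)
        params[name] = int(round(v)) if typ is int else float(v)
    return params


def sample_hyperparameters(algorithm, rng) -> dict:
    """One draw from the declared search space (always inside its bounds)."""
    return _unit_to_params(algorithm, rng.random(len(_space_items(algorithm))))


def make_estimator(algorithm, params, seed):
    seed = int(seed) % (2 ** 31)
    if algorithm == "elasticnet_lr":
        return LogisticRegression(
            solver="saga", max_iter=3000, tol=1e-3,
            l1_ratio=params["l1_ratio"], C=params["C"], random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params["n_estimators"]),
            max_features=max(params["max_features"], 1e-3),
            max_depth=int(params["max_depth"]),
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed, n_jobs=1)
    if algorithm == "xgboost":
        return xgb.XGBClassifier(
            n_estimators=int(params["n_estimators"]),
            max_depth=int(params["max_depth"]),
            min_child_weight=params["min_child_weight"],
            max_delta_step=params["max_delta_step"],
            learning_rate=params["learning_rate"],
            gamma=params["gamma"], subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"],
            colsample_bylevel=params["colsample_bylevel"],
            reg_alpha=params["reg_alpha"], reg_lambda=params["reg_lambda"],
            scale_pos_weight=params["scale_pos_weight"],
            eval_metric="logloss", tree_method="hist", n_jobs=1,
            random_state=seed, verbosity=0)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# --------------------------------------------------------------------------
# Bayesian hyperparameter tuning (GP + expected improvement)
# --------------------------------------------------------------------------

def _cv_cross_entropy(algorithm, params, X, y, folds, repeats, seed,
                      use_adasyn=True, adasyn_k=5):
    """Mean validation cross-entropy over repeated stratified k-fold CV,
    with ADASYN applied inside each training fold."""
    rkf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                  random_state=int(seed) % (2 ** 31))
    losses = []
    for fold_i, (tr, va) in enumerate(rkf.split(X, y)):
        Xt, yt = X[tr], y[tr]
        if use_adasyn and len(np.unique(yt)) == 2:
            Xt, yt = adasyn_oversample(Xt, yt, seed=seed * 1000 + fold_i,
                                       k=adasyn_k)
        est = make_estimator(algorithm, params, seed=seed * 77 + fold_i)
        est.fit(Xt, yt)
        proba = est.predict_proba(X[va])[:, 1]
        losses.append(log_loss(y[va], proba, labels=[0, 1]))
    return float(np.mean(losses))


def _expected_improvement(mu, sigma, best):
    from scipy.stats import norm
    sigma = np.clip(sigma, 1e-12, None)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def tune_hyperparameters(algorithm, X, y, seed, budget: int = 300,
                         cv_folds: int = 5, cv_repeats: int = 20,
                         n_initial: int = 10, use_adasyn: bool = True,
                         adasyn_k: int = 5):
    """Gaussian-process Bayesian search minimizing CV cross-entropy.

    ``budget`` evaluations total (first ``n_initial`` random, then expected
    improvement over a GP surrogate on the unit cube).  Returns
    ``(best_params, best_loss, history)``; deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    dim = len(_space_items(algorithm))
    n_initial = min(n_initial, budget)

    pts, losses = [], []

    def evaluate(u):
        params = _unit_to_params(algorithm, u)
        loss = _cv_cross_entropy(algorithm, params, X, y, cv_folds,
                                 cv_repeats, seed=int(rng.integers(2 ** 31)),
                                 use_adasyn=use_adasyn, adasyn_k=adasyn_k)
        if not np.isfinite(loss):
            worst = max((l for l in losses if np.isfinite(l)), default=10.0)
            log.warning("tuning: non-finite loss, assigning worst=%.3f", worst)
            loss = worst
        pts.append(np.asarray(u, dtype=float))
        losses.append(loss)

    for _ in range(n_initial):
        evaluate(rng.random(dim))

    while len(pts) < budget:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * \
            Matern(length_scale=np.full(dim, 0.3),
                   length_scale_bounds=(1e-2, 1e2), nu=2.5) + \
            WhiteKernel(1e-4, (1e-8, 1e1))
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=0)
        with warnings.catch_warnings():
            # hyperparameters at a length-scale bound are fine for an
            # acquisition surrogate
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(pts), np.asarray(losses))
        cand = rng.random((512, dim))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, np.min(losses))
        evaluate(cand[int(np.argmax(ei))])

    best = int(np.argmin(losses))
    history = [(_unit_to_params(algorithm, p), l)
               for p, l in zip(pts, losses)]
    return _unit_to_params(algorithm, pts[best]), float(losses[best]), history


# --------------------------------------------------------------------------
# Metrics and bootstrap evaluation
# --------------------------------------------------------------------------

@dataclass
class MetricSet:
    accuracy: float
    auc: float
    precision: float
    f1: float
    balanced_accuracy: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Metric battery at a fixed classification threshold.

    AUC is the rank statistic with tie correction; undefined precision
    (no positive prediction) is reported as 0 with a log flag.  Single-class
    label vectors leave the AUC undefined and raise.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (scores >= threshold).astype(int)
    if pred.sum() == 0:
        log.debug("compute_metrics: no positive predictions, precision=0")
    return MetricSet(
        accuracy=float(accuracy_score(labels, pred)),
        auc=float(roc_auc_score(labels, scores)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        balanced_accuracy=float(balanced_accuracy_score(labels, pred)),
    )


METRIC_NAMES = ("accuracy", "auc", "precision", "f1", "balanced_accuracy")


@dataclass
class BootstrapResult:
    algorithm: str
    params: dict
    n_iterations: int
    metrics: dict          # split -> DataFrame (iterations x metrics)
    aggregated: dict       # split -> metric -> {mean, ci_low, ci_high}
    auc_distribution_test: np.ndarray
    test_predictions: np.ndarray  # (iterations, n_test)
    sampled_indices: list
    models: list = field(default_factory=list)

    def summary(self) -> dict:
        return {"algorithm": self.algorithm,
                "n_iterations": self.n_iterations,
                "metrics": self.aggregated}


def _aggregate(frame: pd.DataFrame) -> dict:
    out = {}
    for m in frame.columns:
        v = frame[m].to_numpy()
        out[m] = {"mean": round(float(np.mean(v)), 10),
                  "ci_low": round(float(np.percentile(v, 2.5)), 10),
                  "ci_high": round(float(np.percentile(v, 97.5)), 10)}
    return out


def bootstrap_evaluate(algorithm, params, X_train, y_train, X_test, y_test,
                       B: int = 1000, seed=0, use_adasyn: bool = True,
                       adasyn_k: int = 5, keep_models: int = 0) -> BootstrapResult:
    """Bootstrap model evaluation with out-of-bag validation.

    Each iteration resamples the training set with replacement (redrawn if
    single-class or if the out-of-bag complement is degenerate), re-applies
    ADASYN to the resample, fits with the fixed tuned hyperparameters, and
    scores the bootstrap sample, its out-of-bag complement and the test set.
    Aggregates are means with percentile 95% CIs; the test-AUC distribution
    is retained for model comparison.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    n = len(y_train)
    rng = np.random.default_rng(seed)
    rows = {"train": [], "oob": [], "test": []}
    aucs, preds, indices, models = [], [], [], []

    for b in range(B):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(np.unique(y_train[idx])) == 2 and oob.size > 0 and \
                    len(np.unique(y_train[oob])) == 2:
                break
        else:  # pragma: no cover - practically unreachable for n >= 10
            raise RuntimeError("could not draw a valid bootstrap resample")
        Xb, yb = X_train[idx], y_train[idx]
        if use_adasyn:
            Xb, yb = adasyn_oversample(Xb, yb, seed=int(rng.integers(2 ** 31)),
                                       k=adasyn_k)
        est = make_estimator(algorithm, params,
                             seed=int(rng.integers(2 ** 31)))
        est.fit(Xb, yb)
        p_boot = est.predict_proba(X_train[idx])[:, 1]
        p_oob = est.predict_proba(X_train[oob])[:, 1]
        p_test = est.predict_proba(X_test)[:, 1]
        rows["train"].append(compute_metrics(y_train[idx], p_boot).as_dict())
        rows["oob"].append(compute_metrics(y_train[oob], p_oob).as_dict())
        m_test = compute_metrics(y_test, p_test)
        rows["test"].append(m_test.as_dict())
        aucs.append(m_test.auc)
        preds.append(p_test)
        indices.append(idx)
        if len(models) < keep_models:
            models.append(est)

    metrics = {s: pd.DataFrame(r)[list(METRIC_NAMES)]
               for s, r in rows.items()}
    aggregated = {s: _aggregate(f) for s, f in metrics.items()}
    return BootstrapResult(
        algorithm=algorithm, params=dict(params), n_iterations=B,
        metrics=metrics, aggregated=aggregated,
        auc_distribution_test=np.asarray(aucs),
        test_predictions=np.asarray(preds), sampled_indices=indices,
        models=models)


# --------------------------------------------------------------------------
# Model comparison and attribution
# --------------------------------------------------------------------------

def compare_auc_wilcoxon(auc_a, auc_b, alternative: str = "greater") -> float:
    """One-sided paired signed-rank test that distribution A is superior."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired AUC vectors must have equal length")
    if np.allclose(a, b):
        log.warning("compare_auc_wilcoxon: identical distributions, p=1")
        return 1.0
    return float(wilcoxon(a, b, alternative=alternative,
                          zero_method="wilcox").pvalue)


def correct_pvalues(pvalues: dict, method: str = "fdr_bh") -> dict:
    """Multiplicity correction over a family of named comparisons
    (Benjamini-Hochberg by default; 'holm' available)."""
    keys = list(pvalues)
    if not keys:
        return {}
    _, corrected, _, _ = multipletests([pvalues[k] for k in keys],
                                       method=method)
    return dict(zip(keys, corrected.tolist()))


def _sampling_shapley(model, X, background, rng, n_permutations):
    """Monte-Carlo Shapley attribution of predict_proba for tabular models."""
    X = np.asarray(X, dtype=float)
    bg = np.asarray(background, dtype=float)
    n, p = X.shape
    contrib = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        base_rows = bg[rng.integers(0, len(bg), n)]
        z = base_rows.copy()
        prev = model.predict_proba(z)[:, 1]
        for j in order:
            z[:, j] = X[:, j]
            cur = model.predict_proba(z)[:, 1]
            contrib[:, j] += cur - prev
            prev = cur
    return contrib / n_permutations


def shap_importance(models, X_test: pd.DataFrame, algorithm: str, seed=0,
                    n_permutations: int = 16,
                    background: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean absolute Shapley attribution per feature over bootstrap models.

    Tree-exact path attributions for XGBoost; seeded Monte-Carlo permutation
    sampling otherwise.  Returns a frame with ``feature``,
    ``mean_abs_attribution`` and ``provenance`` (prefix before the first
    underscore) sorted by importance.
    """
    if not models:
        raise ValueError("no fitted models supplied")
    feats = list(X_test.columns)
    Xv = X_test.to_numpy(dtype=float)
    bg = (background if background is not None else X_test).to_numpy(float)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(feats))
    for model in models:
        n_model_feats = getattr(model, "n_features_in_", len(feats))
        if n_model_feats != len(feats):
            raise ValueError("feature count mismatch with training schema")
        if algorithm == "xgboost":
            dm = xgb.DMatrix(Xv)
            contrib = model.get_booster().predict(dm, pred_contribs=True)
            contrib = contrib[:, :-1]  # drop bias column
        else:
            contrib = _sampling_shapley(model, Xv, bg, rng, n_permutations)
        acc += np.abs(contrib).mean(axis=0)
    acc /= len(models)
    out = pd.DataFrame({
        "feature": feats,
        "mean_abs_attribution": acc,
        "provenance": [f.split("_", 1)[0] for f in feats],
    })
    return out.sort_values("mean_abs_attribution", ascending=False,
                           kind="stable").reset_index(drop=True)


def provenance_shares(importance: pd.DataFrame) -> pd.Series:
    """Share of total attribution mass per provenance (tbr / ttp / morph / ...)."""
    total = importance["mean_abs_attribution"].sum()
    if total == 0:
        return importance.groupby("provenance")["mean_abs_attribution"].sum()
    return importance.groupby("provenance")["mean_abs_attribution"].sum() / total


def correlate_with_reference(features: pd.DataFrame, reference) -> pd.DataFrame:
    """|Spearman| screen of every feature against the reference TBR_mean.

    Constant features have undefined rank correlation and are reported as
    missing.  Output is heatmap-ready: feature, provenance, family, rho,
    abs_rho.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) < 5:
        raise ValueError("need at least 5 subjects for a Spearman screen")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rho = np.nan
        else:
            rho = spearmanr(x, reference)[0]
        parts = col.split("_")
        provenance = parts[0]
        family = parts[1] if provenance in ("tbr", "ttp") and len(parts) > 1 \
            else provenance
        rows.append({"feature": col, "provenance": provenance,
                     "family": family, "rho": rho,
                     "abs_rho": abs(rho) if np.isfinite(rho) else np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# End-to-end experiment plumbing
# --------------------------------------------------------------------------

def features_from_cohort(cohort, lam=None) -> pd.DataFrame:
    """Run preprocessing + feature extraction for every cohort subject.

    Per subject: resample to 2 mm if needed, HYPR-LR denoise the dynamic
    series, compute the brain reference, build TBR and TTP parametric
    images, and extract 94+94 radiomic features (prefixes ``tbr_``/``ttp_``)
    plus 11 shared morphological features and the scalar ``tbr_mean``.
    """
    from . import preprocessing as pp
    from . import radiomics as rx

    rows = []
    for spec in cohort.subjects:
        sid = spec.subject_id
        dyn = pp.resample_isotropic(cohort.dynamic_images[sid])
        stat = pp.resample_isotropic(cohort.static_images[sid])
        tmask = pp.resample_isotropic(cohort.tumor_masks[sid])
        bmask = pp.resample_isotropic(cohort.brain_masks[sid])
        dyn = pp.hypr_lr_denoise(dyn)
        ref = pp.compute_brain_reference(stat, dyn, bmask)
        kwargs = {} if lam is None else {"lam": lam}
        tbr_img, tbr_mean = pp.make_tbr_image(stat, ref, tmask)
        ttp_img, valid = pp.make_ttp_image(dyn, ref, tmask, **kwargs)
        morph = rx.extract_morphology(valid)
        tbr_vec = rx.extract_feature_vector(tbr_img, valid)
        ttp_vec = rx.extract_feature_vector(ttp_img, valid)
        row = {"subject_id": sid, "center": spec.center,
               "batch_id": spec.batch_id, "pfs_days": spec.label_pfs_days,
               "tbr_mean": tbr_mean}
        row.update({k: float(v) for k, v in asdict(spec.clinical).items()})
        row.update(morph.to_dict())
        row.update({f"tbr_{k}": float(v) for k, v in tbr_vec.items()})
        row.update({f"ttp_{k}": float(v) for k, v in ttp_vec.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    table["label"] = dichotomize_labels(table["pfs_days"])
    return table


def resolve_feature_set(name: str, columns) -> list:
    """Resolve a named feature-set choice into concrete table columns."""
    columns = list(columns)
    morph = [c for c in columns if c.startswith("morph_")]
    static = [c for c in columns if c.startswith("tbr_") and c != "tbr_mean"]
    dynamic = [c for c in columns if c.startswith("ttp_")]
    mapping = {
        "clinical": CLINICAL_COLUMNS,
        "tbr_mean": ["tbr_mean"],
        "clinical+tbr_mean": CLINICAL_COLUMNS + ["tbr_mean"],
        "static": static + morph,
        "dynamic": dynamic + morph,
        "static+dynamic": static + dynamic + morph,
    }
    if name not in mapping:
        raise ValueError(f"unknown feature set {name!r}; "
                         f"choose from {FEATURE_SET_NAMES}")
    cols = mapping[name]
    missing = [c for c in cols if c not in columns]
    if missing:
        raise ValueError(f"feature set {name!r} missing columns {missing}")
    return cols


@dataclass
class PipelineSettings:
    """Desk-scale defaults; ``paper_scale()`` restores the full protocol
    (B=1000 bootstraps, 300 search iterations, 20 CV repeats)."""

    bootstraps: int = 100
    budget: int = 30
    cv_folds: int = 5
    cv_repeats: int = 3
    correlation_threshold: float = 0.9
    adasyn_k: int = 5
    use_adasyn: bool = True
    harmonize: bool = True
    reference_batch: str = "vereos"
    train_center: str = "A"
    keep_models: int = 0

    @classmethod
    def paper_scale(cls, **overrides) -> "PipelineSettings":
        base = dict(bootstraps=1000, budget=300, cv_repeats=20)
        base.update(overrides)
        return cls(**base)


@dataclass
class ExperimentResult:
    feature_set: str
    algorithm: str
    retained_features: list
    best_params: dict
    cv_loss: float
    bootstrap: BootstrapResult


def _harmonizable_columns(columns) -> list:
    return [c for c in columns
            if c == "tbr_mean" or c.startswith(("tbr_", "ttp_", "morph_"))]


def run_experiment(table: pd.DataFrame, feature_set: str, algorithm: str,
                   settings: PipelineSettings, seed) -> ExperimentResult:
    """Full train/test experiment for one feature set and one algorithm.

    Train subjects come from ``settings.train_center``, test subjects from
    the other center(s).  Image-derived features are ComBat-harmonized
    (label-free, anchored on the reference scanner), then z-scored,
    cluster-reduced and merged with categorical clinical indicators before
    tuning and bootstrap evaluation.  All label-aware transforms are fit on
    training data only.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    cols = resolve_feature_set(feature_set, table.columns)
    is_train = table["center"] == settings.train_center
    if is_train.all() or (~is_train).any() is False:
        raise ValueError("both a training and a test center are required")
    train = table[is_train].reset_index(drop=True)
    test = table[~is_train].reset_index(drop=True)

    harm_cols = _harmonizable_columns(cols)
    if settings.harmonize and harm_cols:
        # ComBat is label-free and per-scanner effects can only be estimated
        # from that scanner's own subjects, so it is fit on the full table
        # (anchored on the training-center reference scanner); all
        # label-aware transforms below remain fit on training data only.
        model = fit_combat(table[cols].loc[:, harm_cols], table["batch_id"],
                           reference_batch=settings.reference_batch)
        train = train.copy()
        test = test.copy()
        train[harm_cols] = apply_combat(model, train[harm_cols],
                                        train["batch_id"]).to_numpy()
        test[harm_cols] = apply_combat(model, test[harm_cols],
                                       test["batch_id"]).to_numpy()

    numeric = [c for c in cols if c not in CLINICAL_CATEGORICAL]
    categorical = [c for c in cols if c in CLINICAL_CATEGORICAL]
    train_t, test_t, _ = zscore(train, test, columns=numeric)
    retained = reduce_by_clustering(train_t[numeric],
                                    threshold=settings.correlation_threshold) \
        if len(numeric) > 1 else numeric
    final_cols = retained + categorical

    X_train = train_t[final_cols].to_numpy(dtype=float)
    X_test = test_t[final_cols].to_numpy(dtype=float)
    y_train = train["label"].to_numpy(dtype=int)
    y_test = test["label"].to_numpy(dtype=int)

    best_params, cv_loss, _ = tune_hyperparameters(
        algorithm, X_train, y_train, seed=seeds[0], budget=settings.budget,
        cv_folds=settings.cv_folds, cv_repeats=settings.cv_repeats,
        use_adasyn=settings.use_adasyn, adasyn_k=settings.adasyn_k)
    boot = bootstrap_evaluate(
        algorithm, best_params, X_train, y_train, X_test, y_test,
        B=settings.bootstraps, seed=seeds[1],
        use_adasyn=settings.use_adasyn, adasyn_k=settings.adasyn_k,
        keep_models=settings.keep_models)
    return ExperimentResult(feature_set=feature_set, algorithm=algorithm,
                            retained_features=final_cols,
                            best_params=best_params, cv_loss=cv_loss,
                            bootstrap=boot)


def compare_feature_sets(table: pd.DataFrame, feature_sets, algorithms,
                         settings: PipelineSettings, seed,
                         comparisons=None, correction: str = "fdr_bh"):
    """Run experiments for every (feature set, algorithm) pair and perform
    one-sided Wilcoxon superiority comparisons of the test-AUC
    distributions with multiplicity correction.

    ``comparisons``: iterable of ((set_a, algo_a), (set_b, algo_b)) pairs to
    test "A superior to B"; defaults to dynamic-vs-static and
    static+dynamic-vs-static within each algorithm where available.
    Returns ``(results, corrected_pvalues)``.
    """
    results = {}
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(feature_sets) * len(algorithms)))
    for fs in feature_sets:
        for algo in algorithms:
            s = int(next(child).generate_state(1)[0] % (2 ** 31))
            results[(fs, algo)] = run_experiment(table, fs, algo, settings, s)

    if comparisons is None:
        comparisons = []
        for algo in algorithms:
            for a, b in (("dynamic", "static"), ("static+dynamic", "static")):
                if (a, algo) in results and (b, algo) in results:
                    comparisons.append(((a, algo), (b, algo)))
    raw = {}
    for key_a, key_b in comparisons:
        name = f"{key_a[0]}|{key_a[1]}>{key_b[0]}|{key_b[1]}"
        raw[name] = compare_auc_wilcoxon(
            results[key_a].bootstrap.auc_distribution_test,
            results[key_b].bootstrap.auc_distribution_test)
    return results, correct_pvalues(raw, method=correction)


def metrics_json(results: dict) -> str:
    """Deterministic JSON of aggregated metrics for a results mapping
    ``(feature_set, algorithm) -> ExperimentResult``."""
    payload = {}
    for (fs, algo), res in sorted(results.items()):
        payload[f"{fs}|{algo}"] = {
            "best_params": {k: (round(v, 12) if isinstance(v, float) else v)
                            for k, v in sorted(res.best_params.items())},
            "cv_loss": round(res.cv_loss, 12),
            "metrics": res.bootstrap.aggregated,
        }
    return json.dumps(payload, sort_keys=True, indent=1)
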