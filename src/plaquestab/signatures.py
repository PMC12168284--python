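"""Penalized zero-sum log-contrast ("balance") signatures.

A microbial signature is a pair of signed taxon sets with coefficients that
sum to zero: the score Σ βₜ·log(relative abundance of t) is then a log
contrast — invariant to the total count of a sample — whose value best
predicts an outcome (turnover level, CD4 count, age, tooth position, sex).
Sparsity comes from an L1 penalty on CLR-transformed features (the CLR
geometry realizes the zero-sum constraint: adding a constant to all
coefficients leaves the score on CLR coordinates unchanged, so projecting
the selected coefficients to zero sum is without loss). The penalty is
chosen by cross-validation with a one-standard-error parsimony rule: the
minimum number of taxa with maximum predictive power.

Cross-validation folds are stratified by subject so repeated teeth from one
child never straddle folds; fold assignment is derived from sorted subject
ids, making the fit invariant to sample ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.metrics import roc_auc_score

import sklearn

from .composition import DEFAULT_PSEUDOCOUNT
from .tables import FeatureTable

_SKLEARN_NEW_PENALTY_API = tuple(
    int(x) for x in sklearn.__version__.split(".")[:2]
) >= (1, 8)


def _l1_logistic(c: float) -> LogisticRegression:
    kwargs = {"l1_ratio": 1.0} if _SKLEARN_NEW_PENALTY_API else {"penalty": "l1"}
    return LogisticRegression(
        C=c, solver="liblinear", max_iter=2000, random_state=0, **kwargs
    )


@dataclass
class BalanceSignature:
    """Signed taxon sets + coefficients defining a log-contrast score."""

    taxa: list[str]
    coefficients: np.ndarray  # zero-sum, aligned with taxa
    intercept: float
    mode: str  # "continuous" | "binary"
    cv_metric: float  # cross-validated Pearson R (continuous) or AUC (binary)
    apparent_metric: float  # same metric computed on all training samples
    cv_folds: int
    penalty: float
    seed: int | None
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    classes: tuple | None = None  # binary mode: (negative, positive) class

    @property
    def is_empty(self) -> bool:
        return len(self.taxa) == 0

    def positive_taxa(self) -> list[str]:
        return [t for t, c in zip(self.taxa, self.coefficients) if c > 0]

    def negative_taxa(self) -> list[str]:
        return [t for t, c in zip(self.taxa, self.coefficients) if c < 0]

    def to_json(self, path) -> None:
        payload = {
            "taxa": self.taxa,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "mode": self.mode,
            "cv_metric": None if np.isnan(self.cv_metric) else self.cv_metric,
            "apparent_metric": (
                None if np.isnan(self.apparent_metric) else self.apparent_metric
            ),
            "cv_folds": self.cv_folds,
            "penalty": self.penalty,
            "seed": self.seed,
            "pseudocount": self.pseudocount,
            "classes": list(self.classes) if self.classes else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SignaturePrediction:
    scores: pd.Series
    pearson_r: float | None = None
    p_value: float | None = None


def _log_relative_abundance(
    table: FeatureTable, pseudocount: float
) -> pd.DataFrame:
    shifted = table.data.to_numpy(dtype=float) + pseudocount
    rel = shifted / shifted.sum(axis=1, keepdims=True)
    return pd.DataFrame(np.log(rel), index=table.data.index, columns=table.data.columns)


def _subject_folds(subjects: np.ndarray, n_folds: int) -> np.ndarray:
    """Deterministic, order-invariant subject-grouped fold assignment."""
    uniq = sorted(set(subjects))
    fold_of = {s: i % n_folds for i, s in enumerate(uniq)}
    return np.array([fold_of[s] for s in subjects])


def fit_balance_signature(
    table: FeatureTable,
    outcome,
    mode: str = "continuous",
    lambda_path: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int | None = None,
    subject_ids=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BalanceSignature:
    """Fit a sparse zero-sum log-contrast predictor of ``outcome``.

    ``outcome`` aligns with the table's samples (Series by id or array in
    order). Continuous mode: lasso path with squared loss, metric Pearson R.
    Binary mode: L1 logistic path, metric AUC. In both, the one-SE rule
    prefers the sparsest model within one standard error of the best
    cross-validated score; a pure-noise outcome typically collapses to the
    empty signature.
    """
    y = (
        outcome.loc[table.data.index].to_numpy(dtype=float)
        if isinstance(outcome, pd.Series) and mode == "continuous"
        else np.asarray(
            outcome.loc[table.data.index] if isinstance(outcome, pd.Series) else outcome
        )
    )
    if len(y) != len(table.sample_ids):
        raise ValueError("outcome length does not match table")
    if len(y) < 20:
        raise ValueError("need outcome for at least 20 samples")
    if mode not in ("continuous", "binary"):
        raise ValueError(f"unknown mode {mode!r}")

    logrel = _log_relative_abundance(table, pseudocount)
    z = logrel.to_numpy() - logrel.to_numpy().mean(axis=1, keepdims=True)  # CLR
    taxa = list(table.data.columns)
    n, p = z.shape

    subjects = (
        np.asarray(list(subject_ids))
        if subject_ids is not None
        else np.asarray(table.sample_ids)
    )
    folds = _subject_folds(subjects, cv_folds)

    if mode == "continuous":
        y = y.astype(float)
        if np.ptp(y) == 0:
            raise ValueError("constant outcome")
        return _fit_continuous(
            z, y, taxa, folds, cv_folds, lambda_path, seed, pseudocount, logrel
        )
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary mode needs exactly 2 outcome classes, got {len(classes)}")
    return _fit_binary(
        z, y, classes, taxa, folds, cv_folds, lambda_path, seed, pseudocount, logrel
    )


def _finalize(
    beta: np.ndarray,
    taxa: list[str],
    logrel: pd.DataFrame,
    y,
    mode: str,
    cv_metric: float,
    cv_folds: int,
    penalty: float,
    seed,
    pseudocount: float,
    classes=None,
) -> BalanceSignature:
    support = np.flatnonzero(beta)
    if len(support) < 2:
        return BalanceSignature(
            [], np.array([]), float("nan"), mode, cv_metric, float("nan"),
            cv_folds, penalty, seed, pseudocount,
            tuple(classes) if classes is not None else None,
        )
    gamma = beta[support] - beta[support].mean()
    if np.allclose(gamma, 0):
        return BalanceSignature(
            [], np.array([]), float("nan"), mode, cv_metric, float("nan"),
            cv_folds, penalty, seed, pseudocount,
            tuple(classes) if classes is not None else None,
        )
    sel_taxa = [taxa[i] for i in support]
    scores = logrel.iloc[:, support].to_numpy() @ gamma
    if mode == "continuous":
        intercept = float(np.mean(y) - scores.mean())
        apparent = float(pearsonr(scores, np.asarray(y, float))[0])
    else:
        intercept = 0.0
        y_bin = (np.asarray(y) == classes[1]).astype(int)
        apparent = float(roc_auc_score(y_bin, scores))
    return BalanceSignature(
        sel_taxa, gamma, intercept, mode, cv_metric, apparent,
        cv_folds, penalty, seed, pseudocount,
        tuple(classes) if classes is not None else None,
    )


def _fit_continuous(z, y, taxa, folds, cv_folds, lambda_path, seed, pc, logrel):
    n = len(y)
    yc = y - y.mean()
    if lambda_path is None:
        amax = np.abs(z.T @ yc).max() / n
        lambda_path = amax * np.logspace(0, -2.5, 30)
    alphas = np.sort(np.asarray(lambda_path, float))[::-1]

    fold_mse = []
    oof = {a: np.full(n, np.nan) for a in range(len(alphas))}
    for f in sorted(set(folds)):
        tr, va = folds != f, folds == f
        if va.sum() == 0 or tr.sum() < 2:
            continue
        zm, ym = z[tr].mean(axis=0), y[tr].mean()
        _, coefs, _ = lasso_path(z[tr] - zm, y[tr] - ym, alphas=alphas)
        preds = (z[va] - zm) @ coefs + ym  # (n_va, n_alphas)
        fold_mse.append(((preds - y[va, None]) ** 2).mean(axis=0))
        for a in range(len(alphas)):
            oof[a][va] = preds[:, a]
    fold_mse = np.asarray(fold_mse)
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(fold_mse))
    best = int(np.argmin(mean_mse))
    within = np.where(mean_mse <= mean_mse[best] + se_mse[best])[0]
    chosen = int(within[0])  # alphas sorted descending: first = sparsest

    pred = oof[chosen]
    cv_metric = (
        float(pearsonr(pred[~np.isnan(pred)], y[~np.isnan(pred)])[0])
        if np.nanstd(pred) > 0
        else float("nan")
    )
    zc = z - z.mean(axis=0)
    _, coefs, _ = lasso_path(zc, y - y.mean(), alphas=alphas)
    beta = coefs[:, chosen]
    return _finalize(
        beta, taxa, logrel, y, "continuous", cv_metric,
        cv_folds, float(alphas[chosen]), seed, pc,
    )


def _fit_binary(z, y, classes, taxa, folds, cv_folds, lambda_path, seed, pc, logrel):
    n = len(y)
    y_bin = (y == classes[1]).astype(int)
    if lambda_path is None:
        lambda_path = np.logspace(-2.5, 1, 15)  # C grid (inverse penalty)
    cs = np.sort(np.asarray(lambda_path, float))  # ascending C = sparsest first

    aucs = np.full((cv_folds, len(cs)), np.nan)
    for f in sorted(set(folds)):
        tr, va = folds != f, folds == f
        if va.sum() == 0 or len(np.unique(y_bin[tr])) < 2 or len(np.unique(y_bin[va])) < 2:
            continue
        for ci, c in enumerate(cs):
            clf = _l1_logistic(c)
            clf.fit(z[tr], y_bin[tr])
            scores = clf.decision_function(z[va])
            aucs[f, ci] = roc_auc_score(y_bin[va], scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_auc = np.nanmean(aucs, axis=0)
        se_auc = np.nanstd(aucs, axis=0, ddof=1) / np.sqrt(
            np.maximum((~np.isnan(aucs)).sum(axis=0), 1)
        )
    best = int(np.nanargmax(mean_auc))
    within = np.where(mean_auc >= mean_auc[best] - se_auc[best])[0]
    chosen = int(within[0])  # smallest C = strongest penalty = sparsest

    clf = _l1_logistic(cs[chosen])
    clf.fit(z, y_bin)
    beta = clf.coef_.ravel()
    return _finalize(
        beta, taxa, logrel, y, "binary", float(mean_auc[chosen]),
        cv_folds, float(cs[chosen]), seed, pc, classes=classes,
    )


def predict_balance(
    signature: BalanceSignature, table: FeatureTable, outcome=None
) -> SignaturePrediction:
    """Balance score per sample; Pearson R and p against a known continuous
    outcome when provided. Taxa missing from the table are imputed at the
    pseudocount (i.e. treated as unobserved) with a warning."""
    logrel = _log_relative_abundance(table, signature.pseudocount)
    if signature.is_empty:
        scores = pd.Series(
            np.full(len(table.sample_ids), signature.intercept if np.isfinite(signature.intercept) else 0.0),
            index=table.data.index, name="balance_score",
        )
        return SignaturePrediction(scores)
    missing = [t for t in signature.taxa if t not in logrel.columns]
    if missing:
        warnings.warn(f"{len(missing)} signature taxa absent from table; imputed at pseudocount")
        # an absent taxon behaves like a zero count: log(pc / rowsum)
        shifted_tot = table.data.to_numpy(dtype=float).sum(axis=1) + signature.pseudocount * len(
            table.taxon_ids
        )
        for t in missing:
            logrel[t] = np.log(signature.pseudocount / shifted_tot)
    x = logrel[signature.taxa].to_numpy()
    scores = pd.Series(
        x @ signature.coefficients + signature.intercept,
        index=table.data.index,
        name="balance_score",
    )
    if outcome is not None and signature.mode == "continuous":
        y = (
            outcome.loc[table.data.index].to_numpy(dtype=float)
            if isinstance(outcome, pd.Series)
            else np.asarray(outcome, float)
        )
        r, p = pearsonr(scores.to_numpy(), y)
        return SignaturePrediction(scores, float(r), float(p))
    return SignaturePrediction(scores)


def signature_report(signature: BalanceSignature, top_k: int | None = None) -> pd.DataFrame:
    """Coefficient table ranked by |coefficient| within each sign group
    (ties broken lexicographically by taxon id)."""
    rows = [
        {"taxon": t, "coefficient": float(c), "side": "positive" if c > 0 else "negative"}
        for t, c in zip(signature.taxa, signature.coefficients)
    ]
    df = pd.DataFrame(rows, columns=["taxon", "coefficient", "side"])
    if df.empty:
        return df
    df["absc"] = df["coefficient"].abs()
    df = (
        df.sort_values(["side", "absc", "taxon"], ascending=[False, False, True])
        .drop(columns="absc")
        .reset_index(drop=True)
    )
    if top_k is not None:
        df = df.groupby("side", group_keys=False, sort=False).head(top_k).reset_index(drop=True)
    return df
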