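"""Phase-wise healthy-vs-tumor classification.

For each contrast phase, an L2-penalized logistic regression (C = 1,
matching scikit-learn defaults) is evaluated with leave-one-out cross
validation: every ROI is left out in turn, the classifier is trained on
the remaining ROIs, and the class probability of the held-out ROI is
predicted.  Out-of-fold probabilities are summarized as a ROC curve and
the Mann-Whitney AUC (ties counted 1/2), with a DeLong 95% confidence
interval by default (a patient-level bootstrap is available).

Features are not standardized by default; an optional within-fold
z-scaling flag exists because unscaled penalized regression on features
spanning many orders of magnitude can be numerically fragile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger("dceradiomics")

POSITIVE_LABEL = "tumor"


@dataclass
class ClassifierConfig:
    C: float = 1.0
    scale_features: bool = False
    ci_method: str = "delong"      # or "bootstrap"
    max_iter: int = 2000
    tol: float = 1e-6
    n_bootstrap: int = 1000
    bootstrap_seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.ci_method not in ("delong", "bootstrap"):
            raise ValueError("ci_method must be 'delong' or 'bootstrap'")


@dataclass
class PhaseAuc:
    phase: int
    auc: float
    ci_low: float
    ci_high: float
    probabilities: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_LABEL or l == 1 else 0 for l in labels])
    return y


def _impute_median(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaNs with the training-fold column median (0 if all-NaN)."""
    med = np.zeros(train.shape[1])
    has_data = np.isfinite(train).any(axis=0)
    med[has_data] = np.nanmedian(train[:, has_data], axis=0)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    return tr, te


def loo_probabilities(features: np.ndarray, labels, cfg: ClassifierConfig | None = None
                      ) -> np.ndarray:
    """Out-of-fold tumor-class probabilities under leave-one-out CV."""
    cfg = cfg or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 ROIs per class")
    n = len(y)
    probs = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, Xte = _impute_median(X[keep], X[[i]])
        if cfg.scale_features:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        # scikit-learn's default penalty is the L2 ridge used here
        clf = LogisticRegression(
            C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter, tol=cfg.tol,
        )
        clf.fit(Xtr, y[keep])
        probs[i] = clf.predict_proba(Xte)[0, list(clf.classes_).index(1)]
    return probs


def _mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    pos = scores[y == 1]
    neg = scores[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def _delong_se(scores: np.ndarray, y: np.ndarray, auc: float) -> float:
    """DeLong standard error of the AUC via placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc(probabilities, labels, cfg: ClassifierConfig | None = None,
            phase: int = 1) -> PhaseAuc:
    """AUC with 95% CI from out-of-fold probabilities."""
    cfg = cfg or ClassifierConfig()
    scores = np.asarray(probabilities, dtype=float)
    y = _binary_labels(labels)
    auc = _mann_whitney_auc(scores, y)
    if cfg.ci_method == "delong":
        se = _delong_se(scores, y, auc)
        z = sps.norm.ppf(0.975)
        lo, hi = auc - z * se, auc + z * se
    else:
        rng = np.random.default_rng(cfg.bootstrap_seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        boots = []
        for _ in range(cfg.n_bootstrap):
            bp = rng.choice(idx_pos, len(idx_pos))
            bn = rng.choice(idx_neg, len(idx_neg))
            ys = np.r_[np.ones(len(bp), int), np.zeros(len(bn), int)]
            boots.append(_mann_whitney_auc(np.r_[scores[bp], scores[bn]], ys))
        lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = float(min(max(lo, 0.0), auc))
    hi = float(max(min(hi, 1.0), auc))
    return PhaseAuc(phase=phase, auc=auc, ci_low=lo, ci_high=hi,
                    probabilities=scores, labels=y)


def roc_points(probabilities, labels) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) over all score thresholds."""
    scores = np.asarray(probabilities, dtype=float)
    y = _binary_labels(labels)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((1 - y).sum(), 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def classify_by_phase(table: pd.DataFrame, cfg: ClassifierConfig | None = None
                      ) -> list[PhaseAuc]:
    """One LOO evaluation per phase from a long-format feature table.

    Instances are (subject, roi) pairs; flagged feature values enter as
    NaN and are imputed per training fold.  Instances with no data at a
    phase are skipped with a warning.
    """
    cfg = cfg or ClassifierConfig()
    df = table.copy()
    if "flag" in df:
        df.loc[df["flag"].astype(bool), "value"] = np.nan
    out = []
    feature_order = sorted(df["feature"].unique())
    for phase in range(1, 8):
        sub = df[df["phase"] == phase]
        wide = sub.pivot_table(index=["subject", "roi"], columns="feature",
                               values="value", aggfunc="first", dropna=False)
        wide = wide.reindex(columns=feature_order)
        all_nan = wide.isna().all(axis=1)
        if all_nan.any():
            for subj, roi in wide.index[all_nan]:
                logger.warning("phase %d: skipping %s/%s (no data)", phase, subj, roi)
            wide = wide[~all_nan]
        labels = [roi for _, roi in wide.index]
        probs = loo_probabilities(wide.to_numpy(), labels, cfg)
        out.append(roc_auc(probs, labels, cfg, phase=phase))
    return out
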