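"""Conversion-risk classifier: PCA + Fisher-discriminant selection, SVM ensemble.

Desk-scale re-implementation of the described architecture class: features
are median-imputed and standardized on the training split, projected onto
principal components, the components ranked by the Fisher Discriminant
Ratio (μ₁−μ₀)²/(σ₀²+σ₁²), and the top-ranked components feed an ensemble of
linear support-vector classifiers trained on bootstrap resamples with
consensus (majority) voting.  The proprietary tool's kernel, component and
member counts are unpublished; the defaults here reproduce the architecture
class, not the proprietary instance, and are fully configurable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .schema import (COGNITIVE_FIELDS, VOLUMETRIC_FIELDS, ConfigurationError,
                     ValidationError)

__all__ = ["RiskModelConfig", "RiskModel", "fdr_score", "feature_columns",
           "train_risk_model", "predict_risk", "cross_validate_risk"]

MODEL_VERSION = "1"

FEATURE_BLOCKS = {
    "volumetric": list(VOLUMETRIC_FIELDS),
    "cognitive": list(COGNITIVE_FIELDS),
}


def feature_columns(blocks=("volumetric", "cognitive")) -> list[str]:
    """Feature names for the requested blocks (MRI-only vs MRI+cognitive)."""
    cols: list[str] = []
    for b in blocks:
        if b not in FEATURE_BLOCKS:
            raise ConfigurationError(f"unknown feature block {b!r}")
        cols += FEATURE_BLOCKS[b]
    return cols


def fdr_score(values_class0, values_class1) -> float:
    """Fisher Discriminant Ratio (μ₁−μ₀)² / (σ₀²+σ₁²), sample moments.

    Zero pooled variance with separated means returns +inf (sentinel) with
    a warning; with equal means the score is 0.
    """
    x0 = np.asarray(values_class0, dtype=float)
    x1 = np.asarray(values_class1, dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValidationError("each class needs >= 2 samples")
    num = (x1.mean() - x0.mean()) ** 2
    den = x0.var(ddof=1) + x1.var(ddof=1)
    if den == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero pooled variance with separated means; FDR = inf")
        return float("inf")
    return float(num / den)


@dataclass(frozen=True)
class RiskModelConfig:
    n_components_kept: int = 10
    variance_explained: float = 0.95
    n_members: int = 21
    resample_fraction: float = 0.8
    vote_threshold: float = 0.5
    svm_c: float = 1.0

    def __post_init__(self):
        if not 0 < self.vote_threshold <= 1:
            raise ValidationError("vote threshold must be in (0, 1]")
        if self.n_members < 1:
            raise ValidationError("need at least one ensemble member")


@dataclass
class RiskModel:
    """Fitted pipeline state: imputation, scaling, PCA basis, members."""

    feature_names: list[str]
    medians: np.ndarray
    scale_mean: np.ndarray
    scale_std: np.ndarray
    pca: PCA
    fdr_scores: np.ndarray          # per retained PCA component
    selected_components: np.ndarray  # index set, FDR-ranked
    members: list[LinearSVC]
    config: RiskModelConfig
    classes: tuple = ("LR", "HR")   # negative, positive
    version: str = MODEL_VERSION


def _design(model_or_names, X: pd.DataFrame, medians=None):
    names = model_or_names
    missing = [c for c in names if c not in X.columns]
    if missing:
        raise ValidationError(f"feature matrix missing columns {missing[:5]}")
    extra = None  # extra columns are permitted and ignored
    A = X[names].to_numpy(dtype=float)
    if medians is not None:
        idx = np.where(np.isnan(A))
        A[idx] = medians[idx[1]]
    return A


def train_risk_model(X: pd.DataFrame, y, config: RiskModelConfig | None = None,
                     seed: int = 0, features: list[str] | None = None) -> RiskModel:
    """Fit the ensemble on a training table; deterministic given the seed.

    ``y`` is binary: 1/True = converter (high risk).  Components explaining
    ``variance_explained`` of the training variance are retained, then the
    top ``n_components_kept`` by Fisher Discriminant Ratio are selected.
    """
    config = config or RiskModelConfig()
    names = features if features is not None else \
        [c for c in feature_columns() if c in X.columns]
    yv = np.asarray(y).astype(int)
    if set(np.unique(yv)) != {0, 1}:
        raise ValidationError("both classes must be present in training labels")
    if min((yv == 0).sum(), (yv == 1).sum()) < 10:
        raise ValidationError("need >= 10 subjects per class")
    A = X[names].to_numpy(dtype=float)
    medians = np.nanmedian(A, axis=0)
    idx = np.where(np.isnan(A))
    A[idx] = medians[idx[1]]
    mean = A.mean(axis=0)
    std = A.std(axis=0)
    std[std == 0] = 1.0
    Z = (A - mean) / std
    n_keep_var = min(len(names), len(Z) - 1)
    pca = PCA(n_components=n_keep_var, svd_solver="full", random_state=0)
    P = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_var = int(np.searchsorted(cum, config.variance_explained) + 1)
    P = P[:, :n_var]
    scores = np.array([fdr_score(P[yv == 0, j], P[yv == 1, j]) for j in range(n_var)])
    order = np.argsort(-scores, kind="stable")
    selected = order[:min(config.n_components_kept, n_var)]
    Psel = P[:, selected]
    rng = np.random.default_rng(seed)
    n = len(Psel)
    n_draw = max(2, int(round(config.resample_fraction * n)))
    members = []
    for _ in range(config.n_members):
        while True:  # bootstrap resample must contain both classes
            rows = rng.integers(0, n, size=n_draw)
            if len(np.unique(yv[rows])) == 2:
                break
        clf = LinearSVC(C=config.svm_c, dual=False)
        clf.fit(Psel[rows], yv[rows])
        members.append(clf)
    return RiskModel(names, medians, mean, std, pca, scores, selected,
                     members, config)


def _project(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    A = _design(model.feature_names, X, model.medians)
    Z = (A - model.scale_mean) / model.scale_std
    P = model.pca.transform(Z)
    return P[:, model.selected_components]


def predict_risk(model: RiskModel, X: pd.DataFrame):
    """Consensus vote over the ensemble.

    Returns ``(risk_classes, vote_fractions)``; a subject is HR iff the
    fraction of members voting converter is at or above the vote threshold
    (ties at the threshold are HR).  Vote fractions support ROC analysis.
    """
    Psel = _project(model, X)
    votes = np.mean([m.predict(Psel) for m in model.members], axis=0)
    labels = np.where(votes >= model.config.vote_threshold, "HR", "LR")
    return labels, votes


def cross_validate_risk(X: pd.DataFrame, y, config: RiskModelConfig | None = None,
                        seed: int = 0, n_splits: int = 5,
                        features: list[str] | None = None) -> dict:
    """Stratified k-fold cross-validated accuracy of the ensemble."""
    yv = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs, all_votes, all_true = [], [], []
    for k, (tr, te) in enumerate(skf.split(X, yv)):
        model = train_risk_model(X.iloc[tr], yv[tr], config,
                                 seed=seed * 1009 + k, features=features)
        labels, votes = predict_risk(model, X.iloc[te])
        pred = (labels == "HR").astype(int)
        accs.append(float((pred == yv[te]).mean()))
        all_votes.append(votes)
        all_true.append(yv[te])
    return {"fold_accuracies": accs,
            "accuracy": float(np.mean(accs)),
            "votes": np.concatenate(all_votes),
            "truth": np.concatenate(all_true)}
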