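"""Adverse-event prediction harness.

Each side effect becomes a binary classification problem over treatments:
features are per-gene log2 fold changes and (log) expression levels from the
DE contrasts, labels are the clinical positive/negative calls (unknowns are
excluded).  The evaluation protocol is bootstrap cross-validation:

* for each of ``n_boot`` bootstrap iterations, draw a fresh stratified
  80/20 train/test split and resample the training side with replacement;
* run feature selection *inside* the training portion only (genes
  differentially expressed versus the atheroprone control in at least a
  minimum fraction of training treatments);
* fit the model (hyperparameters picked by inner stratified CV on the
  training portion), score the held-out treatments, and record the AUC;
* the per-model score is the mean of the bootstrap AUCs, and the best model
  per side effect is the arg-max of that mean.

Seven classifier families are supported: lasso, ridge, linear-kernel SVM,
RBF-kernel SVM, elastic net, random forest and k-nearest-neighbours.
Continuous features are z-scored inside each fit (train-estimated) for the
penalized/SVM/kNN models and left raw for the random forest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import Database, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "ClassifierEval",
    "MODEL_NAMES",
    "build_feature_table",
    "build_labels",
    "DEFrequencySelector",
    "VarianceSelector",
    "compute_auc",
    "evaluate_model",
    "evaluate_side_effect",
    "pick_best_model",
]

MODEL_NAMES = ("elasticnet", "knn", "lasso", "random_forest", "ridge", "svm_linear", "svm_rbf")
_ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FeatureTable:
    """Treatments x features matrix with per-column provenance.

    Columns are named ``lfc|<cell type>|<gene>`` (fold-change features) and
    ``expr|<cell type>|<gene>`` (log2 mean-expression features); ``provenance``
    maps each column to ``fold_change`` or ``expression``.
    """

    X: pd.DataFrame
    provenance: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValidationError("feature table contains missing values")
        if self.X.columns.duplicated().any():
            raise ValidationError("feature table has duplicate column names")
        if not self.provenance.index.equals(self.X.columns):
            raise ValidationError("provenance must cover exactly the feature columns")
        bad = set(self.provenance.unique()) - {"fold_change", "expression"}
        if bad:
            raise ValidationError(f"unknown provenance tag(s): {sorted(bad)}")


def build_feature_table(
    database: Database,
    cell_types: Sequence[str] = ("EC", "SMC"),
) -> tuple[FeatureTable, pd.DataFrame]:
    """Assemble features and the companion per-gene DE-FDR table.

    Rows are compounds whose designated treatment has a contrast in every
    requested cell type.  Returns ``(features, de_fdr)`` where ``de_fdr``
    (same rows, columns ``<cell type>|<gene>``) holds each gene's FDR in that
    compound's contrast — the raw material for in-fold feature selection.
    """
    refs = {ct: database.references(ct) for ct in cell_types}
    compound_ids = sorted(set.intersection(*(set(refs[ct]) for ct in cell_types)))
    if not compound_ids:
        raise ValidationError("no compound has contrasts in all requested cell types")
    feature_blocks: list[pd.DataFrame] = []
    fdr_blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for ct in cell_types:
        lfc = pd.DataFrame(
            {cid: refs[ct][cid].indexed()["log_fc"] for cid in compound_ids}
        ).T
        expr = pd.DataFrame(
            {cid: np.log2(refs[ct][cid].indexed()["mean_expr"] + 0.5) for cid in compound_ids}
        ).T
        fdr = pd.DataFrame(
            {cid: refs[ct][cid].indexed()["fdr"] for cid in compound_ids}
        ).T
        lfc.columns = [f"lfc|{ct}|{g}" for g in lfc.columns]
        expr.columns = [f"expr|{ct}|{g}" for g in expr.columns]
        fdr.columns = [f"{ct}|{g}" for g in fdr.columns]
        provenance.update({c: "fold_change" for c in lfc.columns})
        provenance.update({c: "expression" for c in expr.columns})
        feature_blocks.extend([lfc, expr])
        fdr_blocks.append(fdr)
    X = pd.concat(feature_blocks, axis=1)
    if X.isna().any().any():  # genes absent from some contrast: drop their columns
        X = X.dropna(axis=1)
        provenance = {c: provenance[c] for c in X.columns}
    de_fdr = pd.concat(fdr_blocks, axis=1).dropna(axis=1)
    return FeatureTable(X=X, provenance=pd.Series(provenance).reindex(X.columns)), de_fdr


def build_labels(database: Database, side_effect: str) -> pd.Series:
    """Binary labels (1 = positive) for one side effect; unknowns excluded."""
    labels = {}
    for compound in database.compounds:
        lab = compound.side_effects.get(side_effect, "unknown")
        if lab == "positive":
            labels[compound.compound_id] = 1
        elif lab == "negative":
            labels[compound.compound_id] = 0
    if not labels:
        raise ValidationError(f"no labelled compounds for side effect {side_effect!r}")
    return pd.Series(labels, name=side_effect)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

class FeatureSelector(Protocol):
    name: str

    def select(self, train_ids: pd.Index, features: FeatureTable) -> list[str]: ...


@dataclass
class VarianceSelector:
    """Top-k features by variance on the training rows (deterministic tie-break)."""

    k: int = 200
    name: str = "variance_topk"

    def select(self, train_ids: pd.Index, features: FeatureTable) -> list[str]:
        var = features.X.loc[train_ids].var(axis=0)
        ranked = sorted(features.X.columns, key=lambda c: (-var[c], c))
        keep = set(ranked[: self.k])
        return [c for c in features.X.columns if c in keep]


@dataclass
class DEFrequencySelector:
    """Genes DE (fdr <= threshold) in at least ``min_fraction`` of the
    training treatments, per cell type; selected genes contribute both their
    fold-change and expression features.

    Falls back to top-k variance when nothing passes; ``max_features`` caps
    dimensionality (keeping the most frequently DE genes).
    """

    de_fdr: pd.DataFrame
    fdr_threshold: float = 0.10
    min_fraction: float = 0.10
    fallback_k: int = 200
    max_features: int | None = 2000
    name: str = "de_frequency"

    def select(self, train_ids: pd.Index, features: FeatureTable) -> list[str]:
        flags = self.de_fdr.loc[train_ids] <= self.fdr_threshold
        frac = flags.mean(axis=0)
        keys = [k for k in self.de_fdr.columns if frac[k] >= self.min_fraction]
        if not keys:
            log.warning("DE selector found no genes; falling back to top-%d variance", self.fallback_k)
            return VarianceSelector(self.fallback_k).select(train_ids, features)
        if self.max_features is not None and 2 * len(keys) > self.max_features:
            keys = sorted(keys, key=lambda k: (-frac[k], k))[: self.max_features // 2]
        keyset = set(keys)
        cols = []
        for col in features.X.columns:
            kind, _, rest = col.partition("|")
            if rest in keyset:
                cols.append(col)
        return cols


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _make_model(name: str, random_state: int):
    """(estimator, param_grid) for one of the seven supported families."""
    scale = ("scale", StandardScaler())
    if name == "lasso":
        clf = LogisticRegression(penalty="l1", solver="liblinear", max_iter=5000,
                                 random_state=random_state)
        return Pipeline([scale, ("clf", clf)]), {"clf__C": [0.1, 1.0]}
    if name == "ridge":
        clf = LogisticRegression(penalty="l2", solver="liblinear", max_iter=5000,
                                 random_state=random_state)
        return Pipeline([scale, ("clf", clf)]), {"clf__C": [0.1, 1.0]}
    if name == "elasticnet":
        clf = SGDClassifier(loss="log_loss", penalty="elasticnet", l1_ratio=0.5,
                            max_iter=200, tol=1e-3, early_stopping=True,
                            validation_fraction=0.15, n_iter_no_change=5,
                            random_state=random_state)
        return Pipeline([scale, ("clf", clf)]), {"clf__alpha": [1e-3, 1e-2]}
    if name == "svm_linear":
        return Pipeline([scale, ("clf", SVC(kernel="linear", random_state=random_state))]), \
            {"clf__C": [0.1, 1.0]}
    if name == "svm_rbf":
        return Pipeline([scale, ("clf", SVC(kernel="rbf", gamma="scale", random_state=random_state))]), \
            {"clf__C": [1.0, 10.0]}
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=random_state), {}
    if name == "knn":
        return Pipeline([scale, ("clf", KNeighborsClassifier(n_neighbors=5))]), {}
    raise ValidationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """AUC as P(random positive outranks random negative), ties counting 1/2.

    Returns ``None`` when only one class is present.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        return None
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class ClassifierEval:
    """Bootstrap evaluation of one (side effect, model, selector) triple."""

    side_effect: str
    model_name: str
    selector_name: str
    boot_aucs: list[float]
    mean_auc: float
    roc_curve: list[tuple[float, float]] = field(default_factory=list)


def evaluate_model(
    features: FeatureTable,
    labels: pd.Series,
    model_name: str,
    selector: FeatureSelector,
    k_folds: int = 10,
    n_boot: int = 150,
    seed: int = 0,
    test_fraction: float = 0.2,
    permute_labels: bool = False,
) -> ClassifierEval:
    """Bootstrap cross-validated evaluation of one model (see module docstring).

    Splits are derived from ``seed`` alone, so all models evaluated with the
    same seed see identical resampling (paired comparison).  A bootstrap whose
    fit fails is recorded as NaN and excluded from the mean with a warning.

    With ``permute_labels`` the labels are freshly permuted (uniformly at
    random) at every bootstrap iteration, which makes ``mean_auc`` a
    Monte-Carlo estimate of the permutation-null expectation (0.5 for a
    random classifier) rather than the score of one arbitrary permutation —
    a single permutation can align with latent cluster structure by chance
    and bias the whole 150-bootstrap mean in either direction.
    """
    if model_name not in MODEL_NAMES:
        raise ValidationError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    ids = labels.index.intersection(features.X.index)
    y_all = labels.loc[ids].to_numpy(dtype=int)
    if np.unique(y_all).size < 2 or min(np.bincount(y_all)) < 2:
        raise ValidationError("need at least two labelled treatments per class")
    X_all = features.X.loc[ids]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    model_rs = int(np.random.SeedSequence([seed, MODEL_NAMES.index(model_name)]).generate_state(1)[0] % (2**31))

    boot_aucs: list[float] = []
    tprs: list[np.ndarray] = []
    for b in range(n_boot):
        split_rs = int(rng.integers(2**31))
        inner_rs = int(rng.integers(2**31))
        y_b = rng.permutation(y_all) if permute_labels else y_all
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=split_rs)
        (train_idx, test_idx), = sss.split(X_all, y_b)
        # bootstrap-perturb the training portion (stratified, with replacement)
        boot_idx = np.concatenate([
            rng.choice(train_idx[y_b[train_idx] == cls],
                       size=(y_b[train_idx] == cls).sum(), replace=True)
            for cls in np.unique(y_b[train_idx])
        ])
        cols = selector.select(ids[np.unique(train_idx)], features)
        X_tr = X_all.iloc[boot_idx][cols].to_numpy()
        y_tr = y_b[boot_idx]
        X_te = X_all.iloc[test_idx][cols].to_numpy()
        y_te = y_b[test_idx]
        estimator, grid = _make_model(model_name, model_rs)
        try:
            if grid and max(len(v) for v in grid.values()) > 1:
                folds = min(k_folds, int(np.bincount(y_tr).min()))
                cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=inner_rs)
                search = GridSearchCV(estimator, grid, scoring="roc_auc", cv=cv, n_jobs=None)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(X_tr, y_tr)
                fitted = search.best_estimator_
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitted = estimator.fit(X_tr, y_tr)
            scores = _scores(fitted, X_te)
            auc = compute_auc(scores, y_te)
        except Exception as exc:  # noqa: BLE001 - model failure is data, not a crash
            log.warning("bootstrap %d: %s failed (%s); recorded as undefined", b, model_name, exc)
            auc = None
        if auc is None:
            boot_aucs.append(np.nan)
            continue
        boot_aucs.append(auc)
        fpr, tpr, _ = roc_curve(y_te, scores)
        tprs.append(np.interp(_ROC_GRID, fpr, tpr))
    valid = [a for a in boot_aucs if not np.isnan(a)]
    if not valid:
        raise ValidationError(f"all {n_boot} bootstraps failed for model {model_name!r}")
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full_like(_ROC_GRID, np.nan)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ClassifierEval(
        side_effect=str(labels.name),
        model_name=model_name,
        selector_name=selector.name,
        boot_aucs=boot_aucs,
        mean_auc=float(np.mean(valid)),
        roc_curve=list(zip(_ROC_GRID.tolist(), mean_tpr.tolist())),
    )


def pick_best_model(evals: Sequence[ClassifierEval]) -> ClassifierEval:
    """Arg-max by mean AUC; ties broken by lexicographic model name (logged)."""
    if not evals:
        raise ValidationError("pick_best_model requires a non-empty evaluation list")
    ranked = sorted(evals, key=lambda e: (-e.mean_auc, e.model_name))
    if len(ranked) > 1 and ranked[0].mean_auc == ranked[1].mean_auc:
        log.info(
            "mean-AUC tie between %s and %s; picking %s (lexicographic)",
            ranked[0].model_name, ranked[1].model_name, ranked[0].model_name,
        )
    return ranked[0]


def evaluate_side_effect(
    features: FeatureTable,
    labels: pd.Series,
    selector: FeatureSelector,
    models: Sequence[str] = MODEL_NAMES,
    k_folds: int = 10,
    n_boot: int = 150,
    seed: int = 0,
    permute_labels: bool = False,
) -> list[ClassifierEval]:
    """Evaluate every requested model on one side effect (shared resampling)."""
    return [
        evaluate_model(features, labels, name, selector, k_folds=k_folds, n_boot=n_boot,
                       seed=seed, permute_labels=permute_labels)
        for name in models
    ]
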