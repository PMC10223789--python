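"""Classification, ablation, importance, and hyperparameter sweeps.

Binary gene-dependency labels are predicted from feature tables with a
zoo of ten scikit-learn classifiers at library-default hyperparameters.
Evaluation is stratified 5-fold cross-validation scored by the F1 of the
dependent (positive) class; features are z-scored inside each training
fold because the path-feature scales differ by orders of magnitude and
several zoo members are scale-sensitive.

Feature-class ablations (single and pairwise over the four network
classes), single-feature ablations, permutation importance, and the two
hyperparameter sweeps (dependency binarization cutoff, MI pruning cutoff)
all reuse the same cross-validation protocol so their F1 values are
directly comparable.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import (
    NETWORK_FEATURE_CLASSES,
    DependencyLabels,
    FeatureTable,
    GeneSetCollection,
)
from .features import compute_network_features
from .labeling import binarize
from .network import prune_network

logger = logging.getLogger(__name__)

FEATURE_SETS = ("network", "expression", "combined")

#: Dependency-cutoff sweep grid: -1.5 to 0.1 in 0.1 increments (17 points).
DEFAULT_DEPENDENCY_GRID = tuple(np.round(np.arange(-1.5, 0.1 + 1e-9, 0.1), 10))
#: Wider grid variant extending to 0.25.
EXTENDED_DEPENDENCY_GRID = tuple(np.round(np.arange(-1.5, 0.25 + 1e-9, 0.1), 10))
#: MI pruning-cutoff sweep grid.
DEFAULT_PRUNING_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass
class ModelSpec:
    """One zoo member: a scikit-learn classifier at default hyperparameters."""

    name: str = "logistic_regression"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_ZOO:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {sorted(MODEL_ZOO)}"
            )

    def build(self):
        factory, takes_seed = MODEL_ZOO[self.name]
        kwargs = dict(self.hyperparameters)
        if takes_seed:
            kwargs.setdefault("random_state", self.seed)
        return factory(**kwargs)


MODEL_ZOO: dict[str, tuple] = {
    "adaboost": (AdaBoostClassifier, True),
    "decision_tree": (DecisionTreeClassifier, True),
    "gaussian_process": (GaussianProcessClassifier, True),
    "knn": (KNeighborsClassifier, False),
    "linear_svc": (LinearSVC, True),
    "logistic_regression": (LogisticRegression, True),
    "random_forest": (RandomForestClassifier, True),
    "ridge": (RidgeClassifier, True),
    "sgd_linear_svc": (SGDClassifier, True),
    "rbf_svc": (SVC, True),
}


def f1_score(n_tp: int, n_fp: int, n_fn: int) -> float:
    """F1 = 2PR/(P+R) from confusion counts, on the positive class.

    Returns 0 when there are no true positives but errors exist, and 0
    (with a warning) in the fully degenerate case tp = fp = fn = 0.
    """
    if min(n_tp, n_fp, n_fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if n_tp == 0:
        if n_fp == 0 and n_fn == 0:
            warnings.warn("F1 undefined for tp=fp=fn=0; returning 0", stacklevel=2)
        return 0.0
    precision = n_tp / (n_tp + n_fp)
    recall = n_tp / (n_tp + n_fn)
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class CVResult:
    """Cross-validated F1 for one (model, feature set) cell."""

    model: str
    feature_set: str
    fold_scores: list[float]
    f1_mean: float
    f1_sd: float
    n_instances: int
    n_dependent: int


@dataclass
class AblationResult:
    removed: tuple[str, ...]
    f1_mean: float
    f1_sd: float
    delta_vs_full: float
    fold_scores: list[float]


@dataclass
class ImportanceResult:
    """Permutation importance: mean held-out F1 drop per shuffled feature."""

    table: pd.DataFrame  # columns: feature_class, feature, importance_mean, importance_sd
    n_repeats: int
    seed: int


@dataclass
class SweepResult:
    axis: str  # "dependency_cutoff" or "mi_pruning_cutoff"
    table: pd.DataFrame  # columns: cutoff, f1_mean, f1_sd, n_dependent, status


def _align_xy(
    features: FeatureTable, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intersect label genes with feature rows; genes without features are
    dropped with a logged count (their features are undefined off-network)."""
    have = set(features.gene_ids)
    genes = [g for g in labels.index if g in have]
    dropped = len(labels) - len(genes)
    if dropped:
        logger.info("dropping %d labeled genes absent from the feature table", dropped)
    if not genes:
        raise ValueError("no overlap between labeled genes and feature rows")
    X = features.data.loc[genes].to_numpy(dtype=float)
    y = labels.loc[genes].to_numpy(dtype=int)
    return X, y, genes


def _check_trainable(y: np.ndarray, k: int) -> None:
    pos, neg = int(y.sum()), int(len(y) - y.sum())
    if min(pos, neg) < k:
        raise ValueError(
            f"need at least {k} instances of each class for {k}-fold stratified CV; "
            f"got {pos} dependent / {neg} non-dependent. Lower k, change the "
            "cutoff, or supply more genes."
        )


def _cv_splits(y: np.ndarray, k: int, seed: int):
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.zeros(len(y)), y
    )


def _make_pipeline(spec: ModelSpec):
    return make_pipeline(StandardScaler(), clone(spec.build()))


def crossval_f1(
    features: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
    feature_set: str = "network",
) -> CVResult:
    """Stratified k-fold cross-validated F1 of the dependent class.

    ``labels`` is a binary Series indexed by gene (1 = dependent).  The
    scaler is fit on each training fold only; folds are shuffled with the
    given seed so repeated calls are bit-reproducible.
    """
    spec = spec or ModelSpec()
    X, y, _ = _align_xy(features, labels)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    _check_trainable(y, k)
    fold_scores = []
    for train, test in _cv_splits(y, k, seed):
        pipe = _make_pipeline(spec)
        pipe.fit(X[train], y[train])
        pred = pipe.predict(X[test])
        fold_scores.append(float(_sk_f1(y[test], pred, pos_label=1, zero_division=0)))
    return CVResult(
        model=spec.name,
        feature_set=feature_set,
        fold_scores=fold_scores,
        f1_mean=float(np.mean(fold_scores)),
        f1_sd=float(np.std(fold_scores, ddof=1)),
        n_instances=len(y),
        n_dependent=int(y.sum()),
    )


def pool_instances(
    features_by_lineage, labels: DependencyLabels
) -> tuple[FeatureTable, pd.Series]:
    """Pan-cancer instance pooling: one row per (gene, lineage) pair.

    ``features_by_lineage`` maps lineage -> FeatureTable (or is a single
    table shared by every lineage).  Instance ids are ``gene|lineage``.
    Genes labeled in a lineage but absent from its feature table are
    dropped with a logged count.
    """
    frames, ys = [], []
    for lineage in labels.table["lineage"].unique():
        table = (
            features_by_lineage[lineage]
            if isinstance(features_by_lineage, dict)
            else features_by_lineage
        )
        y = labels.for_lineage(lineage)
        have = set(table.gene_ids)
        genes = [g for g in y.index if g in have]
        if len(genes) < len(y):
            logger.info(
                "pool_instances: %s drops %d labeled genes without features",
                lineage,
                len(y) - len(genes),
            )
        block = table.data.loc[genes].copy()
        block.index = [f"{g}|{lineage}" for g in genes]
        frames.append(block)
        ys.append(pd.Series(y.loc[genes].to_numpy(), index=block.index))
    pooled = FeatureTable(pd.concat(frames))
    return pooled, pd.concat(ys)


def _select_feature_set(features: FeatureTable, feature_set: str) -> FeatureTable:
    if feature_set == "network":
        wanted = [c for c in NETWORK_FEATURE_CLASSES if c in features.classes]
        if not wanted:
            raise ValueError("no network feature classes present")
        return features.select_classes(wanted)
    if feature_set == "expression":
        return features.select_classes(["expression"])
    if feature_set == "combined":
        return features
    raise ValueError(f"unknown feature set {feature_set!r}")


def run_model_zoo(
    features: FeatureTable,
    labels: pd.Series,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    models: tuple[str, ...] | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every requested model on every requested feature set.

    Per-cell failures are recorded (status column) without aborting the
    grid.  Returns a tidy DataFrame, one row per model x feature set.
    """
    models = models or tuple(sorted(MODEL_ZOO))
    rows = []
    for name in models:
        for fs in feature_sets:
            row = {"model": name, "feature_set": fs}
            try:
                sub = _select_feature_set(features, fs)
                res = crossval_f1(sub, labels, ModelSpec(name, seed=seed), k, seed, fs)
                row.update(
                    f1_mean=res.f1_mean,
                    f1_sd=res.f1_sd,
                    fold_scores=res.fold_scores,
                    n_instances=res.n_instances,
                    n_dependent=res.n_dependent,
                    status="ok",
                )
            except Exception as exc:  # record-and-continue grid policy
                logger.warning("zoo cell (%s, %s) failed: %s", name, fs, exc)
                row.update(
                    f1_mean=np.nan,
                    f1_sd=np.nan,
                    fold_scores=[],
                    n_instances=0,
                    n_dependent=0,
                    status=f"error: {exc}",
                )
            rows.append(row)
    return pd.DataFrame(rows)


def ablate_classes(
    features: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    arity: int = 1,
    k: int = 5,
    seed: int = 0,
) -> list[AblationResult]:
    """Retrain with every size-``arity`` subset of the four network feature
    classes removed (4 single or 6 pairwise ablations)."""
    if arity not in (1, 2):
        raise ValueError("arity must be 1 or 2")
    spec = spec or ModelSpec(seed=seed)
    present = [c for c in NETWORK_FEATURE_CLASSES if c in features.classes]
    missing = set(NETWORK_FEATURE_CLASSES) - set(present)
    if missing:
        raise KeyError(f"feature table lacks network classes: {sorted(missing)}")
    base = features.select_classes(present)
    full = crossval_f1(base, labels, spec, k, seed)
    results = []
    for removed in itertools.combinations(NETWORK_FEATURE_CLASSES, arity):
        res = crossval_f1(base.drop_classes(removed), labels, spec, k, seed)
        results.append(
            AblationResult(
                removed=removed,
                f1_mean=res.f1_mean,
                f1_sd=res.f1_sd,
                delta_vs_full=res.f1_mean - full.f1_mean,
                fold_scores=res.fold_scores,
            )
        )
    return results


def ablate_single_features(
    features: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    class_filter: str | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[AblationResult]:
    """Retrain with one feature column removed at a time."""
    spec = spec or ModelSpec(seed=seed)
    full = crossval_f1(features, labels, spec, k, seed)
    if class_filter is not None and class_filter not in features.classes:
        raise KeyError(f"unknown feature class {class_filter!r}")
    columns = [
        c
        for c in features.data.columns
        if class_filter is None or c[0] == class_filter
    ]
    results = []
    for col in columns:
        res = crossval_f1(features.drop_feature(col[1]), labels, spec, k, seed)
        results.append(
            AblationResult(
                removed=(col[1],),
                f1_mean=res.f1_mean,
                f1_sd=res.f1_sd,
                delta_vs_full=res.f1_mean - full.f1_mean,
                fold_scores=res.fold_scores,
            )
        )
    return results


def permutation_importance(
    features: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    k: int = 5,
) -> ImportanceResult:
    """Mean held-out F1 drop when one feature column is shuffled.

    For each CV fold the model is fit on the training split and each
    feature of the held-out split is permuted ``n_repeats`` times; drops
    are pooled across folds and repeats.  Deterministic under a fixed
    seed.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    spec = spec or ModelSpec(seed=seed)
    X, y, _ = _align_xy(features, labels)
    _check_trainable(y, k)
    per_fold = []
    for fold_i, (train, test) in enumerate(_cv_splits(y, k, seed)):
        pipe = _make_pipeline(spec)
        pipe.fit(X[train], y[train])
        imp = _sk_permutation_importance(
            pipe,
            X[test],
            y[test],
            scoring=lambda est, Xs, ys: _sk_f1(
                ys, est.predict(Xs), pos_label=1, zero_division=0
            ),
            n_repeats=n_repeats,
            random_state=seed + fold_i,
        )
        per_fold.append(imp.importances)  # (n_features, n_repeats)
    pooled = np.concatenate(per_fold, axis=1)
    table = pd.DataFrame(
        {
            "feature_class": [c[0] for c in features.data.columns],
            "feature": [c[1] for c in features.data.columns],
            "importance_mean": pooled.mean(axis=1),
            "importance_sd": pooled.std(axis=1, ddof=1),
        }
    ).sort_values("importance_mean", ascending=False, ignore_index=True)
    return ImportanceResult(table=table, n_repeats=n_repeats, seed=seed)


def sweep_dependency_cutoff(
    mean_scores: pd.Series,
    features: FeatureTable,
    spec: ModelSpec | None = None,
    grid: tuple[float, ...] = DEFAULT_DEPENDENCY_GRID,
    k: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Re-binarize the lineage-mean scores at each cutoff and re-evaluate.

    Cutoffs yielding a class too small for stratified CV are recorded as
    missing rather than aborting the sweep.
    """
    if len(grid) == 0:
        raise ValueError("empty cutoff grid")
    grid = tuple(sorted(grid))
    spec = spec or ModelSpec(seed=seed)
    rows = []
    for cutoff in grid:
        labels = binarize(mean_scores, cutoff=cutoff).for_lineage("all")
        row = {"cutoff": cutoff, "n_dependent": int(labels.sum())}
        try:
            res = crossval_f1(features, labels, spec, k, seed)
            row.update(f1_mean=res.f1_mean, f1_sd=res.f1_sd, status="ok")
        except ValueError as exc:
            logger.warning("dependency cutoff %.2f skipped: %s", cutoff, exc)
            row.update(f1_mean=np.nan, f1_sd=np.nan, status="missing")
        rows.append(row)
    return SweepResult(axis="dependency_cutoff", table=pd.DataFrame(rows))


def sweep_pruning_cutoff(
    base_network: nx.Graph,
    gene_sets: GeneSetCollection,
    mean_scores: pd.Series,
    spec: ModelSpec | None = None,
    grid: tuple[float, ...] = DEFAULT_PRUNING_GRID,
    label_cutoff: float = -1.0,
    path_mode: str = "raw",
    k: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Re-prune the network at each MI cutoff, recompute features, re-train.

    ``base_network`` is the unpruned (post-DPI, if applicable) MI graph; a
    cutoff of 0 reproduces the no-pruning baseline.  Cutoffs that empty
    the network of edges are recorded as missing with a warning.
    """
    if any(c < 0 for c in grid):
        raise ValueError("pruning cutoffs must be >= 0")
    grid = tuple(sorted(grid))
    spec = spec or ModelSpec(seed=seed)
    labels = binarize(mean_scores, cutoff=label_cutoff).for_lineage("all")
    rows = []
    for cutoff in grid:
        pruned = prune_network(base_network, cutoff)
        row = {"cutoff": cutoff, "n_edges": pruned.number_of_edges()}
        if pruned.number_of_edges() == 0:
            logger.warning("pruning cutoff %.2f empties the network", cutoff)
            row.update(f1_mean=np.nan, f1_sd=np.nan, status="missing")
            rows.append(row)
            continue
        try:
            feats = compute_network_features(pruned, gene_sets, path_mode=path_mode)
            res = crossval_f1(feats, labels, spec, k, seed)
            row.update(f1_mean=res.f1_mean, f1_sd=res.f1_sd, status="ok")
        except ValueError as exc:
            logger.warning("pruning cutoff %.2f skipped: %s", cutoff, exc)
            row.update(f1_mean=np.nan, f1_sd=np.nan, status="missing")
        rows.append(row)
    return SweepResult(axis="mi_pruning_cutoff", table=pd.DataFrame(rows))
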