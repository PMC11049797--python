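"""UMAP embedding and the repeated train/test linear-SVM evaluation harness.

The classification question is whether incubation temperature (30 vs 34 C)
leaves a recoverable trace in the coloration profile.  Profiles (or their
UMAP embedding) are split 75/25 into train and test, a linear-kernel SVM is
fitted, and precision, recall, F1 and ROC AUC are recorded; the split and
fit are repeated (default 10x) and each metric is summarized as mean +/- SD.
The analysis is run separately per colony of origin, and a parameter sweep
covers the UMAP neighbour counts (5, 10, 20, 50, 75, 99) crossed with 2-10
output dimensions.

By default UMAP is fitted once on the full per-colony dataset before
splitting (transductive preprocessing).  The leakage-free alternative --
refitting UMAP on each training split via the :class:`UmapLinearSVM`
estimator -- is available with ``umap_fit="train"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NEIGHBORS_GRID",
    "DIMS_GRID",
    "UMAPParams",
    "EvalProtocol",
    "ClassMetrics",
    "embed_umap",
    "binary_metrics",
    "evaluate_classifier",
    "sweep_umap_svm",
    "classify_profiles",
    "classify_by_colony",
    "UmapLinearSVM",
]

#: Default sweep grids: neighbour counts span local to near-global structure
#: for ~100 samples per colony; dimensions 2 (visualizable) through 10.
NEIGHBORS_GRID = (5, 10, 20, 50, 75, 99)
DIMS_GRID = tuple(range(2, 11))


@dataclass(frozen=True)
class UMAPParams:
    """UMAP settings; defaults match the headline analysis (75 neighbours of
    ~100 per colony to capture global variation, 2 output components)."""

    n_neighbors: int = 75
    n_components: int = 2
    min_dist: float = 0.1
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated stratified train/test evaluation settings."""

    train_fraction: float = 0.75
    n_replicates: int = 10
    seed: int = 0
    positive_label: object | None = None  # None -> second class in sort order
    C: float = 1.0
    fixed_split: bool = False
    max_retries: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ClassMetrics:
    """Per-replicate classifier metrics with mean +/- SD summaries."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    auc: np.ndarray
    positive_label: object = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("precision", "recall", "f1", "auc"):
            x = np.asarray(getattr(self, name), dtype=float)
            out[f"{name}_mean"] = float(x.mean())
            out[f"{name}_sd"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return out


def embed_umap(X: np.ndarray, params: UMAPParams) -> np.ndarray:
    """Embed profiles with UMAP; deterministic for a fixed seed.

    Row order is preserved: embedding[i] corresponds to X[i].
    """
    import umap  # deferred: umap import is slow (numba)

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if params.n_neighbors >= n:
        raise ValueError(
            f"n_neighbors={params.n_neighbors} must be < n_samples={n}"
        )
    with warnings.catch_warnings():
        # fixing random_state forces single-threading; that is the point
        warnings.filterwarnings("ignore", message=".*random_state.*")
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        reducer = umap.UMAP(
            n_neighbors=params.n_neighbors,
            n_components=params.n_components,
            min_dist=params.min_dist,
            metric=params.metric,
            random_state=params.seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def binary_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    positive_label: object,
) -> dict[str, float]:
    """Precision, recall, F1 and ROC AUC for one test set.

    ``scores`` must be oriented so larger values favour the positive label.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_label
    return {
        "precision": float(
            precision_score(pos, y_pred == positive_label, zero_division=0)
        ),
        "recall": float(recall_score(pos, y_pred == positive_label, zero_division=0)),
        "f1": float(f1_score(pos, y_pred == positive_label, zero_division=0)),
        "auc": float(roc_auc_score(pos, np.asarray(scores, dtype=float))),
    }


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def evaluate_classifier(
    X: np.ndarray, y: np.ndarray, protocol: EvalProtocol = EvalProtocol()
) -> ClassMetrics:
    """Repeated stratified-split evaluation of a linear-kernel SVM.

    Each replicate draws a fresh stratified split at ``train_fraction``,
    fits ``SVC(kernel="linear")`` on the training part and scores the test
    part; AUC comes from the decision-function scores.  With
    ``fixed_split=True`` the first split is reused in every replicate
    (replicates then differ only through the deterministic fit, emulating
    protocols that resample nothing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    positive = (
        protocol.positive_label if protocol.positive_label is not None else classes[1]
    )
    if positive not in classes:
        raise ValueError(f"positive_label {positive!r} not among classes")
    seeds = _replicate_seeds(protocol.seed, protocol.n_replicates)
    if protocol.fixed_split:
        seeds = np.full(protocol.n_replicates, seeds[0])

    per_rep: list[dict[str, float]] = []
    for rep_seed in seeds:
        split = None
        for attempt in range(protocol.max_retries):
            Xtr, Xte, ytr, yte = train_test_split(
                X,
                y,
                train_size=protocol.train_fraction,
                stratify=y,
                random_state=int(rep_seed) + attempt,
            )
            if np.unique(ytr).size == 2 and np.unique(yte).size == 2:
                split = (Xtr, Xte, ytr, yte)
                break
        if split is None:
            raise ValueError(
                "could not draw a split containing both classes; "
                "dataset too small for the requested train_fraction"
            )
        Xtr, Xte, ytr, yte = split
        clf = SVC(kernel="linear", C=protocol.C)
        clf.fit(Xtr, ytr)
        scores = clf.decision_function(Xte)
        if positive == clf.classes_[0]:
            scores = -scores
        per_rep.append(binary_metrics(yte, clf.predict(Xte), scores, positive))

    return ClassMetrics(
        precision=np.array([m["precision"] for m in per_rep]),
        recall=np.array([m["recall"] for m in per_rep]),
        f1=np.array([m["f1"] for m in per_rep]),
        auc=np.array([m["auc"] for m in per_rep]),
        positive_label=positive,
    )


def classify_profiles(
    X: np.ndarray,
    y: np.ndarray,
    preprocess: str = "raw",
    umap_params: UMAPParams = UMAPParams(),
    protocol: EvalProtocol = EvalProtocol(),
    umap_fit: str = "all",
) -> ClassMetrics:
    """Evaluate the SVM on raw profiles or on a UMAP embedding.

    ``umap_fit="all"`` embeds the full dataset once before splitting
    (transductive, the default protocol); ``umap_fit="train"`` refits UMAP
    inside each training split via :class:`UmapLinearSVM` (leakage-free).
    """
    if preprocess not in ("raw", "umap"):
        raise ValueError("preprocess must be 'raw' or 'umap'")
    if preprocess == "raw":
        return evaluate_classifier(X, y, protocol)
    if umap_fit == "all":
        emb = embed_umap(X, umap_params)
        return evaluate_classifier(emb, y, protocol)
    if umap_fit != "train":
        raise ValueError("umap_fit must be 'all' or 'train'")
    return _evaluate_umap_train(X, y, umap_params, protocol)


def _evaluate_umap_train(
    X: np.ndarray,
    y: np.ndarray,
    umap_params: UMAPParams,
    protocol: EvalProtocol,
) -> ClassMetrics:
    """Leakage-free variant: UMAP refitted on every training split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    positive = (
        protocol.positive_label if protocol.positive_label is not None else classes[1]
    )
    seeds = _replicate_seeds(protocol.seed, protocol.n_replicates)
    if protocol.fixed_split:
        seeds = np.full(protocol.n_replicates, seeds[0])
    per_rep = []
    for rep_seed in seeds:
        Xtr, Xte, ytr, yte = train_test_split(
            X,
            y,
            train_size=protocol.train_fraction,
            stratify=y,
            random_state=int(rep_seed),
        )
        est = UmapLinearSVM(
            n_neighbors=min(umap_params.n_neighbors, Xtr.shape[0] - 1),
            n_components=umap_params.n_components,
            min_dist=umap_params.min_dist,
            metric=umap_params.metric,
            C=protocol.C,
            random_state=umap_params.seed,
        )
        est.fit(Xtr, ytr)
        scores = est.decision_function(Xte)
        if positive == est.classes_[0]:
            scores = -scores
        per_rep.append(binary_metrics(yte, est.predict(Xte), scores, positive))
    return ClassMetrics(
        precision=np.array([m["precision"] for m in per_rep]),
        recall=np.array([m["recall"] for m in per_rep]),
        f1=np.array([m["f1"] for m in per_rep]),
        auc=np.array([m["auc"] for m in per_rep]),
        positive_label=positive,
    )


def sweep_umap_svm(
    X: np.ndarray,
    y: np.ndarray,
    neighbors_grid: tuple[int, ...] = NEIGHBORS_GRID,
    dims_grid: tuple[int, ...] = DIMS_GRID,
    protocol: EvalProtocol = EvalProtocol(),
    umap_seed: int = 0,
    sort_by_f1: bool = False,
) -> pd.DataFrame:
    """Evaluate every (n_neighbors, n_components) grid cell.

    Returns one row per cell with the four metric means and SDs.  The
    default grids give 6 x 9 = 54 cells.
    """
    if not neighbors_grid or not dims_grid:
        raise ValueError("sweep grids must be non-empty")
    rows = []
    for nn in neighbors_grid:
        for dim in dims_grid:
            params = UMAPParams(n_neighbors=nn, n_components=dim, seed=umap_seed)
            emb = embed_umap(X, params)
            metrics = evaluate_classifier(emb, y, protocol)
            rows.append(
                {"n_neighbors": nn, "n_components": dim, **metrics.summary()}
            )
    table = pd.DataFrame(rows)
    if sort_by_f1:
        table = table.sort_values("f1_mean", ascending=False, ignore_index=True)
    return table


def classify_by_colony(
    X: np.ndarray,
    meta: pd.DataFrame,
    label: str = "temperature",
    umap_params: UMAPParams = UMAPParams(),
    protocol: EvalProtocol = EvalProtocol(),
) -> pd.DataFrame:
    """Run raw and UMAP-preprocessed evaluation separately per colony.

    Returns the four-row table (gray/yellow x raw/umap) with columns
    group, preprocessing, <metric>_mean, <metric>_sd.
    """
    from .coloration_index import validate_metadata

    meta = validate_metadata(meta)
    if len(meta) != X.shape[0]:
        raise ValueError("metadata rows must match profile rows")
    rows = []
    for colony in ("gray", "yellow"):
        sel = (meta["colony"] == colony).to_numpy()
        if not sel.any():
            continue
        Xc = X[sel]
        yc = meta.loc[sel, label].to_numpy()
        for preprocess in ("raw", "umap"):
            metrics = classify_profiles(
                Xc, yc, preprocess=preprocess, umap_params=umap_params,
                protocol=protocol,
            )
            rows.append(
                {"group": colony, "preprocessing": preprocess, **metrics.summary()}
            )
    return pd.DataFrame(rows)


class UmapLinearSVM(BaseEstimator, ClassifierMixin):
    """UMAP embedding followed by a linear-kernel SVM, as one estimator.

    scikit-learn compatible (``get_params``/``set_params``, ``fit``,
    ``predict``, ``decision_function``), so it drops into pipelines and
    model-selection utilities.  Fitting embeds the training data and fits
    the SVM in the embedded space; prediction maps new samples through the
    fitted UMAP transform.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of the two class labels
    embedding_ : ndarray, training embedding (n_samples, n_components)
    umap_ : the fitted UMAP reducer
    svm_ : the fitted SVC
    """

    def __init__(
        self,
        n_neighbors: int = 75,
        n_components: int = 2,
        min_dist: float = 0.1,
        metric: str = "euclidean",
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.n_components = n_components
        self.min_dist = min_dist
        self.metric = metric
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        import umap

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.n_neighbors >= X.shape[0]:
            raise ValueError("n_neighbors must be < n_samples")
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*random_state.*")
            warnings.filterwarnings("ignore", message=".*n_jobs value.*")
            self.umap_ = umap.UMAP(
                n_neighbors=self.n_neighbors,
                n_components=self.n_components,
                min_dist=self.min_dist,
                metric=self.metric,
                random_state=self.random_state,
            )
            self.embedding_ = np.asarray(self.umap_.fit_transform(X), dtype=float)
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(self.embedding_, y)
        self.classes_ = self.svm_.classes_
        return self

    def _transform(self, X):
        check_is_fitted(self, "umap_")
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*random_state.*")
            return np.asarray(self.umap_.transform(np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.svm_.predict(self._transform(X))

    def decision_function(self, X):
        return self.svm_.decision_function(self._transform(X))
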