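"""Cross-validation protocols and the accuracy metric.

Provides leave-one-out and repeated k-fold cross-validation of the full
pipeline (per-fold gene filter -> sparse random projection -> CRC or SRC),
plus the reduced-dimension sweep that maps target dimension M to mean
accuracy.

Leakage note: by default the differential-expression filter is refit on the
training portion of every fold.  A ``"global"`` filter scope that fits the
filter once on the complete dataset is also available; it reproduces the
common practice of prefiltering a published matrix before any splitting, at
the cost of mild selection leakage.  The projection matrix is data
independent, so sharing it across folds leaks nothing.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import build_dictionary, classify_crc, classify_src, fit_crc
from .data_io import LabeledExpressionSet
from .preprocess import apply_filter, t_test_filter
from .projection import make_sparse_projection

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "PipelineConfig",
    "accuracy",
    "loocv",
    "kfold_cv",
    "dimension_sweep",
    "derive_seed",
]


def derive_seed(seed: int, name: str, index: int = 0) -> int:
    """Expand one experiment seed into independent named sub-streams.

    Deterministic, collision-resistant (SeedSequence over the root seed, a
    CRC32 of the stream name, and an index), and always below 2**31.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode()), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionCounts:
    """Correct/total tallies per class; the binary TP/TN/FP/FN view maps
    class 0 to "positive" and class 1 to "negative"."""

    per_class_correct: np.ndarray
    per_class_total: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.per_class_correct = np.asarray(self.per_class_correct, dtype=int)
        self.per_class_total = np.asarray(self.per_class_total, dtype=int)
        if np.any(self.per_class_correct < 0) or np.any(self.per_class_total < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.per_class_correct > self.per_class_total):
            raise ValueError("correct counts exceed totals")

    @classmethod
    def binary(cls, TP: int, TN: int, FP: int, FN: int,
               class_names: Sequence[str] = ("positive", "negative")) -> "ConfusionCounts":
        return cls(per_class_correct=np.array([TP, TN]),
                   per_class_total=np.array([TP + FN, TN + FP]),
                   class_names=list(class_names))

    @property
    def n_evaluated(self) -> int:
        return int(self.per_class_total.sum())

    def add_outcome(self, class_index: int, correct: bool) -> None:
        self.per_class_total[class_index] += 1
        if correct:
            self.per_class_correct[class_index] += 1

    def per_class_recall(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.per_class_correct / self.per_class_total


def accuracy(counts: ConfusionCounts) -> float:
    """Overall fraction of correctly labeled samples.

    For two classes this is (TP + TN) / (TP + FN + TN + FP); for more it is
    the same overall-correct fraction generalized across classes.
    """
    total = counts.n_evaluated
    if total == 0:
        raise ValueError("no evaluated samples: accuracy undefined")
    return float(counts.per_class_correct.sum()) / total


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to rerun a cross-validated experiment.

    Parameters
    ----------
    alpha
        Significance level of the per-fold gene prefilter; ``None`` disables
        filtering.
    filter_scope
        ``"fold"`` refits the filter on each training fold (default);
        ``"global"`` fits it once on the full dataset.
    projection_dim
        Target dimension M of the sparse random projection; ``None`` keeps
        the original features.
    rho, projection_scaling
        Sparsity parameter and scaling mode of the sensing matrix.
    redraw_projection
        Redraw the sensing matrix on every CV repetition instead of sharing
        one draw across the experiment.
    lam
        CRC ridge parameter lambda (> 0).
    classifier
        ``"crc"`` or ``"src"``.
    """

    alpha: float | None = None
    filter_scope: str = "fold"
    equal_var: bool = False
    projection_dim: int | None = None
    rho: float = 3.0
    projection_scaling: str = "unbiased"
    redraw_projection: bool = False
    lam: float = 1e-3
    classifier: str = "crc"
    omp_max_nonzeros: int | None = None
    omp_tol: float = 1e-6
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.classifier not in ("crc", "src"):
            raise ValueError(f"classifier must be 'crc' or 'src', got {self.classifier!r}")
        if self.filter_scope not in ("fold", "global"):
            raise ValueError(f"filter_scope must be 'fold' or 'global'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CVResult:
    """Cross-validation outcome with enough metadata to reproduce it."""

    scheme: str
    k: int | None
    repeats: int
    per_repeat_accuracy: list[float]
    mean_accuracy: float
    seed: int
    config: dict
    confusion: ConfusionCounts | None = None

    def to_json_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "k": self.k,
            "repeats": self.repeats,
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "seed": self.seed,
            "config": self.config,
        }
        if self.confusion is not None:
            d["per_class_correct"] = self.confusion.per_class_correct.tolist()
            d["per_class_total"] = self.confusion.per_class_total.tolist()
            d["class_names"] = self.confusion.class_names
        return d


# ---------------------------------------------------------------------------
# per-fold pipeline
# ---------------------------------------------------------------------------

def _fit_fold_predictor(train: LabeledExpressionSet, cfg: PipelineConfig,
                        proj_seed: int):
    """Fit filter+projection+classifier on a training fold.

    Returns ``predict(raw_vector) -> label`` operating on full-length
    feature vectors.  When the target dimension exceeds the post-filter
    feature count, M is capped at that count (with a warning).
    """
    kept = None
    if cfg.alpha is not None:
        filt = t_test_filter(train, alpha=cfg.alpha, equal_var=cfg.equal_var)
        if filt.n_kept == 0:
            logger.warning("gene filter kept no features; using all features")
        else:
            kept = filt.kept_indices
            train = apply_filter(train, filt)

    proj = None
    if cfg.projection_dim is not None:
        M = cfg.projection_dim
        if M > train.n_features:
            logger.warning("projection dim %d exceeds %d available features; "
                           "capping", M, train.n_features)
            M = train.n_features
        proj = make_sparse_projection(train.n_features, M, rho=cfg.rho,
                                      seed=proj_seed,
                                      scaling=cfg.projection_scaling)

    dictionary = build_dictionary(train, proj)
    model = fit_crc(dictionary, cfg.lam) if cfg.classifier == "crc" else None

    def predict(raw: np.ndarray) -> str:
        y = np.asarray(raw, dtype=float).ravel()
        if kept is not None:
            y = y[kept]
        if proj is not None:
            from .projection import apply_projection
            y = apply_projection(proj, y)
        if model is not None:
            return classify_crc(model, y).predicted_class
        return classify_src(dictionary, y,
                            max_nonzeros=cfg.omp_max_nonzeros,
                            residual_tol=cfg.omp_tol).predicted_class

    return predict


def _maybe_global_filter(data: LabeledExpressionSet,
                         cfg: PipelineConfig) -> tuple[LabeledExpressionSet, PipelineConfig]:
    if cfg.alpha is not None and cfg.filter_scope == "global":
        filt = t_test_filter(data, alpha=cfg.alpha, equal_var=cfg.equal_var)
        if filt.n_kept == 0:
            logger.warning("global gene filter kept no features; using all")
        else:
            data = apply_filter(data, filt)
        cfg = dataclasses.replace(cfg, alpha=None)
    return data, cfg


def _check_classes(data: LabeledExpressionSet) -> None:
    idx = data.label_indices()
    for k, name in enumerate(data.class_names):
        if int(np.sum(idx == k)) == 1:
            logger.warning("class %r has a single sample; it can never be "
                           "classified correctly under LOOCV", name)


# ---------------------------------------------------------------------------
# CV schemes
# ---------------------------------------------------------------------------

def loocv(data: LabeledExpressionSet, config: PipelineConfig | None = None,
          seed: int = 0, repeats: int = 1) -> CVResult:
    """Leave-one-out cross-validation of the configured pipeline.

    Deterministic for a fixed projection; ``repeats > 1`` is only useful
    together with ``redraw_projection`` (each repetition then sees a fresh
    sensing matrix).
    """
    cfg = config or PipelineConfig()
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples for LOOCV")
    _check_classes(data)
    data, fold_cfg = _maybe_global_filter(data, cfg)
    n = data.n_samples
    classes = data.class_names
    label_idx = data.label_indices()
    confusion = ConfusionCounts(np.zeros(len(classes), dtype=int),
                                np.zeros(len(classes), dtype=int), classes)
    per_repeat = []
    for rep in range(repeats):
        proj_seed = derive_seed(seed, "projection",
                                rep if cfg.redraw_projection else 0)
        correct = 0
        for j in range(n):
            train = data.subset_samples([i for i in range(n) if i != j])
            predict = _fit_fold_predictor(train, fold_cfg, proj_seed)
            ok = predict(data.values[:, j]) == data.labels[j]
            correct += ok
            confusion.add_outcome(label_idx[j], ok)
        per_repeat.append(correct / n)
    return CVResult(scheme="loocv", k=None, repeats=repeats,
                    per_repeat_accuracy=per_repeat,
                    mean_accuracy=float(np.mean(per_repeat)), seed=seed,
                    config=cfg.to_dict(), confusion=confusion)


def kfold_cv(data: LabeledExpressionSet, k: int = 10, repeats: int = 100,
             seed: int = 0, config: PipelineConfig | None = None) -> CVResult:
    """Repeated (default 100x) stratified k-fold cross-validation.

    Each repetition reshuffles samples into k near-equal folds; each fold is
    held out once and the per-repetition accuracy pools all n predictions.
    """
    cfg = config or PipelineConfig()
    n = data.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    _check_classes(data)
    data, fold_cfg = _maybe_global_filter(data, cfg)
    classes = data.class_names
    label_idx = data.label_indices()
    confusion = ConfusionCounts(np.zeros(len(classes), dtype=int),
                                np.zeros(len(classes), dtype=int), classes)
    per_repeat = []
    for rep in range(repeats):
        rep_seed = derive_seed(seed, "folds", rep)
        proj_seed = derive_seed(seed, "projection",
                                rep if cfg.redraw_projection else 0)
        if cfg.stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=rep_seed)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        correct = 0
        for train_idx, test_idx in splitter.split(np.zeros(n), label_idx):
            train = data.subset_samples(train_idx)
            if len(set(train.labels)) < len(classes):
                logger.warning("a training fold lost an entire class")
            predict = _fit_fold_predictor(train, fold_cfg, proj_seed)
            for j in test_idx:
                ok = predict(data.values[:, j]) == data.labels[j]
                correct += ok
                confusion.add_outcome(label_idx[j], ok)
        per_repeat.append(correct / n)
    return CVResult(scheme="kfold", k=k, repeats=repeats,
                    per_repeat_accuracy=per_repeat,
                    mean_accuracy=float(np.mean(per_repeat)), seed=seed,
                    config=cfg.to_dict(), confusion=confusion)


def dimension_sweep(data: LabeledExpressionSet, dims: Sequence[int],
                    config: PipelineConfig | None = None, seed: int = 0,
                    repeats: int = 1, scheme: str = "loocv",
                    k: int = 10) -> pd.DataFrame:
    """Mean CV accuracy as a function of the reduced dimension M.

    Duplicated dims are dropped (with a warning); dims exceeding the number
    of available (post-filter) features are skipped.  Returns a two-column
    frame ``(M, mean_accuracy)`` ordered by M.
    """
    cfg = config or PipelineConfig()
    uniq = sorted(set(int(d) for d in dims))
    if len(uniq) < len(dims):
        logger.warning("duplicate dims removed: %s", sorted(dims))
    if cfg.alpha is not None:
        n_avail = t_test_filter(data, alpha=cfg.alpha,
                                equal_var=cfg.equal_var).n_kept
        if n_avail == 0:
            n_avail = data.n_features
    else:
        n_avail = data.n_features
    rows = []
    for M in uniq:
        if M > n_avail:
            logger.warning("skipping M=%d > %d available features", M, n_avail)
            continue
        cfg_m = dataclasses.replace(cfg, projection_dim=M)
        if scheme == "loocv":
            res = loocv(data, cfg_m, seed=seed, repeats=repeats)
        elif scheme == "kfold":
            res = kfold_cv(data, k=k, repeats=repeats, seed=seed, config=cfg_m)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        rows.append({"M": M, "mean_accuracy": res.mean_accuracy})
    return pd.DataFrame(rows, columns=["M", "mean_accuracy"])
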