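"""Preprocessing: differential-expression prefilter, log transform, scaling.

The prefilter keeps genes whose per-feature test of a class-mean difference
is significant at level ``alpha`` (default 0.05).  For two classes this is a
two-sided two-sample t-test (Welch by default); for more classes a one-way
ANOVA F-test at the same level.  No multiple-testing correction is applied
by default; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import LabeledExpressionSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureFilterResult",
    "t_test_filter",
    "apply_filter",
    "log_transform",
    "normalize_columns",
]


@dataclasses.dataclass
class FeatureFilterResult:
    """Outcome of the per-feature significance filter.

    ``kept_indices`` is strictly increasing (original feature order is
    preserved); a feature is kept iff its p-value is below ``alpha``.
    """

    kept_indices: np.ndarray
    p_values: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    def to_frame(self):
        """Two-column table (feature index, p-value) for export."""
        import pandas as pd

        return pd.DataFrame(
            {"feature_index": np.arange(len(self.p_values)),
             "p_value": self.p_values,
             "kept": np.isin(np.arange(len(self.p_values)), self.kept_indices)}
        )


def t_test_filter(
    data: LabeledExpressionSet,
    alpha: float = 0.05,
    equal_var: bool = False,
    correction: str = "none",
) -> FeatureFilterResult:
    """Per-feature class-difference filter at significance level ``alpha``.

    Parameters
    ----------
    data
        Expression set with K >= 2 classes, each holding >= 2 samples.
    alpha
        Raw significance level; features with p < alpha are kept.
    equal_var
        Use the pooled-variance (Student) t-test instead of Welch. Only
        meaningful for K = 2.
    correction
        ``"none"`` (raw p-values) or ``"bh"`` (Benjamini-Hochberg adjusted
        p-values compared against the same alpha).

    Features with zero variance in every class get p = 1 and are never kept.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    classes = data.class_names
    if len(classes) < 2:
        raise ValueError("need at least two classes to filter")
    idx = data.label_indices()
    groups = []
    for k, name in enumerate(classes):
        cols = np.nonzero(idx == k)[0]
        if len(cols) < 2:
            raise ValueError(
                f"class {name!r} has {len(cols)} sample(s); "
                "need >= 2 per class to estimate variance"
            )
        groups.append(data.values[:, cols])

    with np.errstate(divide="ignore", invalid="ignore"):
        if len(groups) == 2:
            _, p = stats.ttest_ind(groups[0], groups[1], axis=1,
                                   equal_var=equal_var)
        else:
            _, p = stats.f_oneway(*groups, axis=1)
    p = np.asarray(p, dtype=float)
    # constant features yield nan statistics; define them as uninformative
    p[~np.isfinite(p)] = 1.0

    p_decide = p
    if correction == "bh":
        p_decide = stats.false_discovery_control(p, method="bh")
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    kept = np.nonzero(p_decide < alpha)[0]
    return FeatureFilterResult(kept_indices=kept, p_values=p, alpha=alpha)


def apply_filter(
    data: LabeledExpressionSet, result: FeatureFilterResult
) -> LabeledExpressionSet:
    """Restrict ``data`` to the kept features, preserving order."""
    return data.subset_features(result.kept_indices)


def log_transform(data: LabeledExpressionSet) -> LabeledExpressionSet:
    """Apply log2(x + 1) cellwise, the standard transform for RPKM units."""
    if np.any(data.values < 0):
        raise ValueError("log2(x+1) transform requires non-negative values")
    return LabeledExpressionSet(
        np.log2(data.values + 1.0),
        list(data.feature_ids),
        list(data.sample_ids),
        list(data.labels),
    )


def normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Scale every column to unit Euclidean norm.

    Zero columns are left as zeros (with a logged warning); they carry no
    information and contribute nothing to any linear coding.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    norms = np.linalg.norm(matrix, axis=0)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero column(s) left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    return matrix / safe


def normalize_vector(y: np.ndarray) -> np.ndarray:
    """Unit-normalize a single query vector (zero vectors pass through)."""
    y = np.asarray(y, dtype=float).ravel()
    n = np.linalg.norm(y)
    return y if n == 0 else y / n
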