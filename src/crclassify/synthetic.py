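"""Synthetic expression-like datasets and sparse-signal fixtures.

The generator emulates the shape of classic microarray / RNA-seq benchmark
matrices: a handful of classes, tens to hundreds of samples, hundreds to
thousands of features, of which only a small informative subset carries
class-mean shifts on top of i.i.d. Gaussian noise.  An optional low-rank
mode routes all signal and structure through ``redundancy_rank`` latent
factors, producing the highly coherent, compressible data for which random
projection to very few dimensions loses almost nothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import LabeledExpressionSet

__all__ = ["SyntheticSpec", "generate_dataset", "generate_sparse_signal"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of a synthetic labeled expression set.

    Parameters
    ----------
    n_classes, samples_per_class
        Class count K >= 2 and per-class sample counts (an int is expanded
        to all classes).
    n_features, n_informative
        Total feature count and the number carrying class signal.
    effect_size
        Class-mean separation on informative features, in units of
        ``noise_sigma``.  For two classes every informative feature is
        shifted by exactly ``effect_size * noise_sigma`` between the
        classes; for K > 2 the class centers sit on a regular simplex scaled
        so the root-mean-square per-feature gap equals the same quantity for
        every class pair.
    noise_sigma
        Standard deviation of the additive Gaussian noise.
    baseline_range
        Per-gene constant expression levels, drawn once uniformly from this
        interval and shared by all classes.  Real intensity data sit on a
        large positive gene-specific baseline; without one, two-class
        centers would be mirror images through the origin, a degenerate
        geometry that unit normalization collapses onto a single signed
        direction and that no intensity-like dataset exhibits.
    redundancy_rank
        If set, the noiseless signal is confined to this many latent
        dimensions: data = loadings (n_features x r) @ factors (r x n)
        + noise, with class structure living in the factors.
    distribution
        ``"gaussian"`` (default) or ``"lognormal"``, which exponentiates the
        Gaussian field base-2 to mimic right-skewed intensity data.
    """

    n_classes: int = 2
    samples_per_class: int | list[int] = 20
    n_features: int = 500
    n_informative: int = 20
    effect_size: float = 5.0
    noise_sigma: float = 1.0
    baseline_range: tuple[float, float] = (2.0, 8.0)
    redundancy_rank: int | None = None
    seed: int = 0
    distribution: str = "gaussian"

    def counts(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        return list(self.samples_per_class)

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if any(c < 1 for c in self.counts()):
            raise ValueError("every class needs at least one sample")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        lo, hi = self.baseline_range
        if lo > hi:
            raise ValueError("baseline_range must be (low, high) with low <= high")
        if self.redundancy_rank is not None and not (
            1 <= self.redundancy_rank <= self.n_features
        ):
            raise ValueError("redundancy_rank must lie in [1, n_features]")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def _simplex_centers(K: int, dim: int, pair_distance: float,
                     rng: np.random.Generator) -> np.ndarray:
    """K points in R^dim with all pairwise distances == pair_distance.

    Vertices of a regular simplex, randomly rotated into the target space
    (requires dim >= K - 1; we embed via K axes and center, which spans a
    (K-1)-dimensional affine set).
    """
    if dim < K - 1:
        raise ValueError(f"need at least {K - 1} dimensions for {K} "
                         "equidistant class centers")
    # e_i / sqrt(2) are pairwise at distance 1; center, then rotate
    V = np.eye(K) / np.sqrt(2.0)
    V -= V.mean(axis=0, keepdims=True)
    # random orthonormal embedding of R^K into R^dim
    A = rng.standard_normal((dim, K))
    Q, _ = np.linalg.qr(A)
    return pair_distance * (Q @ V.T).T  # K x dim


def generate_dataset(spec: SyntheticSpec) -> LabeledExpressionSet:
    """Draw a labeled expression set; bit-identical for the same seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    n = sum(counts)
    K = spec.n_classes
    labels = []
    for k, c in enumerate(counts):
        labels += [f"class{k}"] * c
    label_idx = np.repeat(np.arange(K), counts)

    gap = spec.effect_size * spec.noise_sigma

    if spec.redundancy_rank is None:
        means = np.zeros((spec.n_features, n))
        if spec.n_informative > 0 and spec.effect_size != 0:
            if K == 2:
                # exact per-feature gap, random sign per feature
                signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
                centers = np.outer(np.array([0.5, -0.5]), np.ones(spec.n_informative))
                centers *= gap * signs  # K x n_informative
            else:
                # RMS per-feature gap == gap for every class pair
                centers = _simplex_centers(
                    K, spec.n_informative,
                    gap * np.sqrt(spec.n_informative), rng)
            means[: spec.n_informative, :] = centers[label_idx].T
        lo, hi = spec.baseline_range
        baseline = rng.uniform(lo, hi, size=spec.n_features)
        values = baseline[:, None] + means + spec.noise_sigma * rng.standard_normal(
            (spec.n_features, n))
    else:
        r = spec.redundancy_rank
        # latent factors: class centers on a simplex in R^r plus latent
        # within-class noise at noise_sigma, all riding on a shared latent
        # baseline so the rank-r structure dominates; observed noise is
        # full rank, also at noise_sigma
        if K == 2:
            direction = rng.standard_normal(r)
            direction /= np.linalg.norm(direction)
            centers = np.outer(np.array([0.5, -0.5]) * gap, direction)
        else:
            centers = _simplex_centers(K, r, gap, rng)
        offset = rng.standard_normal(r)
        offset *= 4.0 * max(gap, 1.0) / np.linalg.norm(offset)
        T = (offset[:, None] + centers[label_idx].T
             + spec.noise_sigma * rng.standard_normal((r, n)))
        A = rng.standard_normal((spec.n_features, r))
        Q, _ = np.linalg.qr(A)  # orthonormal loadings
        values = Q @ T + spec.noise_sigma * rng.standard_normal(
            (spec.n_features, n))

    if spec.distribution == "lognormal":
        values = np.exp2(values)

    feature_ids = [f"G{i + 1}" for i in range(spec.n_features)]
    sample_ids = [f"S{j + 1}" for j in range(n)]
    return LabeledExpressionSet(values, feature_ids, sample_ids, labels)


def generate_sparse_signal(
    N: int, K: int, amplitude_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A length-N vector with exactly K nonzero entries, plus its support.

    Nonzero magnitudes are uniform in ``amplitude_range`` with random sign;
    the sorted support indices are returned for oracle comparisons.
    """
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    lo, hi = amplitude_range
    if not 0 < lo <= hi:
        raise ValueError("amplitude_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    support = np.sort(rng.choice(N, size=K, replace=False))
    x = np.zeros(N)
    if K:
        mags = rng.uniform(lo, hi, size=K)
        signs = rng.choice([-1.0, 1.0], size=K)
        x[support] = mags * signs
    return x, support
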