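"""Feature scoring (chi-squared + Relief) and metaheuristic weight optimization.

The weighted-feature objective maximized over the per-feature weight vector
``w`` (each entry in [0.01, 0.99]) is

    TL(w) = mean_f[ chi2_f(X·diag(w)) / n ] + mean_f[ relief_f(X·diag(w)) ],

the sum of a chi-squared association term (discretized feature vs class) and
a deterministic Relief relevance term. Both terms are *anchored*: bin edges
(10 equal-width bins over the unweighted training range) and the Relief
normalization ranges are computed once from the unweighted training data and
held fixed, so that rescaling a column by its weight genuinely moves the
objective — under per-evaluation re-normalization the objective would be
scale-invariant and the optimization degenerate. The chi-squared term is
divided by the sample count to put it on a bounded scale comparable to Relief.

The Relief variant is deterministic: every sample serves once as the pivot;
its nearest hit (same class) and nearest miss (other class) are found by
Euclidean distance over all anchored-normalized features jointly, ties broken
toward the lowest sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hydrosoil.data import LabeledTable
from hydrosoil.iemoa import IEMOAConfig, OptimizationResult, SearchSpace, optimize

__all__ = [
    "WeightVector",
    "WeightAnchors",
    "WEIGHT_LOWER",
    "WEIGHT_UPPER",
    "chi_squared_feature_score",
    "relief_scores",
    "make_anchors",
    "weighting_objective",
    "optimize_feature_weights",
    "apply_weights",
]

WEIGHT_LOWER = 0.01
WEIGHT_UPPER = 0.99
N_BINS = 10


@dataclass(frozen=True)
class WeightVector:
    """One multiplicative weight per feature, each in [0.01, 0.99]."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < WEIGHT_LOWER) or np.any(w > WEIGHT_UPPER):
            raise ValueError(f"every weight must lie in [{WEIGHT_LOWER}, {WEIGHT_UPPER}]")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class WeightAnchors:
    """Fixed discretization/normalization state from the unweighted training data.

    ``bin_edges[f]`` are the absolute chi-squared bin edges for feature f;
    ``ranges[f]`` is the Relief normalization range (max − min). Both refer to
    the *unweighted* matrix and are reused unchanged for every weighted
    evaluation.
    """

    bin_edges: tuple[np.ndarray, ...]
    ranges: np.ndarray


def chi_squared_feature_score(values, labels, bin_edges) -> float:
    """Chi-squared statistic Σ (O−E)²/E of a discretized feature vs the class.

    Values are binned against ``bin_edges`` (left-closed, right-open; final bin
    right-closed; out-of-range values clipped into the extreme bins). Rows and
    columns of the contingency table with zero marginals are dropped before the
    sum. Degenerate inputs (single class, fewer than two non-empty bins) score
    0 with a warning rather than raising.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        warnings.warn("chi-squared undefined for a single class; returning 0")
        return 0.0
    n_bins = edges.size - 1
    bins = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    obs = np.zeros((n_bins, classes.size))
    np.add.at(obs, (bins, y), 1.0)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        warnings.warn("fewer than 2 non-empty bins/classes; chi-squared degenerate, returning 0")
        return 0.0
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(np.sum((obs - expected) ** 2 / expected))


def relief_scores(features, labels, ranges) -> np.ndarray:
    """Deterministic Relief: per-feature mean of |pivot − miss| − |pivot − hit|.

    Each sample is the pivot once; the nearest hit/miss are found by Euclidean
    distance over all range-normalized features, excluding the pivot, ties
    broken toward the lowest index. Differences are divided by ``ranges`` so
    scores land in [−1, 1]; zero-range features score exactly 0. Pivots whose
    class has a single member are skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    ranges = np.asarray(ranges, dtype=float)
    n, d = X.shape
    safe = np.where(ranges > 0, ranges, 1.0)
    Xn = X / safe
    Xn[:, ranges <= 0] = 0.0

    _, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y)
    if counts.size < 2:
        raise ValueError("relief requires at least 2 classes")

    # full pairwise distances; desk-scale n makes the O(n^2 d) cost trivial
    diff = Xn[:, None, :] - Xn[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(dist, np.inf)

    scores = np.zeros(d)
    n_pivots = 0
    same = y[:, None] == y[None, :]
    for i in range(n):
        if counts[y[i]] < 2:
            warnings.warn(f"sample {i} is its class's only member; skipped as pivot")
            continue
        row = dist[i]
        hit = int(np.argmin(np.where(same[i], row, np.inf)))
        miss = int(np.argmin(np.where(~same[i], row, np.inf)))
        scores += np.abs(Xn[i] - Xn[miss]) - np.abs(Xn[i] - Xn[hit])
        n_pivots += 1
    if n_pivots == 0:
        raise ValueError("relief requires at least 2 samples in some class")
    scores /= n_pivots
    scores[ranges <= 0] = 0.0
    return scores


def make_anchors(table: LabeledTable, n_bins: int = N_BINS) -> WeightAnchors:
    """Equal-width bin edges and normalization ranges from unweighted data."""
    X = table.features
    edges = []
    for f in range(X.shape[1]):
        lo, hi = X[:, f].min(), X[:, f].max()
        if hi <= lo:
            hi = lo + 1.0  # constant column: arbitrary unit-width bins, scores 0 anyway
        edges.append(np.linspace(lo, hi, n_bins + 1))
    ranges = X.max(axis=0) - X.min(axis=0)
    return WeightAnchors(bin_edges=tuple(edges), ranges=ranges)


def weighting_objective(
    weights: WeightVector, table: LabeledTable, anchors: WeightAnchors
) -> float:
    """The anchored chi-squared + Relief objective TL(w) (larger is better)."""
    w = weights.weights
    if len(w) != table.n_features or len(anchors.bin_edges) != table.n_features:
        raise ValueError("weights/anchors do not conform to the table's feature count")
    Xw = table.features * w
    n = table.n_samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi = np.array([
            chi_squared_feature_score(Xw[:, f], table.labels, anchors.bin_edges[f])
            for f in range(table.n_features)
        ])
        relief = relief_scores(Xw, table.labels, anchors.ranges)
    return float(np.mean(chi / n) + np.mean(relief))


def optimize_feature_weights(
    table: LabeledTable, iemoa_config: IEMOAConfig | None = None,
    anchors: WeightAnchors | None = None,
) -> tuple[WeightVector, OptimizationResult]:
    """Maximize the anchored objective over [0.01, 0.99]^n_features with IEMOA."""
    if iemoa_config is None:
        iemoa_config = IEMOAConfig()
    if anchors is None:
        anchors = make_anchors(table)
    space = SearchSpace.box(WEIGHT_LOWER, WEIGHT_UPPER, table.n_features)
    cfg = IEMOAConfig(
        population_size=iemoa_config.population_size,
        max_iterations=iemoa_config.max_iterations,
        seed=iemoa_config.seed,
        minimize=False,
    )
    result = optimize(lambda w: weighting_objective(WeightVector(w), table, anchors), space, cfg)
    return WeightVector(result.best_position), result


def apply_weights(table: LabeledTable, weights: WeightVector) -> LabeledTable:
    """Columnwise multiply: the weighted feature matrix WF = X · diag(w)."""
    if len(weights) != table.n_features:
        raise ValueError("weight vector length does not match feature count")
    return table.with_features(table.features * weights.weights)
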