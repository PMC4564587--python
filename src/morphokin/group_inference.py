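"""Between-population shape inference: Procrustes distance matrices with
permutation significance, and leave-one-out cross-validated discriminant
classification of specimens into populations from PC scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import DistanceMatrix
from .procrustes import ProcrustesResults, procrustes_distance

__all__ = [
    "population_distance_matrix",
    "PermutedDistanceResult",
    "pairwise_permutation_test",
    "ConfusionMatrix",
    "lda_loocv",
]


def _group_indices(labels) -> tuple[list[str], list[np.ndarray]]:
    labels = [str(l) for l in labels]
    uniq: list[str] = []
    for l in labels:
        if l not in uniq:
            uniq.append(l)
    arr = np.asarray(labels)
    return uniq, [np.flatnonzero(arr == g) for g in uniq]


def _mean_shape(aligned: np.ndarray, idx: np.ndarray) -> np.ndarray:
    m = aligned[idx].mean(axis=0)
    m = m - m.mean(axis=0)
    return m / np.sqrt((m**2).sum())


def population_distance_matrix(sample: ProcrustesResults, labels=None) -> DistanceMatrix:
    """Pairwise Procrustes distances between population mean shapes.

    Each group's mean of aligned coordinates is re-normalised to unit
    centroid size (keeping it in shape space) before between-mean distances
    are computed.
    """
    if labels is None:
        labels = sample.populations
        if labels is None:
            raise ValueError("sample carries no population labels; pass labels=")
    if len(labels) != sample.n_specimens:
        raise ValueError("one label per specimen required")
    groups, indices = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means = [_mean_shape(sample.aligned, idx) for idx in indices]
    n = len(groups)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = procrustes_distance(means[i], means[j])
    return DistanceMatrix(groups, d)


@dataclass
class PermutedDistanceResult:
    """Pairwise population distances with permutation p-values.

    ``p_values`` is aligned with ``matrix.labels``; the upper triangle is
    meaningful (the matrix is symmetric, diagonal NaN).
    """

    matrix: DistanceMatrix
    p_values: np.ndarray
    n_perm: int
    seed: int

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        out = []
        labels = self.matrix.labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if self.p_values[i, j] < alpha:
                    out.append((labels[i], labels[j]))
        return out

    def summary(self, alpha: float = 0.05) -> str:
        labels = self.matrix.labels
        lines = [
            f"Pairwise population Procrustes distances "
            f"({self.n_perm} permutations; * p < {alpha:g})"
        ]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                star = " *" if self.p_values[i, j] < alpha else ""
                lines.append(
                    f"  {labels[i]} - {labels[j]}: "
                    f"d = {self.matrix.values[i, j]:.4f}, "
                    f"p = {self.p_values[i, j]:.4f}{star}"
                )
        return "\n".join(lines)


def pairwise_permutation_test(
    sample: ProcrustesResults,
    labels=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutedDistanceResult:
    """Permutation significance of every pairwise between-mean distance.

    For each pair of populations the two groups are pooled, group labels are
    reshuffled preserving group sizes, and the between-mean Procrustes
    distance is recomputed; the one-sided p-value is
    ``(1 + #{permuted >= observed}) / (1 + n_perm)`` (add-one convention, so
    the smallest attainable p is ``1/(n_perm+1)``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if labels is None:
        labels = sample.populations
        if labels is None:
            raise ValueError("sample carries no population labels; pass labels=")
    groups, indices = _group_indices(labels)
    for g, idx in zip(groups, indices):
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    matrix = population_distance_matrix(sample, labels)
    rng = np.random.default_rng(seed)
    n = len(groups)
    p = np.full((n, n), np.nan)
    aligned = sample.aligned
    for i in range(n):
        for j in range(i + 1, n):
            pool = np.concatenate([indices[i], indices[j]])
            n_i = indices[i].size
            observed = matrix.values[i, j]
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                d = procrustes_distance(
                    _mean_shape(aligned, perm[:n_i]),
                    _mean_shape(aligned, perm[n_i:]),
                )
                if d >= observed - 1e-12:
                    count += 1
            p[i, j] = p[j, i] = (1 + count) / (1 + n_perm)
    return PermutedDistanceResult(matrix=matrix, p_values=p, n_perm=n_perm, seed=seed)


class ConfusionMatrix:
    """Cross-validated classification counts in population-table layout.

    Rows are true populations, columns predicted; the per-group percent
    correct column comes first in the tabular rendering.
    """

    def __init__(self, labels, counts):
        self.labels = [str(l) for l in labels]
        self.counts = np.asarray(counts, dtype=int)
        g = len(self.labels)
        if self.counts.shape != (g, g):
            raise ValueError("counts must be square and match labels")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_group_pct(self) -> np.ndarray:
        totals = self.row_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * np.diag(self.counts) / totals, np.nan)

    @property
    def overall_pct(self) -> float:
        return float(100.0 * np.trace(self.counts) / self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.insert(0, "% Correct", np.round(self.per_group_pct, 1))
        df["Total"] = self.row_totals
        return df

    def summary(self) -> str:
        return (
            self.to_dataframe().to_string()
            + f"\n\n{self.overall_pct:.1f}% of cross-validated grouped cases "
            "correctly classified."
        )


def lda_loocv(
    scores: np.ndarray,
    labels,
    n_components: int | None = None,
    variance_fractions=None,
    cumulative_variance: float = 0.95,
) -> ConfusionMatrix:
    """Leave-one-out cross-validated linear discriminant classification.

    A linear discriminant classifier (pooled within-group covariance) is
    refit with each specimen left out in turn and used to classify it.  The
    PC basis itself is computed once on the full sample and not refit per
    fold, mirroring discriminant analysis run on precomputed PC scores (a
    mild, documented leakage).

    Parameters
    ----------
    scores : (n, m) ndarray
        PC scores (or any feature matrix).
    labels : sequence of str
        Population label per specimen.  Groups of one specimen are excluded
        with a warning (they cannot be left out and refit).
    n_components : int, optional
        Number of leading score columns used.  Default: the leading columns
        covering ``cumulative_variance`` if ``variance_fractions`` is given,
        else all columns; always capped at n - g - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if scores.shape[0] != labels.size:
        raise ValueError("one label per row of scores required")

    groups, indices = _group_indices(labels)
    singletons = [g for g, idx in zip(groups, indices) if idx.size < 2]
    if singletons:
        warnings.warn(
            f"excluding single-specimen group(s) {singletons} from LOOCV",
            stacklevel=2,
        )
        keep = ~np.isin(labels, singletons)
        scores, labels = scores[keep], labels[keep]
        groups = [g for g in groups if g not in singletons]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 specimens")

    n, g = scores.shape[0], len(groups)
    if n_components is None:
        if variance_fractions is not None:
            csum = np.cumsum(np.asarray(variance_fractions, dtype=float))
            n_components = int(np.searchsorted(csum, cumulative_variance - 1e-12) + 1)
        else:
            n_components = scores.shape[1]
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    # the pooled covariance must be estimable in every fold
    n_components = min(n_components, scores.shape[1], n - g - 1)
    if n_components < 1:
        raise ValueError(
            f"sample too small for LOOCV LDA: n={n}, groups={g} leave no usable dimension"
        )
    x = scores[:, :n_components]

    label_order = sorted(groups)
    pos = {l: i for i, l in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(x[mask], labels[mask])
        pred = str(clf.predict(x[i : i + 1])[0])
        counts[pos[labels[i]], pos[pred]] += 1
    # present rows in first-appearance order of the input
    order = [label_order.index(g_) for g_ in groups]
    return ConfusionMatrix(
        [label_order[i] for i in order], counts[np.ix_(order, order)]
    )
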