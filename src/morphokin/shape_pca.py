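"""Tangent-space principal component analysis of superimposed shapes,
allometry/ontogeny regressions of PC scores, and morphing along PC axes.

After superimposition the aligned coordinates live close to a linear tangent
space at the consensus, where ordinary multivariate statistics apply.  PCA of
the flattened aligned coordinates yields axes of shape variation; regressing
PC scores on log centroid size (allometry) or numeric age (ontogeny) reveals
growth-related shape change; morphing the consensus along a component
visualises what shape change an axis encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .procrustes import ProcrustesResults

__all__ = ["ShapePCA", "ShapePCAResults", "fit_pca", "PCRegression", "regress_pc"]


@dataclass
class PCRegression:
    """Ordinary least-squares regression of one PC's scores on a covariate."""

    pc_index: int
    covariate: str
    scope: str
    r: float
    p: float | None
    slope: float
    intercept: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05

    def summary(self) -> str:
        ptxt = "NA (scope too small)" if self.p is None else f"{self.p:.4g}"
        return (
            f"PC{self.pc_index + 1} ~ {self.covariate} [{self.scope}]: "
            f"R = {self.r:.3f}, p = {ptxt}, slope = {self.slope:.4g}, n = {self.n}"
        )


class ShapePCAResults:
    """Principal components of shape variation about the consensus.

    Attributes
    ----------
    mean_shape : (K, 3) ndarray
        Centre of the PCA (the sample mean of the aligned coordinates).
    components : (m, 3K) ndarray
        Orthonormal axes in flattened shape space, ordered by variance.
    variance_fractions : (m,) ndarray
        Fraction of total variance per component (sums to 1 over the
        retained, non-null components).
    scores : (n, m) ndarray
        Specimen scores; columns have exactly zero mean.
    projection : str
        'procrustes_residuals' or 'orthogonal_tangent'.
    """

    def __init__(self, mean_shape, components, variance_fractions, scores, projection):
        self.mean_shape = np.asarray(mean_shape, dtype=float)
        self.components = np.asarray(components, dtype=float)
        self.variance_fractions = np.asarray(variance_fractions, dtype=float)
        self.scores = np.asarray(scores, dtype=float)
        self.projection = projection

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    def flagged_components(self, threshold: float = 0.05) -> list[int]:
        """Indices of components explaining more than ``threshold`` of variance
        (the conventional cut for which axes are worth visualising)."""
        return [i for i, f in enumerate(self.variance_fractions) if f > threshold]

    def scores_for_variance(self, cumulative: float = 0.95) -> np.ndarray:
        """Scores restricted to the leading components reaching a cumulative
        variance fraction (at least one component is always returned)."""
        csum = np.cumsum(self.variance_fractions)
        m = int(np.searchsorted(csum, cumulative - 1e-12) + 1)
        m = min(m, self.n_components)
        return self.scores[:, :m]

    def morph_along_pc(self, pc_index: int, score: float) -> np.ndarray:
        """Shape at ``mean + score * component[pc_index]``, as (K, 3)."""
        if not 0 <= pc_index < self.n_components:
            raise IndexError(
                f"pc_index {pc_index} out of range (retained {self.n_components})"
            )
        flat = self.mean_shape.reshape(-1) + score * self.components[pc_index]
        return flat.reshape(self.n_landmarks, 3)

    def project(self, shape) -> np.ndarray:
        """Score vector of an arbitrary (K, 3) shape."""
        flat = np.asarray(shape, dtype=float).reshape(-1) - self.mean_shape.reshape(-1)
        return self.components @ flat

    def regress(
        self,
        covariate_values,
        pc_index: int,
        covariate: str = "covariate",
        scope: str = "ALL",
        mask=None,
    ) -> PCRegression:
        """OLS of a PC's scores on a per-specimen covariate; see :func:`regress_pc`."""
        return regress_pc(self, covariate_values, pc_index, covariate, scope, mask)

    def summary(self) -> str:
        lines = ["Shape PCA", f"  projection: {self.projection}"]
        for i, f in enumerate(self.variance_fractions[:10]):
            flag = " *" if f > 0.05 else ""
            lines.append(f"  PC{i + 1}: {100 * f:6.2f}% of variance{flag}")
        if self.n_components > 10:
            lines.append(f"  ... ({self.n_components} components retained)")
        return "\n".join(lines)


class ShapePCA:
    """PCA model over a superimposed sample.

    Parameters
    ----------
    sample : ProcrustesResults
        Output of a GPA fit (needs n >= 3 specimens).
    projection : str
        'procrustes_residuals' (default): PCA of the aligned coordinates
        about their sample mean, without further projection.
        'orthogonal_tangent': residuals are first projected orthogonally to
        the consensus direction (orthogonal tangent-space projection).
    """

    def __init__(self, sample: ProcrustesResults, projection: str = "procrustes_residuals"):
        if projection not in ("procrustes_residuals", "orthogonal_tangent"):
            raise ValueError(f"unknown projection {projection!r}")
        if sample.n_specimens < 3:
            raise ValueError("PCA needs at least 3 specimens")
        self.sample = sample
        self.projection = projection

    def fit(self) -> ShapePCAResults:
        x = self.sample.flattened()
        n, p = x.shape
        if self.projection == "orthogonal_tangent":
            m = self.sample.mean_shape.reshape(-1)
            mhat = m / np.linalg.norm(m)
            x = x - np.outer(x @ mhat, mhat)
        centre = x.mean(axis=0)
        resid = x - centre
        # thin SVD of the centred data; singular values give the variances
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        max_rank = min(n - 1, p - 7)  # 7 similarity dof removed by GPA
        var = s**2
        keep = var > var[0] * 1e-12 if var.size and var[0] > 0 else var > 0
        keep[max_rank:] = False
        components = vt[keep]
        scores = resid @ components.T
        fractions = var[keep] / var[keep].sum()
        mean_shape = centre.reshape(self.sample.n_landmarks, 3)
        return ShapePCAResults(mean_shape, components, fractions, scores, self.projection)


def fit_pca(
    sample: ProcrustesResults, projection: str = "procrustes_residuals"
) -> ShapePCAResults:
    """Convenience wrapper: ``ShapePCA(sample, projection).fit()``."""
    return ShapePCA(sample, projection).fit()


def regress_pc(
    pca: ShapePCAResults,
    covariate_values,
    pc_index: int,
    covariate: str = "covariate",
    scope: str = "ALL",
    mask=None,
) -> PCRegression:
    """Regress one PC's scores on a per-specimen covariate (OLS).

    ``mask`` restricts the regression to a subset of specimens (e.g. one
    population); scopes with fewer than 3 specimens yield a flagged result
    with ``p=None``.  Returns Pearson R, a two-sided p-value, slope and
    intercept.
    """
    if not 0 <= pc_index < pca.n_components:
        raise IndexError(f"pc_index {pc_index} out of range")
    y = pca.scores[:, pc_index]
    x = np.asarray(covariate_values, dtype=float)
    if x.shape != (pca.scores.shape[0],):
        raise ValueError("covariate must have one value per specimen")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        return PCRegression(pc_index, covariate, scope, np.nan, None, np.nan, np.nan, n)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant in scope {scope!r}")
    res = stats.linregress(x, y)
    return PCRegression(
        pc_index=pc_index,
        covariate=covariate,
        scope=scope,
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
    )
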