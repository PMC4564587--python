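"""Ordinary and Generalized Procrustes superimposition.

Superimposition removes location, scale and orientation from landmark
configurations so that only shape differences remain.  The convention here is
partial Procrustes: every configuration is centred and fixed at unit centroid
size, and rotations are proper (determinant +1; reflections are never allowed,
since left/right anatomy must not flip).

:class:`GeneralizedProcrustes` is the model object; its :meth:`fit` returns a
:class:`ProcrustesResults` carrying aligned coordinates, centroid sizes, the
consensus (mean) shape and convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "center_and_scale",
    "optimal_rotation",
    "opa_align",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "ProcrustesResults",
    "gpa",
    "repeatability_test",
]


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        if not config.is_complete:
            raise ValueError(
                f"specimen {config.specimen_id!r} has missing landmarks; "
                "filter or subset before superimposition"
            )
        return np.asarray(config.coords, dtype=float)
    x = np.asarray(config, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected (K, 3) coordinates, got shape {x.shape}")
    return x


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark-to-centroid distances.

    For a :class:`LandmarkConfiguration` only present landmarks contribute.
    """
    if isinstance(config, LandmarkConfiguration):
        if not config.present_mask.any():
            raise ValueError(f"specimen {config.specimen_id!r} has no present landmarks")
        x = config.coords[config.present_mask]
    else:
        x = np.asarray(config, dtype=float)
    centred = x - x.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def center_and_scale(coords) -> np.ndarray:
    """Centre at the origin and rescale to unit centroid size."""
    x = _as_coords(coords)
    x = x - x.mean(axis=0)
    cs = np.sqrt((x**2).sum())
    if cs <= 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return x / cs


def _check_nondegenerate(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 landmarks, got {x.shape[0]}")
    centred = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("degenerate configuration: landmarks are collinear")


def optimal_rotation(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||moving @ R - reference||_F (no reflection)."""
    h = moving.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(3)
    flip[-1] = d
    return (u * flip) @ vt


def opa_align(moving, reference) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of one configuration onto another.

    Both configurations are centred and scaled to unit centroid size, the
    moving one is rotated onto the reference by the optimal proper rotation,
    and the (partial) Procrustes distance — root summed squared landmark
    differences of the aligned pair — is returned with the aligned coordinates.
    """
    a = _as_coords(moving)
    b = _as_coords(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    _check_nondegenerate(a)
    _check_nondegenerate(b)
    a = center_and_scale(a)
    b = center_and_scale(b)
    aligned = a @ optimal_rotation(a, b)
    dist = float(np.sqrt(((aligned - b) ** 2).sum()))
    return aligned, dist


def procrustes_distance(shape_a, shape_b) -> float:
    """Partial Procrustes distance between two shapes after full superimposition."""
    return opa_align(shape_a, shape_b)[1]


@dataclass
class ProcrustesResults:
    """Output of a Generalized Procrustes fit.

    Attributes
    ----------
    configs : list of LandmarkConfiguration or None
        The input configurations, when the model was built from them.
    aligned : (n, K, 3) ndarray
        Superimposed coordinates; each specimen centred at the origin with
        unit centroid size.
    centroid_sizes : (n,) ndarray
        Centroid sizes on the original (pre-scaling) coordinates.
    mean_shape : (K, 3) ndarray
        Consensus shape, unit centroid size.
    iterations : int
    converged : bool
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    iterations: int
    converged: bool
    configs: Sequence[LandmarkConfiguration] | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    @property
    def populations(self) -> list[str] | None:
        if self.configs is None:
            return None
        return [c.population for c in self.configs]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (n, 3K) matrix (x1 y1 z1 x2 ...)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def residual_rms(self) -> np.ndarray:
        """Per-specimen root-mean-square residual from the consensus."""
        diff = self.aligned - self.mean_shape
        return np.sqrt((diff**2).sum(axis=(1, 2)) / self.n_landmarks)

    def summary(self) -> str:
        lines = [
            "Generalized Procrustes Analysis",
            f"  specimens:      {self.n_specimens}",
            f"  landmarks:      {self.n_landmarks}",
            f"  iterations:     {self.iterations} (converged={self.converged})",
            f"  centroid size:  mean {self.centroid_sizes.mean():.4f}, "
            f"range [{self.centroid_sizes.min():.4f}, {self.centroid_sizes.max():.4f}]",
            f"  mean residual:  {self.residual_rms().mean():.6f}",
        ]
        return "\n".join(lines)


class GeneralizedProcrustes:
    """Generalized Procrustes Analysis over a sample of configurations.

    Iteratively rotates every centred, unit-size configuration onto the
    current consensus, recomputes the consensus, and repeats until the
    consensus stabilises.  The consensus is initialised from the first
    configuration (order invariance of the result, up to a joint rotation, is
    a verified property).

    Parameters
    ----------
    configs : sequence of LandmarkConfiguration or (K, 3) arrays
        At least two complete configurations with a common landmark set.
    tol : float
        Convergence threshold on the root summed squared change of the
        consensus between iterations.
    max_iter : int
    """

    def __init__(self, configs: Sequence, tol: float = 1e-10, max_iter: int = 100):
        if len(configs) < 2:
            raise ValueError("GPA needs at least 2 configurations")
        self._input = list(configs)
        coords = [_as_coords(c) for c in configs]
        k = coords[0].shape[0]
        if any(c.shape[0] != k for c in coords):
            raise ValueError("all configurations must share the same landmark count")
        for c in coords:
            _check_nondegenerate(c)
        self.coords = np.stack(coords)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self) -> ProcrustesResults:
        raw = self.coords
        sizes = np.array([centroid_size(x) for x in raw])
        scaled = np.stack([center_and_scale(x) for x in raw])
        mean = scaled[0].copy()
        aligned = scaled
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            aligned = np.stack([x @ optimal_rotation(x, mean) for x in scaled])
            new_mean = aligned.mean(axis=0)
            new_mean = new_mean / np.sqrt((new_mean**2).sum())
            change = np.sqrt(((new_mean - mean) ** 2).sum())
            mean = new_mean
            if change < self.tol:
                converged = True
                break
        # final pass so every specimen is aligned to the converged consensus
        aligned = np.stack([x @ optimal_rotation(x, mean) for x in scaled])
        configs = (
            self._input
            if all(isinstance(c, LandmarkConfiguration) for c in self._input)
            else None
        )
        return ProcrustesResults(
            aligned=aligned,
            centroid_sizes=sizes,
            mean_shape=mean,
            iterations=it,
            converged=converged,
            configs=configs,
        )


def gpa(configs: Sequence, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResults:
    """Convenience wrapper: ``GeneralizedProcrustes(configs).fit()``."""
    return GeneralizedProcrustes(configs, tol=tol, max_iter=max_iter).fit()


def repeatability_test(
    trials_a: Sequence, trials_b: Sequence
) -> tuple[float, float]:
    """Digitising-repeatability check between two sets of repeated trials.

    All trials (same specimen digitised repeatedly, e.g. on different days)
    are superimposed together; each trial's root-mean-square Procrustes
    residual from the consensus is computed, and the two trial sets are
    compared with a paired two-sided t-test.  A non-significant result means
    the landmarks were digitised consistently across sessions.

    Returns ``(t, p)``.  Identical trial sets give ``t = 0, p = 1``.
    """
    if len(trials_a) != len(trials_b):
        raise ValueError("trial sets must have equal length (paired design)")
    if len(trials_a) < 2:
        raise ValueError("need at least 2 trial pairs")
    res = gpa(list(trials_a) + list(trials_b))
    rms = res.residual_rms()
    a, b = rms[: len(trials_a)], rms[len(trials_a) :]
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
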