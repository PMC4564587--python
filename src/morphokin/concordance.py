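"""Mantel correlation between morphological and molecular distance matrices,
with exact-enumeration or Monte-Carlo nulls, and population-exclusion
sensitivity scans.

The Mantel statistic is the Pearson correlation over the n(n-1)/2 unordered
off-diagonal pairs of two distance matrices sharing a label set.  Its null
distribution is generated by permuting the population labels of one matrix
(a simultaneous row/column shuffle).  For small n every one of the n!
permutations is enumerated, which makes the p-value exactly reproducible;
larger label sets fall back to seeded Monte-Carlo sampling with the add-one
convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DistanceMatrix

__all__ = [
    "MantelResult",
    "MantelTest",
    "mantel",
    "exclude_population",
    "exclusion_scan",
]

#: Exact enumeration is used whenever n! does not exceed this bound (n <= 8).
EXACT_ENUMERATION_LIMIT = 50_000


@dataclass
class MantelResult:
    """Result of one Mantel test.

    ``p`` is for the requested ``tail``; ``p_upper``, ``p_lower`` and
    ``p_two_sided`` are always carried so that tail-convention choices are
    transparent.
    """

    r: float
    p: float
    tail: str
    method: str
    n_perm: int
    seed: int | None
    n_labels: int
    p_upper: float
    p_lower: float
    p_two_sided: float

    def summary(self) -> str:
        return (
            f"Mantel test (n={self.n_labels}, {self.method}, "
            f"{self.n_perm} permutations)\n"
            f"  r = {self.r:.4f}\n"
            f"  p[{self.tail}] = {self.p:.4g} "
            f"(upper {self.p_upper:.4g}, lower {self.p_lower:.4g}, "
            f"two-sided {self.p_two_sided:.4g})"
        )


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("constant off-diagonal distances: correlation undefined")
    return float((xc * yc).sum() / denom)


class MantelTest:
    """Mantel matrix-correlation model for two labelled distance matrices.

    Matrices are reconciled by label (never by position); a label mismatch
    raises with the differing labels listed.

    Parameters
    ----------
    morph, mol : DistanceMatrix
        Morphological and molecular distance matrices over the same
        populations (n >= 4).
    tail : {'upper', 'lower', 'two-sided'}
        Which tail of the permutation null yields the headline p-value.
        Upper (large positive correlation is evidence of concordance) is the
        classical convention and the default.
    """

    def __init__(self, morph: DistanceMatrix, mol: DistanceMatrix, tail: str = "upper"):
        if tail not in ("upper", "lower", "two-sided"):
            raise ValueError(f"unknown tail {tail!r}")
        only_morph = sorted(set(morph.labels) - set(mol.labels))
        only_mol = sorted(set(mol.labels) - set(morph.labels))
        if only_morph or only_mol:
            raise ValueError(
                "label mismatch between matrices: "
                f"only in first = {only_morph}, only in second = {only_mol}"
            )
        if morph.n < 4:
            raise ValueError(f"Mantel test needs n >= 4 labels, got {morph.n}")
        self.morph = morph
        self.mol = mol.reorder(morph.labels)
        self.tail = tail

    def fit(self, n_perm: int = 9999, seed: int | None = 0) -> MantelResult:
        n = self.morph.n
        x = _tri(self.morph.values)
        b = self.mol.values
        r_obs = _pearson(x, _tri(b))

        exact = math.factorial(n) <= EXACT_ENUMERATION_LIMIT
        if exact:
            perms = np.array(list(itertools.permutations(range(n))))
            r_null = self._null_statistics(x, b, perms)
            total = len(perms)
            # the identity permutation is part of the enumerated null
            ge = int((r_null >= r_obs - 1e-12).sum())
            le = int((r_null <= r_obs + 1e-12).sum())
            extreme = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
            p_up, p_lo, p_two = ge / total, le / total, extreme / total
            method, used, seed_out = "exact_enumeration", total, None
        else:
            if n_perm < 1:
                raise ValueError("n_perm must be >= 1")
            rng = np.random.default_rng(seed)
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
            r_null = self._null_statistics(x, b, perms)
            ge = int((r_null >= r_obs - 1e-12).sum())
            le = int((r_null <= r_obs + 1e-12).sum())
            extreme = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
            p_up = (1 + ge) / (1 + n_perm)
            p_lo = (1 + le) / (1 + n_perm)
            p_two = (1 + extreme) / (1 + n_perm)
            method, used, seed_out = "monte_carlo", n_perm, seed

        p = {"upper": p_up, "lower": p_lo, "two-sided": p_two}[self.tail]
        return MantelResult(
            r=r_obs,
            p=p,
            tail=self.tail,
            method=method,
            n_perm=used,
            seed=seed_out,
            n_labels=n,
            p_upper=p_up,
            p_lower=p_lo,
            p_two_sided=p_two,
        )

    @staticmethod
    def _null_statistics(x: np.ndarray, b: np.ndarray, perms: np.ndarray) -> np.ndarray:
        n = b.shape[0]
        iu, ju = np.triu_indices(n, 1)
        # permuted matrices' upper triangles, one row per permutation
        y = b[perms[:, iu], perms[:, ju]]
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
        return (yc @ xc) / denom


def mantel(
    morph: DistanceMatrix,
    mol: DistanceMatrix,
    tail: str = "upper",
    seed: int | None = 0,
    n_perm: int = 9999,
) -> MantelResult:
    """Convenience wrapper: ``MantelTest(morph, mol, tail).fit(n_perm, seed)``."""
    return MantelTest(morph, mol, tail=tail).fit(n_perm=n_perm, seed=seed)


def exclude_population(matrix: DistanceMatrix, label: str) -> DistanceMatrix:
    """Distance matrix with one population's row and column removed."""
    return matrix.drop(label)


def exclusion_scan(
    morph: DistanceMatrix,
    mol: DistanceMatrix,
    tail: str = "upper",
    seed: int | None = 0,
    n_perm: int = 9999,
) -> pd.DataFrame:
    """Mantel result per single-population exclusion, plus the full baseline.

    Identifies populations whose inclusion unduly drives (or destroys) the
    morphology-genetics concordance.  Returns a table with one row per
    excluded label ('NONE' first for the all-populations baseline) and
    columns ``excluded, n, r, p, method``.
    """
    if morph.n < 5:
        raise ValueError("exclusion scan needs n >= 5 (each subset needs n >= 4)")
    rows = []
    base = mantel(morph, mol, tail=tail, seed=seed, n_perm=n_perm)
    rows.append(
        {"excluded": "NONE", "n": base.n_labels, "r": base.r, "p": base.p, "method": base.method}
    )
    for label in morph.labels:
        res = mantel(
            morph.drop(label), mol.drop(label), tail=tail, seed=seed, n_perm=n_perm
        )
        rows.append(
            {"excluded": label, "n": res.n_labels, "r": res.r, "p": res.p, "method": res.method}
        )
    return pd.DataFrame(rows)
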