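"""Pairwise genetic distances from diploid STR genotype tables.

Differentiation is estimated by a three-level nested analysis of variance
(among populations / among individuals within populations / within
individuals, i.e. between the two gene copies).  Run on per-allele indicator
variables and summed over alleles and loci this yields the Weir-Cockerham
multilocus theta (F_ST); run on allele repeat sizes it yields the
allele-size R_ST convention appropriate for stepwise-mutating
microsatellites.  Either estimate can be linearised to the genetic distance
D = F / (1 - F), which grows roughly linearly with divergence time under
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING_ALLELE, DistanceMatrix, STRGenotypeTable

__all__ = ["FstOptions", "pairwise_fst", "slatkin_linearize", "variance_components"]


@dataclass(frozen=True)
class FstOptions:
    """Options for pairwise F_ST estimation.

    estimator : 'weir_cockerham' (allele-identity theta) or
        'rst_allele_size' (variance components on repeat sizes).
    linearize : apply D = F/(1-F) entrywise to the result.
    min_individuals : minimum individuals typed per population for a locus
        to enter a pairwise estimate.
    """

    estimator: str = "weir_cockerham"
    linearize: bool = False
    min_individuals: int = 2

    def __post_init__(self) -> None:
        if self.estimator not in ("weir_cockerham", "rst_allele_size"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.min_individuals < 2:
            raise ValueError("min_individuals must be >= 2")


def variance_components(values: np.ndarray, pop_index: np.ndarray) -> tuple[float, float, float]:
    """Nested ANOVA variance components for diploid per-copy values.

    ``values`` is (n_individuals, 2); ``pop_index`` assigns each individual
    to a population 0..r-1.  Returns ``(a, b, c)``: among-population,
    among-individual-within-population, and within-individual components.
    Applied to 0/1 allele indicators these are exactly the Weir-Cockerham
    components for that allele.
    """
    r = int(pop_index.max()) + 1
    n_i = np.bincount(pop_index, minlength=r).astype(float)
    if (n_i < 1).any() or r < 2:
        raise ValueError("need at least one individual in each of >= 2 populations")
    n_tot = n_i.sum()
    ind_mean = values.mean(axis=1)
    pop_sum = np.bincount(pop_index, weights=ind_mean, minlength=r)
    pop_mean = pop_sum / n_i
    grand = ind_mean.mean()

    ss_within_ind = ((values - ind_mean[:, None]) ** 2).sum()
    ss_among_ind = 2.0 * ((ind_mean - pop_mean[pop_index]) ** 2).sum()
    ss_among_pop = 2.0 * (n_i * (pop_mean - grand) ** 2).sum()

    df_wi = n_tot  # one df per individual (2 copies - 1)
    df_ai = n_tot - r
    df_ap = r - 1
    ms_wi = ss_within_ind / df_wi
    ms_ai = ss_among_ind / df_ai if df_ai > 0 else 0.0
    ms_ap = ss_among_pop / df_ap

    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    c = ms_wi
    b = (ms_ai - ms_wi) / 2.0
    a = (ms_ap - ms_ai) / (2.0 * n_c)
    return float(a), float(b), float(c)


def _locus_components(
    geno: np.ndarray, pop_index: np.ndarray, estimator: str
) -> tuple[float, float] | None:
    """Summed (a, a+b+c) for one locus, or None if not estimable."""
    if estimator == "rst_allele_size":
        a, b, c = variance_components(geno.astype(float), pop_index)
        return a, a + b + c
    # Weir-Cockerham: indicator ANOVA per allele, summed
    alleles = np.unique(geno)
    if alleles.size < 2:
        return 0.0, 0.0  # monomorphic locus carries no information
    num = den = 0.0
    for allele in alleles:
        a, b, c = variance_components((geno == allele).astype(float), pop_index)
        num += a
        den += a + b + c
    return num, den


def pairwise_fst(table: STRGenotypeTable, options: FstOptions | None = None) -> DistanceMatrix:
    """Multilocus pairwise F_ST (or R_ST) between all populations.

    Variance components are summed over loci and alleles before taking the
    ratio (the standard multilocus estimator); per-locus components may be
    negative and are retained in the sums, but a negative multilocus ratio is
    floored at zero in the returned matrix (raw values are available on the
    result as ``raw_values``).  Missing genotypes are dropped per locus and
    individual (pairwise deletion).
    """
    options = options or FstOptions()
    pops = table.population_labels
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    n = len(pops)
    raw = np.zeros((n, n))
    pop_arr = np.asarray(table.populations)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (pop_arr == pops[i]) | (pop_arr == pops[j])
            geno = table.genotypes[keep]
            idx = (pop_arr[keep] == pops[j]).astype(int)
            num = den = 0.0
            used = 0
            for l in range(table.n_loci):
                g = geno[:, l, :]
                typed = g[:, 0] != MISSING_ALLELE
                counts = np.bincount(idx[typed], minlength=2)
                if counts.min() < options.min_individuals:
                    continue
                comp = _locus_components(g[typed], idx[typed], options.estimator)
                if comp is None:
                    continue
                num += comp[0]
                den += comp[1]
                used += 1
            if used == 0:
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no locus with "
                    f">= {options.min_individuals} typed individuals each"
                )
            raw[i, j] = raw[j, i] = num / den if den > 0 else 0.0
    floored = np.clip(raw, 0.0, None)
    result = DistanceMatrix(pops, floored)
    result.raw_values = raw  # unfloored estimates, for transparency
    if options.linearize:
        result = slatkin_linearize(result)
    return result


def slatkin_linearize(matrix: DistanceMatrix) -> DistanceMatrix:
    """Entrywise linearised genetic distance D = F / (1 - F).

    Requires all entries in [0, 1); complete fixation (F = 1) has no finite
    linearisation and raises.
    """
    f = matrix.values
    if (f >= 1.0).any():
        bad = np.argwhere(f >= 1.0)[0]
        raise ValueError(
            f"cannot linearise F >= 1 (entry {matrix.labels[bad[0]]!r}, "
            f"{matrix.labels[bad[1]]!r})"
        )
    return DistanceMatrix(matrix.labels, f / (1.0 - f), check=False)
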