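"""Synthetic study-system generator: STR genotypes and landmark ontogenetic
series with controllable genetics-morphology concordance.

The generator emulates the structure of a seven-population cranial ontogeny
study: per-population series over three subadult age categories plus adults,
a 44-landmark basicranial scheme, and STR genotypes whose pairwise F_ST
approximates a target matrix.  All latent quantities (true population shape
offsets, realized genetic distances, the allometric vector) are returned as
a :class:`SyntheticTruth` so every pipeline stage can be tested against
known ground truth.

Genotypes are drifted from an ancestral allele-frequency spectrum with a
covariance calibrated so that the expected pairwise Weir-Cockerham theta
matches the target matrix to first order.  Landmark shapes place population
mean offsets in tangent space by classical-scaling embedding of the genetic
matrix — the minimal construction making between-population shape distances
proportional to genetic distances, which is exactly the structure a Mantel
test detects.  A ``concordance`` dial in [0, 1] blends those offsets with
random offsets of equal norm, so the genetics-morphology correlation can be
tuned from none (0) to maximal (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AgeCategory,
    AgeEncoding,
    DistanceMatrix,
    LandmarkConfiguration,
    STRGenotypeTable,
)
from .popgen import FstOptions, pairwise_fst
from .reference_tables import (
    REFERENCE_POPULATIONS,
    make_fixture_tables,
    reference_fst_matrix,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_template",
    "default_cell_counts",
    "simulate_genotypes",
    "simulate_landmarks",
    "simulate_study",
    "make_fixture_tables",
]

#: Subadult specimens per population and age category in the emulated
#: sampling design (columns AC1, AC2, AC3; totals 48/51/85).
_SUBADULT_COUNTS: dict[str, tuple[int, int, int]] = {
    "Alaska": (10, 6, 14),
    "Austria": (5, 10, 13),
    "Egypt": (9, 7, 11),
    "Mexico": (8, 7, 15),
    "Peru": (3, 8, 19),
    "Polynesia": (2, 6, 9),
    "Utah": (11, 7, 4),
}

#: Adults per population.  The emulated design included adults only in a
#: subset of analyses and does not fix their counts; eight per population is
#: a realistic museum-series size.
_DEFAULT_ADULTS = 8


def default_cell_counts(
    populations: Sequence[str] | None = None, adults: int = _DEFAULT_ADULTS
) -> dict[tuple[str, AgeCategory], int]:
    """Specimens per (population, age category), shaped like the study design."""
    populations = list(populations or REFERENCE_POPULATIONS)
    counts: dict[tuple[str, AgeCategory], int] = {}
    for pop in populations:
        ac1, ac2, ac3 = _SUBADULT_COUNTS.get(pop, (5, 8, 12))
        counts[(pop, AgeCategory.AC1)] = ac1
        counts[(pop, AgeCategory.AC2)] = ac2
        counts[(pop, AgeCategory.AC3)] = ac3
        counts[(pop, AgeCategory.ADULT)] = adults
    return counts


def default_template(n_landmarks: int = 44) -> np.ndarray:
    """Deterministic pseudo-anatomical landmark template (synthetic).

    A stylised cranial-base-like configuration: points scattered over a
    bilaterally symmetric half-ellipsoid shell with a flat midline strip,
    in millimetre scale.  Constructed from a frozen internal seed — it is a
    synthetic stand-in, not derived from any specimen.
    """
    rng = np.random.default_rng(434420)
    half = n_landmarks // 2
    # paired bilateral points on an ellipsoid patch
    theta = rng.uniform(0.2, np.pi - 0.2, size=half)
    phi = rng.uniform(0.15 * np.pi, 0.85 * np.pi, size=half)
    a, b, c = 65.0, 50.0, 35.0  # semi-axes, mm
    x = a * np.sin(phi) * np.cos(theta)
    y = b * np.sin(phi) * np.sin(theta)
    z = -c * np.cos(phi)
    left = np.stack([x, y, z], axis=1)
    right = left * np.array([1.0, -1.0, 1.0])
    pts = np.empty((2 * half, 3))
    pts[0::2] = left
    pts[1::2] = right
    if pts.shape[0] < n_landmarks:  # odd count: add a midline point
        pts = np.vstack([pts, [[0.0, 0.0, -c]]])
    pts = pts[:n_landmarks]
    # small deterministic roughness so no landmark sits exactly on the shell
    pts += rng.normal(0.0, 1.5, size=pts.shape)
    return pts


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Attributes
    ----------
    seed : int
        Mandatory; every random draw flows from it.
    populations : list of str
    n_per_cell : mapping (population, AgeCategory) -> int
        Landmark-series sample sizes; defaults to the emulated study design.
    n_genotype_individuals : int
        Individuals per population in the genotype table.
    n_loci : int
        STR loci (a fixture-scale stand-in for a genome-wide panel).
    target_genetic : DistanceMatrix
        Pairwise F_ST targets for drift calibration.
    concordance : float in [0, 1]
        Blend between genetically structured and random population shape
        offsets (1 = offsets exactly embed the genetic matrix).
    shape_template : (K, 3) array
    between_pop_scale : float
        Procrustes-distance units per unit of genetic distance; 1.0 makes
        population shape distances numerically comparable to the F_ST
        targets (~0.03-0.15).
    allometry_per_year : float
        Magnitude of shape change (unit-size tangent space) per year of age.
    noise_sd : float
        Isotropic digitising + individual noise per coordinate, unit-size
        scale.
    size_by_age : mapping AgeCategory -> centroid size (mm)
        Growth in overall size across categories.
    age_encoding : AgeEncoding
    """

    seed: int
    populations: Sequence[str] = field(default_factory=lambda: list(REFERENCE_POPULATIONS))
    n_per_cell: Mapping[tuple[str, AgeCategory], int] | None = None
    n_genotype_individuals: int = 30
    n_loci: int = 50
    target_genetic: DistanceMatrix | None = None
    concordance: float = 1.0
    shape_template: np.ndarray | None = None
    between_pop_scale: float = 1.0
    allometry_per_year: float = 0.004
    noise_sd: float = 0.004
    size_by_age: Mapping[AgeCategory, float] = field(
        default_factory=lambda: {
            AgeCategory.AC1: 80.0,
            AgeCategory.AC2: 95.0,
            AgeCategory.AC3: 105.0,
            AgeCategory.ADULT: 110.0,
        }
    )
    age_encoding: AgeEncoding = field(default_factory=AgeEncoding)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no implicit entropy)")
        self.seed = int(self.seed)
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.populations = list(self.populations)
        if self.target_genetic is None:
            ref = reference_fst_matrix()
            if not set(self.populations) <= set(ref.labels):
                raise ValueError(
                    "populations not covered by the reference F_ST matrix; "
                    "pass target_genetic explicitly"
                )
            self.target_genetic = DistanceMatrix(
                self.populations, _submatrix(ref, self.populations), check=False
            )
        if self.target_genetic.labels != self.populations:
            self.target_genetic = self.target_genetic.reorder(self.populations)
        if (self.target_genetic.values >= 1.0).any():
            raise ValueError("target F_ST >= 1 is unattainable")
        if self.n_per_cell is None:
            self.n_per_cell = default_cell_counts(self.populations)
        if self.shape_template is None:
            self.shape_template = default_template()
        self.shape_template = np.asarray(self.shape_template, dtype=float)


def _submatrix(matrix: DistanceMatrix, labels: Sequence[str]) -> np.ndarray:
    idx = [matrix.labels.index(l) for l in labels]
    return matrix.values[np.ix_(idx, idx)]


@dataclass
class SyntheticTruth:
    """Realized latent values of one synthetic draw (recovery-test oracle)."""

    config: SyntheticConfig
    population_offsets: dict[str, np.ndarray]  # tangent vectors, flattened 3K
    genetic_matrix: DistanceMatrix  # matrix used to plant the offsets
    allometric_vector: np.ndarray  # flattened 3K, per year of age
    offset_distances: DistanceMatrix  # pairwise norms ||u_p - u_q||


def _drift_covariance(target: np.ndarray) -> np.ndarray:
    """Population drift covariance whose pairwise theta matches ``target``.

    For small divergence the expected pairwise theta between populations p, q
    with drift deviations of covariance S is (S_pp + S_qq - 2 S_pq) / 2, so
    double-centring the target matrix solves for S; tiny negative eigenvalues
    from non-Euclidean targets are clipped.
    """
    n = target.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    s = -j @ target @ j
    w, v = np.linalg.eigh(s)
    return (v * np.clip(w, 0.0, None)) @ v.T


def _draw_locus(rng: np.random.Generator, chol: np.ndarray, n_pops: int):
    """One locus: allele repeat sizes and per-population frequencies."""
    n_alleles = int(rng.integers(3, 7))
    start = int(rng.integers(8, 31 - n_alleles))
    sizes = np.arange(start, start + n_alleles)
    ancestral = rng.dirichlet(np.full(n_alleles, 1.5))
    freqs = np.empty((n_pops, n_alleles))
    for a in range(n_alleles):
        sd = np.sqrt(max(ancestral[a] * (1.0 - ancestral[a]), 1e-12))
        freqs[:, a] = ancestral[a] + chol @ rng.standard_normal(n_pops) * sd
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum(axis=1, keepdims=True)
    return sizes, freqs


def _expected_theta(freq_draws: list[np.ndarray], n_pops: int) -> np.ndarray:
    """Large-sample pairwise Weir-Cockerham theta implied by drawn frequencies.

    Per pair and locus, summed over alleles: numerator s2 = (p1-p2)^2/2,
    denominator s2/2 + pbar(1-pbar) (the infinite-sample limit of the
    variance components under Hardy-Weinberg genotypes).
    """
    num = np.zeros((n_pops, n_pops))
    den = np.zeros((n_pops, n_pops))
    for freqs in freq_draws:
        for p in range(n_pops):
            for q in range(p + 1, n_pops):
                s2 = ((freqs[p] - freqs[q]) ** 2 / 2.0).sum()
                pbar = (freqs[p] + freqs[q]) / 2.0
                d = s2 / 2.0 + (pbar * (1.0 - pbar)).sum()
                num[p, q] += s2
                den[p, q] += d
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / den, 0.0)
    return theta + theta.T


def _calibrated_cholesky(
    target: np.ndarray, rng: np.random.Generator, n_iter: int = 3, n_cal_loci: int = 300
) -> np.ndarray:
    """Drift Cholesky factor, iteratively recalibrated against the target.

    Clipping frequencies to the simplex shrinks the realized divergence below
    the first-order calculation, so the effective target is adjusted
    multiplicatively until frequency-only simulations reproduce the requested
    pairwise theta.
    """
    n_pops = target.shape[0]
    eff = target.copy()
    chol = None
    for _ in range(n_iter):
        cov = _drift_covariance(eff)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_pops))
        if not (target > 0).any():
            break
        draws = [_draw_locus(rng, chol, n_pops)[1] for _ in range(n_cal_loci)]
        theta = _expected_theta(draws, n_pops)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((theta > 1e-4) & (target > 0), target / theta, 1.0)
        eff = eff * np.clip(ratio, 0.5, 2.0)
        np.fill_diagonal(eff, 0.0)
    return chol


def simulate_genotypes(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[STRGenotypeTable, DistanceMatrix]:
    """Simulate drifted STR genotypes and return them with the realized F_ST.

    Per locus an ancestral spectrum of contiguous repeat sizes (within 8-30)
    is drawn; population allele frequencies deviate from it with the
    calibrated drift covariance; diploid genotypes are sampled under
    Hardy-Weinberg within populations.  The realized matrix is computed from
    the simulated table by the package's own Weir-Cockerham estimator.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pops = config.populations
    n_pops = len(pops)
    chol = _calibrated_cholesky(config.target_genetic.values, rng)

    n_ind = config.n_genotype_individuals
    ids, pop_labels = [], []
    for pop in pops:
        for i in range(n_ind):
            ids.append(f"{pop}_g{i + 1:03d}")
            pop_labels.append(pop)
    genotypes = np.empty((len(ids), config.n_loci, 2), dtype=int)

    for locus in range(config.n_loci):
        sizes, freqs = _draw_locus(rng, chol, n_pops)
        for p, pop in enumerate(pops):
            rows = [i for i, l in enumerate(pop_labels) if l == pop]
            draws = rng.choice(sizes, size=(len(rows), 2), p=freqs[p])
            genotypes[rows, locus, :] = draws

    table = STRGenotypeTable(ids, pop_labels, [f"STR{l + 1:03d}" for l in range(config.n_loci)], genotypes)
    realized = pairwise_fst(table, FstOptions(estimator="weir_cockerham"))
    return table, realized


def simulate_landmarks(
    config: SyntheticConfig,
    genetic: DistanceMatrix | None = None,
    seed: int | None = None,
) -> tuple[list[LandmarkConfiguration], SyntheticTruth]:
    """Simulate landmark ontogenetic series with planted population structure.

    Population mean offsets are a classical-scaling embedding of ``genetic``
    (default: the config's target matrix) mapped into tangent space and
    scaled by ``between_pop_scale``, blended with equal-norm random offsets
    according to ``concordance``.  Each specimen adds its age-dependent
    allometric deformation and isotropic landmark noise, then receives a
    random rotation, translation and age-dependent size to mimic raw
    digitised coordinates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genetic = genetic if genetic is not None else config.target_genetic
    if genetic.labels != list(config.populations):
        genetic = genetic.reorder(config.populations)
    pops = list(config.populations)
    n_pops = len(pops)

    template = config.shape_template
    k = template.shape[0]
    dim = 3 * k
    max_dim = dim - 7
    template_unit = template - template.mean(axis=0)
    template_unit = template_unit / np.sqrt((template_unit**2).sum())
    flat_template = template_unit.reshape(-1)

    # classical scaling of the genetic distance matrix
    d2 = genetic.values**2
    j = np.eye(n_pops) - np.ones((n_pops, n_pops)) / n_pops
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0.0) * 1e-10
    n_dim = int(pos.sum())
    if n_dim > max_dim:
        raise ValueError(f"embedding dimension {n_dim} exceeds 3K-7 = {max_dim}")
    y = v[:, pos] * np.sqrt(w[pos])  # n_pops x n_dim, ||y_p - y_q|| ~ genetic

    # orthonormal directions carrying the embedding into tangent space
    basis = rng.standard_normal((dim, n_dim))
    basis -= np.outer(flat_template, flat_template @ basis)  # keep off the size/position direction
    basis, _ = np.linalg.qr(basis)
    u = (y @ basis.T) * config.between_pop_scale  # genetic offsets, n_pops x dim

    # Random offsets share one common norm (the RMS of the genetic offset
    # norms): per-population norm matching would leak the genetic outlier
    # structure into the "unstructured" component and bias the c=0 null.
    c = config.concordance
    vrand = rng.standard_normal((n_pops, dim))
    vrand -= vrand.mean(axis=0)
    common = float(np.sqrt((np.linalg.norm(u, axis=1) ** 2).mean()))
    norms_v = np.linalg.norm(vrand, axis=1)
    vrand = vrand * (common / np.where(norms_v > 0, norms_v, 1.0))[:, None]
    offsets = c * u + (1.0 - c) * vrand

    allometric = rng.standard_normal(dim)
    allometric -= (allometric @ flat_template) * flat_template
    allometric /= np.linalg.norm(allometric)
    allometric *= config.allometry_per_year

    age_ref = 10.0  # centre of the subadult age range, years
    configs: list[LandmarkConfiguration] = []
    for p, pop in enumerate(pops):
        for ac in (AgeCategory.AC1, AgeCategory.AC2, AgeCategory.AC3, AgeCategory.ADULT):
            n_cell = int(config.n_per_cell.get((pop, ac), 0))
            age = config.age_encoding.numeric_age(ac)
            for i in range(n_cell):
                flat = (
                    flat_template
                    + offsets[p]
                    + (age - age_ref) * allometric
                    + rng.normal(0.0, config.noise_sd, size=dim)
                )
                shape = flat.reshape(k, 3)
                # similarity transform mimicking raw digitisation
                rot = _random_rotation(rng)
                size = config.size_by_age[ac] * float(np.exp(rng.normal(0.0, 0.04)))
                shape = shape - shape.mean(axis=0)
                shape = shape / np.sqrt((shape**2).sum())
                coords = shape @ rot * size + rng.uniform(-100.0, 100.0, size=3)
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=f"{pop}_{ac.value}_{i + 1:03d}",
                        population=pop,
                        age_category=ac,
                        coords=coords,
                    )
                )

    off_d = np.zeros((n_pops, n_pops))
    for p in range(n_pops):
        for q in range(p + 1, n_pops):
            off_d[p, q] = off_d[q, p] = np.linalg.norm(offsets[p] - offsets[q])
    truth = SyntheticTruth(
        config=config,
        population_offsets={pop: offsets[p].copy() for p, pop in enumerate(pops)},
        genetic_matrix=genetic,
        allometric_vector=allometric,
        offset_distances=DistanceMatrix(pops, off_d, check=False),
    )
    return configs, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


def simulate_study(
    config: SyntheticConfig,
) -> tuple[list[LandmarkConfiguration], STRGenotypeTable, SyntheticTruth]:
    """Full synthetic study: genotypes, then landmarks planted on the realized
    genetic structure.  Landmark offsets embed the *realized* F_ST matrix so
    that morphology and the genotype table share one truth."""
    rng = np.random.default_rng(config.seed)
    geno_seed, lm_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    table, realized = simulate_genotypes(config, seed=geno_seed)
    configs, truth = simulate_landmarks(config, genetic=realized, seed=lm_seed)
    return configs, table, truth
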