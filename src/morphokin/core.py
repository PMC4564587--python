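"""Core domain types for landmark-based morphometrics and STR population genetics.

The central objects are :class:`LandmarkConfiguration` (one specimen's ordered
3D landmarks plus identity metadata), :class:`RegionDefinition` (a named,
possibly overlapping subset of the landmark scheme), :class:`DistanceMatrix`
(a labelled symmetric distance matrix, used for both morphological Procrustes
distances and molecular F_ST-type distances), and :class:`STRGenotypeTable`
(diploid microsatellite genotypes, individuals x loci).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeCategory",
    "AgeEncoding",
    "LandmarkConfiguration",
    "RegionDefinition",
    "DistanceMatrix",
    "STRGenotypeTable",
    "OCCIPITAL",
    "TEMPORAL",
    "SPHENOID",
    "BASICRANIUM",
    "DEFAULT_REGIONS",
]


class AgeCategory(enum.Enum):
    """Ontogenetic stage scored from molar eruption.

    AC1: first molars not yet erupted (roughly <5 years).
    AC2: M1 erupted, M2 not (roughly 5-12 years).
    AC3: M2 erupted, M3 not (roughly 13-18 years).
    ADULT: full permanent dentition.
    """

    AC1 = "AC1"
    AC2 = "AC2"
    AC3 = "AC3"
    ADULT = "ADULT"

    @classmethod
    def coerce(cls, value: "AgeCategory | str") -> "AgeCategory":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().upper())


#: Category midpoint ages in years.  The three subadult stages map to the
#: midpoints of their rough chronological ranges; adults, whose age cannot be
#: estimated from dental eruption, default to a nominal young-adult age.
DEFAULT_AGE_YEARS: dict[AgeCategory, float] = {
    AgeCategory.AC1: 2.5,
    AgeCategory.AC2: 8.5,
    AgeCategory.AC3: 15.5,
    AgeCategory.ADULT: 21.0,
}


@dataclass(frozen=True)
class AgeEncoding:
    """Numeric age (years) assigned to each ontogenetic category.

    The mapping must be strictly increasing with category order; the adult
    value is a convention (dental eruption gives no adult age estimate) and is
    therefore configurable.
    """

    ages: Mapping[AgeCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_YEARS)
    )

    def __post_init__(self) -> None:
        order = [AgeCategory.AC1, AgeCategory.AC2, AgeCategory.AC3, AgeCategory.ADULT]
        vals = [float(self.ages[c]) for c in order]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"age encoding must be strictly increasing across categories, got {vals}"
            )

    def numeric_age(self, category: AgeCategory | str) -> float:
        return float(self.ages[AgeCategory.coerce(category)])


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmark coordinates with identity metadata.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    population : str
        Population label.
    age_category : AgeCategory
        Ontogenetic stage (AC1/AC2/AC3/ADULT).
    coords : (K, 3) ndarray
        Landmark coordinates in millimetres.  Rows whose landmark is absent
        (``present_mask`` False) may hold NaN.
    landmark_names : sequence of str, optional
        Names per landmark; defaults to ``L1..LK``.
    present_mask : (K,) bool ndarray, optional
        False marks a landmark missing on this specimen; such landmarks are
        excluded from any analysis that uses them.  Defaults to all True
        (non-finite coordinate rows are auto-marked missing).
    """

    specimen_id: str
    population: str
    age_category: AgeCategory
    coords: np.ndarray
    landmark_names: Sequence[str] | None = None
    present_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age_category = AgeCategory.coerce(self.age_category)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (K, 3), got shape {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError(f"need at least 3 landmarks, got {coords.shape[0]}")
        self.coords = coords
        k = coords.shape[0]
        if self.landmark_names is None:
            self.landmark_names = [f"L{i + 1}" for i in range(k)]
        else:
            self.landmark_names = [str(n) for n in self.landmark_names]
            if len(self.landmark_names) != k:
                raise ValueError("landmark_names length must match coords")
        if self.present_mask is None:
            self.present_mask = np.isfinite(coords).all(axis=1)
        else:
            self.present_mask = np.asarray(self.present_mask, dtype=bool)
            if self.present_mask.shape != (k,):
                raise ValueError("present_mask shape must be (K,)")
            # a landmark with non-finite coordinates can never be "present"
            self.present_mask = self.present_mask & np.isfinite(coords).all(axis=1)
        if not np.isfinite(coords[self.present_mask]).all():
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return bool(self.present_mask.all())

    def subset(self, region: "RegionDefinition") -> "LandmarkConfiguration":
        """Return the configuration restricted to a region's landmarks."""
        return subset_region(self, region)


@dataclass(frozen=True)
class RegionDefinition:
    """A named subset of the landmark scheme, by 1-based landmark numbers.

    Regions may overlap (several landmarks sit on sutures between cranial
    bones and belong to more than one region).
    """

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"region {self.name!r} has duplicate indices")
        if any(i < 1 for i in idx):
            raise ValueError(f"region {self.name!r} indices are 1-based, got {min(idx)}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def zero_based(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int) - 1


# The bundled 44-landmark basicranial scheme: three overlapping cranial-bone
# regions.  Landmarks 1, 2, 13, 33, 36 lie on sutures and are shared.
OCCIPITAL = RegionDefinition("occipital", tuple(range(1, 14)))
TEMPORAL = RegionDefinition("temporal", tuple(range(13, 35)) + (36, 37))
SPHENOID = RegionDefinition("sphenoid", (1, 2, 33, 35, 36) + tuple(range(38, 45)))
BASICRANIUM = RegionDefinition("basicranium", tuple(range(1, 45)))

DEFAULT_REGIONS: dict[str, RegionDefinition] = {
    r.name: r for r in (BASICRANIUM, TEMPORAL, OCCIPITAL, SPHENOID)
}


def subset_region(
    config: LandmarkConfiguration, region: RegionDefinition
) -> LandmarkConfiguration:
    """Restrict a configuration to a region's landmarks, in region order."""
    idx = region.zero_based()
    if idx.size and idx.max() >= config.n_landmarks:
        raise IndexError(
            f"region {region.name!r} index {idx.max() + 1} exceeds "
            f"K={config.n_landmarks} of specimen {config.specimen_id!r}"
        )
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        population=config.population,
        age_category=config.age_category,
        coords=config.coords[idx].copy(),
        landmark_names=[config.landmark_names[i] for i in idx],
        present_mask=config.present_mask[idx].copy(),
    )


def filter_complete(
    configs: Iterable[LandmarkConfiguration],
    region: RegionDefinition | None = None,
    verbose: bool = False,
) -> list[LandmarkConfiguration]:
    """Keep only specimens with every landmark of ``region`` present.

    Specimens incomplete for a region are excluded from that region's
    analyses rather than imputed.  Returns the region-subset configurations;
    with ``region=None`` filters on completeness of the full configuration.
    """
    kept: list[LandmarkConfiguration] = []
    removed: dict[tuple[str, str], int] = {}
    for cfg in configs:
        sub = subset_region(cfg, region) if region is not None else cfg
        if sub.is_complete:
            kept.append(sub)
        else:
            key = (cfg.population, cfg.age_category.value)
            removed[key] = removed.get(key, 0) + 1
    if removed and verbose:
        for (pop, ac), n in sorted(removed.items()):
            warnings.warn(
                f"excluded {n} incomplete specimen(s) from {pop}/{ac}"
                + (f" for region {region.name!r}" if region is not None else ""),
                stacklevel=2,
            )
    if not kept:
        warnings.warn("no complete specimens remain after filtering", stacklevel=2)
    return kept


class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix with zero diagonal.

    Used both for morphological (Procrustes) and molecular (F_ST / Slatkin)
    distances.  Label order defines row/column order; all alignment between
    matrices is done by label, never by position.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray, *, check: bool = True):
        self.labels = [str(l) for l in labels]
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if check:
            if not np.isfinite(values).all():
                raise ValueError("non-finite entries in distance matrix")
            if np.abs(values - values.T).max(initial=0.0) > 1e-9:
                raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
            if np.abs(np.diag(values)).max(initial=0.0) > 1e-9:
                raise ValueError("distance matrix diagonal is not zero")
            if values.min(initial=0.0) < -1e-12:
                raise ValueError("negative entries in distance matrix")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        self.values = np.clip(values, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy 'condensed' form)."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns re-ordered to ``labels``."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        if len(labels) != self.n:
            raise ValueError("reorder requires the full label set")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], check=False)

    def drop(self, label: str) -> "DistanceMatrix":
        """Return a copy with one population's row and column removed."""
        if label not in self.labels:
            raise KeyError(f"label {label!r} not in matrix (have {self.labels})")
        keep = [i for i, l in enumerate(self.labels) if l != label]
        return DistanceMatrix(
            [self.labels[i] for i in keep],
            self.values[np.ix_(keep, keep)],
            check=False,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n}, labels={self.labels})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


MISSING_ALLELE = -1


class STRGenotypeTable:
    """Diploid microsatellite genotypes: individuals x loci allele repeat sizes.

    ``genotypes`` is an (n, L, 2) integer array of allele repeat sizes;
    missing alleles are coded :data:`MISSING_ALLELE` (never zero).  Allele
    order within a genotype is not meaningful.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        populations: Sequence[str],
        loci: Sequence[str],
        genotypes: np.ndarray,
    ):
        self.individual_ids = [str(i) for i in individual_ids]
        self.populations = [str(p) for p in populations]
        self.loci = [str(l) for l in loci]
        g = np.asarray(genotypes, dtype=int)
        n, L = len(self.individual_ids), len(self.loci)
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(self.populations) != n:
            raise ValueError("populations length must match individuals")
        if g.shape != (n, L, 2):
            raise ValueError(f"genotypes shape {g.shape}, expected {(n, L, 2)}")
        valid = g != MISSING_ALLELE
        if (g[valid] <= 0).any():
            raise ValueError("allele repeat sizes must be positive integers")
        # a genotype is missing as a whole: half-missing pairs are invalid
        if (valid[..., 0] != valid[..., 1]).any():
            raise ValueError("half-missing genotypes are not allowed")
        self.genotypes = g

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        return np.asarray([p == population for p in self.populations], dtype=bool)

    def __repr__(self) -> str:
        return (
            f"STRGenotypeTable(n={self.n_individuals}, loci={self.n_loci}, "
            f"populations={self.population_labels})"
        )
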