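"""Config-driven end-to-end pipeline.

One run covers, for each cranial region and age grouping: superimposition,
shape PCA, pairwise population distances with permutation significance,
leave-one-out discriminant classification, and PC-on-age / PC-on-size
regressions; plus, when genotypes are available, the molecular F_ST matrix
and Mantel concordance tests with a population-exclusion sensitivity scan.
All outputs are plain-text tables under an output directory together with a
JSON manifest (seed, config hash, package version) that makes the run
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import exclusion_scan, mantel
from .core import (
    AgeCategory,
    AgeEncoding,
    DEFAULT_REGIONS,
    DistanceMatrix,
    LandmarkConfiguration,
    RegionDefinition,
    STRGenotypeTable,
    filter_complete,
)
from .group_inference import lda_loocv, pairwise_permutation_test
from .io import export_wireframe, read_genotypes, read_landmarks, write_matrix
from .popgen import FstOptions, pairwise_fst
from .procrustes import gpa
from .shape_pca import fit_pca
from .synthetic import SyntheticConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("morphokin.pipeline")

#: The four analysis groupings: combined subadults and each subadult stage.
AGE_GROUPINGS: dict[str, tuple[AgeCategory, ...]] = {
    "all_subadults": (AgeCategory.AC1, AgeCategory.AC2, AgeCategory.AC3),
    "AC1": (AgeCategory.AC1,),
    "AC2": (AgeCategory.AC2,),
    "AC3": (AgeCategory.AC3,),
}


@dataclass
class PipelineConfig:
    """Inputs and switches for one pipeline run.

    Exactly one landmark source may be given: ``landmarks_path`` (TPS or
    table file) or ``synthetic`` (a generator config).  ``genotypes_path``
    supplies molecular data when landmarks come from files.  With
    ``morph_matrices`` (mapping of grouping name -> matrix file) and
    ``mol_matrix`` set, the run is fixture-only: Mantel reports are computed
    straight from the distance matrices.
    """

    outdir: str | Path
    seed: int = 0
    landmarks_path: str | Path | None = None
    landmarks_format: str = "tps"
    genotypes_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    morph_matrices: Mapping[str, str | Path] | None = None
    mol_matrix: str | Path | None = None
    regions: Mapping[str, RegionDefinition] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    n_perm: int = 1000
    mantel_tail: str = "upper"
    fst_options: FstOptions = field(default_factory=FstOptions)
    age_encoding: AgeEncoding = field(default_factory=AgeEncoding)
    run_permutations: bool = True
    run_classification: bool = True
    run_regressions: bool = True
    wireframe_edges: Sequence[tuple[int, int]] | None = None

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "landmarks": str(self.landmarks_path),
            "genotypes": str(self.genotypes_path),
            "synthetic": None if self.synthetic is None else vars(self.synthetic).get("seed"),
            "regions": {n: list(r.indices) for n, r in self.regions.items()},
            "n_perm": self.n_perm,
            "tail": self.mantel_tail,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns a report dict of output paths and key results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report: dict = {"outputs": [], "mantel": None, "classification": {}}
    rng = np.random.default_rng(config.seed)

    try:
        configs: list[LandmarkConfiguration] | None = None
        genotypes: STRGenotypeTable | None = None
        mol: DistanceMatrix | None = None
        morph_fixed: dict[str, DistanceMatrix] = {}

        with _stage("inputs"):
            if config.synthetic is not None:
                configs, genotypes, _truth = simulate_study(config.synthetic)
                logger.info(
                    "simulated %d specimens, %d genotyped individuals",
                    len(configs),
                    genotypes.n_individuals,
                )
            elif config.landmarks_path is not None:
                configs = read_landmarks(config.landmarks_path, config.landmarks_format)
                logger.info("read %d specimens from %s", len(configs), config.landmarks_path)
            if config.genotypes_path is not None:
                genotypes = read_genotypes(config.genotypes_path)
            if config.morph_matrices is not None:
                from .io import read_matrix

                morph_fixed = {
                    name: read_matrix(path) for name, path in config.morph_matrices.items()
                }
            if config.mol_matrix is not None:
                from .io import read_matrix

                mol = read_matrix(config.mol_matrix)

        if genotypes is not None:
            with _stage("fst"):
                mol = pairwise_fst(genotypes, config.fst_options)
                path = outdir / "fst.tsv"
                write_matrix(mol, path)
                report["outputs"].append(str(path))

        morph_by_region_grouping: dict[tuple[str, str], DistanceMatrix] = {}

        if configs is not None:
            for region_name, region in config.regions.items():
                with _stage(f"region:{region_name}"):
                    complete = filter_complete(configs, region)
                    n_removed = len(configs) - len(complete)
                    if n_removed:
                        logger.info(
                            "region %s: excluded %d incomplete specimens",
                            region_name,
                            n_removed,
                        )
                    if len(complete) < 3:
                        logger.warning("region %s: too few specimens, skipped", region_name)
                        continue

                    # full-sample superimposition + PCA (adults included, for
                    # visualisation and classification inputs)
                    sample = gpa(complete)
                    pca = fit_pca(sample)
                    scores_path = outdir / f"scores_{region_name}.csv"
                    _write_scores(pca, sample, scores_path)
                    report["outputs"].append(str(scores_path))

                    subadult_mask = np.array(
                        [c.age_category != AgeCategory.ADULT for c in complete]
                    )

                    if config.run_classification and subadult_mask.sum() >= 10:
                        sub_scores = pca.scores[subadult_mask]
                        sub_labels = [
                            c.population for c, m in zip(complete, subadult_mask) if m
                        ]
                        try:
                            cm = lda_loocv(
                                sub_scores,
                                sub_labels,
                                variance_fractions=pca.variance_fractions,
                            )
                            path = outdir / f"classification_{region_name}.csv"
                            cm.to_dataframe().to_csv(path)
                            report["outputs"].append(str(path))
                            report["classification"][region_name] = cm.overall_pct
                            logger.info(
                                "region %s: %.1f%% cross-validated correct",
                                region_name,
                                cm.overall_pct,
                            )
                        except ValueError as exc:
                            logger.warning("classification skipped (%s): %s", region_name, exc)

                    if config.run_regressions:
                        reg_path = outdir / f"regressions_{region_name}.csv"
                        _write_regressions(pca, sample, complete, config.age_encoding, reg_path)
                        report["outputs"].append(str(reg_path))

                    if config.wireframe_edges is not None or region_name == "basicranium":
                        edges = list(
                            config.wireframe_edges
                            or [(i, i + 1) for i in range(1, sample.n_landmarks)]
                        )
                        for pc in pca.flagged_components(0.05)[:4]:
                            s = 2.0 * float(np.std(pca.scores[:, pc]))
                            for sign, tag in ((+s, "pos"), (-s, "neg")):
                                path = outdir / f"wireframe_{region_name}_PC{pc + 1}_{tag}.obj"
                                export_wireframe(pca.morph_along_pc(pc, sign), edges, path)
                                report["outputs"].append(str(path))

                    # per-grouping distance matrices with permutation p-values
                    for grouping, cats in AGE_GROUPINGS.items():
                        members = [c for c in complete if c.age_category in cats]
                        pops = {c.population for c in members}
                        counts = {p: sum(c.population == p for c in members) for p in pops}
                        usable = {p for p, n in counts.items() if n >= 2}
                        members = [c for c in members if c.population in usable]
                        if len(usable) < 2:
                            logger.warning(
                                "region %s / %s: fewer than 2 usable groups, skipped",
                                region_name,
                                grouping,
                            )
                            continue
                        sub_sample = gpa(members)
                        if config.run_permutations:
                            perm_seed = int(rng.integers(0, 2**31 - 1))
                            res = pairwise_permutation_test(
                                sub_sample, n_perm=config.n_perm, seed=perm_seed
                            )
                            dm = res.matrix
                            ppath = outdir / f"pvalues_{region_name}_{grouping}.tsv"
                            _write_pvalues(res, ppath)
                            report["outputs"].append(str(ppath))
                        else:
                            from .group_inference import population_distance_matrix

                            dm = population_distance_matrix(sub_sample)
                        dpath = outdir / f"distances_{region_name}_{grouping}.tsv"
                        write_matrix(dm, dpath)
                        report["outputs"].append(str(dpath))
                        morph_by_region_grouping[(region_name, grouping)] = dm

        if config.morph_matrices is not None:
            # fixture-only mode: treat supplied matrices as the basicranium suite
            for grouping, dm in morph_fixed.items():
                morph_by_region_grouping[("basicranium", grouping)] = dm

        if mol is not None and morph_by_region_grouping:
            with _stage("mantel"):
                rows = []
                for (region_name, grouping), dm in sorted(morph_by_region_grouping.items()):
                    common = sorted(set(dm.labels) & set(mol.labels))
                    if len(common) < 4:
                        continue
                    dsub = _restrict(dm, common)
                    msub = _restrict(mol, common)
                    res = mantel(
                        dsub,
                        msub,
                        tail=config.mantel_tail,
                        seed=config.seed,
                        n_perm=min(config.n_perm * 10, 9999),
                    )
                    rows.append(
                        {
                            "region": region_name,
                            "grouping": grouping,
                            "n": res.n_labels,
                            "r": res.r,
                            "p": res.p,
                            "p_upper": res.p_upper,
                            "p_lower": res.p_lower,
                            "method": res.method,
                        }
                    )
                    if grouping == "all_subadults" and len(common) >= 5:
                        scan = exclusion_scan(
                            dsub,
                            msub,
                            tail=config.mantel_tail,
                            seed=config.seed,
                            n_perm=min(config.n_perm * 10, 9999),
                        )
                        spath = outdir / f"exclusion_{region_name}.csv"
                        scan.to_csv(spath, index=False)
                        report["outputs"].append(str(spath))
                mantel_df = pd.DataFrame(rows)
                mpath = outdir / "mantel_report.csv"
                mantel_df.to_csv(mpath, index=False)
                report["outputs"].append(str(mpath))
                report["mantel"] = mantel_df

        manifest = {
            "package": "morphokin",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.digest(),
            "n_perm": config.n_perm,
            "outputs": report["outputs"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report["manifest"] = manifest
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _restrict(matrix: DistanceMatrix, labels: list[str]) -> DistanceMatrix:
    m = matrix
    for label in [l for l in matrix.labels if l not in labels]:
        m = m.drop(label)
    return m.reorder(labels)


def _write_scores(pca, sample, path: Path) -> None:
    cols = {f"PC{i + 1}": pca.scores[:, i] for i in range(min(pca.n_components, 10))}
    df = pd.DataFrame(cols)
    if sample.configs is not None:
        df.insert(0, "specimen_id", [c.specimen_id for c in sample.configs])
        df.insert(1, "population", [c.population for c in sample.configs])
        df.insert(2, "age_category", [c.age_category.value for c in sample.configs])
    df["centroid_size"] = sample.centroid_sizes
    df.to_csv(path, index=False)


def _write_pvalues(res, path: Path) -> None:
    labels = res.matrix.labels
    lines = ["\t" + "\t".join(labels)]
    for i, label in enumerate(labels):
        cells = []
        for j in range(len(labels)):
            v = res.p_values[i, j]
            cells.append("" if math.isnan(v) else f"{v:.4f}")
        lines.append(label + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_regressions(pca, sample, configs, age_encoding: AgeEncoding, path: Path) -> None:
    """Per-population and all-population PC regressions on age and log size
    (only subadults carry estimable dental ages; adults use the configured
    nominal age)."""
    ages = np.array([age_encoding.numeric_age(c.age_category) for c in configs])
    logcs = np.log(sample.centroid_sizes)
    pops = np.array([c.population for c in configs])
    n_pc = min(pca.n_components, 6)
    rows = []
    scopes = [("ALL", np.ones(len(configs), dtype=bool))] + [
        (p, pops == p) for p in sorted(set(pops))
    ]
    for covariate, values in (("numeric_age", ages), ("log_centroid_size", logcs)):
        for scope, mask in scopes:
            for pc in range(n_pc):
                if mask.sum() < 3 or np.ptp(values[mask]) == 0:
                    continue
                reg = pca.regress(values, pc, covariate=covariate, scope=scope, mask=mask)
                rows.append(
                    {
                        "covariate": covariate,
                        "scope": scope,
                        "pc": pc + 1,
                        "r": reg.r,
                        "p": reg.p,
                        "slope": reg.slope,
                        "n": reg.n,
                        "significant": reg.significant,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
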