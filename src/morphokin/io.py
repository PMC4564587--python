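"""Readers and writers for landmark, genotype, distance-matrix and wireframe files.

Supported formats, all plain text:

* TPS (3D ``LM3=`` blocks) landmark files.  Each block is ``LM3=K``, K lines
  of ``x y z``, then a mandatory ``ID=`` line; optional ``POPULATION=`` and
  ``AGE=`` lines carry metadata, and ``SCALE=`` lines are ignored.  A
  coordinate line of ``NA NA NA`` marks a missing landmark.
* Tidy landmark tables (CSV): one row per (specimen, landmark) with columns
  ``specimen_id, population, age_category, landmark, x, y, z``; blank
  coordinate cells mark missing landmarks.
* Genotype tables (CSV): one row per individual, ``individual_id,
  population`` then one ``a1/a2`` column per locus, ``.`` for missing.
* Square labelled distance matrices: header row of labels, then one row per
  label (label followed by n numeric entries).
* OBJ-style wireframes: ``v x y z`` vertex records and ``l i j`` edge records.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING_ALLELE,
    AgeCategory,
    DistanceMatrix,
    LandmarkConfiguration,
    STRGenotypeTable,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_genotypes",
    "write_genotypes",
    "read_matrix",
    "write_matrix",
    "export_wireframe",
    "read_wireframe",
]

_FMT = "%.6f"


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path: str | Path, format: str = "tps") -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or tidy-table file."""
    path = Path(path)
    if format == "tps":
        configs = _read_tps(path)
    elif format == "table":
        configs = _read_table(path)
    else:
        raise ValueError(f"unknown landmark format {format!r} (use 'tps' or 'table')")
    ids = [c.specimen_id for c in configs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate specimen ids in {path}: {sorted(dupes)}")
    return configs


def _read_tps(path: Path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM3="):
            raise ValueError(f"{path}: expected 'LM3=' header, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = np.full((k, 3), np.nan)
        for j in range(k):
            if i >= len(lines):
                raise ValueError(f"{path}: truncated coordinate block (expected {k} rows)")
            parts = lines[i].split()
            i += 1
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: coordinate line {i} has {len(parts)} fields, expected 3"
                )
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                coords[j] = np.nan  # NA / missing landmark
        meta = {"ID": None, "POPULATION": "unknown", "AGE": "ADULT"}
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, _, val = lines[i].partition("=")
            key = key.strip().upper()
            if key in meta or key == "SCALE":
                if key != "SCALE":
                    meta[key] = val.strip()
                i += 1
            else:
                break
        if meta["ID"] is None:
            raise ValueError(f"{path}: TPS block without mandatory ID= line")
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta["ID"],
                population=meta["POPULATION"],
                age_category=AgeCategory.coerce(meta["AGE"]),
                coords=coords,
            )
        )
    return configs


def _read_table(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, dtype={"specimen_id": str, "population": str})
    required = {"specimen_id", "population", "age_category", "landmark", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    configs = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                population=str(grp["population"].iloc[0]),
                age_category=AgeCategory.coerce(grp["age_category"].iloc[0]),
                coords=coords,
                landmark_names=[str(n) for n in grp["landmark"]],
            )
        )
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration], path: str | Path, format: str = "tps"
) -> None:
    """Write configurations as TPS (LM3 dialect) or a tidy CSV table."""
    path = Path(path)
    if format == "tps":
        out = []
        for c in configs:
            out.append(f"LM3={c.n_landmarks}")
            for j in range(c.n_landmarks):
                if c.present_mask[j]:
                    out.append(" ".join(_FMT % v for v in c.coords[j]))
                else:
                    out.append("NA NA NA")
            out.append(f"ID={c.specimen_id}")
            out.append(f"POPULATION={c.population}")
            out.append(f"AGE={c.age_category.value}")
            out.append("")
        path.write_text("\n".join(out))
    elif format == "table":
        rows = []
        for c in configs:
            for j in range(c.n_landmarks):
                x, y, z = (
                    (_FMT % v for v in c.coords[j]) if c.present_mask[j] else ("", "", "")
                )
                rows.append(
                    {
                        "specimen_id": c.specimen_id,
                        "population": c.population,
                        "age_category": c.age_category.value,
                        "landmark": c.landmark_names[j],
                        "x": x,
                        "y": y,
                        "z": z,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path) -> STRGenotypeTable:
    """Read a diploid STR genotype table (CSV, 'a1/a2' cells, '.' missing)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["individual_id", "population"]:
            raise ValueError(
                f"{path}: first two columns must be individual_id, population"
            )
        loci = header[2:]
        ids, pops, geno = [], [], []
        for row in reader:
            if not row:
                continue
            ids.append(row[0])
            pops.append(row[1])
            pairs = []
            for locus, cell in zip(loci, row[2:]):
                cell = cell.strip()
                if cell in (".", "", "./."):
                    pairs.append((MISSING_ALLELE, MISSING_ALLELE))
                else:
                    a, _, b = cell.partition("/")
                    try:
                        pairs.append((int(a), int(b)))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: bad genotype {cell!r} at {row[0]}/{locus}"
                        ) from exc
            geno.append(pairs)
    return STRGenotypeTable(ids, pops, loci, np.asarray(geno, dtype=int))


def write_genotypes(table: STRGenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "population"] + table.loci)
        for i, (iid, pop) in enumerate(zip(table.individual_ids, table.populations)):
            cells = []
            for l in range(table.n_loci):
                a, b = table.genotypes[i, l]
                cells.append("." if a == MISSING_ALLELE else f"{a}/{b}")
            writer.writerow([iid, pop] + cells)


# ---------------------------------------------------------------------------
# distance matrices


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labelled distance matrix (tab- or comma-separated)."""
    path = Path(path)
    text = path.read_text().strip()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return DistanceMatrix(labels, values)


def write_matrix(matrix: DistanceMatrix, path: str | Path, fmt: str = "%.6f") -> None:
    path = Path(path)
    lines = ["\t" + "\t".join(matrix.labels)]
    for label, row in zip(matrix.labels, matrix.values):
        lines.append(label + "\t" + "\t".join(fmt % v for v in row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# wireframes


def export_wireframe(
    shape: np.ndarray, edges: Sequence[tuple[int, int]], path: str | Path
) -> None:
    """Write a landmark shape and connecting edges as an OBJ-style wireframe.

    Vertices are ``v x y z`` records; edges are ``l i j`` records with
    1-based vertex indices.
    """
    shape = np.asarray(shape, dtype=float)
    k = shape.shape[0]
    for i, j in edges:
        if not (1 <= i <= k and 1 <= j <= k):
            raise IndexError(f"edge ({i}, {j}) out of range for {k} vertices")
    lines = [f"v {_FMT % x} {_FMT % y} {_FMT % z}" for x, y, z in shape]
    lines += [f"l {i} {j}" for i, j in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_wireframe(path: str | Path) -> tuple[np.ndarray, list[tuple[int, int]]]:
    verts, edges = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(p) for p in parts[1:4]])
        elif parts[0] == "l":
            edges.append((int(parts[1]), int(parts[2])))
    return np.asarray(verts, dtype=float), edges
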