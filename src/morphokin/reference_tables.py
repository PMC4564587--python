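"""Bundled reference distance matrices for a seven-population study system.

These are published summary matrices for seven modern human population
samples (Alaska, Austria, Egypt, Mexico, Peru, Polynesia, Utah):

* ``reference_fst_matrix`` — pairwise multilocus F_ST among the populations'
  molecular representatives, estimated from a large panel of autosomal STR
  loci (values roughly 0.04-0.15).
* ``reference_procrustes_matrix(group)`` — pairwise Procrustes distances
  between population mean basicranial shapes, for the combined subadult
  sample ('all_subadults') and the three ontogenetic stages ('AC1', 'AC2',
  'AC3').

They serve as deterministic fixtures: concordance analyses on them are fully
reproducible, and the synthetic-data generator uses the F_ST matrix as its
default drift-calibration target.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import DistanceMatrix
from .io import write_matrix

__all__ = [
    "REFERENCE_POPULATIONS",
    "reference_fst_matrix",
    "reference_procrustes_matrix",
    "make_fixture_tables",
]

REFERENCE_POPULATIONS = [
    "Alaska",
    "Austria",
    "Egypt",
    "Mexico",
    "Peru",
    "Polynesia",
    "Utah",
]

# lower triangles, row-wise, in REFERENCE_POPULATIONS order
_FST_TRI = [
    [0.0455],
    [0.0530, 0.1068],
    [0.0580, 0.0606, 0.0731],
    [0.0951, 0.0984, 0.1110, 0.0443],
    [0.0759, 0.0759, 0.0808, 0.1028, 0.1443],
    [0.0984, 0.1076, 0.1190, 0.0600, 0.0973, 0.1461],
]

_PROCRUSTES_TRI = {
    "all_subadults": [
        [0.0361],
        [0.0779, 0.0703],
        [0.0398, 0.0444, 0.0745],
        [0.0493, 0.0513, 0.0846, 0.0411],
        [0.0618, 0.0532, 0.0809, 0.0631, 0.0740],
        [0.0694, 0.0684, 0.0998, 0.0638, 0.0548, 0.0805],
    ],
    "AC1": [
        [0.1580],
        [0.1110, 0.1611],
        [0.1341, 0.1518, 0.0816],
        [0.1127, 0.1867, 0.1581, 0.1571],
        [0.1045, 0.1735, 0.1066, 0.1102, 0.1519],
        [0.1068, 0.1485, 0.1040, 0.0908, 0.1592, 0.1019],
    ],
    "AC2": [
        [0.0870],
        [0.1289, 0.1337],
        [0.0831, 0.0765, 0.0948],
        [0.1035, 0.0867, 0.1423, 0.0799],
        [0.0799, 0.0940, 0.1016, 0.0849, 0.1115],
        [0.0888, 0.0869, 0.1039, 0.0722, 0.0871, 0.0715],
    ],
    "AC3": [
        [0.0543],
        [0.0994, 0.0921],
        [0.0559, 0.0601, 0.0909],
        [0.0558, 0.0682, 0.1021, 0.0506],
        [0.0659, 0.0620, 0.1031, 0.0774, 0.0796],
        [0.0953, 0.0960, 0.1382, 0.0886, 0.0795, 0.1042],
    ],
}


def _from_lower_triangle(tri: list[list[float]]) -> DistanceMatrix:
    n = len(tri) + 1
    m = np.zeros((n, n))
    for i, row in enumerate(tri, start=1):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return DistanceMatrix(REFERENCE_POPULATIONS, m)


def reference_fst_matrix() -> DistanceMatrix:
    """The bundled 7x7 molecular F_ST reference matrix."""
    return _from_lower_triangle(_FST_TRI)


def reference_procrustes_matrix(group: str = "all_subadults") -> DistanceMatrix:
    """A bundled 7x7 basicranial Procrustes distance matrix.

    ``group`` is one of 'all_subadults', 'AC1', 'AC2', 'AC3'.
    """
    if group not in _PROCRUSTES_TRI:
        raise KeyError(f"unknown group {group!r}; have {sorted(_PROCRUSTES_TRI)}")
    return _from_lower_triangle(_PROCRUSTES_TRI[group])


def make_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Write every bundled reference matrix as a labelled matrix file.

    Returns a mapping from matrix name to the written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    path = outdir / "fst_reference.tsv"
    write_matrix(reference_fst_matrix(), path, fmt="%.4f")
    written["fst"] = path
    for group in _PROCRUSTES_TRI:
        path = outdir / f"procrustes_{group}.tsv"
        write_matrix(reference_procrustes_matrix(group), path, fmt="%.4f")
        written[group] = path
    return written
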