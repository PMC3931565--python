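"""Readers and writers for the pipeline's tabular formats.

All tables are long-format CSV (one observation per row); the pairwise
sequence-divergence matrix is additionally accepted as a PHYLIP-style square
matrix or a newick tree (converted to patristic distances via dendropy).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import WellSeries

__all__ = [
    "FormatError",
    "StrainRecord",
    "CrossRecord",
    "DivergenceMatrix",
    "read_plate_timeseries",
    "write_plate_timeseries",
    "wells_from_frame",
    "read_strain_metadata",
    "read_cross_design",
    "read_divergence_matrix",
    "write_divergence_matrix",
    "divergence_from_newick",
    "write_manifest",
    "sha256_of",
]

ORIGINS = ("wild", "domesticated")

PLATE_COLUMNS = ["strain", "environment", "replicate", "time_h", "od"]


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


@dataclass(frozen=True)
class StrainRecord:
    strain_id: str
    origin: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise FormatError(
                f"origin of {self.strain_id!r} must be one of {ORIGINS}, "
                f"got {self.origin!r}"
            )


@dataclass(frozen=True)
class CrossRecord:
    hybrid_id: str
    parent1: str
    parent2: str
    cross_class: str | None = None

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise FormatError(f"hybrid {self.hybrid_id!r} has identical parents")


@dataclass
class DivergenceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise FormatError(f"matrix shape {self.d.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise FormatError("divergence labels are not unique")
        if np.any(self.d < -1e-9):
            raise FormatError("divergence matrix has negative entries")
        if np.max(np.abs(self.d - self.d.T)) > 1e-9:
            raise FormatError("divergence matrix is not symmetric (tolerance 1e-9)")
        diag = np.diag(self.d)
        if np.any(np.abs(diag) > 1e-9):
            raise FormatError("divergence matrix has a nonzero diagonal")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# plate OD time series
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_plate_timeseries(path: str | Path) -> list[WellSeries]:
    """Read a long-format plate CSV into one :class:`WellSeries` per culture.

    Groups with fewer than 3 time points are kept but flagged unusable;
    duplicate (culture, time) rows are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, str(path))
    for col in ("time_h", "od"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, counting the header line
            raise FormatError(f"{path}: non-numeric {col!r} at line {row}")
        df[col] = coerced
    if df[["time_h", "od"]].isna().any().any():
        raise FormatError(f"{path}: empty time_h/od cells")
    wells: list[WellSeries] = []
    for (strain, env, rep), grp in df.groupby(
        ["strain", "environment", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise FormatError(
                f"{path}: duplicate time points for culture ({strain}, {env}, {rep})"
            )
        w = WellSeries(
            strain_id=str(strain),
            environment_id=str(env),
            replicate=int(rep),
            times=grp["time_h"].to_numpy(),
            od_raw=grp["od"].to_numpy(),
        )
        if len(w) < 3:
            w.usable = False
            w.flags.append("too_few_points")
        wells.append(w)
    return wells


def wells_from_frame(df: pd.DataFrame) -> list[WellSeries]:
    """Same contract as :func:`read_plate_timeseries` for an in-memory frame."""
    _require_columns(df, PLATE_COLUMNS, "plate table")
    wells = []
    for (strain, env, rep), grp in df.groupby(
        ["strain", "environment", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise FormatError(
                f"duplicate time points for culture ({strain}, {env}, {rep})"
            )
        w = WellSeries(
            strain_id=str(strain),
            environment_id=str(env),
            replicate=int(rep),
            times=grp["time_h"].to_numpy(dtype=float),
            od_raw=grp["od"].to_numpy(dtype=float),
        )
        if len(w) < 3:
            w.usable = False
            w.flags.append("too_few_points")
        wells.append(w)
    return wells


def write_plate_timeseries(wells: list[WellSeries] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(wells, pd.DataFrame):
        df = wells[PLATE_COLUMNS]
    else:
        rows = []
        for w in wells:
            for t, od in zip(w.times, w.od_raw):
                rows.append((w.strain_id, w.environment_id, w.replicate, t, od))
        df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# strain metadata and cross design
# ---------------------------------------------------------------------------

def read_strain_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain table (columns strain, origin); origins validated."""
    df = pd.read_csv(path)
    _require_columns(df, ["strain", "origin"], str(path))
    if df["strain"].duplicated().any():
        dup = df.loc[df["strain"].duplicated(), "strain"].iloc[0]
        raise FormatError(f"{path}: duplicate strain id {dup!r}")
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        raise FormatError(
            f"{path}: origin must be one of {ORIGINS}, got "
            f"{df.loc[bad, 'origin'].iloc[0]!r}"
        )
    return df[["strain", "origin"]].astype({"strain": str})


def read_cross_design(path: str | Path) -> pd.DataFrame:
    """Read the hybrid design table (columns hybrid, parent1, parent2)."""
    df = pd.read_csv(path)
    _require_columns(df, ["hybrid", "parent1", "parent2"], str(path))
    if (df["parent1"] == df["parent2"]).any():
        h = df.loc[df["parent1"] == df["parent2"], "hybrid"].iloc[0]
        raise FormatError(f"{path}: hybrid {h!r} has identical parents")
    pairs = df.apply(lambda r: frozenset((r["parent1"], r["parent2"])), axis=1)
    if pairs.duplicated().any():
        h = df.loc[pairs.duplicated(), "hybrid"].iloc[0]
        raise FormatError(f"{path}: duplicate parent pair for hybrid {h!r}")
    return df[["hybrid", "parent1", "parent2"]].astype(str)


# ---------------------------------------------------------------------------
# divergence matrix
# ---------------------------------------------------------------------------

def read_divergence_matrix(path: str | Path) -> DivergenceMatrix:
    """Read a labeled square CSV or a PHYLIP-style square distance matrix."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first and first.split()[0].isdigit() and "," not in first:
        return _read_phylip_square(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: divergence matrix is not square {df.shape}")
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise FormatError(f"{path}: row and column labels differ")
    return DivergenceMatrix(labels, df.to_numpy(dtype=float))


def _read_phylip_square(path: Path) -> DivergenceMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FormatError(f"{path}: empty PHYLIP matrix")
    n = int(tokens[0])
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise FormatError(
            f"{path}: PHYLIP square matrix with n={n} needs {expected} tokens, "
            f"found {len(tokens)}"
        )
    labels, rows = [], []
    pos = 1
    for _ in range(n):
        labels.append(tokens[pos])
        rows.append([float(x) for x in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return DivergenceMatrix(labels, np.array(rows))


def write_divergence_matrix(matrix: DivergenceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="")


def divergence_from_newick(path: str | Path) -> DivergenceMatrix:
    """Patristic distances from a newick tree (branch-length sums between tips)."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DivergenceMatrix(labels, d)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    parameters: dict,
    seed: int | None = None,
    inputs: dict[str, str | Path] | None = None,
) -> None:
    """JSON record of a pipeline run: command, parameters, seed, input hashes."""
    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in (inputs or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
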