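"""File-backed genotype storage.

The marker matrix is kept in a single binary file (little-endian, float64,
column-major so each marker's scores are one contiguous block) with a JSON
sidecar descriptor.  The matrix is addressed through :class:`numpy.memmap`
and is never duplicated in full: scans read one marker column at a time,
and imputation rewrites columns in place.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "MarkerInfo",
    "Phenotype",
    "CovariateMatrix",
    "load_text_genotypes",
    "read_marker_map",
    "read_phenotype",
    "read_covariates",
    "impute_missing",
    "attach",
]

_DESCRIPTOR_SUFFIX = ".desc.json"


class GenotypeStoreError(Exception):
    """Base error for genotype-store problems."""


class GenotypeParseError(GenotypeStoreError):
    """A genotype table could not be parsed."""


class GenotypeValidationError(GenotypeStoreError):
    """Parsed genotype scores violate the [0, 2] contract."""


class StoreTypeError(GenotypeStoreError):
    """The backing file is not double precision."""


class StoreCorruptionError(GenotypeStoreError):
    """Descriptor and binary file disagree."""


@dataclass
class MarkerMatrix:
    """n x m genotype scores, individuals in rows, markers in columns.

    ``values`` is a float64 memmap onto ``data_path``; every column is a
    contiguous run of the backing file.  Missing scores are represented as
    NaN until :func:`impute_missing` runs.
    """

    values: np.ndarray
    sample_ids: list[str]
    descriptor_path: Path | None = None
    data_path: Path | None = None

    def __post_init__(self) -> None:
        if self.values.dtype != np.float64:
            raise StoreTypeError(
                f"marker matrix must be double precision, got {self.values.dtype}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise StoreCorruptionError("sample_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        """Memmap view (no copy) of marker ``j``'s scores."""
        return self.values[:, j]

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def flush(self) -> None:
        if isinstance(self.values, np.memmap):
            self.values.flush()


@dataclass
class MarkerInfo:
    """Marker map: name, chromosome label, 1-based base-pair position."""

    name: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.name = np.asarray(self.name, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if not (len(self.name) == len(self.chromosome) == len(self.position)):
            raise ValueError("marker map columns have unequal lengths")
        if np.any(self.position <= 0):
            raise ValueError("marker positions must be positive 1-based integers")

    def __len__(self) -> int:
        return len(self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.name, "chrom": self.chromosome, "pos": self.position}
        )


@dataclass
class Phenotype:
    """Trait values keyed by sample identifier; NaN marks missing."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.sample_ids) != len(self.y):
            raise ValueError("phenotype sample_ids and values have unequal lengths")

    def aligned_to(self, matrix: MarkerMatrix) -> np.ndarray:
        """Trait vector reordered to the matrix's rows.

        Sample-ID sets must match exactly; unmatched IDs on either side are
        an error rather than a silent intersection.
        """
        pheno_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if pheno_ids != matrix_ids:
            missing = sorted(matrix_ids - pheno_ids)[:5]
            extra = sorted(pheno_ids - matrix_ids)[:5]
            raise ValueError(
                "phenotype and genotype sample IDs do not match "
                f"(genotype-only: {missing}, phenotype-only: {extra})"
            )
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([order[s] for s in matrix.sample_ids])
        return self.y[idx]


@dataclass
class CovariateMatrix:
    """q covariate columns over n individuals; no missing values allowed."""

    sample_ids: list[str]
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("covariate rows do not match sample_ids")
        if np.isnan(self.values).any():
            raise ValueError("covariates must not contain missing values")
        if not self.names:
            self.names = [f"cov{i + 1}" for i in range(self.values.shape[1])]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def aligned_to(self, matrix: MarkerMatrix) -> np.ndarray:
        cov_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if cov_ids != matrix_ids:
            raise ValueError("covariate and genotype sample IDs do not match")
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([order[s] for s in matrix.sample_ids])
        return self.values[idx]


def _descriptor_path(data_path: Path) -> Path:
    return data_path.with_suffix(data_path.suffix + _DESCRIPTOR_SUFFIX)


def create_store(
    data_path: str | Path, n: int, m: int, sample_ids: list[str]
) -> MarkerMatrix:
    """Allocate an empty float64 backing file plus descriptor."""
    data_path = Path(data_path)
    data_path.parent.mkdir(parents=True, exist_ok=True)
    values = np.memmap(data_path, dtype=np.float64, mode="w+", shape=(n, m), order="F")
    desc = {
        "n": n,
        "m": m,
        "dtype": "float64",
        "order": "F",
        "byteorder": "little",
        "sample_ids": list(sample_ids),
        "data_file": data_path.name,
    }
    desc_path = _descriptor_path(data_path)
    desc_path.write_text(json.dumps(desc))
    if sys.byteorder != "little":  # pragma: no cover - x86/arm are little-endian
        raise StoreCorruptionError("big-endian hosts are not supported")
    return MarkerMatrix(values, list(sample_ids), desc_path, data_path)


def from_array(
    array: np.ndarray, sample_ids: list[str], data_path: str | Path
) -> MarkerMatrix:
    """Write an in-memory genotype array into a new backing store."""
    array = np.asarray(array, dtype=np.float64)
    matrix = create_store(data_path, array.shape[0], array.shape[1], sample_ids)
    matrix.values[:] = array
    matrix.flush()
    return matrix


def attach(descriptor_path: str | Path) -> MarkerMatrix:
    """Reopen a store from its descriptor without re-parsing any text.

    The memmap is opened read-write in place; no in-memory copy of the
    matrix is made.  Only double-precision backings are accepted.
    """
    descriptor_path = Path(descriptor_path)
    if not descriptor_path.exists():
        raise FileNotFoundError(f"descriptor not found: {descriptor_path}")
    desc = json.loads(descriptor_path.read_text())
    if desc.get("dtype") != "float64":
        raise StoreTypeError(
            "backing store must be double precision (float64); "
            f"descriptor declares {desc.get('dtype')!r}"
        )
    data_path = descriptor_path.parent / desc["data_file"]
    if not data_path.exists():
        raise FileNotFoundError(f"backing file not found: {data_path}")
    n, m = int(desc["n"]), int(desc["m"])
    expected = n * m * 8
    actual = data_path.stat().st_size
    if actual != expected:
        raise StoreCorruptionError(
            f"backing file is {actual} bytes, descriptor implies {expected}"
        )
    values = np.memmap(data_path, dtype=np.float64, mode="r+", shape=(n, m), order="F")
    return MarkerMatrix(values, list(desc["sample_ids"]), descriptor_path, data_path)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise GenotypeParseError(f"no markers parsed from {path}") from None


def load_text_genotypes(
    path: str | Path,
    orientation: str = "markers-in-columns",
    missing_code: str = "NA",
    store_path: str | Path | None = None,
    map_path: str | Path | None = None,
) -> tuple[MarkerMatrix, MarkerInfo]:
    """Parse a delimited genotype table into a file-backed matrix.

    Parameters
    ----------
    path
        TSV (default) or CSV (by extension) with a header row and an
        identifier first column.  ``markers-in-columns``: rows are samples,
        columns markers.  ``markers-in-rows``: transposed.
    missing_code
        Cell value marking a missing score; stored as NaN pre-imputation.
    store_path
        Destination of the binary backing file (default: alongside the
        input with a ``.gstore`` suffix).
    map_path
        Optional marker-map TSV (marker, chrom, pos).  Without it markers
        are placed on chromosome "1" at consecutive positions.
    """
    path = Path(path)
    if orientation not in ("markers-in-columns", "markers-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise GenotypeParseError(f"no markers parsed from {path}")
    if orientation == "markers-in-rows":
        raw = raw.T

    marker_names = [str(c) for c in raw.columns]
    sample_ids = [str(i) for i in raw.index]

    cells = raw.to_numpy(dtype=object)
    cells[cells == missing_code] = np.nan
    try:
        values = cells.astype(np.float64)
    except (TypeError, ValueError):
        bad = _first_bad_cell(raw, missing_code)
        raise GenotypeParseError(
            f"non-numeric genotype cell at row {bad[0]!r}, column {bad[1]!r}: {bad[2]!r}"
        ) from None
    with np.errstate(invalid="ignore"):
        out_of_range = (values < 0) | (values > 2)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise GenotypeValidationError(
            f"genotype score out of [0, 2] at sample {sample_ids[r]!r}, "
            f"marker {marker_names[c]!r}: {values[r, c]}"
        )

    if store_path is None:
        store_path = path.with_suffix(path.suffix + ".gstore")
    matrix = from_array(values, sample_ids, store_path)

    if map_path is not None:
        info = read_marker_map(map_path)
        if list(info.name) != marker_names:
            raise GenotypeValidationError(
                "marker map names do not match genotype table columns"
            )
    else:
        info = MarkerInfo(
            name=np.array(marker_names, dtype=object),
            chromosome=np.array(["1"] * len(marker_names), dtype=object),
            position=np.arange(1, len(marker_names) + 1),
        )
    return matrix, info


def _first_bad_cell(raw: pd.DataFrame, missing_code: str) -> tuple[str, str, str]:
    for c in raw.columns:
        col = raw[c]
        for r, v in col.items():
            if v == missing_code:
                continue
            try:
                float(v)
            except (TypeError, ValueError):
                return str(r), str(c), str(v)
    return "?", "?", "?"  # pragma: no cover


def read_marker_map(path: str | Path) -> MarkerInfo:
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = [c.lower() for c in df.columns]
    name_col, chrom_col, pos_col = df.columns[:3]
    return MarkerInfo(
        name=df[name_col].astype(str).to_numpy(dtype=object),
        chromosome=df[chrom_col].astype(str).to_numpy(dtype=object),
        position=df[pos_col].to_numpy(dtype=np.int64),
    )


def read_phenotype(path: str | Path) -> Phenotype:
    df = pd.read_csv(path, sep="\t", header=0, na_values=["NA"])
    ids = df.iloc[:, 0].astype(str).tolist()
    y = df.iloc[:, 1].to_numpy(dtype=np.float64)
    return Phenotype(ids, y)


def read_covariates(path: str | Path) -> CovariateMatrix:
    df = pd.read_csv(path, sep="\t", header=0)
    ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return CovariateMatrix(ids, values, names=[str(c) for c in df.columns[1:]])


def impute_missing(
    matrix: MarkerMatrix, info: MarkerInfo | None = None
) -> MarkerMatrix:
    """Replace each missing score by its marker's nonmissing mean, in place.

    When the coded allele is the minor one the mean lies in (0, 1].  A
    marker with no nonmissing scores is an error.
    """
    all_missing: list[str] = []
    for j in range(matrix.m):
        col = matrix.values[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        if mask.all():
            name = str(info.name[j]) if info is not None else f"#{j}"
            all_missing.append(name)
            continue
        col[mask] = col[~mask].mean()
    if all_missing:
        raise GenotypeValidationError(
            f"markers with all scores missing: {all_missing}"
        )
    matrix.flush()
    return matrix
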