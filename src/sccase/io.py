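"""Reading, writing and preprocessing of peak-by-cell accessibility matrices.

Single-cell chromatin accessibility (scCAS) data arrive as a sparse,
near-binary count matrix over genomic peaks.  This module provides the
on-disk formats (Matrix Market triplets and dense TSV), the standard
peak-prevalence filter (drop peaks open in fewer than 1% of cells) and the
TF-IDF reweighting that normalizes cells by depth and down-weights
ubiquitously open peaks.

Peak coordinates follow the 0-based half-open BED convention; strand is
ignored because accessibility is strandless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "Peak",
    "PeakByCellMatrix",
    "CellLabels",
    "SccaseIOError",
    "DimensionMismatchError",
    "read_matrix",
    "write_matrix",
    "read_peaks",
    "write_peaks",
    "filter_peaks",
    "tfidf_transform",
    "binarize",
]


class SccaseIOError(ValueError):
    """Malformed or inconsistent input data."""


class DimensionMismatchError(SccaseIOError):
    """Matrix dimensions disagree with the peaks/barcodes sidecar files."""


@dataclass(frozen=True)
class Peak:
    """A genomic interval of open chromatin (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Peak":
        """Parse ``chr:start-end`` or tab-separated BED-style ``chr start end``."""
        text = text.strip()
        if "\t" in text:
            fields = text.split("\t")
            if len(fields) < 3:
                raise SccaseIOError(f"cannot parse peak line {text!r}")
            chrom, start, end = fields[0], fields[1], fields[2]
        else:
            try:
                chrom, rest = text.rsplit(":", 1)
                start, end = rest.split("-")
            except ValueError as exc:
                raise SccaseIOError(f"cannot parse peak {text!r}") from exc
        return cls(chrom, int(start), int(end))


@dataclass
class PeakByCellMatrix:
    """A non-negative peaks x cells matrix with coordinates and barcodes.

    ``values`` may be a dense ndarray or a scipy sparse matrix; ``layer_tag``
    records the processing stage (``raw``, ``filtered``, ``tfidf``,
    ``enhanced`` or ``truth``).
    """

    values: np.ndarray | sp.spmatrix
    peaks: list[Peak]
    barcodes: list[str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        m, n = self.values.shape
        if len(self.peaks) != m:
            raise DimensionMismatchError(
                f"{len(self.peaks)} peaks but matrix has {m} rows"
            )
        if len(self.barcodes) != n:
            raise DimensionMismatchError(
                f"{len(self.barcodes)} barcodes but matrix has {n} columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise SccaseIOError("duplicate cell barcodes")
        if self.min() < 0 and self.layer_tag != "tfidf":
            raise SccaseIOError("matrix contains negative entries")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float ndarray (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def min(self) -> float:
        if sp.issparse(self.values):
            return self.values.min() if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def with_values(self, values, layer_tag: str) -> "PeakByCellMatrix":
        return PeakByCellMatrix(values, list(self.peaks), list(self.barcodes), layer_tag)


@dataclass
class CellLabels:
    """An ordered barcode -> cell-type assignment."""

    barcodes: list[str]
    types: list[str]

    def __post_init__(self) -> None:
        if len(self.barcodes) != len(self.types):
            raise SccaseIOError("barcodes and types differ in length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise SccaseIOError("duplicate barcodes in labels")

    def __len__(self) -> int:
        return len(self.barcodes)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.barcodes, self.types))

    def aligned_to(self, barcodes: Sequence[str]) -> np.ndarray:
        """Return the type of each barcode in the given order."""
        mapping = self.as_dict()
        missing = [b for b in barcodes if b not in mapping]
        if missing:
            raise SccaseIOError(f"{len(missing)} barcodes without labels, e.g. {missing[0]!r}")
        return np.array([mapping[b] for b in barcodes])

    def indices_by_type(self) -> dict[str, np.ndarray]:
        arr = np.asarray(self.types)
        return {t: np.flatnonzero(arr == t) for t in dict.fromkeys(self.types)}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CellLabels":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 2:
            raise SccaseIOError(f"label file {path} needs two columns (barcode, type)")
        return cls(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"barcode": self.barcodes, "type": self.types}).to_csv(
            path, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PEAK_FILENAMES = ("peaks.bed", "peaks.tsv", "peaks.txt", "features.tsv", "features.bed")
_BARCODE_FILENAMES = ("barcodes.tsv", "barcodes.txt")
_MATRIX_FILENAMES = ("matrix.mtx",)


def read_peaks(path: str | Path) -> list[Peak]:
    path = Path(path)
    if not path.exists():
        raise SccaseIOError(f"peak file not found: {path}")
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith(("#", "track", "browser")):
                peaks.append(Peak.parse(line))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def _find(directory: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        if (directory / name).exists():
            return directory / name
    raise SccaseIOError(f"no {what} file in {directory} (looked for {', '.join(candidates)})")


def read_matrix(path: str | Path, format: str | None = None) -> PeakByCellMatrix:
    """Read a peaks x cells matrix.

    ``format`` is ``"mtx-dir"`` (a directory with matrix.mtx, a peaks file and
    barcodes.tsv) or ``"dense-tsv"`` (header row of barcodes, first column of
    ``chr:start-end`` peak ids).  If omitted it is inferred from the path.
    """
    path = Path(path)
    if not path.exists():
        raise SccaseIOError(f"input not found: {path}")
    if format is None:
        format = "mtx-dir" if path.is_dir() else "dense-tsv"

    if format == "mtx-dir":
        mtx_path = _find(path, _MATRIX_FILENAMES, "matrix")
        values = sp.csr_matrix(mmread(mtx_path))
        peaks = read_peaks(_find(path, _PEAK_FILENAMES, "peaks"))
        bc_path = _find(path, _BARCODE_FILENAMES, "barcodes")
        barcodes = [l.strip() for l in open(bc_path) if l.strip()]
        m, n = values.shape
        if len(peaks) != m:
            raise DimensionMismatchError(
                f"{mtx_path} declares {m} rows but peak file lists {len(peaks)} peaks"
            )
        if len(barcodes) != n:
            raise DimensionMismatchError(
                f"{mtx_path} declares {n} columns but {bc_path} lists {len(barcodes)} barcodes"
            )
    elif format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        peaks = [Peak.parse(str(p)) for p in df.index]
        barcodes = [str(b) for b in df.columns]
    else:
        raise SccaseIOError(f"unknown format {format!r}")

    if (values.min() if not sp.issparse(values) else (values.min() if values.nnz else 0)) < 0:
        raise SccaseIOError(f"negative entries in {path}")
    return PeakByCellMatrix(values, peaks, barcodes, layer_tag="raw")


def write_matrix(X: PeakByCellMatrix, path: str | Path, format: str = "mtx-dir") -> None:
    """Write a matrix as a Matrix Market directory or a dense TSV."""
    path = Path(path)
    if format == "mtx-dir":
        path.mkdir(parents=True, exist_ok=True)
        vals = X.values if sp.issparse(X.values) else sp.csr_matrix(X.values)
        mmwrite(path / "matrix.mtx", sp.coo_matrix(vals))
        write_peaks(X.peaks, path / "peaks.bed")
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(X.barcodes) + "\n")
    elif format == "dense-tsv":
        df = pd.DataFrame(X.dense(), index=[str(p) for p in X.peaks], columns=X.barcodes)
        df.to_csv(path, sep="\t")
    else:
        raise SccaseIOError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def binarize(X: PeakByCellMatrix) -> PeakByCellMatrix:
    """Binary accessibility indicator (1 where any reads were observed)."""
    if sp.issparse(X.values):
        vals = (X.values > 0).astype(np.int8)
    else:
        vals = (np.asarray(X.values) > 0).astype(np.int8)
    return X.with_values(vals, X.layer_tag)


def _cells_per_peak(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (np.asarray(values) > 0).sum(axis=1)


def filter_peaks(X: PeakByCellMatrix, min_cell_fraction: float = 0.01) -> PeakByCellMatrix:
    """Drop peaks accessible in fewer than ``min_cell_fraction`` of cells.

    A peak is kept iff it is non-zero in at least ``ceil(min_cell_fraction*n)``
    cells (inclusive boundary).  Idempotent at a fixed threshold.
    """
    if X.layer_tag not in ("raw", "filtered"):
        raise SccaseIOError(f"filter_peaks expects a raw count layer, got {X.layer_tag!r}")
    if not 0 <= min_cell_fraction <= 1:
        raise SccaseIOError("min_cell_fraction must lie in [0, 1]")
    threshold = math.ceil(min_cell_fraction * X.n_cells)
    keep = _cells_per_peak(X.values) >= threshold
    if not keep.any():
        raise SccaseIOError(
            "peak filter removed every peak; lower min_cell_fraction "
            f"(threshold was {threshold} cells)"
        )
    values = X.values[keep] if not sp.issparse(X.values) else X.values.tocsr()[np.flatnonzero(keep)]
    peaks = [p for p, k in zip(X.peaks, keep) if k]
    return PeakByCellMatrix(values, peaks, list(X.barcodes), layer_tag="filtered")


def tfidf_transform(X: PeakByCellMatrix, idf_on_binarized: bool = True) -> PeakByCellMatrix:
    """TF-IDF reweighting of a filtered count matrix.

    The term frequency divides each entry by its cell's total count; the
    inverse document frequency is ``log(n / occurrence_i)``.  By default the
    per-peak occurrence is the number of cells in which the peak is open,
    which keeps the transform non-negative as the downstream NMF requires;
    with ``idf_on_binarized=False`` the occurrence is the summed read count,
    which for multi-counts can exceed ``n`` and produce negative weights.
    Natural logarithms are used throughout.
    """
    if X.layer_tag not in ("filtered", "raw"):
        raise SccaseIOError(f"tfidf_transform expects counts, got layer {X.layer_tag!r}")
    dense = X.dense()
    colsums = dense.sum(axis=0)
    if np.any(colsums == 0):
        bad = int(np.flatnonzero(colsums == 0)[0])
        raise SccaseIOError(
            f"cell {X.barcodes[bad]!r} has no reads in any peak; term frequency undefined"
        )
    occurrence = (dense > 0).sum(axis=1) if idf_on_binarized else dense.sum(axis=1)
    with np.errstate(divide="ignore"):
        idf = np.where(occurrence > 0, np.log(X.n_cells / np.where(occurrence > 0, occurrence, 1)), 0.0)
    values = (dense / colsums) * idf[:, None]
    # entries at zero counts stay exactly zero regardless of the idf value
    values[dense == 0] = 0.0
    out = X.with_values(values, "tfidf")
    if not idf_on_binarized and values.min() < 0:
        warnings.warn(
            "literal count-based IDF produced negative weights; the model "
            "requires a non-negative matrix (use idf_on_binarized=True)",
            stacklevel=2,
        )
    return out
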