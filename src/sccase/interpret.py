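"""Interpretation of the fitted factors: cell type-specific and background peaks.

Each column of the projection matrix W is a program of peaks; the matching
row of the cell embedding H says how active that program is in each cell.
For a chosen cell group, the program with the highest mean activation over
the group's cells is taken as its program, and the top-coefficient peaks of
that W column are the group's specific peaks.  Background peaks — used as a
matched control set by downstream enrichment tools — are the peaks whose
mean W coefficient sits closest to the global mean coefficient.

Peak lists are exported as BED6 (name = rank, score = coefficient rescaled
to 0..1000) plus a full TSV score table.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellLabels, Peak

__all__ = [
    "specific_peaks",
    "background_peaks",
    "peak_overlap",
    "write_bed",
    "write_score_table",
]


def _table(peaks: Sequence[Peak], idx: np.ndarray, coeffs: np.ndarray,
           component: int | None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [peaks[i].chrom for i in idx],
            "start": [peaks[i].start for i in idx],
            "end": [peaks[i].end for i in idx],
            "peak_index": idx,
            "component": component if component is not None else -1,
            "coefficient": coeffs,
            "rank": np.arange(1, len(idx) + 1),
        }
    )


def specific_peaks(W: np.ndarray, H: np.ndarray, peaks: Sequence[Peak],
                   groups, target_group: str, top_n: int = 100,
                   agg: str = "mean") -> pd.DataFrame:
    """Top-``top_n`` peaks of the program most active in ``target_group``.

    The program is the embedding row with the highest mean (or, with
    ``agg="median"``, median) activation over the group's cells; ties in the
    peak coefficients are broken by peak order.  Two groups dominated by the
    same program receive the same list.
    """
    if isinstance(groups, CellLabels):
        groups = np.asarray(groups.types)
    else:
        groups = np.asarray(groups)
    members = np.flatnonzero(groups == target_group)
    if members.size == 0:
        raise ValueError(f"unknown or empty group {target_group!r}")
    reducer = np.median if agg == "median" else np.mean
    activation = reducer(H[:, members], axis=1)
    component = int(np.argmax(activation))
    coeffs = W[:, component]
    top_n = min(top_n, W.shape[0])
    order = np.argsort(-coeffs, kind="stable")[:top_n]
    return _table(peaks, order, coeffs[order], component)


def background_peaks(W: np.ndarray, peaks: Sequence[Peak],
                     n_background: int = 1000) -> pd.DataFrame:
    """Peaks whose mean coefficient is closest to the global mean of W."""
    if n_background > W.shape[0]:
        warnings.warn(
            f"n_background={n_background} capped at the {W.shape[0]} available peaks",
            stacklevel=2,
        )
        n_background = W.shape[0]
    row_means = W.mean(axis=1)
    closeness = np.abs(row_means - W.mean())
    order = np.argsort(closeness, kind="stable")[:n_background]
    return _table(peaks, order, row_means[order], None)


def peak_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Peaks present in both tables (overlap is reported, never silent)."""
    shared = sorted(set(table_a["peak_index"]) & set(table_b["peak_index"]))
    return table_a[table_a["peak_index"].isin(shared)]


def write_bed(table: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: name = rank, score = coefficient scaled to 0..1000."""
    coeffs = table["coefficient"].to_numpy(dtype=float)
    span = coeffs.max() - coeffs.min()
    scores = np.zeros(len(coeffs), dtype=int) if span == 0 else np.round(
        1000 * (coeffs - coeffs.min()) / span
    ).astype(int)
    with open(path, "w") as fh:
        for (_, row), score in zip(table.iterrows(), scores):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{int(row['rank'])}\t{score}\t.\n"
            )


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
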