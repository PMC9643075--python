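"""Range occupancy on an equal-area grid, and multicollinearity screening.

Range size is measured as occupancy: the number of equal-area grid
cells a species' range intersects, divided by the total number of cells
covering the study region.  The grid is supplied as explicit cell
geometries (projection handling is out of scope).  Predictors are
screened for multicollinearity with an iterative pairwise-correlation /
variance-inflation-factor rule in the style of ``usdm::vifcor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

__all__ = [
    "OccupancyMatrix",
    "rasterize_range",
    "range_occupancy",
    "vif_screen",
]

#: pairwise |Pearson r| above which one of a predictor pair is dropped
#: (the vifcor convention)
DEFAULT_CORR_THRESHOLD = 0.9


@dataclass
class OccupancyMatrix:
    """Boolean species × grid-cell presence matrix."""

    presence: pd.DataFrame  # index: species, columns: cell ids, values bool

    def __post_init__(self):
        if self.presence.index.has_duplicates:
            raise ValueError("duplicate species ids")
        if self.presence.columns.has_duplicates:
            raise ValueError("duplicate cell ids")

    @property
    def total_cells(self) -> int:
        return self.presence.shape[1]

    def occupancy(self) -> pd.Series:
        occ = self.presence.sum(axis=1).astype(int)
        return pd.Series(
            [range_occupancy(int(o), self.total_cells) for o in occ],
            index=self.presence.index, name="occupancy")


def rasterize_range(range_geom: BaseGeometry,
                    cells: dict[str, BaseGeometry] | list[BaseGeometry], *,
                    mode: str = "intersects") -> set:
    """Cell ids whose cell is occupied by the range polygon(s).

    ``mode="intersects"`` (default) counts any positive-area overlap;
    ``mode="centers"`` counts cells whose centroid falls inside the
    range (sensitivity-check variant).
    """
    if not isinstance(range_geom, BaseGeometry):
        raise ValueError("range must be a shapely geometry")
    if range_geom.is_empty:
        raise ValueError("empty range geometry")
    if not range_geom.is_valid:
        raise ValueError(
            f"invalid range geometry: {explain_validity(range_geom)}")
    if not isinstance(cells, dict):
        cells = {i: c for i, c in enumerate(cells)}
    if mode == "intersects":
        return {cid for cid, cell in cells.items()
                if range_geom.intersection(cell).area > 0.0}
    if mode == "centers":
        return {cid for cid, cell in cells.items()
                if range_geom.contains(cell.centroid)}
    raise ValueError(f"unknown mode {mode!r}")


def range_occupancy(occupied: int, total_cells: int) -> float:
    """Occupied cells / total cells, in (0, 1]."""
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    if not 0 < occupied <= total_cells:
        raise ValueError(
            f"occupied must lie in (0, total]; got {occupied}/{total_cells}"
            " (a species occupying no cell cannot be analysed)")
    return occupied / total_cells


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 − R²_j) from regressing column j on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack((np.ones(n), others))
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            raise np.linalg.LinAlgError(
                "constant predictor column encountered in VIF computation")
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(X: pd.DataFrame,
               threshold: float = DEFAULT_CORR_THRESHOLD):
    """Iterative pairwise-correlation screen with VIF tie-breaking.

    Repeatedly finds the predictor pair with the largest absolute
    Pearson correlation; while it reaches ``threshold``, the pair
    member with the larger VIF is dropped (on equal VIFs, the
    higher-index column goes, so earlier columns survive longer).

    Returns ``(retained, excluded)`` where ``excluded`` is a list of
    ``{"variable", "abs_corr", "vif"}`` records.  Exactly collinear
    pairs (|r| = 1, infinite VIF) are resolved by the same drop rule;
    a constant column, whose correlations are undefined, raises a
    singularity error naming it.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise np.linalg.LinAlgError(
            f"singular predictor set: constant column(s) {constant}")
    cols = list(X.columns)
    work = X.astype(float).copy()
    excluded: list[dict] = []
    while len(cols) >= 2:
        corr = work[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = abs(corr[i, j])
        if r < threshold:
            break
        vifs = _vifs(work[cols].to_numpy())
        # of the offending pair, drop the larger-VIF member; ties drop
        # the higher column index
        if vifs[i] > vifs[j]:
            drop = i
        elif vifs[j] > vifs[i]:
            drop = j
        else:
            drop = max(i, j)
        excluded.append({"variable": cols[drop], "abs_corr": float(r),
                         "vif": float(vifs[drop])})
        cols.pop(drop)
    return cols, excluded
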