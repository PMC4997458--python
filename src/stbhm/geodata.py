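"""Raster grids and their preprocessing.

Plain-text (ESRI ASCII-grid style) raster I/O, iterated focal-mean imputation
of missing cells, concentration-grade classification, and aggregation of cell
values to analysis units (zonal means and space-time panels).

Conventions: row 0 is the top/north row; (row, col) indices are 0-based; cells
are treated as equal-area so areal shares are cell-count shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .panel import SpaceTimePanel

__all__ = [
    "RasterGrid",
    "ZoneLabels",
    "GradeScheme",
    "RasterParseError",
    "read_raster",
    "write_raster",
    "impute_focal",
    "classify_grades",
    "area_percent_by_grade",
    "zonal_mean",
    "build_panel",
    "WHO_GRADE_SCHEME",
]


class RasterParseError(ValueError):
    """Malformed text-raster file."""


@dataclass
class RasterGrid:
    """A single-year lattice of concentrations (μg/m³) or population counts.

    ``values`` and ``missing_mask`` have identical 2-D shapes; values are
    finite and non-negative wherever the mask is False. ``nodata_value`` is
    only a serialization sentinel.
    """

    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_size: float = 0.1
    nodata_value: float = -9999.0
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValueError("observed raster cells must be finite")
        if observed.size and observed.min() < 0:
            raise ValueError("observed raster cells must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]


@dataclass
class ZoneLabels:
    """Integer raster mapping cells to analysis units (0 = outside study area)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("zone labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("zone labels must be >= 0")
        n = int(self.labels.max())
        present = np.unique(self.labels[self.labels > 0])
        if n and len(present) != n:
            missing = sorted(set(range(1, n + 1)) - set(present.tolist()))
            raise ValueError(f"unit ids missing from zone raster: {missing}")

    @property
    def n_units(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class GradeScheme:
    """Banded concentration categories.

    ``breaks`` are strictly increasing thresholds (μg/m³); grade ``g`` covers
    ``[breaks[g-2], breaks[g-1])`` with grade 1 open below and the top grade
    closed above (left-closed, right-open intervals).
    """

    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "breaks", tuple(float(b) for b in self.breaks))
        if len(self.breaks) < 1:
            raise ValueError("need at least one break")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("grade breaks must be strictly increasing")

    @property
    def n_grades(self) -> int:
        return len(self.breaks) + 1

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_grades + 1))


#: WHO guideline / interim-target thresholds (15, 25, 35 μg/m³) plus the 70
#: μg/m³ severe-pollution bound: five grades <15, 15–25, 25–35, 35–70, >70.
WHO_GRADE_SCHEME = GradeScheme(breaks=(15.0, 25.0, 35.0, 70.0))


def read_raster(path, nodata: float | None = None) -> RasterGrid:
    """Read an ESRI-ASCII-style text raster.

    Header lines (case-insensitive keys): ``ncols``, ``nrows``, optional
    ``xllcorner``/``yllcorner``, ``cellsize``, ``NODATA_value``; then ``nrows``
    whitespace-separated rows of ``ncols`` numbers each. ``nodata`` overrides
    the header sentinel.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    i = 0
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterParseError(f"bad header line {i + 1!r}: {lines[i]}") from exc
            i += 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise RasterParseError(f"missing required header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    sentinel = nodata if nodata is not None else header.get("nodata_value", -9999.0)
    body = lines[i:]
    if len(body) != nrows:
        raise RasterParseError(f"expected {nrows} data rows, found {len(body)}")
    for r, line in enumerate(body):
        parts = line.split()
        if len(parts) != ncols:
            raise RasterParseError(
                f"row {r}: expected {ncols} columns, found {len(parts)}"
            )
        row = []
        for c, tok in enumerate(parts):
            try:
                row.append(float(tok))
            except ValueError as exc:
                raise RasterParseError(f"row {r}, column {c}: non-numeric cell {tok!r}") from exc
        rows.append(row)
    values = np.array(rows, dtype=float)
    mask = values == sentinel
    values = np.where(mask, np.nan, values)
    values[mask] = 0.0  # placeholder under the mask; never read
    return RasterGrid(
        values=values,
        missing_mask=mask,
        cell_size=float(header.get("cellsize", 0.1)),
        nodata_value=float(sentinel),
    )


def write_raster(grid: RasterGrid, path) -> None:
    """Write a :class:`RasterGrid` in the ESRI-ASCII-style text format."""
    nrows, ncols = grid.shape
    out = np.where(grid.missing_mask, grid.nodata_value, grid.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {grid.nodata_value}\n")
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def _window_offsets(window: int) -> tuple[int, int]:
    """Inclusive (lo, hi) row/col offsets of the focal window.

    An even window has no central cell; the convention used here anchors the
    window so cell (r, c) spans rows r+lo..r+hi with lo = -(w//2 - 1) for even
    w and -(w//2) for odd w, hi = w//2. For w=6 that is -2..+3.
    """
    hi = window // 2
    lo = -hi + (1 if window % 2 == 0 else 0)
    return lo, hi


def impute_focal(grid: RasterGrid, window: int = 6, max_iter: int = 100) -> RasterGrid:
    """Fill missing cells by iterated focal (sliding-window) means.

    Each pass fills every missing cell that has at least one observed cell in
    its ``window x window`` neighborhood with the mean of the observed cells of
    the *previous* pass (Jacobi-style, order-independent); passes repeat until
    no cell is missing. Observed cells are never altered. Windows are truncated
    at the grid edge.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if grid.n_missing == 0:
        return grid
    observed = ~grid.missing_mask
    if not observed.any():
        raise ValueError("cannot impute an all-missing grid")
    values = np.where(observed, grid.values, 0.0)
    lo, hi = _window_offsets(window)
    kernel = np.ones((window, window))
    # correlate's kernel center sits at index window//2 + origin; choosing
    # origin so the covered offsets are exactly lo..hi (for w=6: -2..+3).
    origin = -(window // 2) - lo
    for _ in range(max_iter):
        sums = ndimage.correlate(values, kernel, mode="constant", cval=0.0,
                                 origin=origin)
        counts = ndimage.correlate(observed.astype(float), kernel,
                                   mode="constant", cval=0.0, origin=origin)
        fillable = (~observed) & (counts > 0.5)
        if not fillable.any():
            raise ValueError(
                f"no fillable cells left but {int((~observed).sum())} still missing"
            )
        values = np.where(fillable, sums / np.maximum(counts, 1.0), values)
        observed = observed | fillable
        if observed.all():
            return RasterGrid(
                values=values,
                missing_mask=np.zeros_like(observed, dtype=bool),
                cell_size=grid.cell_size,
                nodata_value=grid.nodata_value,
                year=grid.year,
            )
    raise ValueError(
        f"imputation did not converge in {max_iter} passes; "
        f"{int((~observed).sum())} cells still missing"
    )


def classify_grades(grid: RasterGrid, scheme: GradeScheme = WHO_GRADE_SCHEME) -> np.ndarray:
    """Map each cell to its concentration grade (integer array, same shape).

    Intervals are left-closed, right-open: a value equal to a break belongs to
    the grade above it.
    """
    if grid.n_missing:
        raise ValueError("grid must be fully observed; run impute_focal first")
    breaks = np.asarray(scheme.breaks)
    return np.searchsorted(breaks, grid.values, side="right").astype(int) + 1


def area_percent_by_grade(
    grade_array: np.ndarray,
    zones: ZoneLabels | None = None,
    grades: Iterable[int] | None = None,
) -> pd.Series:
    """Percent of study-area cells in each grade.

    With ``zones`` given, only cells with label > 0 count. ``grades`` fixes
    the index (defaults to 1..max observed grade); percentages sum to 100.
    """
    grade_array = np.asarray(grade_array)
    if zones is not None:
        if zones.shape != grade_array.shape:
            raise ValueError("zone raster shape must match grade array")
        inside = grade_array[zones.labels > 0]
    else:
        inside = grade_array.ravel()
    if inside.size == 0:
        raise ValueError("empty study area")
    if grades is None:
        grades = range(1, int(inside.max()) + 1)
    grades = list(grades)
    counts = np.array([(inside == g).sum() for g in grades], dtype=float)
    return pd.Series(100.0 * counts / inside.size, index=pd.Index(grades, name="grade"),
                     name="area_percent")


def zonal_mean(grid: RasterGrid, zones: ZoneLabels) -> np.ndarray:
    """Arithmetic mean of the cells of each unit, ordered by unit id 1..n."""
    if grid.n_missing:
        raise ValueError("grid must be fully observed")
    if zones.shape != grid.shape:
        raise ValueError("zone raster shape must match grid")
    labels = zones.labels
    n = zones.n_units
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    empty = np.nonzero(counts == 0)[0] + 1
    if empty.size:
        raise ValueError(f"units with zero cells: {empty.tolist()}")
    sums = np.bincount(labels.ravel(), weights=grid.values.ravel(), minlength=n + 1)[1:]
    return sums / counts


def build_panel(grids: Sequence[RasterGrid], zones: ZoneLabels) -> SpaceTimePanel:
    """Aggregate a stack of annual grids to a unit x year panel.

    Grids must carry consecutive, strictly increasing ``year`` labels and be
    fully observed; the panel's centered time codes are t* = year - mean(year).
    """
    if not grids:
        raise ValueError("no grids given")
    years = np.array([g.year for g in grids])
    if any(y is None for y in years):
        raise ValueError("every grid needs a year label")
    years = years.astype(int)
    if np.any(np.diff(years) != 1):
        raise ValueError("grids must cover consecutive years without gaps or duplicates")
    values = np.column_stack([zonal_mean(g, zones) for g in grids])
    return SpaceTimePanel(values=values, years=years)
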