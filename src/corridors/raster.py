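"""Raster lattice primitives shared by every pipeline stage.

Grid convention, stated once and used everywhere: ``values`` is indexed
row-major from the top-left, so the column index increases eastwards (+x)
and the row index increases southwards (y increases northwards).
``origin_x``/``origin_y`` are the map coordinates of the grid's lower-left
corner. The centre of cell ``(row, col)`` therefore sits at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y + (n_rows - row - 0.5) * cell_size

All rasters taking part in one analysis must share shape, origin and cell
size (equal-area projection with square cells is assumed upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RasterGrid",
    "PredictorStack",
    "PresenceSet",
    "TerminalRegion",
]


@dataclass
class RasterGrid:
    """A 2-D cell lattice with georeferencing and a nodata mask.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values; must be finite wherever ``nodata_mask`` is False.
    origin_x, origin_y : float
        Map coordinates (m) of the lower-left corner of the grid.
    cell_size : float
        Side length of the square cells, in map units (m).
    nodata_mask : ndarray of bool, optional
        True marks cells outside the study area (e.g. a lake mask).
    crs_label : str
        Free-text label of the coordinate reference system.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1000.0
    nodata_mask: np.ndarray | None = None
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape does not match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("values must be finite on valid (non-nodata) cells")

    # -- shape & masks -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells inside the study area."""
        return ~self.nodata_mask

    # -- georeferencing ------------------------------------------------
    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Map coordinates (x, y) of the centre of cell(s) (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cell(s) containing map point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = (
            self.n_rows
            - 1
            - np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        )
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # -- compatibility -------------------------------------------------
    def is_compatible(self, other: "RasterGrid", *, tol: float = 1e-6) -> bool:
        """Same shape, origin and cell size (the shared-lattice contract)."""
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
        )

    def require_compatible(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.is_compatible(other):
            raise ValueError(
                f"{what} is not grid-compatible: shapes {self.shape} vs {other.shape}, "
                f"cell sizes {self.cell_size} vs {other.cell_size}, origins "
                f"({self.origin_x}, {self.origin_y}) vs ({other.origin_x}, {other.origin_y})"
            )

    def with_values(
        self, values: np.ndarray, nodata_mask: np.ndarray | None = None
    ) -> "RasterGrid":
        """New grid on the same lattice with different values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
        )


@dataclass
class PredictorStack:
    """An ordered, named collection of grid-compatible predictor rasters."""

    layers: dict[str, RasterGrid]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = list(self.layers)
        if len(self.names) != len(set(self.names)):
            raise ValueError("predictor names must be unique")
        if set(self.names) != set(self.layers):
            raise ValueError("names and layers keys disagree")
        if not self.layers:
            raise ValueError("a PredictorStack needs at least one layer")
        ref = self.layers[self.names[0]]
        for name in self.names[1:]:
            ref.require_compatible(self.layers[name], f"predictor layer '{name}'")

    @property
    def grid(self) -> RasterGrid:
        """Reference grid (first layer) defining the shared lattice."""
        return self.layers[self.names[0]]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for name in self.names:
            mask &= self.layers[name].valid_mask
        return mask

    def __len__(self) -> int:
        return len(self.names)

    def as_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Design matrix (n_points, n_layers) of layer values at cells."""
        return np.column_stack(
            [self.layers[name].values[rows, cols] for name in self.names]
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Design matrix of layer values at map points (n, 2) of (x, y)."""
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        rows, cols = self.grid.cell_of(points[:, 0], points[:, 1])
        inside = (
            (rows >= 0)
            & (rows < self.grid.n_rows)
            & (cols >= 0)
            & (cols < self.grid.n_cols)
        )
        if not np.all(inside):
            raise ValueError("some points fall outside the grid extent")
        return self.as_matrix(rows, cols)


@dataclass
class PresenceSet:
    """Species-labelled point records (presences, or pseudo-absences)."""

    species: str
    points: np.ndarray  # (n, 2) of map (x, y)
    source_label: str = "sighting"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TerminalRegion:
    """One of the two reserves between which connectivity is computed."""

    name: str
    mask: np.ndarray  # 2-D bool on the shared grid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("terminal mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"terminal '{self.name}' is empty")

    def require_disjoint(self, other: "TerminalRegion") -> None:
        if np.any(self.mask & other.mask):
            raise ValueError(
                f"terminals '{self.name}' and '{other.name}' overlap"
            )
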