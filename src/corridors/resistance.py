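"""Suitability-to-resistance scaling.

Landscape resistance is derived from habitat suitability HS in [0, 1]
under two conventions:

* linear:     cost = (1 - HS) * 100 + 1, so a fully suitable 1-km cell
  costs 1 cost-weighted km to cross and a 1%-suitable cell costs 100.
* non-linear: the linear cost squared, steepening the penalty for poor
  habitat to reflect uncertainty in how suitability maps onto movement.

Both are strictly decreasing in suitability, so they induce identical
cell rankings; stacked multi-species indices in [0, S] must first be
rescaled to [0, 1] with :func:`normalize_stacked`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .raster import RasterGrid
from .sdm import SuitabilityMap

__all__ = [
    "ResistanceSurface",
    "ResistanceScaler",
    "linear_resistance",
    "nonlinear_resistance",
    "normalize_stacked",
]


@dataclass
class ResistanceSurface:
    """Per-cell traversal cost (cost-weighted km per km of movement)."""

    grid: RasterGrid
    scaling: str  # "linear" | "nonlinear"
    source_species: str = ""

    def __post_init__(self) -> None:
        if self.scaling not in ("linear", "nonlinear"):
            raise ValueError(f"unknown scaling '{self.scaling}'")
        v = self.grid.values[self.grid.valid_mask]
        hi = 101.0 if self.scaling == "linear" else 101.0**2
        if v.size and (v.min() < 1 - 1e-9 or v.max() > hi + 1e-6):
            raise ValueError(f"{self.scaling} resistance values outside [1, {hi}]")


class ResistanceScaler(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the resistance scaling
    element-wise to arrays of suitability values in [0, 1]."""

    def __init__(self, scaling: str = "linear"):
        self.scaling = scaling

    def fit(self, X, y=None):
        if self.scaling not in ("linear", "nonlinear"):
            raise ValueError(f"unknown scaling '{self.scaling}'")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.nanmin(X) < -1e-9 or np.nanmax(X) > 1 + 1e-9:
            raise ValueError("suitability values must lie in [0, 1]")
        cost = (1.0 - X) * 100.0 + 1.0
        return cost**2 if self.scaling == "nonlinear" else cost


def _scale(hs: SuitabilityMap, scaling: str) -> ResistanceSurface:
    if hs.n_species != 1:
        raise ValueError(
            "stacked suitability must be rescaled to [0, 1] first "
            "(see normalize_stacked)"
        )
    grid = hs.grid
    v = grid.values[grid.valid_mask]
    if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
        raise ValueError("suitability values must lie in [0, 1]")
    cost = ResistanceScaler(scaling).fit(None).transform(
        np.clip(grid.values, 0.0, 1.0)
    )
    cost = np.where(grid.nodata_mask, 0.0, cost)
    return ResistanceSurface(
        grid=grid.with_values(cost),
        scaling=scaling,
        source_species=hs.species_label,
    )


def linear_resistance(hs: SuitabilityMap) -> ResistanceSurface:
    """Linear scaling: cost = (1 - HS) * 100 + 1, in [1, 101]."""
    return _scale(hs, "linear")


def nonlinear_resistance(hs: SuitabilityMap) -> ResistanceSurface:
    """Non-linear scaling: the linear cost squared, in [1, 10201]."""
    return _scale(hs, "nonlinear")


def normalize_stacked(stacked: SuitabilityMap,
                      n_species: int | None = None) -> SuitabilityMap:
    """Rescale a stacked index from [0, S] to [0, 1] by dividing by S."""
    s = stacked.n_species if n_species is None else n_species
    if s < 1:
        raise ValueError("n_species must be >= 1")
    v = stacked.grid.values[stacked.grid.valid_mask]
    if v.size and (v.min() < -1e-9 or v.max() > s + 1e-9):
        raise ValueError(f"stacked values outside [0, {s}]")
    return SuitabilityMap(
        grid=stacked.grid.with_values(stacked.grid.values / s),
        species_label=stacked.species_label,
        n_species=1,
    )
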