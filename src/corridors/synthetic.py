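"""Seeded synthetic landscapes, species and transect-sampled presences.

The generators emulate the statistical structure of a savanna corridor
study area: a ~1-km equal-area grid, smooth autocorrelated environmental
fields (standing in for vegetation indices and land-cover fractions),
exact Euclidean distance-to-feature fields (standing in for distance to
settlements, rivers or reserves), two disjoint terminal reserves in
opposite corners, and species whose occurrence probability is a known
logistic function of the predictors, observed along parallel
north-south line transects. Every generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import PredictorStack, PresenceSet, RasterGrid, TerminalRegion

__all__ = [
    "SyntheticSpeciesSpec",
    "make_predictor_stack",
    "distance_field",
    "make_terminals",
    "true_suitability",
    "sample_transect_presences",
    "plant_corridor_landscape",
    "make_species_assemblage",
]


@dataclass
class SyntheticSpeciesSpec:
    """A synthetic species: logistic species-habitat relationship.

    ``coefficients`` maps predictor names to log-odds slopes; suitability
    is ``logistic(intercept + sum(coef * predictor))``. ``detection_scale``
    thins the per-cell detection probability along transects.
    """

    name: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    detection_scale: float = 1.0

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError(f"species '{self.name}' needs a nonzero coefficient")
        if not 0 < self.detection_scale <= 1:
            raise ValueError("detection_scale must be in (0, 1]")


def _standardize(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    v = values[valid]
    out = values - v.mean()
    sd = v.std()
    if sd > 0:
        out = out / sd
    return out


def distance_field(shape: tuple[int, int], feature_cells: np.ndarray,
                   cell_size: float) -> np.ndarray:
    """Exact Euclidean distance (map units) from each cell centre to the
    nearest feature cell centre."""
    feature_cells = np.asarray(feature_cells, dtype=int).reshape(-1, 2)
    if len(feature_cells) == 0:
        raise ValueError("at least one feature cell is required")
    occupied = np.ones(shape, dtype=bool)
    occupied[feature_cells[:, 0], feature_cells[:, 1]] = False
    # exact EDT: distance in cell units to the nearest zero (feature) cell
    return ndimage.distance_transform_edt(occupied) * cell_size


def make_predictor_stack(
    shape: tuple[int, int],
    cell_size: float = 1000.0,
    n_smooth_fields: int = 4,
    n_distance_fields: int = 4,
    seed: int = 0,
    smooth_sigma: float = 5.0,
    n_feature_points: int = 5,
    nodata_mask: np.ndarray | None = None,
) -> PredictorStack:
    """Generate a standardized synthetic predictor stack.

    Smooth fields are Gaussian-filtered white noise (kernel sd
    ``smooth_sigma`` cells), mimicking vegetation indices and land-cover
    fractions; distance fields are exact Euclidean distance transforms
    from ``n_feature_points`` seeded random feature cells, mimicking
    distance-to-settlement/river/reserve layers. Every layer is
    standardized to mean 0, sd 1 over valid cells.
    """
    n_rows, n_cols = shape
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10x10 cells")
    if n_smooth_fields < 0 or n_distance_fields < 0:
        raise ValueError("layer counts must be nonnegative")
    if n_smooth_fields + n_distance_fields < 1:
        raise ValueError("at least one predictor layer must be requested")
    rng = np.random.default_rng(seed)
    if nodata_mask is None:
        nodata_mask = np.zeros(shape, dtype=bool)
    valid = ~nodata_mask

    layers: dict[str, RasterGrid] = {}
    names: list[str] = []
    for i in range(n_smooth_fields):
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=smooth_sigma)
        name = f"smooth_{i}"
        layers[name] = RasterGrid(
            _standardize(smooth, valid), cell_size=cell_size,
            nodata_mask=nodata_mask.copy(), crs_label="synthetic-equal-area",
        )
        names.append(name)
    for i in range(n_distance_fields):
        flat_valid = np.flatnonzero(valid.ravel())
        picks = rng.choice(flat_valid, size=min(n_feature_points, len(flat_valid)),
                           replace=False)
        cells = np.column_stack(np.unravel_index(picks, shape))
        dist = distance_field(shape, cells, cell_size)
        name = f"distance_{i}"
        layers[name] = RasterGrid(
            _standardize(dist, valid), cell_size=cell_size,
            nodata_mask=nodata_mask.copy(), crs_label="synthetic-equal-area",
        )
        names.append(name)
    return PredictorStack(layers=layers, names=names)


def _corner_block(shape: tuple[int, int], frac: float) -> tuple[int, int]:
    """Side lengths (rows, cols) of a corner block covering ~frac of cells."""
    target = max(1, round(frac * shape[0] * shape[1]))
    r = max(1, round(np.sqrt(target)))
    c = max(1, round(target / r))
    return min(r, shape[0]), min(c, shape[1])


def make_terminals(
    grid: RasterGrid,
    frac: float = 0.05,
    placement: str = "opposite_corners",
    names: tuple[str, str] = ("reserve_a", "reserve_b"),
) -> tuple[TerminalRegion, TerminalRegion]:
    """Two disjoint terminal reserves on the shared grid.

    The default placement puts rectangular blocks of ~``frac`` of the
    cells in the north-west and south-east corners (the two-park
    geometry of a corridor study).
    """
    if placement != "opposite_corners":
        raise ValueError(f"unknown placement '{placement}'")
    r, c = _corner_block(grid.shape, frac)
    mask_a = np.zeros(grid.shape, dtype=bool)
    mask_b = np.zeros(grid.shape, dtype=bool)
    mask_a[:r, :c] = True          # north-west corner
    mask_b[-r:, -c:] = True        # south-east corner
    mask_a &= grid.valid_mask
    mask_b &= grid.valid_mask
    a = TerminalRegion(names[0], mask_a)
    b = TerminalRegion(names[1], mask_b)
    a.require_disjoint(b)
    return a, b


def true_suitability(spec: SyntheticSpeciesSpec,
                     predictors: PredictorStack) -> RasterGrid:
    """Ground-truth suitability map: per-cell logistic of the spec's
    linear predictor. Values lie strictly in (0, 1)."""
    missing = set(spec.coefficients) - set(predictors.names)
    if missing:
        raise ValueError(
            f"species '{spec.name}' references unknown predictors: {sorted(missing)}"
        )
    grid = predictors.grid
    eta = np.full(grid.shape, float(spec.intercept))
    for name, coef in spec.coefficients.items():
        eta = eta + coef * predictors.layers[name].values
    suit = 1.0 / (1.0 + np.exp(-eta))
    nodata = ~predictors.valid_mask
    suit = np.where(nodata, 0.0, suit)
    return grid.with_values(suit, nodata_mask=nodata)


def sample_transect_presences(
    truth: RasterGrid,
    transect_spacing: float,
    detection_scale: float = 1.0,
    seed: int = 0,
    species: str = "synthetic",
    source_label: str = "sighting",
) -> PresenceSet:
    """Presence points detected along parallel north-south transects.

    Transects run down every ``transect_spacing / cell_size``-th column
    (bisecting those cells). Each valid cell a transect crosses yields a
    presence with probability ``detection_scale * truth(cell)``; detected
    points are placed at the cell centre jittered uniformly within the
    cell. Deterministic given the seed.
    """
    step = transect_spacing / truth.cell_size
    if transect_spacing < truth.cell_size or abs(step - round(step)) > 1e-9:
        raise ValueError("transect_spacing must be a positive multiple of cell_size")
    if not 0 < detection_scale <= 1:
        raise ValueError("detection_scale must be in (0, 1]")
    step = int(round(step))
    rng = np.random.default_rng(seed)
    cols = np.arange(0, truth.n_cols, step)
    on_transect = np.zeros(truth.shape, dtype=bool)
    on_transect[:, cols] = True
    candidates = on_transect & truth.valid_mask
    rows, ccols = np.nonzero(candidates)
    p = detection_scale * truth.values[rows, ccols]
    detected = rng.random(len(rows)) < p
    rows, ccols = rows[detected], ccols[detected]
    x, y = truth.cell_center(rows, ccols)
    jitter = rng.uniform(-0.5, 0.5, size=(len(rows), 2)) * truth.cell_size
    points = np.column_stack([x, y]) + jitter
    return PresenceSet(species=species, points=points, source_label=source_label)


@dataclass
class PlantedCorridor:
    """A suitability raster with a known high-suitability channel."""

    suitability: RasterGrid
    channel_mask: np.ndarray = field(repr=False)
    channel_value: float = 0.9
    matrix_value: float = 0.09


def plant_corridor_landscape(
    shape: tuple[int, int],
    channel_width: int = 3,
    contrast: float = 10.0,
    seed: int = 0,
    channel_value: float = 0.9,
    cell_size: float = 1000.0,
) -> PlantedCorridor:
    """Suitability raster whose optimal corridor is known by construction.

    An L-shaped channel of value ``channel_value`` runs from the default
    north-west terminal down the western edge and along the southern edge
    to the south-east terminal, through a uniform low-suitability matrix
    of value ``channel_value / contrast``. The channel cell set is
    returned for tests. ``seed`` is accepted for interface uniformity;
    the construction is deterministic.
    """
    if contrast <= 1:
        raise ValueError("contrast must exceed 1")
    n_rows, n_cols = shape
    if channel_width >= min(n_rows, n_cols):
        raise ValueError("channel wider than the grid")
    matrix_value = channel_value / contrast
    values = np.full(shape, matrix_value)
    channel = np.zeros(shape, dtype=bool)
    channel[:, :channel_width] = True        # west edge, north to south
    channel[-channel_width:, :] = True       # south edge, west to east
    values[channel] = channel_value
    grid = RasterGrid(values, cell_size=cell_size, crs_label="synthetic-equal-area")
    return PlantedCorridor(
        suitability=grid,
        channel_mask=channel,
        channel_value=channel_value,
        matrix_value=matrix_value,
    )


def make_species_assemblage(
    predictors: PredictorStack,
    n_species: int = 7,
    seed: int = 0,
    prevalence: float = 0.25,
    coef_scale: float = 1.5,
    include_generalist: bool = True,
    detection_scale: float = 1.0,
) -> list[SyntheticSpeciesSpec]:
    """A synthetic ungulate assemblage with distinct habitat niches.

    Specialists draw independent coefficient vectors; if
    ``include_generalist`` the last species is the niche-centroid
    generalist whose coefficients are the mean of the specialists' (the
    construction behind the habitat-generalist-as-proxy property).
    Intercepts are set so each species' mean suitability over valid cells
    is close to ``prevalence``.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    n_spec = n_species - 1 if include_generalist and n_species > 1 else n_species
    coef_matrix = rng.normal(0.0, coef_scale, size=(n_spec, len(predictors.names)))
    specs: list[SyntheticSpeciesSpec] = []
    valid = predictors.valid_mask
    rows, cols = np.nonzero(valid)
    design = predictors.as_matrix(rows, cols)
    logit_prev = float(np.log(prevalence / (1 - prevalence)))

    def build(name: str, coefs: np.ndarray) -> SyntheticSpeciesSpec:
        eta = design @ coefs
        intercept = logit_prev - float(eta.mean())
        return SyntheticSpeciesSpec(
            name=name,
            coefficients=dict(zip(predictors.names, coefs.tolist())),
            intercept=intercept,
            detection_scale=detection_scale,
        )

    for i in range(n_spec):
        specs.append(build(f"species_{i:02d}", coef_matrix[i]))
    if include_generalist and n_species > 1:
        specs.append(build("generalist", coef_matrix.mean(axis=0)))
    return specs
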