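"""Reading and writing the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
the cell values, top row first. Values are written as float32 rendered
with nine significant digits, which round-trips float32 exactly; masks
are written as 0/1 integers. Point sets are CSV with header
``species,x,y``.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .raster import PredictorStack, PresenceSet, RasterGrid, TerminalRegion

NODATA_VALUE = -9999.0

__all__ = [
    "read_raster",
    "write_raster",
    "write_mask",
    "read_mask",
    "read_points_csv",
    "write_points_csv",
    "read_predictor_dir",
    "write_predictor_stack",
]


def write_raster(grid: RasterGrid, path: str | os.PathLike, *, fmt: str = "%.9g") -> None:
    """Write a grid as an ESRI ASCII raster (lossless for float32)."""
    vals = np.asarray(grid.values, dtype=np.float32).copy()
    vals[grid.nodata_mask] = NODATA_VALUE
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA_VALUE:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(fmt % v for v in row))
            fh.write("\n")


def read_raster(path: str | os.PathLike, crs_label: str = "") -> RasterGrid:
    """Read an ESRI ASCII raster; cells equal to NODATA_value are masked."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field '{key}'")
    nodata = header.get("nodata_value", NODATA_VALUE)
    values = np.loadtxt(lines[n_header:], dtype=np.float32, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    mask = values == np.float32(nodata)
    values = values.astype(float)
    values[mask] = np.nan
    # keep masked cells finite so the RasterGrid invariant holds trivially
    values[mask] = 0.0
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_mask=mask,
        crs_label=crs_label,
    )


def write_mask(mask_grid: RasterGrid | TerminalRegion, path: str | os.PathLike,
               template: RasterGrid | None = None) -> None:
    """Write a boolean mask (or TerminalRegion) as a 0/1 byte raster."""
    if isinstance(mask_grid, TerminalRegion):
        if template is None:
            raise ValueError("writing a TerminalRegion requires a template grid")
        grid = template.with_values(
            mask_grid.mask.astype(float), nodata_mask=np.zeros_like(mask_grid.mask)
        )
    else:
        grid = mask_grid
    write_raster(grid, path, fmt="%d")


def read_mask(path: str | os.PathLike, name: str = "terminal") -> TerminalRegion:
    grid = read_raster(path)
    return TerminalRegion(name=name, mask=grid.values > 0.5)


def write_points_csv(points: PresenceSet | Iterable[PresenceSet],
                     path: str | os.PathLike) -> None:
    """Write one or more point sets as CSV with header species,x,y."""
    sets = [points] if isinstance(points, PresenceSet) else list(points)
    frames = [
        pd.DataFrame(
            {"species": ps.species, "x": ps.points[:, 0], "y": ps.points[:, 1]}
        )
        for ps in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_points_csv(path: str | os.PathLike, species: str | None = None,
                    source_label: str = "sighting") -> PresenceSet | list[PresenceSet]:
    """Read species points; returns one set if ``species`` is given."""
    df = pd.read_csv(path)
    for col in ("species", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if species is not None:
        sub = df[df["species"] == species]
        return PresenceSet(species, sub[["x", "y"]].to_numpy(), source_label)
    return [
        PresenceSet(sp, sub[["x", "y"]].to_numpy(), source_label)
        for sp, sub in df.groupby("species", sort=True)
    ]


def write_predictor_stack(stack: PredictorStack, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name in stack.names:
        write_raster(stack.layers[name], os.path.join(out_dir, f"{name}.asc"))


def read_predictor_dir(path: str | os.PathLike) -> PredictorStack:
    """Load every ``.asc`` in a directory (sorted) as one predictor stack.

    Raises with the offending layer's name if the lattice disagrees.
    """
    names = sorted(
        os.path.splitext(f)[0] for f in os.listdir(path) if f.endswith(".asc")
    )
    if not names:
        raise ValueError(f"no .asc rasters found in {path}")
    layers: dict[str, RasterGrid] = {}
    ref: RasterGrid | None = None
    for name in names:
        grid = read_raster(os.path.join(path, f"{name}.asc"))
        if ref is not None:
            ref.require_compatible(grid, f"predictor layer '{name}'")
        else:
            ref = grid
        layers[name] = grid
    return PredictorStack(layers=layers, names=names)
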