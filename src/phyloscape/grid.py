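"""Analysis grids, per-cell layers, presence/absence matrices, and raster
alignment.

Coordinates are abstract map units (km, decimal degrees, ...): distances
are Euclidean on cell centroids and the unit is carried as metadata, never
interpreted.  Rasters are plain row/column arrays with a south-west corner
and a cell size (ESRI ASCII grid convention, row 0 = northernmost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "GridLayer",
    "OccurrenceMatrix",
    "Raster",
    "align_layer",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class Grid:
    """A set of analysis cells: unique ids, centroid coordinates and one
    cell size.  ``shape=(ny, nx)`` is set when the grid is a full regular
    rectangle in row-major order (north row first), which terrain analysis
    requires."""

    cell_ids: tuple
    x: np.ndarray
    y: np.ndarray
    cell_size: float
    unit: str = "map units"
    shape: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if len({(float(a), float(b)) for a, b in zip(self.x, self.y)}) != self.n_cells:
            raise ValueError("cell centroids must be distinct")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def index_of(self, cell_id) -> int:
        try:
            return self._index[cell_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {c: i for i, c in enumerate(self.cell_ids)}
            )
            return self._index[cell_id]

    @classmethod
    def regular(
        cls, nx: int, ny: int, cell_size: float = 1.0, x0: float = 0.0,
        y0: float = 0.0, unit: str = "map units",
    ) -> "Grid":
        """Full ``ny`` x ``nx`` rectangle; ids ``c000000`` .. row-major with
        the NORTH row first, matching raster array order.  (x0, y0) is the
        south-west corner of the gridded region."""
        if nx < 2 or ny < 2:
            raise ValueError("grid dims must be >= 2")
        cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
        x = x0 + (cols.ravel() + 0.5) * cell_size
        y = y0 + (ny - rows.ravel() - 0.5) * cell_size
        ids = tuple(f"c{i:06d}" for i in range(nx * ny))
        return cls(ids, x, y, cell_size, unit, shape=(ny, nx))

    def to_array(self, values: np.ndarray) -> np.ndarray:
        if self.shape is None:
            raise ValueError("grid is not a declared regular rectangle")
        return np.asarray(values, dtype=float).reshape(self.shape)

    def from_array(self, arr: np.ndarray) -> np.ndarray:
        if self.shape is None:
            raise ValueError("grid is not a declared regular rectangle")
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.shape:
            raise ValueError(f"array shape {arr.shape} != grid shape {self.shape}")
        return arr.ravel()

    def to_csv(self, path) -> None:
        pd.DataFrame({"cell_id": self.cell_ids, "x": self.x, "y": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, cell_size: float, unit: str = "map units") -> "Grid":
        df = pd.read_csv(path)
        return cls(tuple(df["cell_id"]), df["x"].to_numpy(), df["y"].to_numpy(),
                   cell_size, unit)


@dataclass
class GridLayer:
    """One numeric value (NaN = missing) per grid cell."""

    grid: Grid
    values: np.ndarray
    name: str = "layer"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError(
                f"layer '{self.name}': {self.values.size} values for "
                f"{self.grid.n_cells} cells"
            )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def standardized(self) -> "GridLayer":
        v = self.values
        mu, sd = np.nanmean(v), np.nanstd(v)
        if sd == 0:
            raise ValueError(f"layer '{self.name}' is constant; cannot standardize")
        return GridLayer(self.grid, (v - mu) / sd, self.name, "sd units")


class OccurrenceMatrix:
    """Binary cells x species presence/absence bound to a grid."""

    def __init__(self, grid: Grid, species: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix)
        if matrix.shape != (grid.n_cells, len(species)):
            raise ValueError("matrix shape does not match grid cells x species")
        if matrix.dtype != bool:
            uniq = np.unique(matrix)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("presence values must be 0/1")
            matrix = matrix.astype(bool)
        if len(set(species)) != len(species):
            raise ValueError("duplicate species names")
        self.grid = grid
        self.species = list(species)
        self.matrix = matrix

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def richness(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)

    @property
    def range_sizes(self) -> pd.Series:
        return pd.Series(self.matrix.sum(axis=0).astype(int), index=self.species,
                         name="range_cells")

    def drop_species(self, names) -> "OccurrenceMatrix":
        keep = [j for j, s in enumerate(self.species) if s not in set(names)]
        return OccurrenceMatrix(
            self.grid, [self.species[j] for j in keep], self.matrix[:, keep]
        )

    @classmethod
    def from_records(
        cls, records, grid: Grid, tree=None, on_unknown_species: str = "error"
    ) -> "OccurrenceMatrix":
        """Build from long-format ``(cell_id, species)`` records.  Duplicates
        collapse to a single presence.  Species absent from ``tree`` (when
        given) are an error, or dropped with a warning when
        ``on_unknown_species='drop'``."""
        records = list(records)
        if not records:
            warnings.warn("no occurrence records; matrix is empty", stacklevel=2)
        species: list[str] = []
        seen = set()
        for _, sp in records:
            if sp not in seen:
                seen.add(sp)
                species.append(sp)
        if tree is not None:
            tips = set(tree.tip_labels)
            unknown = [s for s in species if s not in tips]
            if unknown:
                if on_unknown_species == "drop":
                    warnings.warn(
                        f"dropping {len(unknown)} species not in tree: {unknown}",
                        stacklevel=2,
                    )
                    species = [s for s in species if s in tips]
                else:
                    raise ValueError(f"species not in tree: {unknown}")
        col = {s: j for j, s in enumerate(species)}
        M = np.zeros((grid.n_cells, len(species)), dtype=bool)
        for cell, sp in records:
            if sp not in col:
                continue
            M[grid.index_of(cell), col[sp]] = True
        return cls(grid, species, M)

    def to_long_df(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.matrix)
        return pd.DataFrame(
            {
                "cell_id": [self.grid.cell_ids[i] for i in rows],
                "species": [self.species[j] for j in cols],
            }
        )

    def to_wide_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(int), index=list(self.grid.cell_ids),
            columns=self.species,
        ).rename_axis("cell_id")

    @classmethod
    def from_wide_df(cls, df: pd.DataFrame, grid: Grid) -> "OccurrenceMatrix":
        df = df.reindex(list(grid.cell_ids)).fillna(0)
        return cls(grid, list(df.columns), df.to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OccurrenceMatrix)
            and self.species == other.species
            and self.grid.cell_ids == other.grid.cell_ids
            and np.array_equal(self.matrix, other.matrix)
        )


def read_occurrences(path, grid: Grid, tree=None,
                     on_unknown_species: str = "error") -> OccurrenceMatrix:
    """Read a long-format ``cell_id,species`` CSV onto ``grid``."""
    df = pd.read_csv(path)
    unknown_cells = sorted(set(df["cell_id"]) - set(grid.cell_ids))
    if unknown_cells:
        raise ValueError(f"cell ids not in grid: {unknown_cells[:10]}")
    return OccurrenceMatrix.from_records(
        list(df.itertuples(index=False, name=None)), grid, tree, on_unknown_species
    )


# ---------------------------------------------------------------------------
# rasters


@dataclass
class Raster:
    """Gridded values at native resolution: row 0 is the northern edge,
    (x0, y0) the south-west corner."""

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.x0 + self.ncols * self.cell_size,
            self.y0,
            self.y0 + self.nrows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return xs, ys


def read_ascii_grid(path) -> Raster:
    """Parse an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    body = "\n".join(lines[i:])
    vals = (
        np.array(body.split(), dtype=float) if body.strip() else np.array([])
    )
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(vals, header["xllcorner"], header["yllcorner"],
                  header["cellsize"], nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x0:.10g}\n")
        fh.write(f"yllcorner {raster.y0:.10g}\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def align_layer(
    raster: Raster, target: Grid, method: str = "mean",
    name: str = "layer", units: str = "",
) -> GridLayer:
    """Resample ``raster`` onto the analysis grid.

    ``mean`` averages all source cells whose centres fall inside a target
    cell (aggregation); ``bilinear`` interpolates at the target centroid;
    ``nearest`` takes the nearest source cell centre.  Target cells with no
    overlapping data become missing (NaN).  Coordinate systems must already
    match; disjoint extents are an error.
    """
    if method not in {"mean", "bilinear", "nearest"}:
        raise ValueError(f"unknown method {method!r}")
    xmin, xmax, ymin, ymax = raster.extent
    half = target.cell_size / 2
    if (
        target.x.max() + half <= xmin or target.x.min() - half >= xmax
        or target.y.max() + half <= ymin or target.y.min() - half >= ymax
    ):
        raise ValueError("raster and target grid extents are disjoint")

    out = np.full(target.n_cells, np.nan)
    xs, ys = raster.cell_centers()
    if method == "mean":
        # bin every source cell centre into the target cell containing it
        sx, sy = np.meshgrid(xs, ys)
        sx, sy, sv = sx.ravel(), sy.ravel(), raster.values.ravel()
        ok = ~np.isnan(sv)
        sx, sy, sv = sx[ok], sy[ok], sv[ok]
        for i in range(target.n_cells):
            inside = (
                (np.abs(sx - target.x[i]) <= half)
                & (np.abs(sy - target.y[i]) <= half)
            )
            if inside.any():
                out[i] = sv[inside].mean()
    elif method == "nearest":
        for i in range(target.n_cells):
            cx = np.clip(int((target.x[i] - raster.x0) / raster.cell_size), 0,
                         raster.ncols - 1)
            ry = np.clip(
                int((raster.y0 + raster.nrows * raster.cell_size - target.y[i])
                    / raster.cell_size),
                0, raster.nrows - 1,
            )
            if (xmin <= target.x[i] <= xmax) and (ymin <= target.y[i] <= ymax):
                out[i] = raster.values[ry, cx]
    else:  # bilinear on source cell centres
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (ys[::-1], xs), raster.values[::-1, :],
            bounds_error=False, fill_value=np.nan,
        )
        out = interp(np.column_stack([target.y, target.x]))
    return GridLayer(target, out, name, units)
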