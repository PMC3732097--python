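"""Raster and occurrence data model for presence-only distribution modeling.

This module holds the geographic plumbing shared by the whole toolkit: a stack
of co-registered environmental raster layers with a common ocean/land validity
mask (:class:`EnvStack`), georeferenced occurrence records
(:class:`OccurrenceSet`), equal-area background samples
(:class:`BackgroundSample`), and the samples-with-data table
(:class:`SWDTable`) that pairs point coordinates with extracted predictor
values.

Rasters are cell-center registered, plain geographic lat/lon, square cells.
A point maps to the cell containing it using half-open cell intervals
``[edge, edge + resolution)`` on both axes. Raster file I/O uses the ESRI
ASCII grid format (``ncols``/``nrows``/``xllcorner``/``yllcorner``/
``cellsize``/``NODATA_value`` header followed by rows north to south).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EnvStack",
    "OccurrenceSet",
    "BackgroundSample",
    "SWDTable",
    "GeoreferenceError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_env_stack",
    "snap_to_ocean",
    "dedupe_per_cell",
    "sample_background",
    "extract_swd",
    "coastal_mask",
]

_EARTH_RADIUS_KM = 6371.0


class GeoreferenceError(ValueError):
    """Raised when raster layers do not share a common grid definition."""


def normalize_longitude(lon):
    """Map longitudes into the internal [-180, 180) convention."""
    lon = np.asarray(lon, dtype=float)
    return (lon + 180.0) % 360.0 - 180.0


@dataclass
class EnvStack:
    """Named co-registered raster layers sharing one validity mask.

    Parameters
    ----------
    layer_names : list of str
        Ordered layer identifiers (e.g. ``["SSTmean", "salinity"]``).
    values : ndarray, shape (n_layers, n_rows, n_cols)
        Cell values; row 0 is the northernmost row.
    extent : tuple (lon_min, lon_max, lat_min, lat_max)
        Outer edges of the grid in decimal degrees.
    resolution : float
        Square cell size in degrees.
    valid_mask : ndarray of bool, shape (n_rows, n_cols)
        True where cells are usable (ocean).
    nodata_value : float
        Sentinel written to files for invalid cells.
    """

    layer_names: list
    values: np.ndarray
    extent: tuple
    resolution: float
    valid_mask: np.ndarray
    nodata_value: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape[0] != len(self.layer_names):
            raise GeoreferenceError("number of layers does not match layer_names")
        if self.values.shape[1:] != self.valid_mask.shape:
            raise GeoreferenceError("valid_mask shape does not match layers")
        lon_min, lon_max, lat_min, lat_max = self.extent
        n_rows = int(round((lat_max - lat_min) / self.resolution))
        n_cols = int(round((lon_max - lon_min) / self.resolution))
        if (n_rows, n_cols) != self.valid_mask.shape:
            raise GeoreferenceError(
                f"extent/resolution imply grid {(n_rows, n_cols)} "
                f"but arrays have shape {self.valid_mask.shape}"
            )
        bad = ~np.isfinite(self.values[:, self.valid_mask])
        if bad.any():
            raise GeoreferenceError("non-finite values on valid cells")

    # -- grid geometry -------------------------------------------------

    @property
    def n_rows(self):
        return self.valid_mask.shape[0]

    @property
    def n_cols(self):
        return self.valid_mask.shape[1]

    @property
    def lon_centers(self):
        lon_min = self.extent[0]
        return lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    @property
    def lat_centers(self):
        """Latitude of each row center, row 0 northernmost."""
        lat_max = self.extent[3]
        return lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_index(self, lon, lat):
        """Map points to (row, col) indices; raises if outside the extent."""
        lon = normalize_longitude(lon)
        lat = np.asarray(lat, dtype=float)
        lon_min, lon_max, lat_min, lat_max = self.extent
        if np.any((lon < lon_min) | (lon >= lon_max)):
            raise ValueError("longitude outside raster extent")
        if np.any((lat < lat_min) | (lat >= lat_max)):
            raise ValueError("latitude outside raster extent")
        col = np.floor((lon - lon_min) / self.resolution).astype(int)
        row_from_bottom = np.floor((lat - lat_min) / self.resolution).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def cell_center(self, row, col):
        return self.lon_centers[np.asarray(col)], self.lat_centers[np.asarray(row)]

    def layer(self, name):
        return self.values[self.layer_names.index(name)]

    def subset(self, names):
        """A new stack restricted to the given layers (order preserved as given)."""
        idx = [self.layer_names.index(n) for n in names]
        return EnvStack(list(names), self.values[idx], self.extent,
                        self.resolution, self.valid_mask, self.nodata_value)


@dataclass
class OccurrenceSet:
    """Georeferenced presence records with region labels.

    Wraps a DataFrame with columns ``id, longitude, latitude, region``;
    longitudes are normalized to [-180, 180) on construction.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records.copy()
        required = ["id", "longitude", "latitude", "region"]
        for col in required:
            if col not in df.columns:
                if col == "region":
                    df["region"] = "other"
                elif col == "id":
                    df["id"] = np.arange(len(df))
                else:
                    raise ValueError(f"occurrence table missing column {col!r}")
        df["longitude"] = normalize_longitude(df["longitude"].to_numpy(float))
        lat = df["latitude"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        self.records = df[required].reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @property
    def longitudes(self):
        return self.records["longitude"].to_numpy(float)

    @property
    def latitudes(self):
        return self.records["latitude"].to_numpy(float)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.records.to_csv(path, index=False)

    @classmethod
    def from_points(cls, lons, lats, region="other", ids=None):
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        if ids is None:
            ids = np.arange(len(lons))
        region = np.broadcast_to(np.asarray(region, dtype=object), lons.shape)
        return cls(pd.DataFrame({"id": ids, "longitude": lons,
                                 "latitude": lats, "region": region}))


@dataclass
class BackgroundSample:
    """Random background cells drawn equal-area from an :class:`EnvStack`."""

    rows: np.ndarray
    cols: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    provenance: str
    n: int
    seed: int

    def as_occurrences(self, region="background"):
        return OccurrenceSet.from_points(self.lons, self.lats, region=region)


@dataclass
class SWDTable:
    """Samples-with-data table: point coordinates plus extracted predictor values.

    The Maxent SWD CSV dialect: header
    ``species,longitude,latitude,<layer1>,<layer2>,...``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in ("species", "longitude", "latitude"):
            if col not in self.data.columns:
                raise ValueError(f"SWD table missing column {col!r}")
        if self.data[self.layer_names].isna().any().any():
            raise ValueError("SWD table contains missing predictor values")

    @property
    def layer_names(self):
        return [c for c in self.data.columns
                if c not in ("species", "longitude", "latitude")]

    def predictor_matrix(self, layers=None):
        layers = list(layers) if layers is not None else self.layer_names
        return self.data[layers].to_numpy(float)

    def subset(self, layers):
        cols = ["species", "longitude", "latitude"] + list(layers)
        return SWDTable(self.data[cols].copy())

    def __len__(self):
        return len(self.data)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster file I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_ascii_grid(path):
    """Read an ESRI ASCII grid.

    Returns ``(values, extent, resolution, nodata)`` where invalid cells hold
    NaN. Both cell-corner (``xllcorner``) and cell-center (``xllcenter``)
    registration headers are accepted.
    """
    header = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:
        xll = header["xllcenter"] - cellsize / 2.0
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header["yllcenter"] - cellsize / 2.0
    values = np.loadtxt(lines[data_start:]).reshape(nrows, ncols)
    values = np.where(values == nodata, np.nan, values)
    extent = (xll, xll + ncols * cellsize, yll, yll + nrows * cellsize)
    return values, extent, cellsize, nodata


def write_ascii_grid(path, values, extent, resolution, nodata=-9999.0):
    """Write a 2-D array (NaN = nodata) as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    lon_min, _, lat_min, _ = extent
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {lon_min:.10g}\n")
        fh.write(f"yllcorner {lat_min:.10g}\n")
        fh.write(f"cellsize {resolution:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt="%.8g")


def read_env_stack(paths, layer_names=None):
    """Read co-registered ASCII grids into an :class:`EnvStack`.

    The validity mask is the union of nodata across layers: a cell that is
    nodata in any layer is invalid in the whole stack. Grids with mismatched
    shape, extent, or resolution are rejected.
    """
    paths = list(paths)
    if layer_names is None:
        import os
        layer_names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    arrays = []
    ref = None
    for path in paths:
        values, extent, res, nodata = read_ascii_grid(path)
        if ref is None:
            ref = (values.shape, extent, res)
        else:
            shape0, extent0, res0 = ref
            if values.shape != shape0 or abs(res - res0) > 1e-9 * res0 or \
                    any(abs(a - b) > 1e-6 for a, b in zip(extent, extent0)):
                raise GeoreferenceError(
                    f"grid {path} does not match the first grid's georeferencing")
        arrays.append(values)
    stack = np.stack(arrays)
    valid = np.all(np.isfinite(stack), axis=0)
    stack = np.where(valid[None], stack, 0.0)
    return EnvStack(list(layer_names), stack, ref[1], ref[2], valid)


def stack_from_arrays(layer_names, arrays, extent, resolution, valid_mask=None):
    """Assemble an EnvStack from in-memory arrays, unioning NaN into the mask."""
    values = np.stack([np.asarray(a, dtype=float) for a in arrays])
    finite = np.all(np.isfinite(values), axis=0)
    valid = finite if valid_mask is None else (np.asarray(valid_mask, bool) & finite)
    values = np.where(valid[None], values, 0.0)
    return EnvStack(list(layer_names), values, extent, resolution, valid)


# ---------------------------------------------------------------------------
# Record preprocessing
# ---------------------------------------------------------------------------

def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def snap_to_ocean(occ, stack):
    """Move records on invalid (land) cells to the nearest valid (ocean) cell.

    Distance is great-circle between cell centers; ties broken by the smaller
    (row, column) index. Records already on valid cells are unchanged; moved
    records are placed at the center of their new cell. Idempotent.
    """
    if not stack.valid_mask.any():
        raise ValueError("stack has no valid cells to snap to")
    rows, cols = stack.cell_index(occ.longitudes, occ.latitudes)
    on_land = ~stack.valid_mask[rows, cols]
    if not on_land.any():
        return OccurrenceSet(occ.records.copy())
    vrows, vcols = np.nonzero(stack.valid_mask)
    vlons = stack.lon_centers[vcols]
    vlats = stack.lat_centers[vrows]
    df = occ.records.copy()
    lon = df["longitude"].to_numpy(float)
    lat = df["latitude"].to_numpy(float)
    for i in np.nonzero(on_land)[0]:
        d = _haversine_km(lon[i], lat[i], vlons, vlats)
        # tie-break: among cells at minimal distance, smallest (row, col)
        near = np.nonzero(d <= d.min() * (1 + 1e-12))[0]
        order = np.lexsort((vcols[near], vrows[near]))
        j = near[order[0]]
        lon[i], lat[i] = vlons[j], vlats[j]
    df["longitude"] = lon
    df["latitude"] = lat
    return OccurrenceSet(df)


def dedupe_per_cell(occ, stack):
    """Retain one record per occupied grid cell (the smallest id wins)."""
    rows, cols = stack.cell_index(occ.longitudes, occ.latitudes)
    if not stack.valid_mask[rows, cols].all():
        raise ValueError("all records must lie on valid cells before dedupe")
    df = occ.records.copy()
    df["_cell"] = rows * stack.n_cols + cols
    df = df.sort_values(["_cell", "id"], kind="mergesort")
    df = df.drop_duplicates("_cell", keep="first").drop(columns="_cell")
    return OccurrenceSet(df.sort_values("id", kind="mergesort"))


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(stack, n, box=None, seed=0, replace=False):
    """Draw background cells with probability proportional to cos(latitude).

    The cosine weighting corrects for the shrinking area of lat/lon cells
    toward the poles, emulating random pixel draws from an equal-area grid.

    Parameters
    ----------
    stack : EnvStack
    n : int
        Number of cells to draw.
    box : tuple (lon_min, lon_max, lat_min, lat_max), optional
        Restrict candidates to this region; global when omitted.
    seed : int
    replace : bool
        Draw with replacement (intended for statistical tests only).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidate = stack.valid_mask.copy()
    if box is not None:
        lon_min, lon_max, lat_min, lat_max = box
        lon_ok = (stack.lon_centers >= lon_min) & (stack.lon_centers <= lon_max)
        lat_ok = (stack.lat_centers >= lat_min) & (stack.lat_centers <= lat_max)
        candidate &= lat_ok[:, None] & lon_ok[None, :]
    rows, cols = np.nonzero(candidate)
    if len(rows) == 0 or (not replace and len(rows) < n):
        raise ValueError(
            f"insufficient candidate cells: need {n}, found {len(rows)}")
    w = np.cos(np.radians(stack.lat_centers[rows]))
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=replace, p=w / w.sum())
    rows, cols = rows[idx], cols[idx]
    return BackgroundSample(
        rows=rows, cols=cols,
        lons=stack.lon_centers[cols], lats=stack.lat_centers[rows],
        provenance="global" if box is None else f"box{tuple(box)}",
        n=n, seed=seed)


def extract_swd(points, stack, layers=None, species_label="species"):
    """Build an SWD table by reading each point's cell values from the stack.

    ``points`` may be an :class:`OccurrenceSet` or a :class:`BackgroundSample`.
    """
    layers = list(layers) if layers is not None else list(stack.layer_names)
    if isinstance(points, BackgroundSample):
        rows, cols = points.rows, points.cols
        lons, lats = points.lons, points.lats
    else:
        lons, lats = points.longitudes, points.latitudes
        rows, cols = stack.cell_index(lons, lats)
    bad = ~stack.valid_mask[rows, cols]
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"point {i} at ({lons[i]:.4f}, {lats[i]:.4f}) lies on an invalid cell")
    data = {"species": species_label, "longitude": lons, "latitude": lats}
    for name in layers:
        data[name] = stack.layer(name)[rows, cols]
    return SWDTable(pd.DataFrame(data))


def coastal_mask(stack, max_pixels=7):
    """True for valid cells less than ``max_pixels`` (Chebyshev) from shore.

    Distance is counted in pixels to the nearest invalid (land) cell. An
    all-ocean grid has no shore, so the mask is all false.
    """
    if stack.valid_mask.all():
        return np.zeros_like(stack.valid_mask)
    dist = ndimage.distance_transform_cdt(stack.valid_mask, metric="chessboard")
    return stack.valid_mask & (dist < max_pixels)
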