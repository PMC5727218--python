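"""Raster and coordinate primitives shared by the spatial stages.

Conventions
-----------
* Rasters follow the ESRI ASCII grid layout: row 0 is the *northernmost*
  row; ``xllcorner``/``yllcorner`` give the lower-left corner of the grid.
* Coordinates are cell-center referenced.  A point on a shared cell edge
  belongs to the cell with the larger row/column index, i.e. cells are the
  half-open boxes ``[x, x + cellsize) x [y, y + cellsize)``.
* Geographic distance is great-circle (haversine) on a sphere of radius
  6371.0 km; the analyses here never need ellipsoidal precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridLayer",
    "EnvGrid",
    "OccurrenceSet",
    "AsciiGridError",
    "read_ascii_grid",
    "write_ascii_grid",
    "haversine_km",
    "extract_cell_values",
    "read_occurrences_csv",
    "write_occurrences_csv",
]


class AsciiGridError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


def _check_lonlat(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise ValueError(f"coordinate out of range: lon={lon}, lat={lat}")


@dataclass
class GridLayer:
    """A single real-valued raster layer with a nodata mask.

    ``values`` is an (n_rows, n_cols) float array, row 0 northernmost.
    ``mask`` is True where the cell is NODATA.
    """

    values: np.ndarray
    mask: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D array")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "GridLayer":
        return GridLayer(
            self.values.copy(),
            self.mask.copy(),
            self.xllcorner,
            self.yllcorner,
            self.cellsize,
            self.nodata_value,
        )


class EnvGrid:
    """A georeferenced stack of named environmental layers.

    All layers share dimensions, georeference and nodata mask; typical layer
    names are the bioclimatic variables BIO1..BIO19 (e.g. BIO19 =
    precipitation of the coldest quarter).
    """

    def __init__(self, layers: dict[str, GridLayer]):
        if not layers:
            raise ValueError("EnvGrid needs at least one layer")
        names = list(layers)
        ref = layers[names[0]]
        for name in names[1:]:
            lyr = layers[name]
            if lyr.values.shape != ref.values.shape:
                raise ValueError(f"layer {name!r} shape differs from {names[0]!r}")
            if not np.array_equal(lyr.mask, ref.mask):
                raise ValueError(f"layer {name!r} mask differs from {names[0]!r}")
            if (
                lyr.xllcorner != ref.xllcorner
                or lyr.yllcorner != ref.yllcorner
                or lyr.cellsize != ref.cellsize
            ):
                raise ValueError(f"layer {name!r} georeference differs")
        self.layers: dict[str, GridLayer] = dict(layers)
        self._ref = ref

    # -- geometry -------------------------------------------------------
    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_rows(self) -> int:
        return self._ref.n_rows

    @property
    def n_cols(self) -> int:
        return self._ref.n_cols

    @property
    def mask(self) -> np.ndarray:
        """True where NODATA (shared across layers)."""
        return self._ref.mask

    @property
    def cellsize(self) -> float:
        return self._ref.cellsize

    @property
    def xllcorner(self) -> float:
        return self._ref.xllcorner

    @property
    def yllcorner(self) -> float:
        return self._ref.yllcorner

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def unmasked_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) arrays of unmasked cells in C order."""
        return np.nonzero(~self.mask)

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """(lon, lat) of the center of cell (row, col); row 0 is northernmost."""
        lon = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yllcorner + (self.n_rows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing (lon, lat) under the half-open convention.

        Points on a shared edge fall in the cell with the larger row/column
        index, which for the row axis (row 0 = north) means the cell whose
        southern edge the point sits on wins toward the *north* cell index
        computed from the floor of the offset from the lower-left corner.
        """
        col = int(math.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(math.floor((lat - self.yllcorner) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    def stack(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array in the given layer order."""
        names = list(names) if names is not None else self.layer_names
        return np.stack([self.layers[n].values for n in names])

    def layer_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_unmasked, n_layers) matrix of unmasked cell values."""
        names = list(names) if names is not None else self.layer_names
        rows, cols = self.unmasked_indices()
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])


@dataclass
class OccurrenceSet:
    """Presence localities for one taxon (longitude/latitude degrees)."""

    taxon: str
    points: list[tuple[float, float]] = field(default_factory=list)
    flags: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = [(float(lon), float(lat)) for lon, lat in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def lonlat_array(self) -> np.ndarray:
        return np.array(self.points, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> GridLayer:
    """Read one ESRI ASCII grid file into a :class:`GridLayer`.

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (default -9999).  The body must contain exactly
    nrows*ncols whitespace-separated values, first row northernmost.
    """
    path = Path(path)
    text = path.read_text().split("\n")
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise AsciiGridError(f"{path}: bad header line {i + 1}: {line!r}") from exc
            body_start = i + 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise AsciiGridError(f"{path}: missing header field {key!r}")
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    tokens = " ".join(text[body_start:]).split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise AsciiGridError(f"{path}: non-numeric value in body") from exc
    if flat.size != nrows * ncols:
        raise AsciiGridError(
            f"{path}: body has {flat.size} values, header declares "
            f"{nrows}x{ncols} = {nrows * ncols} (body starts line {body_start + 1})"
        )
    values = flat.reshape(nrows, ncols)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return GridLayer(
        values, mask, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata
    )


def write_ascii_grid(layer: GridLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (lossless round-trip with read)."""
    path = Path(path)
    out = np.where(layer.mask, layer.nodata_value, layer.values)
    fmt = lambda v: format(float(v), ".17g")  # exact float round-trip
    with path.open("w") as fh:
        fh.write(f"ncols {layer.n_cols}\n")
        fh.write(f"nrows {layer.n_rows}\n")
        fh.write(f"xllcorner {fmt(layer.xllcorner)}\n")
        fh.write(f"yllcorner {fmt(layer.yllcorner)}\n")
        fh.write(f"cellsize {fmt(layer.cellsize)}\n")
        fh.write(f"NODATA_value {fmt(layer.nodata_value)}\n")
        for row in out:
            fh.write(" ".join(fmt(v) for v in row) + "\n")


def read_env_dir(path: str | Path, pattern: str = "*.asc") -> EnvGrid:
    """Read every ASCII grid in a directory into one EnvGrid (name = stem)."""
    path = Path(path)
    layers = {p.stem: read_ascii_grid(p) for p in sorted(path.glob(pattern))}
    if not layers:
        raise FileNotFoundError(f"no {pattern} files under {path}")
    return EnvGrid(layers)


def write_env_dir(env: EnvGrid, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, layer in env.layers.items():
        write_ascii_grid(layer, path / f"{name}.asc")


# ---------------------------------------------------------------------------
# Distance and extraction
# ---------------------------------------------------------------------------


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) degree pairs."""
    lon1, lat1 = p1
    lon2, lat2 = p2
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_km_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between two (n, 2) lon/lat arrays."""
    a = np.radians(np.asarray(a, dtype=float))
    b = np.radians(np.asarray(b, dtype=float))
    lat1 = a[:, 1][:, None]
    lat2 = b[:, 1][None, :]
    dphi = lat2 - lat1
    dlam = b[:, 0][None, :] - a[:, 0][:, None]
    h = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def extract_cell_values(
    env: EnvGrid, points: Iterable[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Layer values at the cells containing each point.

    Returns ``(values, masked)`` where ``values`` has one row per point and
    one column per layer (order = ``env.layer_names``) and ``masked`` flags
    points that fall in NODATA cells (their values are NaN, the points are
    not dropped).  Points outside the grid extent raise ``ValueError`` naming
    the offending point.
    """
    pts = list(points)
    names = env.layer_names
    values = np.empty((len(pts), len(names)))
    masked = np.zeros(len(pts), dtype=bool)
    for i, (lon, lat) in enumerate(pts):
        row, col = env.cell_of(lon, lat)  # raises for out-of-extent points
        if env.mask[row, col]:
            masked[i] = True
            values[i] = np.nan
        else:
            for j, name in enumerate(names):
                values[i, j] = env.layers[name].values[row, col]
    return values, masked


# ---------------------------------------------------------------------------
# Occurrence CSV I/O (columns: taxon, lon, lat)
# ---------------------------------------------------------------------------


def read_occurrences_csv(path: str | Path, taxon: str | None = None) -> list[OccurrenceSet]:
    """Read occurrences from CSV with required columns taxon, lon, lat."""
    df = pd.read_csv(path)
    missing = {"taxon", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    out = []
    for name, grp in df.groupby("taxon", sort=True):
        if taxon is not None and str(name) != taxon:
            continue
        out.append(
            OccurrenceSet(str(name), list(zip(grp["lon"].astype(float), grp["lat"].astype(float))))
        )
    return out


def write_occurrences_csv(occurrences: Iterable[OccurrenceSet], path: str | Path) -> None:
    rows = [
        {"taxon": occ.taxon, "lon": lon, "lat": lat}
        for occ in occurrences
        for lon, lat in occ.points
    ]
    pd.DataFrame(rows, columns=["taxon", "lon", "lat"]).to_csv(path, index=False)
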