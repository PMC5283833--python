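"""Co-registered habitat raster stack.

A :class:`Landscape` bundles four layers on one grid — vegetation density in
[0, 1], binary road and animal-path masks, and elevation in meters — plus the
sleep-site coordinate. Layers are stored row-major with the origin at the
minimum (south-west) corner; see :mod:`troopstep._kernels` for the pixel
convention.

Rasters are read and written as ESRI ASCII grids (plain text, one file per
layer) with a small JSON sidecar holding the sleep site.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

LAYER_NAMES = ("vegetation", "roads", "paths", "elevation")
_NODATA = -9999.0


class RegistrationError(ValueError):
    """Raised when layers do not share shape, origin and resolution."""


@dataclasses.dataclass
class Landscape:
    """Raster stack + sleep site.

    Parameters
    ----------
    origin : (float, float)
        World coordinates (m) of the minimum corner of pixel (0, 0).
    resolution : float
        Pixel size in meters (square pixels).
    vegetation, roads, paths, elevation : ndarray (nrows, ncols)
        The four co-registered layers. Masks must be binary.
    sleep_site : (float, float)
        Sleep-site coordinate in world meters.
    """

    origin: tuple[float, float]
    resolution: float
    vegetation: np.ndarray
    roads: np.ndarray
    paths: np.ndarray
    elevation: np.ndarray
    sleep_site: tuple[float, float]

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        shapes = {layer.shape for layer in self._layers()}
        if len(shapes) != 1:
            raise RegistrationError(f"layers have differing shapes: {shapes}")
        self.vegetation = np.ascontiguousarray(self.vegetation, dtype=np.float64)
        self.roads = np.ascontiguousarray(self.roads, dtype=np.float64)
        self.paths = np.ascontiguousarray(self.paths, dtype=np.float64)
        self.elevation = np.ascontiguousarray(self.elevation, dtype=np.float64)
        for name in ("roads", "paths"):
            vals = np.unique(getattr(self, name))
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"{name} mask is not binary")
        if self.vegetation.min() < -1e-9 or self.vegetation.max() > 1 + 1e-9:
            raise ValueError("vegetation density must lie in [0, 1]")

    def _layers(self):
        return (self.vegetation, self.roads, self.paths, self.elevation)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vegetation.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in meters."""
        nr, nc = self.shape
        return (nc * self.resolution, nr * self.resolution)

    def layer(self, name: str) -> np.ndarray:
        if name not in LAYER_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    # -- coordinate helpers -------------------------------------------------
    def world_to_cell(self, xs, ys):
        """(row, col) of the half-open pixel containing each point."""
        x0, y0 = self.origin
        cols = np.floor((np.asarray(xs) - x0) / self.resolution).astype(np.int64)
        rows = np.floor((np.asarray(ys) - y0) / self.resolution).astype(np.int64)
        return rows, cols

    def in_extent(self, xs, ys):
        x0, y0 = self.origin
        w, h = self.extent
        xs = np.asarray(xs)
        ys = np.asarray(ys)
        return (xs >= x0) & (xs < x0 + w) & (ys >= y0) & (ys < y0 + h)

    def pixel_centers(self):
        """(xs, ys) 1-D arrays of pixel-center coordinates."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.resolution
        ys = y0 + (np.arange(nr) + 0.5) * self.resolution
        return xs, ys

    # -- I/O ----------------------------------------------------------------
    def write_dir(self, path) -> None:
        """Write one ESRI ASCII grid per layer plus ``meta.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in LAYER_NAMES:
            write_ascii_grid(
                path / f"{name}.asc", self.layer(name), self.origin, self.resolution
            )
        meta = {"sleep_site": list(self.sleep_site)}
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def read_dir(cls, path) -> "Landscape":
        path = Path(path)
        arrays = {}
        headers = []
        for name in LAYER_NAMES:
            arr, origin, res = read_ascii_grid(path / f"{name}.asc")
            arrays[name] = arr
            headers.append((arr.shape, origin, res))
        if len({(s, o, r) for s, o, r in headers}) != 1:
            raise RegistrationError(
                "layers are not co-registered: " + repr(headers)
            )
        meta = json.loads((path / "meta.json").read_text())
        shape, origin, res = headers[0]
        return cls(
            origin=origin,
            resolution=res,
            sleep_site=tuple(meta["sleep_site"]),
            **arrays,
        )


def write_ascii_grid(path, arr, origin, resolution) -> None:
    """ESRI ASCII grid writer (rows written north to south)."""
    arr = np.asarray(arr, dtype=float)
    nr, nc = arr.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {origin[0]!r}\n"
        f"yllcorner {origin[1]!r}\n"
        f"cellsize {resolution!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    body = np.flipud(arr)  # internal row 0 is the south edge
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array, origin, resolution)."""
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(val)
            else:
                fh.seek(pos)
                break
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (nr, nc):
        raise ValueError(f"grid body {arr.shape} does not match header ({nr},{nc})")
    nodata = header.get("nodata_value", _NODATA)
    arr[arr == nodata] = np.nan
    return (
        np.flipud(arr).copy(),
        (header["xllcorner"], header["yllcorner"]),
        header["cellsize"],
    )
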