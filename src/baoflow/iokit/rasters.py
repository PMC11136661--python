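"""ESRI ASCII grid rasters.

Internally nodata cells are NaN so that every statistic excludes them by
construction; the sentinel is restored on write.  Row 0 of ``values`` is
the northernmost row, as in the file format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class EnvRaster:
    """A single gridded environmental layer."""

    values: np.ndarray  # (nrows, ncols), NaN = nodata
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def same_grid(self, other: "EnvRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Nearest (row, col) for a coordinate; raises if outside the extent."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.cell_index(lon, lat)
        return float(self.values[r, c])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-center coordinates, shape (nrows, ncols)."""
        lon = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)


def read_asc(path: str) -> EnvRaster:
    """Parse an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASC header: missing {key}")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(
            f"ASC data has {data.size} values; header declares {nrows}x{ncols}"
        )
    values = data.reshape(nrows, ncols)
    values[values == nodata] = np.nan
    return EnvRaster(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def write_asc(raster: EnvRaster, path: str, fmt: str = "%.6g") -> None:
    out = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"nodata_value {raster.nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)
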