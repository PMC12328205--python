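"""Gridded stage-slice climate fields on regular latitude-longitude rasters.

Variables follow the palaeoclimate-model convention: mean annual temperature
(MAT, degC), mean annual precipitation (MAP, mm/yr), seasonal variation in
temperature (TSEAS, degC) and seasonal variation in precipitation
(PSEAS, mm). On disk a grid is a plain-text matrix with a '#'-prefixed
sidecar header — small, diffable and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClimateGrid", "ClimateError", "VARIABLES", "read_grid", "write_grid",
           "nearest_cell", "nearest_land_cell"]

VARIABLES = ("MAT", "MAP", "TSEAS", "PSEAS")


class ClimateError(ValueError):
    pass


@dataclass
class ClimateGrid:
    """One climate variable on a regular lat/lon grid for one stage slice."""

    variable: str
    slice_name: str
    age_ma: float
    lats: np.ndarray      # cell-centre latitudes, ascending or descending
    lons: np.ndarray      # cell-centre longitudes
    values: np.ndarray    # (nlat, nlon)
    land: np.ndarray      # (nlat, nlon) bool, True over land

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        if self.variable not in VARIABLES:
            raise ClimateError(f"unknown variable {self.variable!r}")
        if self.values.shape != (len(self.lats), len(self.lons)):
            raise ClimateError("value matrix shape does not match axes")
        if self.land.shape != self.values.shape:
            raise ClimateError("mask shape must equal value shape")
        for ax, name in ((self.lats, "lat"), (self.lons, "lon")):
            if len(ax) > 1:
                steps = np.diff(ax)
                if not np.allclose(steps, steps[0], atol=1e-9):
                    raise ClimateError(f"{name} spacing is not uniform")


def nearest_cell(grid: ClimateGrid, lat: float, lon: float) -> tuple[int, int]:
    i = int(np.argmin(np.abs(grid.lats - lat)))
    j = int(np.argmin(np.abs(grid.lons - lon)))
    return i, j


def nearest_land_cell(
    grid: ClimateGrid, lat: float, lon: float, max_radius_cells: int = 5
) -> tuple[int, int] | None:
    """Nearest land cell within a Chebyshev radius of the nearest cell.

    Candidates are ranked by (grid-index distance, row, column) so ties
    resolve deterministically. Returns None when no land cell is in reach.
    """
    i0, j0 = nearest_cell(grid, lat, lon)
    if grid.land[i0, j0]:
        return i0, j0
    best = None
    for r in range(1, max_radius_cells + 1):
        ring = []
        for di in range(-r, r + 1):
            for dj in range(-r, r + 1):
                if max(abs(di), abs(dj)) != r:
                    continue
                i, j = i0 + di, (j0 + dj) % len(grid.lons)
                if 0 <= i < len(grid.lats) and grid.land[i, j]:
                    ring.append((di * di + dj * dj, i, j))
        if ring:
            best = min(ring)
            return best[1], best[2]
    return None


def write_grid(grid: ClimateGrid, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variable: {grid.variable}\n")
        fh.write(f"# slice: {grid.slice_name}\n")
        fh.write(f"# age_ma: {grid.age_ma}\n")
        fh.write(f"# lat0: {grid.lats[0]}  dlat: {grid.lats[1] - grid.lats[0] if len(grid.lats) > 1 else 0}  nlat: {len(grid.lats)}\n")
        fh.write(f"# lon0: {grid.lons[0]}  dlon: {grid.lons[1] - grid.lons[0] if len(grid.lons) > 1 else 0}  nlon: {len(grid.lons)}\n")
        fh.write("# values\n")
        np.savetxt(fh, grid.values, fmt="%.6g")
        fh.write("# land\n")
        np.savetxt(fh, grid.land.astype(int), fmt="%d")


def read_grid(path) -> ClimateGrid:
    meta: dict[str, str] = {}
    values_lines: list[str] = []
    land_lines: list[str] = []
    section = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body == "values":
                    section = "values"
                elif body == "land":
                    section = "land"
                else:
                    for part in body.split("  "):
                        if ":" in part:
                            k, v = part.split(":", 1)
                            meta[k.strip()] = v.strip()
            elif line.strip():
                (values_lines if section == "values" else land_lines).append(line)
    try:
        nlat, nlon = int(meta["nlat"]), int(meta["nlon"])
        lat0, dlat = float(meta["lat0"]), float(meta["dlat"])
        lon0, dlon = float(meta["lon0"]), float(meta["dlon"])
    except KeyError as exc:
        raise ClimateError(f"grid header missing key {exc.args[0]}") from exc
    lats = lat0 + dlat * np.arange(nlat)
    lons = lon0 + dlon * np.arange(nlon)
    values = np.array([[float(x) for x in ln.split()] for ln in values_lines])
    land = np.array([[int(x) for x in ln.split()] for ln in land_lines], dtype=bool)
    return ClimateGrid(
        variable=meta["variable"],
        slice_name=meta["slice"],
        age_ma=float(meta["age_ma"]),
        lats=lats,
        lons=lons,
        values=values,
        land=land,
    )
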