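"""Depth-envelope habitat projection over gridded bathymetry.

Areas are computed analytically on the sphere (authalic radius): each
lat-lon cell contributes R^2 * dlon * (sin(lat_top) - sin(lat_bottom)),
which is exact and resolution-independent, and equivalent to any equal-area
projection route.  Per-basin suitable area is the summed area of ocean cells
whose depth falls inside the closed envelope interval.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .errors import ValidationError
from .records import BASINS, DepthEnvelope

#: authalic Earth radius, km
EARTH_RADIUS_KM = 6371.0088

BASIN_LABELS = BASINS + ("none",)


@dataclass
class BathymetryGrid:
    """Regular lat-lon grid of elevation (metres, negative below sea level).

    ``lats``/``lons`` are cell-centre coordinates (degrees), strictly
    monotone; ``elevation`` is ``(nlat, nlon)``; ``nodata`` marks cells to
    exclude from all accounting.
    """

    lats: np.ndarray
    lons: np.ndarray
    elevation: np.ndarray
    nodata: np.ndarray | None = None
    #: explicit cell sizes (degrees); inferred from coordinate spacing if None
    dlat_deg: float | None = None
    dlon_deg: float | None = None

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != (self.lats.size, self.lons.size):
            raise ValidationError("elevation shape does not match coordinates")
        for name, coord in (("lats", self.lats), ("lons", self.lons)):
            d = np.diff(coord)
            if coord.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(f"{name} must be strictly monotone")
        if np.any(np.abs(self.lats) > 90):
            raise ValidationError("latitudes outside [-90, 90]")
        if self.nodata is None:
            self.nodata = np.zeros(self.elevation.shape, dtype=bool)
        unmasked = self.elevation[~self.nodata]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValidationError("non-finite elevation outside the nodata mask")

    @property
    def dlat(self) -> float:
        if self.dlat_deg is not None:
            return float(self.dlat_deg)
        return float(np.abs(np.diff(self.lats)).mean()) if self.lats.size > 1 else 180.0

    @property
    def dlon(self) -> float:
        if self.dlon_deg is not None:
            return float(self.dlon_deg)
        return float(np.abs(np.diff(self.lons)).mean()) if self.lons.size > 1 else 360.0


@dataclass
class BasinMask:
    """Per-cell basin label, co-registered with a :class:`BathymetryGrid`."""

    labels: np.ndarray  # dtype str/object, values in BASIN_LABELS

    def __post_init__(self):
        bad = set(np.unique(self.labels)) - set(BASIN_LABELS)
        if bad:
            raise ValidationError(f"unknown basin labels {sorted(bad)}")


@dataclass(frozen=True)
class BasinRow:
    basin: str
    envelope_area_km2: float
    total_ocean_area_km2: float
    percent: float | None  # None when the basin has no ocean area


@dataclass(frozen=True)
class HabitatReport:
    rows: tuple[BasinRow, ...]
    global_envelope_area_km2: float
    global_total_area_km2: float
    global_percent: float | None


def percent_round(envelope_area: float, total_area: float) -> float | None:
    """100*envelope/total at 2 decimals, round-half-even; None when total=0."""
    if total_area == 0:
        return None
    pct = Decimal(100.0 * envelope_area / total_area)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def cell_area_grid(grid: BathymetryGrid) -> np.ndarray:
    """Spherical area (km^2) of every cell: R^2 * dlon * (sin top - sin bot).

    Cell edges extending beyond the poles are clamped at +/-90 deg with a
    warning.
    """
    half_lat = grid.dlat / 2.0
    top = grid.lats + half_lat
    bottom = grid.lats - half_lat
    if np.any(top > 90 + 1e-12) or np.any(bottom < -90 - 1e-12):
        warnings.warn("cell edges cross the poles; clamped at +/-90 deg", stacklevel=2)
    top = np.clip(top, -90.0, 90.0)
    bottom = np.clip(bottom, -90.0, 90.0)
    band = (
        EARTH_RADIUS_KM**2
        * np.deg2rad(grid.dlon)
        * (np.sin(np.deg2rad(top)) - np.sin(np.deg2rad(bottom)))
    )
    return np.repeat(band[:, None], grid.lons.size, axis=1)


def envelope_mask(grid: BathymetryGrid, envelope: DepthEnvelope) -> np.ndarray:
    """Boolean mask of cells whose depth lies in the closed envelope interval."""
    depth = -grid.elevation
    inside = (depth >= envelope.d_min_m) & (depth <= envelope.d_max_m)
    return inside & ~grid.nodata


def habitat_report(
    grid: BathymetryGrid, basin_mask: BasinMask, envelope: DepthEnvelope
) -> HabitatReport:
    """Per-basin suitable area, total ocean area and percent; plus the global row.

    Ocean cells are those with elevation < 0 and a basin label; suitable
    cells additionally fall inside the depth envelope.
    """
    if basin_mask.labels.shape != grid.elevation.shape:
        raise ValidationError("basin mask shape does not match grid")
    areas = cell_area_grid(grid)
    ocean = (grid.elevation < 0) & ~grid.nodata
    suitable = envelope_mask(grid, envelope)
    rows = []
    for basin in BASINS:
        in_basin = basin_mask.labels == basin
        total = float(areas[ocean & in_basin].sum())
        env = float(areas[suitable & in_basin].sum())
        pct = percent_round(env, total)
        if pct is None:
            warnings.warn(f"basin {basin} has zero ocean area", stacklevel=2)
        rows.append(
            BasinRow(
                basin=basin,
                envelope_area_km2=env,
                total_ocean_area_km2=total,
                percent=pct,
            )
        )
    g_env = sum(r.envelope_area_km2 for r in rows)
    g_tot = sum(r.total_ocean_area_km2 for r in rows)
    return HabitatReport(
        rows=tuple(rows),
        global_envelope_area_km2=g_env,
        global_total_area_km2=g_tot,
        global_percent=percent_round(g_env, g_tot),
    )


def write_bathymetry_netcdf(grid: BathymetryGrid, basin_mask: BasinMask | None, path) -> None:
    """Write grid (+optional basin labels as integer codes) to netCDF-3."""
    import xarray as xr

    data = {"elevation": (("lat", "lon"), grid.elevation)}
    if basin_mask is not None:
        codes = np.zeros(basin_mask.labels.shape, dtype=np.int32)
        for i, name in enumerate(BASIN_LABELS):
            codes[basin_mask.labels == name] = i
        data["basin_code"] = (("lat", "lon"), codes)
    ds = xr.Dataset(data, coords={"lat": grid.lats, "lon": grid.lons})
    ds.attrs["basin_legend"] = ",".join(BASIN_LABELS)
    ds.to_netcdf(path, engine="scipy")


def read_bathymetry_netcdf(path) -> tuple[BathymetryGrid, BasinMask | None]:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        grid = BathymetryGrid(
            lats=ds["lat"].values.copy(),
            lons=ds["lon"].values.copy(),
            elevation=ds["elevation"].values.copy(),
        )
        mask = None
        if "basin_code" in ds:
            codes = ds["basin_code"].values
            labels = np.array(BASIN_LABELS, dtype=object)[codes]
            mask = BasinMask(labels=labels)
    return grid, mask


def write_report_csv(report: HabitatReport, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["basin", "envelope_area_km2", "total_ocean_area_km2", "percent"])
        for r in report.rows:
            w.writerow(
                [r.basin, repr(r.envelope_area_km2), repr(r.total_ocean_area_km2),
                 "" if r.percent is None else f"{r.percent:.2f}"]
            )
        w.writerow(
            ["total", repr(report.global_envelope_area_km2),
             repr(report.global_total_area_km2),
             "" if report.global_percent is None else f"{report.global_percent:.2f}"]
        )
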