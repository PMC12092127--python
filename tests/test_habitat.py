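import math

import numpy as np
import pytest

from abyssrange.errors import ValidationError
from abyssrange.habitat import (
    EARTH_RADIUS_KM,
    BasinMask,
    BathymetryGrid,
    cell_area_grid,
    envelope_mask,
    habitat_report,
    percent_round,
    read_bathymetry_netcdf,
    write_bathymetry_netcdf,
)
from abyssrange.records import DepthEnvelope
from abyssrange.simulate import Band, make_synthetic_bathymetry

SPHERE = 4.0 * math.pi * EARTH_RADIUS_KM**2


def uniform_grid(res, elevation=-5000.0):
    nlat, nlon = round(180 / res), round(360 / res)
    lats = -90 + res * (np.arange(nlat) + 0.5)
    lons = -180 + res * (np.arange(nlon) + 0.5)
    return BathymetryGrid(
        lats=lats, lons=lons, elevation=np.full((nlat, nlon), elevation)
    )


class TestCellArea:
    @pytest.mark.parametrize("res", [1.0, 2.0, 5.0])
    def test_whole_sphere_closed_form(self, res):
        total = cell_area_grid(uniform_grid(res)).sum()
        assert abs(total - SPHERE) / SPHERE < 1e-9

    def test_single_zone_cell(self):
        # one cell spanning lon 0-360 and lat 0-30: area = pi R^2
        grid = BathymetryGrid(
            lats=np.array([15.0]), lons=np.array([180.0]),
            elevation=np.array([[-5000.0]]),
            dlat_deg=30.0, dlon_deg=360.0,
        )
        area = cell_area_grid(grid)[0, 0]
        assert area == pytest.approx(math.pi * EARTH_RADIUS_KM**2, rel=1e-12)

    def test_resolution_refinement_keeps_total(self):
        t1 = cell_area_grid(uniform_grid(2.0)).sum()
        t2 = cell_area_grid(uniform_grid(1.0)).sum()
        assert abs(t1 - t2) / t1 < 1e-9

    def test_polar_clamp_warns(self):
        grid = BathymetryGrid(
            lats=np.array([-89.5, -88.0, 89.9]),
            lons=np.array([0.0, 90.0]),
            elevation=np.zeros((3, 2)),
        )
        with pytest.warns(UserWarning, match="clamped"):
            areas = cell_area_grid(grid)
        assert np.all(areas >= 0)


class TestEnvelopeMask:
    def setup_method(self):
        self.env = DepthEnvelope(3890.0, 8931.0)

    def grid_with(self, elevations):
        n = len(elevations)
        return BathymetryGrid(
            lats=np.linspace(-60, 60, n),
            lons=np.array([0.0]),
            elevation=np.array(elevations, dtype=float).reshape(n, 1),
        )

    def test_inside_outside_and_land(self):
        g = self.grid_with([-5000.0, -100.0, 200.0])
        m = envelope_mask(g, self.env)
        assert m[:, 0].tolist() == [True, False, False]

    def test_boundaries_closed(self):
        g = self.grid_with([-3890.0, -8931.0, -3889.9, -8931.1])
        m = envelope_mask(g, self.env)
        assert m[:, 0].tolist() == [True, True, False, False]

    def test_nodata_excluded(self):
        g = self.grid_with([-5000.0, -5000.0])
        g.nodata[0, 0] = True
        assert envelope_mask(g, self.env)[:, 0].tolist() == [False, True]


class TestHabitatReport:
    def test_all_ocean_in_envelope_is_100(self):
        synth = make_synthetic_bathymetry([Band(-90, 90, -5000.0)], 2.0)
        rep = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3890, 8931))
        pacific = next(r for r in rep.rows if r.basin == "Pacific")
        assert pacific.percent == 100.00
        assert rep.global_percent == 100.00

    def test_zone_ratio_50_percent(self):
        # hemisphere ocean (0-90) whose suitable cells form the 0-30 zone:
        # fraction = (sin 30 - sin 0) / (sin 90 - sin 0) = 1/2
        synth = make_synthetic_bathymetry(
            [Band(-90, 0, 100.0), Band(0, 30, -5000.0), Band(30, 90, -100.0)],
            1.0,
        )
        rep = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3890, 8931))
        pacific = next(r for r in rep.rows if r.basin == "Pacific")
        assert pacific.percent == 50.00
        assert pacific.envelope_area_km2 == pytest.approx(
            math.pi * EARTH_RADIUS_KM**2, rel=1e-9
        )

    def test_empty_basin_percent_flagged(self):
        synth = make_synthetic_bathymetry([Band(-90, 90, -5000.0)], 5.0)
        with pytest.warns(UserWarning, match="zero ocean area"):
            rep = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3890, 8931))
        arctic = next(r for r in rep.rows if r.basin == "Arctic")
        assert arctic.percent is None

    def test_envelope_monotonicity(self):
        synth = make_synthetic_bathymetry(
            [Band(-90, 0, -4000.0), Band(0, 90, -9000.0)], 2.0
        )
        small = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3500, 5000))
        large = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3500, 9500))
        for rs, rl in zip(small.rows, large.rows):
            assert rl.envelope_area_km2 >= rs.envelope_area_km2

    def test_basin_totals_partition_ocean(self):
        sectors = [(-180.0, 0.0, "Pacific"), (0.0, 180.0, "Atlantic")]
        synth = make_synthetic_bathymetry(
            [Band(-90, 90, -5000.0)], 2.0, sectors=sectors
        )
        rep = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3890, 8931))
        total = sum(r.total_ocean_area_km2 for r in rep.rows)
        assert abs(total - SPHERE) / SPHERE < 1e-9
        assert rep.global_envelope_area_km2 == pytest.approx(
            sum(r.envelope_area_km2 for r in rep.rows)
        )

    def test_resolution_robustness(self):
        bands = [Band(-90, -30, -2000.0), Band(-30, 46, -6000.0), Band(46, 90, 300.0)]
        envs = []
        for res in (2.0, 1.0):
            synth = make_synthetic_bathymetry(bands, res)
            rep = habitat_report(synth.grid, synth.basin_mask, DepthEnvelope(3890, 8931))
            envs.append(rep.global_envelope_area_km2)
        assert abs(envs[0] - envs[1]) / envs[1] < 0.005


class TestPercentRound:
    def test_half_even_on_exact_ties(self):
        # .125 and .375 are exactly representable: ties go to the even digit
        assert percent_round(56.125, 100.0) == 56.12
        assert percent_round(56.375, 100.0) == 56.38

    def test_plain_cases(self):
        assert percent_round(1.0, 3.0) == 33.33
        assert percent_round(0.0, 1.0) == 0.0
        assert percent_round(1.0, 0.0) is None


class TestNetcdfRoundTrip:
    def test_grid_and_mask_survive(self, tmp_path):
        synth = make_synthetic_bathymetry(
            [Band(-90, 0, 100.0), Band(0, 90, -5000.0)], 5.0,
            sectors=[(-180.0, 0.0, "Indian"), (0.0, 180.0, "Southern")],
        )
        path = tmp_path / "grid.nc"
        write_bathymetry_netcdf(synth.grid, synth.basin_mask, path)
        grid, mask = read_bathymetry_netcdf(path)
        assert np.allclose(grid.elevation, synth.grid.elevation)
        assert np.allclose(grid.lats, synth.grid.lats)
        assert (mask.labels == synth.basin_mask.labels).all()
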