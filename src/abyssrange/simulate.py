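"""Synthetic inputs with known statistical structure.

Three generators mirror the three pipeline input classes:

* a neutral Kingman-coalescent sequence simulator with infinite-sites
  mutation placed onto distinct columns of a fixed-length alignment, so the
  segregating-site count equals the mutation count and Watterson/Tajima
  expectations hold analytically (E[S] = theta * a1, E[k_hat] = theta);
* analytic latitude-band bathymetry grids whose band areas have closed
  forms, with basin labels assigned by longitude sector;
* parametric occurrence-record tables whose depth extremes are forced to
  the requested envelope endpoints.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .errors import ValidationError
from .habitat import BASIN_LABELS, EARTH_RADIUS_KM, BasinMask, BathymetryGrid
from .records import BASINS, OccurrenceRecord

BASES = np.array(list("ACGT"))

#: the default a-priori locality regions sequences are assigned to
DEFAULT_REGIONS = tuple(f"region{i:02d}" for i in range(1, 15))


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    L: int
    theta: float
    seed: int = 0
    regions: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("sample size n must be >= 2")
        if self.L < 1:
            raise ValidationError("alignment length L must be >= 1")
        if not self.theta > 0:
            raise ValidationError("theta must be positive")


def simulate_coalescent_alignment(config: SimulationConfig) -> Alignment:
    """Simulate one neutral coalescent sample without recombination.

    Coalescence times are exponential with rate C(k,2); mutations are
    Poisson(theta * T_total / 2), placed uniformly on branches and assigned
    to distinct alignment columns (infinite sites).  Raises when the
    mutation count exceeds L, advising a longer alignment.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n, config.L

    # build the genealogy: node ids 0..n-1 are leaves
    n_nodes = 2 * n - 1
    node_time = np.zeros(n_nodes)
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n))
    t = 0.0
    next_id = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node_time[next_id] = t
        children[next_id] = (a, b)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    # branch lengths (every non-root node has a parent) and leaf sets
    parent = np.full(n_nodes, -1)
    for p, (a, b) in children.items():
        parent[a] = p
        parent[b] = p
    root = n_nodes - 1
    branch_nodes = [v for v in range(n_nodes) if v != root]
    lengths = np.array([node_time[parent[v]] - node_time[v] for v in branch_nodes])
    total_length = lengths.sum()

    leaves_below: dict[int, np.ndarray] = {}

    def descend(v: int) -> np.ndarray:
        if v < n:
            out = np.array([v])
        else:
            a, b = children[v]
            out = np.concatenate([descend(a), descend(b)])
        leaves_below[v] = out
        return out

    descend(root)

    n_mut = rng.poisson(config.theta * total_length / 2.0)
    if n_mut > L:
        raise ValidationError(
            f"{n_mut} mutations exceed alignment length L={L}; increase L"
        )

    ancestral = rng.choice(BASES, size=L)
    matrix = np.tile(ancestral, (n, 1))
    if n_mut > 0:
        cols = rng.choice(L, size=n_mut, replace=False)
        probs = lengths / total_length
        hit_branches = rng.choice(len(branch_nodes), size=n_mut, p=probs)
        for col, bi in zip(cols, hit_branches):
            v = branch_nodes[bi]
            anc = ancestral[col]
            derived = rng.choice(BASES[BASES != anc])
            matrix[leaves_below[v], col] = derived

    ids = [f"seq{i + 1:03d}" for i in range(n)]
    locality = {
        sid: config.regions[i % len(config.regions)] for i, sid in enumerate(ids)
    }
    return Alignment(ids=ids, matrix=matrix.astype("U1"), locus="other", locality=locality)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(alignment.ids):
            fh.write(f">{sid}\n{''.join(alignment.matrix[i])}\n")


@dataclass(frozen=True)
class Band:
    """Latitude band [lat_min, lat_max) with constant elevation (m)."""

    lat_min: float
    lat_max: float
    elevation_m: float


@dataclass(frozen=True)
class SyntheticGrid:
    grid: BathymetryGrid
    basin_mask: BasinMask
    #: closed-form spherical area (km^2) per (band index, basin) pair
    expected_areas_km2: dict[tuple[int, str], float] = field(default_factory=dict)


def _zone_area(lat_lo: float, lat_hi: float, lon_frac: float) -> float:
    return (
        2.0
        * math.pi
        * EARTH_RADIUS_KM**2
        * (math.sin(math.radians(lat_hi)) - math.sin(math.radians(lat_lo)))
        * lon_frac
    )


def make_synthetic_bathymetry(
    bands: list[Band],
    resolution_deg: float = 1.0,
    sectors: list[tuple[float, float, str]] | None = None,
) -> SyntheticGrid:
    """Analytic bathymetry: constant-elevation latitude bands, sector basins.

    Bands must tile [-90, 90] without overlap and their edges (and sector
    edges) must sit on the cell lattice so the emitted closed-form areas are
    exact for the generated grid.  ``sectors`` are (lon_min, lon_max, basin)
    triples tiling [-180, 180]; default is a single all-Pacific sector.
    """
    bands = sorted(bands, key=lambda b: b.lat_min)
    edge = -90.0
    for b in bands:
        if not math.isclose(b.lat_min, edge, abs_tol=1e-9):
            kind = "overlap" if b.lat_min < edge else "gap"
            raise ValidationError(f"band {kind} at latitude {b.lat_min}")
        if b.lat_max <= b.lat_min:
            raise ValidationError("band lat_max must exceed lat_min")
        edge = b.lat_max
    if not math.isclose(edge, 90.0, abs_tol=1e-9):
        raise ValidationError("bands must cover latitudes up to 90")

    sectors = sectors or [(-180.0, 180.0, "Pacific")]
    for lo, hi, name in sectors:
        if name not in BASIN_LABELS:
            raise ValidationError(f"unknown basin {name!r}")

    res = resolution_deg
    for val in (
        [b.lat_min for b in bands] + [b.lat_max for b in bands]
        + [s[0] for s in sectors] + [s[1] for s in sectors]
    ):
        if not math.isclose((val + 180.0) / res, round((val + 180.0) / res), abs_tol=1e-9):
            raise ValidationError(
                f"boundary {val} deg is not aligned to the {res} deg cell lattice"
            )

    nlat = round(180.0 / res)
    nlon = round(360.0 / res)
    lats = -90.0 + res * (np.arange(nlat) + 0.5)
    lons = -180.0 + res * (np.arange(nlon) + 0.5)

    elevation = np.empty((nlat, nlon))
    for b in bands:
        rows = (lats >= b.lat_min) & (lats < b.lat_max)
        elevation[rows, :] = b.elevation_m

    labels = np.empty((nlat, nlon), dtype=object)
    labels[:] = "none"
    for lo, hi, name in sectors:
        cols = (lons >= lo) & (lons < hi)
        labels[:, cols] = name

    expected: dict[tuple[int, str], float] = {}
    for i, b in enumerate(bands):
        for lo, hi, name in sectors:
            frac = (hi - lo) / 360.0
            expected[(i, name)] = _zone_area(b.lat_min, b.lat_max, frac)

    grid = BathymetryGrid(lats=lats, lons=lons, elevation=elevation)
    return SyntheticGrid(
        grid=grid, basin_mask=BasinMask(labels=labels), expected_areas_km2=expected
    )


def make_synthetic_records(
    n_records: int,
    n_sites: int,
    depth_range: tuple[float, float],
    seed: int = 0,
) -> list[OccurrenceRecord]:
    """Parametric occurrence records hitting the requested envelope exactly.

    Every site id occurs at least once; the first and last records carry the
    envelope endpoints so the derived depth extremes equal ``depth_range``.
    """
    d_min, d_max = depth_range
    if not (0 < d_min <= d_max):
        raise ValidationError(f"invalid depth range {depth_range}")
    if not 1 <= n_sites <= n_records:
        raise ValidationError("need 1 <= n_sites <= n_records")
    if n_records == 1 and d_min != d_max:
        raise ValidationError("a single record cannot span a non-degenerate range")

    rng = np.random.default_rng(seed)
    open_basins = ("Pacific", "Atlantic", "Indian")
    site_ids = [f"site{i + 1:03d}" for i in range(n_sites)]
    site_basin = rng.choice(open_basins, size=n_sites)
    site_lat = rng.uniform(-60, 60, size=n_sites)
    site_lon = rng.uniform(-180, 180, size=n_sites)
    site_feature = [f"feature{(i % 15) + 1:02d}" for i in range(n_sites)]

    # ensure full site coverage, then fill the remainder at random
    assignment = list(range(n_sites)) + list(
        rng.integers(0, n_sites, size=n_records - n_sites)
    )
    rng.shuffle(assignment)
    depths = rng.uniform(d_min, d_max, size=n_records)
    depths[0] = d_min
    if n_records > 1:
        depths[-1] = d_max

    records = []
    for r, si in enumerate(assignment):
        records.append(
            OccurrenceRecord(
                site_id=site_ids[si],
                feature_name=site_feature[si],
                basin=str(site_basin[si]),
                latitude=float(site_lat[si]),
                longitude=float(site_lon[si]),
                depth_m=float(depths[r]),
                record_type=str(rng.choice(("observation", "collection", "both"))),
                source_ref="synthetic",
                n_individuals=int(rng.integers(1, 20)),
            )
        )
    return records


def write_records_csv(records: list[OccurrenceRecord], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["site_id", "feature", "basin", "lat", "lon", "depth_m",
             "record_type", "source_ref", "n_individuals"]
        )
        for r in records:
            w.writerow(
                [r.site_id, r.feature_name, r.basin, repr(r.latitude),
                 repr(r.longitude), repr(r.depth_m), r.record_type,
                 r.source_ref, "" if r.n_individuals is None else r.n_individuals]
            )


def write_ground_truth(path: str | Path, **params) -> None:
    """JSON sidecar of generator parameters and closed-form expectations."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
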