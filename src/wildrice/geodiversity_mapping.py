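"""Grid-based mapping of allelic richness and Shannon diversity.

Diversity statistics are rasterised on a regular lon/lat grid (30 arc
seconds by default): the value of a cell is computed from all genotyped
individuals within a circular neighborhood (5 arc minutes diameter by
default, ~10 km at the equator) of its center, so the maps compare the
genetic profiles of adjacent populations at landscape scale. Cells whose
neighborhood holds no individual are nodata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_structure import haversine_km
from .genotype_io import GenotypeTable
from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityRaster",
    "GridSpec",
    "assign_neighborhoods",
    "diversity_rasters",
]

ARCSEC = 1.0 / 3600.0
ARCMIN = 1.0 / 60.0


@dataclass
class GridSpec:
    """Output grid: resolution in arc seconds, extent from the samples'
    bounding box padded by one neighborhood diameter unless given."""

    resolution_arcsec: float = 30.0
    extent: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax


@dataclass
class DiversityRaster:
    statistic: RasterGrid
    counts: RasterGrid
    diameter_arcmin: float
    resolution_arcsec: float


def _build_grid(
    table: GenotypeTable, spec: GridSpec, diameter_arcmin: float
) -> RasterGrid:
    res = spec.resolution_arcsec * ARCSEC
    if diameter_arcmin * ARCMIN <= res:
        raise ValueError("neighborhood diameter must exceed the cell size")
    if spec.extent is not None:
        xmin, xmax, ymin, ymax = spec.extent
    else:
        lons = [s.lon for s in table.samples if s.lon is not None]
        lats = [s.lat for s in table.samples if s.lat is not None]
        pad = diameter_arcmin * ARCMIN
        xmin, xmax = min(lons) - pad, max(lons) + pad
        ymin, ymax = min(lats) - pad, max(lats) + pad
    ncols = max(int(np.ceil((xmax - xmin) / res)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / res)), 1)
    return RasterGrid(
        values=np.full((nrows, ncols), np.nan), xll=xmin, yll=ymin, cellsize=res
    )


def assign_neighborhoods(
    table: GenotypeTable,
    grid_spec: GridSpec | None = None,
    diameter_arcmin: float = 5.0,
) -> tuple[RasterGrid, dict[tuple[int, int], list[int]]]:
    """Map each output cell to the indices of individuals within a
    great-circle radius of diameter/2 of its center.

    Samples without coordinates are excluded with a warning. Only cells
    with at least one member are returned.
    """
    spec = grid_spec or GridSpec()
    grid = _build_grid(table, spec, diameter_arcmin)
    keep_idx = [
        i for i, s in enumerate(table.samples)
        if s.lon is not None and s.lat is not None
    ]
    if len(keep_idx) < len(table.samples):
        warnings.warn(
            f"{len(table.samples) - len(keep_idx)} samples lack coordinates "
            "and are excluded from mapping"
        )
    slon = np.array([table.samples[i].lon for i in keep_idx])
    slat = np.array([table.samples[i].lat for i in keep_idx])
    radius_km = (
        haversine_km(0.0, 0.0, 0.0, diameter_arcmin * ARCMIN) / 2.0
    )  # meridional arc length of the diameter, halved

    clon, clat = grid.cell_centers()
    members: dict[tuple[int, int], list[int]] = {}
    # restrict the scan to cells within the radius of any sample's bbox
    pad = diameter_arcmin * ARCMIN
    for r in range(grid.nrows):
        lat_row = clat[r, 0]
        if lat_row < slat.min() - pad or lat_row > slat.max() + pad:
            continue
        d = haversine_km(
            clon[r][:, None], np.full((grid.ncols, 1), lat_row),
            slon[None, :], slat[None, :],
        )
        hit = d <= radius_km
        for c in np.flatnonzero(hit.any(axis=1)):
            members[(r, int(c))] = [keep_idx[k] for k in np.flatnonzero(hit[c])]
    return grid, members


def _cell_stats(table: GenotypeTable, idx: list[int]) -> tuple[float, float]:
    """Allelic richness (total distinct alleles over loci) and the mean
    per-locus Shannon entropy of the member allele frequencies.

    Tetraploid partial heterozygotes contribute their observed distinct
    alleles with equal weight (ploidy / #observed copies each)."""
    richness = 0
    entropies = []
    for locus in table.locus_names:
        counts: dict[int, float] = {}
        for i in idx:
            g = table.samples[i].genotypes[locus]
            if g.missing:
                continue
            w = g.declared_ploidy / len(g.alleles)
            for a in g.alleles:
                counts[a] = counts.get(a, 0.0) + w
        if not counts:
            continue
        richness += len(counts)
        tot = sum(counts.values())
        p = np.array([v / tot for v in counts.values()])
        entropies.append(float(-(p * np.log(p)).sum()))
    shannon = float(np.mean(entropies)) if entropies else float("nan")
    return float(richness), shannon


def diversity_rasters(
    table: GenotypeTable,
    neighborhoods: tuple[RasterGrid, dict[tuple[int, int], list[int]]] | None = None,
    grid_spec: GridSpec | None = None,
    diameter_arcmin: float = 5.0,
    richness_mode: str = "total",
) -> tuple[DiversityRaster, DiversityRaster]:
    """Allelic-richness and Shannon-diversity rasters with member counts.

    ``richness_mode="total"`` maps the total distinct-allele count over
    loci; ``"mean"`` divides by the number of scored loci.
    """
    if neighborhoods is None:
        neighborhoods = assign_neighborhoods(table, grid_spec, diameter_arcmin)
    grid, members = neighborhoods
    spec = grid_spec or GridSpec()
    rich = np.full(grid.values.shape, np.nan)
    shan = np.full(grid.values.shape, np.nan)
    count = np.full(grid.values.shape, np.nan)
    n_loci_scored: dict[tuple[int, int], int] = {}
    for (r, c), idx in members.items():
        rv, sv = _cell_stats(table, idx)
        if richness_mode == "mean":
            scored = sum(
                1 for locus in table.locus_names
                if any(not table.samples[i].genotypes[locus].missing for i in idx)
            )
            rv = rv / scored if scored else float("nan")
        elif richness_mode != "total":
            raise ValueError(f"unknown richness mode {richness_mode!r}")
        rich[r, c] = rv
        shan[r, c] = sv
        count[r, c] = len(idx)
    count_grid = grid.with_values(count, name="n_individuals")
    return (
        DiversityRaster(
            statistic=grid.with_values(rich, name="allelic_richness"),
            counts=count_grid,
            diameter_arcmin=diameter_arcmin,
            resolution_arcsec=spec.resolution_arcsec,
        ),
        DiversityRaster(
            statistic=grid.with_values(shan, name="shannon"),
            counts=count_grid,
            diameter_arcmin=diameter_arcmin,
            resolution_arcsec=spec.resolution_arcsec,
        ),
    )


def per_cell_table(div: DiversityRaster) -> pd.DataFrame:
    """Defined cells as rows: center lon/lat, member count, statistic."""
    grid = div.statistic
    lon, lat = grid.cell_centers()
    mask = np.isfinite(grid.values)
    return pd.DataFrame(
        {
            "lon": lon[mask],
            "lat": lat[mask],
            "count": div.counts.values[mask],
            grid.name: grid.values[mask],
        }
    )
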