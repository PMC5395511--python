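"""Synthetic SSR genotypes, climate rasters and occurrence samples.

These generators produce data with the statistical structure the analysis
assumes — multi-deme microsatellite genotypes from a forward Wright–Fisher
simulation with stepwise mutation and partial selfing (tetraploid genotypes
observed only as allele sets, so partial heterozygotes arise naturally),
spatially arranged demes giving isolation by distance under stepping-stone
migration, and smooth-gradient environmental rasters with a known logistic
truth suitability from which presences are drawn.

Everything is reproducible from an explicit integer seed; no global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .genotype_io import Genotype, GenotypeTable, Locus, SampleRecord
from .raster import RasterGrid

__all__ = [
    "PopGenSimConfig",
    "SuitabilityTruth",
    "simulate_ssr_genotypes",
    "simulate_climate_rasters",
    "sample_occurrences",
    "perturb_rasters",
]

_BASE_ALLELE_SIZE = 100  # bp size assigned to repeat count 0


@dataclass
class PopGenSimConfig:
    """Parameters of the forward island/stepping-stone simulation.

    ``migration_rate`` is the per-generation probability that an offspring's
    parents are drawn from another deme: any other deme under the "island"
    model, an adjacent deme under "stepping_stone" (which produces isolation
    by distance when demes sit on a line).
    """

    n_populations: int = 4
    n_individuals_per_pop: int = 30
    ploidy: int = 2
    n_loci: int = 11
    allele_pool_size: int = 8
    repeat_length: int = 2
    migration_rate: float = 0.01
    selfing_rate: float = 0.5
    mutation_rate: float = 1e-3
    n_generations: int = 100
    migration_model: str = "island"  # or "stepping_stone"
    pop_coordinates: list[tuple[float, float]] | None = None
    coordinate_jitter: float = 0.005  # degrees, <= 0.01 so demes stay distinct
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.ploidy}")
        for name in ("migration_rate", "selfing_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_populations", "n_individuals_per_pop", "n_loci",
            "allele_pool_size", "repeat_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.migration_model not in ("island", "stepping_stone"):
            raise ValueError(f"unknown migration model {self.migration_model!r}")
        if self.pop_coordinates is None:
            # demes on a line, equal spacing, so distance rank is unambiguous
            self.pop_coordinates = [
                (float(i) * 0.5, 0.0) for i in range(self.n_populations)
            ]
        if len(self.pop_coordinates) != self.n_populations:
            raise ValueError("pop_coordinates length must equal n_populations")


def _next_generation(
    state: np.ndarray, cfg: PopGenSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One Wright–Fisher generation. ``state``: (P, N, ploidy) repeat counts."""
    P, N, ploidy = state.shape
    half = ploidy // 2

    # source deme per offspring
    home = np.repeat(np.arange(P), N).reshape(P, N)
    migrate = rng.random((P, N)) < cfg.migration_rate
    if cfg.migration_model == "island" and P > 1:
        shift = rng.integers(1, P, size=(P, N))
        source = np.where(migrate, (home + shift) % P, home)
    elif cfg.migration_model == "stepping_stone" and P > 1:
        step = rng.choice([-1, 1], size=(P, N))
        neighbor = np.clip(home + step, 0, P - 1)
        # at the ends the only neighbour is inward
        neighbor = np.where(neighbor == home, home - np.sign(step), neighbor)
        source = np.where(migrate, neighbor, home)
    else:
        source = home

    p1 = rng.integers(0, N, size=(P, N))
    p2 = rng.integers(0, N, size=(P, N))
    selfed = rng.random((P, N)) < cfg.selfing_rate
    p2 = np.where(selfed, p1, p2)

    # gametes: half the allele copies of each parent, sampled without
    # replacement (tetrasomic inheritance for ploidy 4)
    def gametes(parent_idx: np.ndarray) -> np.ndarray:
        parents = state[source, parent_idx]  # (P, N, ploidy)
        order = rng.permuted(
            np.broadcast_to(np.arange(ploidy), (P, N, ploidy)).copy(), axis=2
        )
        return np.take_along_axis(parents, order[..., :half], axis=2)

    offspring = np.concatenate([gametes(p1), gametes(p2)], axis=2)

    # symmetric stepwise mutation, floor at 1 repeat
    mut = rng.random(offspring.shape) < cfg.mutation_rate
    step = rng.choice([-1, 1], size=offspring.shape)
    offspring = np.where(mut, np.maximum(offspring + step, 1), offspring)
    return offspring


def simulate_ssr_genotypes(config: PopGenSimConfig) -> GenotypeTable:
    """Simulate a mixed-ploidy SSR genotype table under the island model.

    Returns a :class:`GenotypeTable` whose tetraploid genotypes expose only
    the set of distinct alleles (copy numbers hidden), as real tetraploid
    SSR scoring does. Allele calls are emitted as fragment sizes in bp
    (``100 + repeat_count * repeat_length``) so the table round-trips
    through the bp-based I/O and repeat-unit conversion.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    P, N, L = cfg.n_populations, cfg.n_individuals_per_pop, cfg.n_loci

    # independent loci: simulate each locus separately
    per_locus_states = []
    for _ in range(L):
        # founders drawn uniformly from a pool of adjacent repeat counts
        state = rng.integers(
            5, 5 + cfg.allele_pool_size, size=(P, N, cfg.ploidy)
        )
        for _ in range(cfg.n_generations):
            state = _next_generation(state, cfg, rng)
        per_locus_states.append(state)

    loci = [
        Locus(name=f"L{j + 1:02d}", repeat_length=cfg.repeat_length)
        for j in range(L)
    ]
    samples = []
    for d in range(P):
        lon0, lat0 = cfg.pop_coordinates[d]
        for i in range(N):
            jit = rng.uniform(-cfg.coordinate_jitter, cfg.coordinate_jitter, size=2)
            genotypes = {}
            for j, locus in enumerate(loci):
                repeats = per_locus_states[j][d, i]
                sizes = tuple(
                    int(_BASE_ALLELE_SIZE + r * cfg.repeat_length) for r in repeats
                )
                genotypes[locus.name] = Genotype(sizes, declared_ploidy=cfg.ploidy)
            samples.append(
                SampleRecord(
                    sample_id=f"P{d + 1}_I{i + 1:03d}",
                    species="synthetic",
                    site_id=f"P{d + 1}",
                    lon=lon0 + float(jit[0]),
                    lat=lat0 + float(jit[1]),
                    genotypes=genotypes,
                )
            )
    return GenotypeTable(loci=loci, samples=samples)


# -- climate rasters --------------------------------------------------

@dataclass
class SuitabilityTruth:
    """Known logistic truth with an optional niche optimum.

    suitability = sigmoid(b0 + sum b_i x_i + sum q_i x_i^2); a negative
    quadratic coefficient makes the species peak at intermediate values of
    that variable (a niche optimum) instead of responding monotonically.
    """

    intercept: float
    coefficients: dict[str, float]
    quadratic: dict[str, float] = field(default_factory=dict)

    def suitability(self, rasters: list[RasterGrid]) -> RasterGrid:
        by_name = {r.name: r for r in rasters}
        eta = np.full(rasters[0].values.shape, self.intercept)
        for name, coef in self.coefficients.items():
            eta = eta + coef * by_name[name].values
        for name, coef in self.quadratic.items():
            eta = eta + coef * by_name[name].values ** 2
        vals = 1.0 / (1.0 + np.exp(-eta))
        for r in rasters:
            vals = np.where(np.isnan(r.values), np.nan, vals)
        return rasters[0].with_values(vals, name="truth")


def simulate_climate_rasters(
    extent: tuple[float, float, float, float] = (-75.0, -70.0, 0.0, 5.0),
    resolution: float = 0.05,
    n_layers: int = 4,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> list[RasterGrid]:
    """Smooth-gradient environmental layers plus a strongly collinear pair.

    Layer ``env1`` is a longitudinal gradient; ``env2`` is env1 rescaled
    plus small noise (to exercise collinearity pruning); remaining layers
    mix latitudinal/diagonal gradients with smoothed noise. A shared
    ``nodata_mask`` (True = nodata) propagates into every layer.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    xmin, xmax, ymin, ymax = extent
    ncols = int(round((xmax - xmin) / resolution))
    nrows = int(round((ymax - ymin) / resolution))
    rng = np.random.default_rng(seed)
    xg, yg = np.meshgrid(
        np.linspace(0, 1, ncols), np.linspace(1, 0, nrows)
    )  # row 0 = north

    def smooth_noise(scale: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=5)
        sd = f.std()
        return f / sd * scale if sd > 0 else f  # unit-sd field times scale

    layers = [xg + smooth_noise(0.3)]
    layers.append(0.8 * layers[0] + 0.1 + smooth_noise(0.01))  # collinear with env1
    for k in range(2, n_layers):
        if k % 2 == 0:
            layers.append(yg + smooth_noise(0.3))
        else:
            # patchy, noise-dominated layer (terrain-like): suitable areas
            # for species tracking it form disjoint patches
            layers.append(0.5 + 0.2 * (xg + yg) / 2 + smooth_noise(0.6))

    out = []
    for k, vals in enumerate(layers):
        if nodata_mask is not None:
            vals = np.where(nodata_mask, np.nan, vals)
        out.append(
            RasterGrid(
                values=vals, xll=xmin, yll=ymin, cellsize=resolution,
                name=f"env{k + 1}",
            )
        )
    return out


def sample_occurrences(
    truth: SuitabilityTruth,
    rasters: list[RasterGrid],
    n_presence: int,
    seed: int = 0,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Draw presences with probability proportional to true suitability.

    At most one presence per grid cell; returns cell-center lon/lat.
    """
    suit = truth.suitability(rasters)
    vals = suit.values
    lon, lat = suit.cell_centers()
    ok = np.isfinite(vals) & (vals > 0)
    idx = np.flatnonzero(ok.ravel())
    if n_presence > idx.size:
        raise ValueError(
            f"n_presence={n_presence} exceeds the {idx.size} cells with "
            "positive suitability"
        )
    w = vals.ravel()[idx]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_presence, replace=False, p=w / w.sum())
    return pd.DataFrame(
        {
            "id": [f"occ{i + 1}" for i in range(n_presence)],
            "species": species,
            "lon": lon.ravel()[chosen],
            "lat": lat.ravel()[chosen],
        }
    )


def perturb_rasters(
    rasters: list[RasterGrid],
    mode: str,
    magnitude: float = 0.1,
    n_replicates: int | None = None,
    seed: int = 0,
) -> list[list[RasterGrid]]:
    """Shifted/rescaled raster sets standing in for palaeo/future climates.

    ``mode="lgm"`` yields 2 replicate sets by default (two global climate
    models); ``mode="future"`` yields 30 (downscaled model ensemble). Each
    replicate applies a per-layer additive shift and mild rescaling drawn
    from the seed; ``magnitude=0`` reproduces the inputs exactly.
    """
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    if n_replicates is None:
        n_replicates = {"lgm": 2, "future": 30}[mode]
    if mode not in ("lgm", "future"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        rep = []
        for r in rasters:
            shift = rng.normal(0.0, magnitude)
            scale = 1.0 + rng.normal(0.0, magnitude / 4)
            rep.append(r.with_values(r.values * scale + shift))
        out.append(rep)
    return out
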