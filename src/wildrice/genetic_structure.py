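"""Genetic distances, ordination, clustering and spatial structure.

Implements the Bruvo microsatellite distance (defined on repeat-unit
differences, usable at any ploidy because it minimises over allele
assignments rather than requiring known copy numbers), Nei's standard
genetic distance for diploids, principal coordinates analysis, UPGMA
clustering with locus-bootstrap branch support, Mantel tests of isolation
by distance, and the rate-of-change (ΔK) statistic used to choose the
number of clusters from Bayesian-clustering log-likelihoods.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "ClusterTree",
    "bruvo_allele_distance",
    "bruvo_genotype_distance",
    "bruvo_matrix",
    "nei_distance_diploid",
    "geographic_distance_matrix",
    "haversine_km",
    "pcoa",
    "upgma_with_bootstrap",
    "cut_supported_clusters",
    "mantel_test",
    "evanno_delta_k",
    "read_structure_loglikelihoods",
]

EARTH_RADIUS_KM = 6371.0088


# -- containers -------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # over positive eigenvalues
    labels: list[str]


@dataclass
class ClusterTree:
    """UPGMA dendrogram with bootstrap branch support.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``supports``
    maps each internal node id (n .. 2n-2) to percent bootstrap support of
    its clade (fraction of locus-bootstrap trees containing the same set
    of samples).
    """

    labels: list[str]
    linkage: np.ndarray
    supports: dict[int, float]
    cophenetic_correlation: float
    n_boot: int

    def clades(self) -> dict[int, frozenset[str]]:
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for k, (i, j, *_rest) in enumerate(self.linkage):
            sets[n + k] = sets[int(i)] | sets[int(j)]
        return sets

    def to_newick(self) -> str:
        n = len(self.labels)

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            k = i - n
            left, right, height, _ = self.linkage[k]
            sup = self.supports.get(i)
            label = "" if sup is None else f"{sup:.1f}"
            return f"({node(int(left))},{node(int(right))}){label}"

        return node(2 * n - 2) + ";"


# -- Bruvo distance ---------------------------------------------------

def bruvo_allele_distance(a: int, b: int) -> float:
    """Per-allele distance 1 - 2^(-|a-b|) on repeat units."""
    return 1.0 - 2.0 ** (-abs(int(a) - int(b)))


@lru_cache(maxsize=200_000)
def _bruvo_sets(g1: tuple[int, ...], g2: tuple[int, ...]) -> float:
    """Minimal mean allele distance between two allele sets (cached).

    Equal set sizes: exact minimum over one-to-one assignments. Unequal
    sizes (unknown copy numbers across ploidy levels): the mean of the
    genome-addition variant (the smaller set is padded with copies of its
    own alleles, minimised over choices) and the genome-loss variant
    (padding alleles are treated as maximally distant, d = 1).
    """
    if len(g1) > len(g2):
        g1, g2 = g2, g1
    k, m = len(g1), len(g2)
    if k == m:
        return min(
            sum(bruvo_allele_distance(a, b) for a, b in zip(g1, perm)) / m
            for perm in itertools.permutations(g2)
        )
    # addition: complete the smaller genotype from its own alleles
    addition = min(
        _bruvo_sets(tuple(sorted(g1 + extra)), g2)
        for extra in itertools.combinations_with_replacement(g1, m - k)
    )
    # loss: unmatched alleles of the larger genotype count as distance 1
    loss = min(
        (
            sum(bruvo_allele_distance(a, b) for a, b in zip(g1, sub))
            + (m - k)
        )
        / m
        for sub in itertools.permutations(g2, k)
    )
    return (addition + loss) / 2.0


def bruvo_genotype_distance(
    alleles1: tuple[int, ...], alleles2: tuple[int, ...]
) -> float:
    """Bruvo distance between two genotypes given as repeat-unit allele sets
    (1-4 distinct members each); NaN when either genotype is missing."""
    a1 = tuple(sorted(set(int(a) for a in alleles1)))
    a2 = tuple(sorted(set(int(a) for a in alleles2)))
    if not a1 or not a2:
        return float("nan")
    return _bruvo_sets(a1, a2)


def bruvo_distance_stack(table) -> tuple[np.ndarray, list[str]]:
    """Per-locus Bruvo distance matrices, shape (n_loci, n, n), NaN where a
    locus is missing in either sample. The input table must already be in
    repeat units (see ``genotype_io.to_repeat_units``)."""
    n = len(table.samples)
    loci = table.locus_names
    stack = np.full((len(loci), n, n), np.nan)
    for li, locus in enumerate(loci):
        genos = [s.genotypes[locus].alleles for s in table.samples]
        for i in range(n):
            stack[li, i, i] = 0.0 if genos[i] else np.nan
            for j in range(i + 1, n):
                d = bruvo_genotype_distance(genos[i], genos[j])
                stack[li, i, j] = stack[li, j, i] = d
    return stack, loci


def bruvo_matrix(table) -> DistanceMatrix:
    """Pairwise Bruvo distances averaged over loci scored in both samples."""
    if len(table.samples) < 2:
        raise ValueError("need at least two samples")
    stack, _ = bruvo_distance_stack(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        vals = np.nanmean(stack, axis=0)
    np.fill_diagonal(vals, 0.0)
    if np.isnan(vals).any():
        bad = np.argwhere(np.isnan(vals))
        ids = table.sample_ids
        pairs = sorted({tuple(sorted((ids[i], ids[j]))) for i, j in bad})
        raise ValueError(f"sample pairs share no scored locus: {pairs[:5]}")
    return DistanceMatrix(list(table.sample_ids), vals)


# -- Nei standard distance (diploid) ----------------------------------

def nei_distance_diploid(table) -> DistanceMatrix:
    """Nei standard genetic distance between individual diploid samples.

    Each sample is an allele-frequency vector per locus (0/0.5/1);
    D = -ln(J_xy / sqrt(J_x J_y)) with the J sums pooled over loci.
    Disjoint homozygotes give infinite distance (identity I = 0).
    """
    n = len(table.samples)
    loci = table.locus_names
    freq: list[dict[str, dict[int, float]]] = []
    for s in table.samples:
        per = {}
        for locus in loci:
            g = s.genotypes[locus]
            if g.declared_ploidy != 2:
                raise ValueError("nei_distance_diploid requires diploid data")
            if g.missing:
                continue
            if len(g.alleles) == 1:
                per[locus] = {g.alleles[0]: 1.0}
            else:
                per[locus] = {g.alleles[0]: 0.5, g.alleles[1]: 0.5}
        freq.append(per)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jxy = jx = jy = 0.0
            shared = set(freq[i]) & set(freq[j])
            if not shared:
                raise ValueError(
                    f"samples {table.sample_ids[i]} and {table.sample_ids[j]} "
                    "share no scored locus"
                )
            for locus in shared:
                fi, fj = freq[i][locus], freq[j][locus]
                jx += sum(v * v for v in fi.values())
                jy += sum(v * v for v in fj.values())
                jxy += sum(fi[a] * fj.get(a, 0.0) for a in fi)
            identity = jxy / math.sqrt(jx * jy)
            vals[i, j] = vals[j, i] = (
                math.inf if identity == 0 else -math.log(identity)
            )
    return DistanceMatrix(list(table.sample_ids), vals)


# -- geography --------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on the WGS84 sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distance_matrix(table) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sample coordinates."""
    pts = [(s.lon, s.lat) for s in table.samples]
    if any(p[0] is None or p[1] is None for p in pts):
        raise ValueError("all samples need coordinates for geographic distances")
    lon = np.array([p[0] for p in pts])
    lat = np.array([p[1] for p in pts])
    vals = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2  # exact symmetry
    return DistanceMatrix(list(table.sample_ids), vals)


# -- ordination -------------------------------------------------------

def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Axes with non-positive eigenvalues carry no usable coordinates and are
    dropped; asking for more axes than there are positive eigenvalues
    truncates with a warning.
    """
    from skbio.stats.ordination import pcoa as _skbio_pcoa
    from skbio import DistanceMatrix as _SkbioDM

    if np.isnan(d.values).any():
        raise ValueError("PCoA requires a complete distance matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(_SkbioDM(d.values, ids=d.labels), method="eigh")
    eig = np.asarray(res.eigvals, dtype=float)
    coords = res.samples.to_numpy()
    pos = eig > 1e-12
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from {n_axes} axes"
        )
        n_axes = n_pos
    prop = eig[pos] / eig[pos].sum()
    return PCoAResult(
        coordinates=coords[:, :n_axes],
        eigenvalues=eig,
        proportion_explained=prop,
        labels=list(d.labels),
    )


# -- UPGMA with locus bootstrap ---------------------------------------

def _clade_sets(Z: np.ndarray, labels: list[str]) -> dict[int, frozenset[str]]:
    n = len(labels)
    sets: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    for k in range(Z.shape[0]):
        i, j = int(Z[k, 0]), int(Z[k, 1])
        sets[n + k] = sets[i] | sets[j]
    return sets


def upgma_with_bootstrap(
    table,
    n_boot: int = 10_000,
    seed: int = 0,
    distance: str = "bruvo",
) -> ClusterTree:
    """UPGMA dendrogram on the full-data distance with locus-bootstrap
    branch support (percent of replicate trees containing each clade) and
    the cophenetic correlation coefficient.

    Bootstrap replicates resample loci with replacement; the per-locus
    Bruvo distance stack is precomputed so each replicate is an average of
    sampled locus matrices.
    """
    if len(table.samples) < 3:
        raise ValueError("need at least three samples to cluster")
    if len(table.loci) < 2:
        raise ValueError("bootstrap over loci needs at least two loci")
    if distance != "bruvo":
        raise ValueError(f"unsupported distance {distance!r}")
    stack, _ = bruvo_distance_stack(table)
    labels = list(table.sample_ids)
    L = stack.shape[0]

    def tree_from(mats: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            vals = np.nanmean(mats, axis=0)
        np.fill_diagonal(vals, 0.0)
        if np.isnan(vals).any():
            vals = np.where(np.isnan(vals), np.nanmax(vals), vals)
        return linkage(squareform(vals, checks=False), method="average")

    Z = tree_from(stack)
    full = np.nanmean(stack, axis=0)
    np.fill_diagonal(full, 0.0)
    coph, _ = cophenet(Z, squareform(full, checks=False))

    n = len(labels)
    clades = _clade_sets(Z, labels)
    internal = {nid: cl for nid, cl in clades.items() if nid >= n}
    hits = {nid: 0 for nid in internal}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        Zb = tree_from(stack[idx])
        boot_clades = set(_clade_sets(Zb, labels).values())
        for nid, cl in internal.items():
            if cl in boot_clades:
                hits[nid] += 1
    supports = {nid: 100.0 * h / n_boot for nid, h in hits.items()}
    return ClusterTree(
        labels=labels,
        linkage=Z,
        supports=supports,
        cophenetic_correlation=float(coph),
        n_boot=n_boot,
    )


def cut_supported_clusters(
    tree: ClusterTree, min_support: float = 95.0
) -> dict[str, int | None]:
    """Assign samples to the maximal well-supported clades.

    A cluster is a clade whose branch support exceeds ``min_support`` and
    that is not nested inside another such clade; the root (the trivial
    clade of all samples) is ignored. Samples outside every supported
    clade map to None.
    """
    clades = tree.clades()
    n = len(tree.labels)
    root = 2 * n - 2
    supported = [
        (nid, cl)
        for nid, cl in clades.items()
        if nid >= n and nid != root and tree.supports.get(nid, 0.0) > min_support
    ]
    # keep maximal clades only
    maximal = [
        (nid, cl)
        for nid, cl in supported
        if not any(cl < other for _, other in supported)
    ]
    maximal.sort(key=lambda t: sorted(t[1])[0])
    assignment: dict[str, int | None] = {l: None for l in tree.labels}
    for k, (_, cl) in enumerate(maximal, start=1):
        for l in cl:
            assignment[l] = k
    return assignment


# -- Mantel test ------------------------------------------------------

def mantel_test(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r of the off-diagonal entries; one-sided p-value from
    permutations of sample labels, p = (1 + #{r_perm >= r_obs})/(n_perm+1).
    """
    if d_gen.labels != d_geo.labels:
        d_geo = d_geo.reorder(d_gen.labels)
    x = d_gen.condensed()
    y = d_geo.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    n = len(d_gen.labels)
    ymat = d_geo.values
    xc = x - x.mean()
    denom = np.sqrt((xc ** 2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(ymat[np.ix_(perm, perm)], checks=False)
        ypc = yp - yp.mean()
        r = float((xc * ypc).sum() / (denom * np.sqrt((ypc ** 2).sum())))
        if r >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


# -- Evanno delta-K ----------------------------------------------------

def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Rate-of-change statistic for choosing the number of clusters K.

    ``runs`` needs columns K, run, lnP (replicate log-likelihoods from a
    Bayesian clustering program). Returns a table per K with mean and sd
    of lnP, the first difference L'(K) = L(K) - L(K-1), the absolute
    second difference |L''(K)| = |L'(K+1) - L'(K)|, and
    ΔK = |L''(K)| / sd(K), defined for interior K only. Zero sd at an
    interior K leaves ΔK undefined (NaN) there.
    """
    required = {"K", "run", "lnP"}
    if not required <= set(runs.columns):
        raise ValueError(f"need columns {sorted(required)}")
    grp = runs.groupby("K")["lnP"]
    out = pd.DataFrame({"mean_lnP": grp.mean(), "sd_lnP": grp.std(ddof=1)})
    out = out.sort_index()
    ks = out.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K values must be consecutive")
    L = out["mean_lnP"].to_numpy()
    lp = np.full(len(ks), np.nan)
    lp[1:] = np.diff(L)  # L'(K)
    lpp = np.full(len(ks), np.nan)
    lpp[1:-1] = np.abs(lp[2:] - lp[1:-1])  # |L''(K)|
    sd = out["sd_lnP"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dk = np.where(sd > 0, lpp / sd, np.nan)
    out["L_prime"] = lp
    out["abs_L_doubleprime"] = lpp
    out["delta_K"] = dk
    if np.any((sd == 0) & np.isfinite(lpp)):
        warnings.warn("zero sd of lnP at an interior K; delta K undefined there")
    return out


def read_structure_loglikelihoods(paths: list[str | Path]) -> pd.DataFrame:
    """Collect 'Estimated Ln Prob of Data' lines from clustering result
    files named so that K and run are recoverable (``*_K<k>_run<r>*``)."""
    rows = []
    pat = re.compile(r"K(\d+)_run(\d+)")
    for p in paths:
        p = Path(p)
        m = pat.search(p.name)
        if not m:
            raise ValueError(f"cannot parse K/run from filename {p.name}")
        for line in p.read_text().splitlines():
            if "Estimated Ln Prob of Data" in line:
                lnp = float(line.split("=")[-1].strip())
                rows.append({"K": int(m.group(1)), "run": int(m.group(2)), "lnP": lnp})
                break
        else:
            raise ValueError(f"no 'Estimated Ln Prob of Data' line in {p}")
    return pd.DataFrame(rows)
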