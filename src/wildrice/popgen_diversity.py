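"""Diversity and differentiation statistics for mixed-ploidy SSR data.

Diploid genotypes are unambiguous, so allele frequencies, observed
heterozygosity and Weir–Cockerham F-statistics are computed directly.
Tetraploid SSR genotypes are observed only as sets of distinct alleles;
when fewer than four alleles are seen the copy numbers are ambiguous
(partial heterozygotes). Following the enumeration convention of
tetraploid SSR software, every full genotype consistent with the observed
set is treated as equally likely, and diversity indices are obtained by
Monte-Carlo resolution: each iteration draws one consistent genotype per
ambiguous call, yields one allele-frequency replicate, and indices are
averaged over replicates.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFrequencies",
    "MCFrequencies",
    "DiversitySummary",
    "enumerate_partial_heterozygote",
    "allele_frequencies",
    "mc_resolve_tetraploid",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "f_statistics",
    "nei_gst",
    "allelic_richness",
    "shannon_index",
    "diversity_summary",
]


# -- containers -------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-locus, per-group allele gene-copy counts.

    ``counts[locus]`` is an array of shape (n_groups, n_alleles) holding
    gene-copy counts; frequencies are rows normalised to 1.
    """

    loci: list[str]
    groups: list[str]
    alleles: dict[str, list[int]]
    counts: dict[str, np.ndarray]

    def frequencies(self, locus: str) -> np.ndarray:
        c = self.counts[locus]
        tot = c.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c / tot, 0.0)

    def gene_copies(self, locus: str) -> np.ndarray:
        return self.counts[locus].sum(axis=-1)

    def pooled(self) -> "AlleleFrequencies":
        """Collapse all groups into one by summing counts."""
        return AlleleFrequencies(
            loci=list(self.loci),
            groups=["pooled"],
            alleles={l: list(a) for l, a in self.alleles.items()},
            counts={l: c.sum(axis=-2, keepdims=True) for l, c in self.counts.items()},
        )


@dataclass
class MCFrequencies(AlleleFrequencies):
    """Monte-Carlo replicate ensemble: ``counts[locus]`` has shape
    (n_iterations, n_groups, n_alleles)."""

    n_iterations: int = 0
    seed: int = 0

    def replicate(self, i: int) -> AlleleFrequencies:
        return AlleleFrequencies(
            loci=list(self.loci),
            groups=list(self.groups),
            alleles={l: list(a) for l, a in self.alleles.items()},
            counts={l: c[i] for l, c in self.counts.items()},
        )


# -- partial heterozygote enumeration ---------------------------------

def enumerate_partial_heterozygote(
    alleles: tuple[int, ...] | frozenset[int], ploidy: int = 4
) -> list[tuple[int, ...]]:
    """All full genotypes (multisets of size ``ploidy``) whose support is
    exactly the observed allele set.

    An observed ABC pattern in a tetraploid may be AABC, ABBC or ABCC; in
    general k observed alleles admit C(ploidy-1, k-1) completions.
    """
    obs = tuple(sorted(set(alleles)))
    if not 1 <= len(obs) <= ploidy:
        raise ValueError(
            f"{len(obs)} observed alleles incompatible with ploidy {ploidy}"
        )
    return [
        g
        for g in itertools.combinations_with_replacement(obs, ploidy)
        if set(g) == set(obs)
    ]


# -- allele frequency extraction --------------------------------------

def _group_of(sample, by: str | dict) -> str:
    if isinstance(by, dict):
        return by[sample.sample_id]
    if by == "site":
        return sample.site_id
    if by == "pooled":
        return "pooled"
    raise ValueError(f"unknown grouping {by!r}")


def allele_frequencies(table: GenotypeTable, by: str | dict = "site") -> AlleleFrequencies:
    """Unambiguous allele gene-copy counts per group.

    Diploids: a homozygote contributes 2 copies of its allele, a
    heterozygote 1 copy of each. Tetraploids with 4 distinct alleles
    contribute 1 copy each; ambiguous (partial-heterozygote) calls get the
    equal-weight convention ploidy/|alleles| copies per observed allele —
    use :func:`mc_resolve_tetraploid` for the Monte-Carlo treatment.
    """
    groups = sorted({_group_of(s, by) for s in table.samples})
    gidx = {g: i for i, g in enumerate(groups)}
    alleles: dict[str, list[int]] = {}
    counts: dict[str, np.ndarray] = {}
    for locus in table.locus_names:
        seen = sorted(
            {a for s in table.samples for a in s.genotypes[locus].alleles}
        )
        aidx = {a: i for i, a in enumerate(seen)}
        c = np.zeros((len(groups), max(len(seen), 1)))
        for s in table.samples:
            g = s.genotypes[locus]
            if g.missing:
                continue
            w = g.declared_ploidy / len(g.alleles)
            for a in g.alleles:
                c[gidx[_group_of(s, by)], aidx[a]] += w
        alleles[locus] = seen
        counts[locus] = c
    return AlleleFrequencies(
        loci=list(table.locus_names), groups=groups, alleles=alleles, counts=counts
    )


def mc_resolve_tetraploid(
    table: GenotypeTable,
    n_iterations: int = 10_000,
    seed: int = 0,
    by: str | dict = "pooled",
) -> MCFrequencies:
    """Monte-Carlo resolution of tetraploid partial heterozygotes.

    Each iteration replaces every ambiguous allele-set call with one full
    genotype drawn uniformly from its consistent completions, producing an
    allele-frequency replicate. Unambiguous calls contribute fixed counts.
    Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    groups = sorted({_group_of(s, by) for s in table.samples})
    gidx = {g: i for i, g in enumerate(groups)}
    alleles: dict[str, list[int]] = {}
    counts: dict[str, np.ndarray] = {}
    for locus in table.locus_names:
        seen = sorted({a for s in table.samples for a in s.genotypes[locus].alleles})
        aidx = {a: i for i, a in enumerate(seen)}
        na = max(len(seen), 1)
        base = np.zeros((len(groups), na))
        ambiguous: list[tuple[int, np.ndarray]] = []
        for s in table.samples:
            g = s.genotypes[locus]
            if g.missing:
                continue
            gi = gidx[_group_of(s, by)]
            if len(g.alleles) in (1, g.declared_ploidy):
                # homozygote or fully resolved genotype
                full = (
                    g.alleles * g.declared_ploidy
                    if len(g.alleles) == 1
                    else g.alleles
                )
                for a in full:
                    base[gi, aidx[a]] += 1
            else:
                opts = enumerate_partial_heterozygote(g.alleles, g.declared_ploidy)
                mat = np.zeros((len(opts), na))
                for k, opt in enumerate(opts):
                    for a in opt:
                        mat[k, aidx[a]] += 1
                ambiguous.append((gi, mat))
        reps = np.broadcast_to(base, (n_iterations, *base.shape)).copy()
        for gi, mat in ambiguous:
            pick = rng.integers(0, mat.shape[0], size=n_iterations)
            reps[:, gi, :] += mat[pick]
        alleles[locus] = seen
        counts[locus] = reps
    return MCFrequencies(
        loci=list(table.locus_names),
        groups=groups,
        alleles=alleles,
        counts=counts,
        n_iterations=n_iterations,
        seed=seed,
    )


# -- diversity indices ------------------------------------------------

def expected_heterozygosity(
    freqs: AlleleFrequencies, unbiased: bool = True, pooled: bool = True
) -> tuple[dict[str, float], float]:
    """Nei gene diversity H_E = 1 - sum(p_i^2) per locus and its mean.

    With ``unbiased`` the small-sample correction n_c/(n_c - 1) is applied,
    n_c being the number of gene copies. Loci with no scored copies are
    dropped from the mean with a warning. For an :class:`MCFrequencies`
    ensemble the statistic is the replicate average.
    """
    f = freqs.pooled() if pooled and len(freqs.groups) > 1 else freqs
    per_locus: dict[str, float] = {}
    for locus in f.loci:
        p = f.frequencies(locus)  # (..., groups, alleles)
        n = f.gene_copies(locus)
        he = 1.0 - (p ** 2).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if unbiased:
                he = np.where(n > 1, he * n / np.maximum(n - 1, 1), he)
        valid = n > 0
        if not valid.any():
            warnings.warn(f"locus {locus}: no scored gene copies; omitted")
            continue
        per_locus[locus] = float(np.mean(he[valid]))
    if not per_locus:
        return {}, float("nan")
    return per_locus, float(np.mean(list(per_locus.values())))


def observed_heterozygosity(table: GenotypeTable) -> tuple[dict[str, float], float]:
    """Fraction of scored diploid individuals with two distinct alleles."""
    per_locus: dict[str, float] = {}
    for locus in table.locus_names:
        scored = het = 0
        for s in table.samples:
            g = s.genotypes[locus]
            if g.declared_ploidy != 2:
                raise ValueError("observed_heterozygosity requires a diploid table")
            if g.missing:
                continue
            scored += 1
            het += len(g.alleles) == 2
        if scored == 0:
            warnings.warn(f"locus {locus}: all genotypes missing; omitted")
            continue
        per_locus[locus] = het / scored
    if not per_locus:
        return {}, float("nan")
    return per_locus, float(np.mean(list(per_locus.values())))


def f_statistics(
    table: GenotypeTable, by: str | dict = "site"
) -> dict[str, float]:
    """Wright's fixation indices for diploid data.

    With two or more populations, Weir–Cockerham (1984) variance-component
    estimators are used, components summed over alleles and loci. With a
    single population F_ST is undefined (NaN) and F_IS = F_IT falls back to
    1 - H_O/H_E with the unbiased H_E.
    """
    groups = sorted({_group_of(s, by) for s in table.samples})
    if len(groups) < 2:
        _, ho = observed_heterozygosity(table)
        freqs = allele_frequencies(table, by=by)
        _, he = expected_heterozygosity(freqs, unbiased=True)
        fis = 1.0 - ho / he if he > 0 else float("nan")
        return {"F_IS": fis, "F_ST": float("nan"), "F_IT": fis}

    gidx = {g: i for i, g in enumerate(groups)}
    r = len(groups)
    sum_a = sum_b = sum_c = 0.0
    for locus in table.locus_names:
        # per-group sample sizes, allele counts and heterozygote counts
        n = np.zeros(r)
        acount: dict[int, np.ndarray] = {}
        hcount: dict[int, np.ndarray] = {}
        for s in table.samples:
            g = s.genotypes[locus]
            if g.declared_ploidy != 2:
                raise ValueError("f_statistics requires a diploid table")
            if g.missing:
                continue
            gi = gidx[_group_of(s, by)]
            n[gi] += 1
            if len(g.alleles) == 1:
                a = g.alleles[0]
                acount.setdefault(a, np.zeros(r))[gi] += 2
            else:
                for a in g.alleles:
                    acount.setdefault(a, np.zeros(r))[gi] += 1
                    hcount.setdefault(a, np.zeros(r))[gi] += 1
        pops = n > 0
        if pops.sum() < 2:
            continue
        n = n[pops]
        ri = len(n)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (ri * nbar - (n ** 2).sum() / (ri * nbar)) / (ri - 1)
        for a, cnt in acount.items():
            p = cnt[pops] / (2 * n)
            h = hcount.get(a, np.zeros(r))[pops] / n
            pbar = (n * p).sum() / (ri * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((ri - 1) * nbar)
            hbar = (n * h).sum() / (ri * nbar)
            inner = pbar * (1 - pbar) - (ri - 1) / ri * s2
            a_comp = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b_comp = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_comp = hbar / 2
            sum_a += a_comp
            sum_b += b_comp
            sum_c += c_comp
    tot = sum_a + sum_b + sum_c
    if tot == 0:
        return {"F_IS": float("nan"), "F_ST": float("nan"), "F_IT": float("nan")}
    return {
        "F_IS": 1.0 - sum_c / (sum_b + sum_c) if (sum_b + sum_c) else float("nan"),
        "F_ST": sum_a / tot,
        "F_IT": 1.0 - sum_c / tot,
    }


def nei_gst(freqs: AlleleFrequencies) -> float:
    """Nei's coefficient of gene differentiation between groups.

    G_ST = (H_T - H_S)/H_T with H_T the gene diversity of the mean group
    frequency vector and H_S the mean within-group gene diversity; the
    multi-locus value is the ratio of sums over loci (stable when some
    loci are monomorphic). For an :class:`MCFrequencies` ensemble, G_ST is
    computed per replicate and averaged.
    """
    if len(freqs.groups) < 2:
        raise ValueError("nei_gst requires at least two groups")
    num = 0.0
    den = 0.0
    is_mc = isinstance(freqs, MCFrequencies)
    shape = None
    num_arr = den_arr = None
    for locus in freqs.loci:
        p = freqs.frequencies(locus)  # (n_groups, n_alleles) or (it, g, a)
        pbar = p.mean(axis=-2)
        ht = 1.0 - (pbar ** 2).sum(axis=-1)
        hs = (1.0 - (p ** 2).sum(axis=-1)).mean(axis=-1)
        if is_mc:
            if num_arr is None:
                num_arr = np.zeros_like(ht)
                den_arr = np.zeros_like(ht)
            num_arr += ht - hs
            den_arr += ht
        else:
            num += float(ht - hs)
            den += float(ht)
    if is_mc:
        if not (den_arr > 0).any():
            raise ValueError("total gene diversity is zero at all loci")
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(den_arr > 0, num_arr / den_arr, np.nan)
        return float(np.nanmean(g))
    if den == 0:
        raise ValueError("total gene diversity is zero at all loci")
    return num / den


def allelic_richness(table: GenotypeTable) -> tuple[int, float]:
    """Total distinct alleles over loci and the mean per-locus count."""
    if not table.samples:
        raise ValueError("empty table")
    per_locus = []
    for locus in table.locus_names:
        seen = {a for s in table.samples for a in s.genotypes[locus].alleles}
        per_locus.append(len(seen))
    return int(sum(per_locus)), float(np.mean(per_locus))


def shannon_index(freqs: AlleleFrequencies) -> float:
    """Mean over loci of the Shannon entropy -sum(p ln p) of allele
    frequencies, computed on the pooled sample."""
    f = freqs.pooled() if len(freqs.groups) > 1 else freqs
    vals = []
    for locus in f.loci:
        n = f.gene_copies(locus)
        if not (np.asarray(n) > 0).all():
            continue
        p = f.frequencies(locus)
        p = p[p > 0]
        vals.append(float(-(p * np.log(p)).sum()))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# -- summary ----------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-locus diversity table plus across-locus means, exportable as CSV
    with one row per locus and a final mean row."""

    per_locus: pd.DataFrame
    means: dict[str, float]
    mc_iterations: int | None = None
    mc_seed: int | None = None

    def to_csv(self, path) -> None:
        df = self.per_locus.copy()
        mean_row = {c: self.means.get(c, np.nan) for c in df.columns}
        df.loc["mean"] = mean_row
        df.to_csv(path, index_label="locus")


def diversity_summary(
    table: GenotypeTable,
    by: str | dict = "site",
    n_iterations: int = 10_000,
    seed: int = 0,
) -> DiversitySummary:
    """Assemble A, H_O, H_E (and F-statistics for diploids) per locus.

    Tetraploid tables use Monte-Carlo resolution for H_E; diploid tables
    get exact values plus Weir–Cockerham F-statistics.
    """
    ploidies = {
        g.declared_ploidy for s in table.samples for g in s.genotypes.values()
    }
    tetraploid = 4 in ploidies
    rows: dict[str, dict[str, float]] = {l: {} for l in table.locus_names}
    for locus in table.locus_names:
        seen = {a for s in table.samples for a in s.genotypes[locus].alleles}
        rows[locus]["A"] = len(seen)
    if tetraploid:
        mc = mc_resolve_tetraploid(table, n_iterations=n_iterations, seed=seed)
        he_locus, he_mean = expected_heterozygosity(mc)
        for l, v in he_locus.items():
            rows[l]["H_E"] = v
        means = {"A": float(np.mean([rows[l]["A"] for l in rows])), "H_E": he_mean}
        df = pd.DataFrame.from_dict(rows, orient="index")
        return DiversitySummary(df, means, mc_iterations=n_iterations, mc_seed=seed)
    freqs = allele_frequencies(table, by="pooled")
    he_locus, he_mean = expected_heterozygosity(freqs)
    ho_locus, ho_mean = observed_heterozygosity(table)
    for l in rows:
        rows[l]["H_O"] = ho_locus.get(l, np.nan)
        rows[l]["H_E"] = he_locus.get(l, np.nan)
    fstats = f_statistics(table, by=by)
    means = {
        "A": float(np.mean([rows[l]["A"] for l in rows])),
        "H_O": ho_mean,
        "H_E": he_mean,
        **fstats,
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return DiversitySummary(df, means)
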