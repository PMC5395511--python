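"""Reading, validating and normalising mixed-ploidy SSR genotype tables.

A genotype table holds one row per individual plant with its species,
collection site, point coordinates (WGS84 decimal degrees) and one allele
call per microsatellite locus. Alleles are fragment sizes in base pairs.
Diploids show one (homozygote) or two distinct alleles per locus;
tetraploids show one to four — a tetraploid locus with fewer distinct
alleles than its ploidy is a *partial heterozygote*: the allele copy
numbers are ambiguous (an observed ABC pattern may be AABC, ABBC or ABCC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "Genotype",
    "SampleRecord",
    "GenotypeTable",
    "DialectConfig",
    "read_genotype_table",
    "write_genotype_table",
    "read_occurrences",
    "to_repeat_units",
    "filter_samples",
]


@dataclass(frozen=True)
class Locus:
    """An SSR marker: name, repeat-unit length (bp) and expected size range."""

    name: str
    repeat_length: int = 1
    allele_size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.repeat_length < 1:
            raise ValueError(f"locus {self.name}: repeat_length must be >= 1")
        if self.allele_size_range is not None:
            lo, hi = self.allele_size_range
            if lo > hi:
                raise ValueError(f"locus {self.name}: allele size range min > max")


@dataclass(frozen=True)
class Genotype:
    """Observed allele set of one individual at one locus.

    ``alleles`` is a sorted tuple of distinct allele sizes; an empty tuple
    means the locus is missing. Copy numbers are not recorded: a tetraploid
    with 1 < |alleles| < 4 is a partial heterozygote.
    """

    alleles: tuple[int, ...]
    declared_ploidy: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(set(self.alleles))))
        if self.declared_ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.declared_ploidy}")
        if len(self.alleles) > self.declared_ploidy:
            raise ValueError(
                f"{len(self.alleles)} distinct alleles exceed declared ploidy "
                f"{self.declared_ploidy}"
            )

    @property
    def missing(self) -> bool:
        return len(self.alleles) == 0

    @property
    def partial_heterozygote(self) -> bool:
        return 1 < len(self.alleles) < self.declared_ploidy


@dataclass
class SampleRecord:
    sample_id: str
    species: str
    site_id: str
    lon: float | None
    lat: float | None
    genotypes: dict[str, Genotype]
    reference_flag: bool = False

    def __post_init__(self) -> None:
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise ValueError(f"sample {self.sample_id}: latitude {self.lat} out of range")
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise ValueError(f"sample {self.sample_id}: longitude {self.lon} out of range")


@dataclass
class GenotypeTable:
    """Ordered loci plus one :class:`SampleRecord` per individual."""

    loci: list[Locus]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        for s in self.samples:
            for l in self.loci:
                s.genotypes.setdefault(l.name, Genotype((), declared_ploidy=2))

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species(self) -> list[str]:
        return sorted({s.species for s in self.samples})

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, keep: list[SampleRecord]) -> "GenotypeTable":
        return GenotypeTable(loci=list(self.loci), samples=list(keep))


@dataclass(frozen=True)
class DialectConfig:
    """Column mapping and token conventions of a genotype CSV."""

    sample_id: str = "sample_id"
    species: str = "species"
    site_id: str = "site_id"
    lon: str = "lon"
    lat: str = "lat"
    ploidy: str = "ploidy"
    reference_flag: str = "reference"
    allele_sep: str = "/"
    missing_token: str = "NA"
    # alleles recorded as fragment sizes in bp ("bp") or repeat units ("repeat")
    allele_units: str = "bp"


def _parse_alleles(token: str, dialect: DialectConfig, row: int, col: str) -> tuple[int, ...]:
    token = str(token).strip()
    if token == "" or token == dialect.missing_token or token.lower() == "nan":
        return ()
    parts = token.split(dialect.allele_sep)
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        raise ValueError(
            f"malformed allele token {token!r} at row {row}, column {col!r}"
        ) from None


def read_genotype_table(
    path: str | Path,
    loci: list[Locus] | None = None,
    dialect: DialectConfig | None = None,
) -> GenotypeTable:
    """Read a genotype CSV.

    Columns not named in the dialect are treated as loci (in file order)
    unless ``loci`` is given explicitly. Tolerates a UTF-8 BOM.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, dtype=str, encoding="utf-8-sig")
    meta_cols = {
        dialect.sample_id, dialect.species, dialect.site_id,
        dialect.lon, dialect.lat, dialect.ploidy, dialect.reference_flag,
    }
    locus_cols = [c for c in df.columns if c not in meta_cols]
    if loci is None:
        loci = [Locus(name=c) for c in locus_cols]
    else:
        missing = [l.name for l in loci if l.name not in df.columns]
        if missing:
            raise ValueError(f"loci absent from file: {missing}")
        locus_cols = [l.name for l in loci]

    samples: list[SampleRecord] = []
    for i, row in df.iterrows():
        ploidy = int(row[dialect.ploidy]) if dialect.ploidy in df.columns else 2
        genotypes = {
            c: Genotype(_parse_alleles(row[c], dialect, i, c), declared_ploidy=ploidy)
            for c in locus_cols
        }
        lon = row.get(dialect.lon)
        lat = row.get(dialect.lat)
        ref = False
        if dialect.reference_flag in df.columns:
            ref = str(row[dialect.reference_flag]).strip().lower() in {"1", "true", "yes"}
        samples.append(
            SampleRecord(
                sample_id=str(row[dialect.sample_id]),
                species=str(row[dialect.species]),
                site_id=str(row.get(dialect.site_id, "")),
                lon=float(lon) if lon not in (None, "") and not pd.isna(lon) else None,
                lat=float(lat) if lat not in (None, "") and not pd.isna(lat) else None,
                genotypes=genotypes,
                reference_flag=ref,
            )
        )
    return GenotypeTable(loci=loci, samples=samples)


def write_genotype_table(
    table: GenotypeTable, path: str | Path, dialect: DialectConfig | None = None
) -> None:
    """Write RFC-4180 CSV in the dialect :func:`read_genotype_table` reads."""
    dialect = dialect or DialectConfig()
    rows = []
    for s in table.samples:
        row: dict[str, object] = {
            dialect.sample_id: s.sample_id,
            dialect.species: s.species,
            dialect.site_id: s.site_id,
            dialect.lon: "" if s.lon is None else s.lon,
            dialect.lat: "" if s.lat is None else s.lat,
            dialect.ploidy: next(iter(s.genotypes.values())).declared_ploidy,
            dialect.reference_flag: int(s.reference_flag),
        }
        for l in table.loci:
            g = s.genotypes[l.name]
            row[l.name] = (
                dialect.missing_token
                if g.missing
                else dialect.allele_sep.join(str(a) for a in g.alleles)
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\r\n")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Occurrence CSV with at least species, lon, lat columns."""
    df = pd.read_csv(path, encoding="utf-8-sig")
    required = {"species", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence file must have columns {sorted(required)}")
    return df


def to_repeat_units(table: GenotypeTable) -> GenotypeTable:
    """Convert allele sizes (bp) to integer repeat units per locus.

    The smallest observed allele at a locus maps to 0; other alleles are
    (size - min) / repeat_length, rounded to the nearest integer with a
    warning when the remainder is nonzero (off-ladder calls).
    """
    new_samples = []
    offsets: dict[str, int] = {}
    for l in table.loci:
        sizes = [
            a for s in table.samples for a in s.genotypes[l.name].alleles
        ]
        offsets[l.name] = min(sizes) if sizes else 0
    warned: set[str] = set()
    for s in table.samples:
        genos = {}
        for l in table.loci:
            g = s.genotypes[l.name]
            units = []
            for a in g.alleles:
                q, r = divmod(a - offsets[l.name], l.repeat_length)
                if r:
                    if l.name not in warned:
                        warnings.warn(
                            f"locus {l.name}: allele sizes not multiples of the "
                            f"repeat length; rounding to nearest unit",
                            stacklevel=2,
                        )
                        warned.add(l.name)
                    q += round(r / l.repeat_length)
                units.append(int(q))
            genos[l.name] = Genotype(tuple(units), declared_ploidy=g.declared_ploidy)
        new_samples.append(replace(s, genotypes=genos))
    new_loci = [replace(l, repeat_length=1, allele_size_range=None) for l in table.loci]
    return GenotypeTable(loci=new_loci, samples=new_samples)


def filter_samples(
    table: GenotypeTable,
    species: str | list[str] | None = None,
    colombian_only: bool = False,
) -> GenotypeTable:
    """Subset by species and/or drop non-local reference accessions."""
    wanted = None
    if species is not None:
        wanted = {species} if isinstance(species, str) else set(species)
        unknown = wanted - set(table.species)
        if unknown:
            raise ValueError(f"species not in table: {sorted(unknown)}")
    keep = [
        s
        for s in table.samples
        if (wanted is None or s.species in wanted)
        and not (colombian_only and s.reference_flag)
    ]
    if not keep:
        raise ValueError("filter produced an empty table")
    logger.info("filter_samples: %d of %d samples retained", len(keep), len(table))
    return table.subset(keep)
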