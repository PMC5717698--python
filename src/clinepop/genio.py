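"""Genotype I/O, locus filtering, and per-population allele frequencies.

The root container is :class:`GenotypeDataset`: individuals x loci biallelic
genotypes coded as counts (0, 1, 2) of a "counted" allele, with population
membership and per-population coordinates/lineage labels.  Data enter either
from Genepop files (with a populations sidecar CSV) or from a plain genotype
CSV; the two round-trip losslessly.

The counted allele at each locus is the numerically smaller allele code seen
in the file (e.g. ``01`` over ``02``).  This is deterministic and dialect
independent; downstream cline detection uses |dp| and is polarity invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

__all__ = [
    "GenotypeDataset",
    "FreqTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_populations_csv",
    "filter_loci",
    "allele_frequencies",
]


class GenepopParseError(ValueError):
    """Malformed Genepop input; message names the offending line."""


@dataclass
class GenotypeDataset:
    """Biallelic genotype matrix with population metadata.

    Parameters
    ----------
    individuals : DataFrame with columns ``individual`` and ``population``.
    loci : ordered locus names (unique).
    genotypes : int array (n_individuals, n_loci) over {0, 1, 2, MISSING},
        counting copies of the counted allele.
    populations : DataFrame indexed by population id with columns
        ``latitude``, ``longitude``, ``lineage``.
    allele_codes : per locus, the (counted, other) raw allele strings; kept
        so Genepop round-trips are identical.  Optional for CSV-born data.
    """

    individuals: pd.DataFrame
    loci: list[str]
    genotypes: np.ndarray
    populations: pd.DataFrame
    allele_codes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        unknown = set(self.individuals["population"]) - set(self.populations.index)
        if unknown:
            raise ValueError(f"individuals reference unknown populations: {sorted(unknown)}")
        if not np.all(np.isfinite(self.populations["latitude"].to_numpy(float))):
            raise ValueError("population latitudes must be finite")

    # -- convenience ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations.index)

    def lineages(self) -> list[str]:
        return list(dict.fromkeys(self.populations["lineage"]))

    def subset_loci(self, loci: list[str]) -> "GenotypeDataset":
        idx = [self.loci.index(l) for l in loci]
        return replace(
            self,
            loci=list(loci),
            genotypes=self.genotypes[:, idx],
            allele_codes={l: self.allele_codes[l] for l in loci if l in self.allele_codes},
        )

    def subset_lineage(self, lineage: str) -> "GenotypeDataset":
        pops = self.populations[self.populations["lineage"] == lineage]
        keep = self.individuals["population"].isin(pops.index).to_numpy()
        return replace(
            self,
            individuals=self.individuals[keep].reset_index(drop=True),
            genotypes=self.genotypes[keep],
            populations=pops,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
            and self.individuals.reset_index(drop=True).equals(other.individuals.reset_index(drop=True))
            and self.populations.sort_index().equals(other.populations.sort_index())
        )


@dataclass
class FreqTable:
    """Counted-allele frequencies p and allele sample sizes m per (population, locus).

    ``p`` is NaN (undefined) wherever ``m`` is zero; ``m`` counts alleles,
    i.e. twice the genotyped individuals, hence always even.
    """

    populations: list[str]
    loci: list[str]
    p: np.ndarray  # (n_pops, n_loci), NaN where undefined
    m: np.ndarray  # (n_pops, n_loci), int
    counts: np.ndarray  # counted-allele counts k = p * m, int

    def for_locus(self, locus: str) -> pd.DataFrame:
        j = self.loci.index(locus)
        return pd.DataFrame(
            {"population": self.populations, "p": self.p[:, j],
             "m": self.m[:, j], "k": self.counts[:, j]}
        ).set_index("population")


# ---------------------------------------------------------------------------
# Genepop dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_populations_csv(path) -> pd.DataFrame:
    """Read the populations sidecar: header ``population,latitude,longitude,lineage``."""
    df = pd.read_csv(path, dtype={"population": str, "lineage": str})
    required = {"population", "latitude", "longitude", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"populations CSV missing columns: {sorted(missing)}")
    return df.set_index("population")


def _default_pop_label(first_individual: str) -> str:
    """Population label = substring before the last underscore (Genepop has no name field)."""
    if "_" in first_individual:
        return first_individual.rsplit("_", 1)[0]
    return first_individual


def read_genepop(path, populations=None) -> GenotypeDataset:
    """Parse a Genepop file into a :class:`GenotypeDataset`.

    Dialect: title line; one locus name per line or comma-separated; ``POP``
    case-insensitive; individual label terminated by a comma; 2-digit allele
    codes (``00`` missing) by default, 3-digit accepted.  Population names
    come from the first individual's label per POP block (text before the
    last underscore) unless ``populations`` — a sidecar DataFrame/CSV path —
    supplies them; the sidecar also supplies latitude/longitude/lineage.

    Raises
    ------
    GenepopParseError
        On malformed lines (names the line number) or when a locus shows
        more than two alleles.
    ValueError
        When an individual's population is absent from the sidecar table.
    """
    if populations is not None and not isinstance(populations, pd.DataFrame):
        populations = read_populations_csv(populations)

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty Genepop file")

    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        if not chunk:
            raise GenepopParseError(f"line {i + 1}: empty locus line")
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP delimiter found")
    if len(set(loci)) != len(loci):
        raise GenepopParseError("duplicate locus names in header")

    pop_blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if _POP_RE.match(line):
            current = []
            pop_blocks.append(current)
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: genotype line before first POP")
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: individual label must end with a comma")
        label, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, found {len(fields)}"
            )
        current.append((label.strip(), fields))

    # First pass: collect allele codes per locus.
    alleles: list[set[str]] = [set() for _ in loci]
    width: int | None = None
    for block in pop_blocks:
        for label, fields in block:
            for j, g in enumerate(fields):
                if len(g) not in (4, 6) or not g.isdigit():
                    raise GenepopParseError(f"bad genotype field {g!r} for {label}")
                w = len(g) // 2
                if width is None:
                    width = w
                elif w != width:
                    raise GenepopParseError("mixed 2- and 3-digit allele codes")
                a1, a2 = g[:w], g[w:]
                zero = "0" * w
                for a in (a1, a2):
                    if a != zero:
                        alleles[j].add(a)
    assert width is not None

    codes: dict[str, tuple[str, str]] = {}
    for j, locus in enumerate(loci):
        obs = sorted(alleles[j], key=int)
        if len(obs) > 2:
            raise GenepopParseError(f"locus {locus}: more than two alleles observed ({obs})")
        if len(obs) == 0:
            obs = ["0" * width]  # all missing; degenerate but representable
        counted = obs[0]
        other = obs[1] if len(obs) == 2 else obs[0]
        codes[locus] = (counted, other)

    zero = "0" * width
    ind_rows = []
    geno_rows = []
    pop_meta_rows = {}
    for block in pop_blocks:
        if not block:
            continue
        pop_name = _default_pop_label(block[0][0])
        for label, fields in block:
            row = np.empty(len(loci), dtype=np.int8)
            for j, g in enumerate(fields):
                a1, a2 = g[:width], g[width:]
                if a1 == zero or a2 == zero:
                    row[j] = MISSING
                else:
                    counted = codes[loci[j]][0]
                    row[j] = (a1 == counted) + (a2 == counted)
            ind_rows.append((label, pop_name))
            geno_rows.append(row)
        pop_meta_rows.setdefault(pop_name, None)

    individuals = pd.DataFrame(ind_rows, columns=["individual", "population"])
    genotypes = np.vstack(geno_rows) if geno_rows else np.empty((0, len(loci)), np.int8)

    if populations is not None:
        unknown = set(individuals["population"]) - set(populations.index)
        if unknown:
            raise ValueError(f"populations absent from sidecar metadata: {sorted(unknown)}")
        pops = populations.loc[list(dict.fromkeys(individuals["population"]))]
    else:
        pops = pd.DataFrame(
            {"latitude": 0.0, "longitude": 0.0, "lineage": "unknown"},
            index=pd.Index(list(pop_meta_rows), name="population"),
        )
    return GenotypeDataset(individuals, loci, genotypes, pops, codes)


def write_genepop(ds: GenotypeDataset, path, title: str = "clinepop export") -> None:
    """Write a dataset in the Genepop dialect read by :func:`read_genepop`."""
    width = max((len(c[0]) for c in ds.allele_codes.values()), default=2)
    zero = "0" * width
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in ds.loci:
            fh.write(locus + "\n")
        for pop in ds.population_ids:
            mask = (ds.individuals["population"] == pop).to_numpy()
            if not mask.any():
                continue
            fh.write("POP\n")
            for i in np.flatnonzero(mask):
                label = ds.individuals["individual"].iloc[i]
                fields = []
                for j, locus in enumerate(ds.loci):
                    counted, other = ds.allele_codes.get(
                        locus, ("1".zfill(width), "2".zfill(width))
                    )
                    g = ds.genotypes[i, j]
                    if g == MISSING:
                        fields.append(zero + zero)
                    elif g == 2:
                        fields.append(counted + counted)
                    elif g == 1:
                        fields.append(counted + other)
                    else:
                        fields.append(other + other)
                fh.write(f"{label}, " + " ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Plain genotype CSV dialect
# ---------------------------------------------------------------------------

def read_genotype_csv(path, populations) -> GenotypeDataset:
    """One row per individual: ``individual,population`` then 0/1/2/NA per locus."""
    if not isinstance(populations, pd.DataFrame):
        populations = read_populations_csv(populations)
    df = pd.read_csv(path, dtype={"individual": str, "population": str})
    loci = [c for c in df.columns if c not in ("individual", "population")]
    geno = df[loci].to_numpy(dtype=float)
    out = np.full(geno.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(geno)
    out[ok] = geno[ok].astype(np.int8)
    return GenotypeDataset(df[["individual", "population"]], loci, out, populations)


def write_genotype_csv(ds: GenotypeDataset, path) -> None:
    geno = ds.genotypes.astype(float)
    geno[geno == MISSING] = np.nan
    df = pd.concat(
        [ds.individuals.reset_index(drop=True), pd.DataFrame(geno, columns=ds.loci)], axis=1
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and frequencies
# ---------------------------------------------------------------------------

def filter_loci(
    ds: GenotypeDataset, maf_min: float = 0.01, max_missing: float = 0.15
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop monomorphic, rare (pooled MAF < ``maf_min``) and patchy loci.

    Rules are applied in order monomorphic -> maf -> missing and each removed
    locus is reported once, under the first rule it violates.  Boundary cases
    are retained (MAF exactly ``maf_min``, missingness exactly ``max_missing``):
    the thresholds exclude strictly-worse loci only.  MAF and missingness are
    pooled over all lineages, mirroring a single filtering pass on the merged
    panel.

    Returns the filtered dataset and a report DataFrame ``locus,rule``.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    g = ds.genotypes
    missing = g == MISSING
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        counted = np.where(missing, 0, g).sum(axis=0)
        p = np.where(n_obs > 0, counted / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1 - p)
    miss_frac = missing.mean(axis=0) if ds.n_individuals else np.ones(ds.n_loci)

    # >= 2 alleles observed: any het, or both homozygote classes present
    poly = np.zeros(ds.n_loci, dtype=bool)
    for j in range(ds.n_loci):
        col = g[~missing[:, j], j]
        poly[j] = len(np.unique(col)) >= 2 if col.size else False

    removed: list[tuple[str, str]] = []
    keep = np.ones(ds.n_loci, dtype=bool)
    for j, locus in enumerate(ds.loci):
        if not poly[j]:
            removed.append((locus, "monomorphic"))
        elif maf[j] < maf_min:
            removed.append((locus, "maf"))
        elif miss_frac[j] > max_missing:
            removed.append((locus, "missing"))
        else:
            continue
        keep[j] = False

    kept = [l for j, l in enumerate(ds.loci) if keep[j]]
    if not kept:
        raise ValueError("no loci remain after filtering (empty panel)")
    report = pd.DataFrame(removed, columns=["locus", "rule"])
    return ds.subset_loci(kept), report


def allele_frequencies(ds: GenotypeDataset) -> FreqTable:
    """Per-(population, locus) counted-allele frequency and allele sample size.

    p = (sum of genotype codes over non-missing individuals) / m with
    m = 2 x genotyped individuals; p is NaN where m = 0 (never coerced to 0).
    """
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("cannot compute frequencies of an empty dataset")
    pops = ds.population_ids
    p = np.full((len(pops), ds.n_loci), np.nan)
    m = np.zeros((len(pops), ds.n_loci), dtype=np.int64)
    k = np.zeros((len(pops), ds.n_loci), dtype=np.int64)
    pop_arr = ds.individuals["population"].to_numpy()
    for i, pop in enumerate(pops):
        sub = ds.genotypes[pop_arr == pop]
        miss = sub == MISSING
        m[i] = 2 * (~miss).sum(axis=0)
        k[i] = np.where(miss, 0, sub).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(m[i] > 0, k[i] / np.maximum(m[i], 1), np.nan)
    return FreqTable(pops, list(ds.loci), p, m, k)
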