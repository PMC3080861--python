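"""Core data containers shared by every analysis in the package.

Genotypes are stored SNP x individual as counts of the reference allele
(0/1/2) with ``9`` marking a missing call, the EIGENSTRAT convention.
Genetic positions are stored internally in Morgans; user-facing interfaces
(CLI flags, reports) speak centimorgans because that is how genetic maps
and the admixture-LD literature quote distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 9

__all__ = [
    "MISSING",
    "SnpTable",
    "IndividualTable",
    "GenotypeMatrix",
    "FreqTable",
    "allele_frequencies",
]


class SnpTable:
    """Per-SNP annotation: identifier, chromosome, physical and genetic position.

    Parameters
    ----------
    snp_id : sequence of str
    chromosome : sequence of int
        Autosome labels. SNPs must be grouped by chromosome and sorted by
        physical position within each chromosome.
    physical_pos : sequence of int
        1-based base-pair positions, strictly increasing within a chromosome.
    genetic_pos : sequence of float
        Cumulative genetic position in Morgans, non-decreasing within a
        chromosome. May be NaN if a genetic map is applied later with
        :func:`admixkit.io.interpolate_genetic_map`.
    """

    def __init__(self, snp_id, chromosome, physical_pos, genetic_pos):
        self.df = pd.DataFrame(
            {
                "snp_id": np.asarray(snp_id, dtype=object),
                "chromosome": np.asarray(chromosome, dtype=np.int64),
                "physical_pos": np.asarray(physical_pos, dtype=np.int64),
                "genetic_pos": np.asarray(genetic_pos, dtype=float),
            }
        )
        self._validate()

    def _validate(self):
        df = self.df
        for chrom, sub in df.groupby("chromosome", sort=False):
            pp = sub["physical_pos"].to_numpy()
            if np.any(np.diff(pp) <= 0):
                raise ValueError(
                    f"physical positions not strictly increasing on chromosome {chrom}"
                )
            gp = sub["genetic_pos"].to_numpy()
            gp = gp[~np.isnan(gp)]
            if gp.size and np.any(np.diff(gp) < 0):
                raise ValueError(
                    f"genetic positions decrease on chromosome {chrom}"
                )

    def __len__(self):
        return len(self.df)

    @property
    def snp_id(self):
        return self.df["snp_id"].to_numpy()

    @property
    def chromosome(self):
        return self.df["chromosome"].to_numpy()

    @property
    def physical_pos(self):
        return self.df["physical_pos"].to_numpy()

    @property
    def genetic_pos(self):
        """Genetic positions in Morgans."""
        return self.df["genetic_pos"].to_numpy()

    @property
    def chromosomes(self):
        """Unique chromosome labels in order of first appearance."""
        return pd.unique(self.df["chromosome"])

    def chromosome_slices(self):
        """Yield ``(chromosome, slice)`` pairs covering the table row ranges."""
        chrom = self.df["chromosome"].to_numpy()
        boundaries = np.flatnonzero(np.diff(chrom)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [len(chrom)]])
        for lo, hi in zip(starts, stops):
            yield int(chrom[lo]), slice(int(lo), int(hi))

    def subset(self, rows) -> "SnpTable":
        sub = self.df.iloc[rows] if not isinstance(rows, slice) else self.df.iloc[rows]
        return SnpTable(
            sub["snp_id"].to_numpy(),
            sub["chromosome"].to_numpy(),
            sub["physical_pos"].to_numpy(),
            sub["genetic_pos"].to_numpy(),
        )

    def __repr__(self):
        return (
            f"SnpTable({len(self)} SNPs, "
            f"{len(self.chromosomes)} chromosomes)"
        )


class IndividualTable:
    """Sample sheet: individual identifier and population label."""

    def __init__(self, individual_id, population):
        self.df = pd.DataFrame(
            {
                "individual_id": np.asarray(individual_id, dtype=object),
                "population": np.asarray(population, dtype=object),
            }
        )
        if self.df["individual_id"].duplicated().any():
            dupes = self.df.loc[self.df["individual_id"].duplicated(), "individual_id"]
            raise ValueError(f"duplicate individual ids: {sorted(set(dupes))}")
        if (self.df["population"].astype(str) == "").any():
            raise ValueError("empty population label")

    def __len__(self):
        return len(self.df)

    @property
    def individual_id(self):
        return self.df["individual_id"].to_numpy()

    @property
    def population(self):
        return self.df["population"].to_numpy()

    @property
    def populations(self):
        return pd.unique(self.df["population"])

    def columns_for(self, population: str) -> np.ndarray:
        """Column indices of the individuals belonging to *population*."""
        cols = np.flatnonzero(self.population == population)
        if cols.size == 0:
            raise ValueError(f"no individuals with population label {population!r}")
        return cols

    def __repr__(self):
        return f"IndividualTable({len(self)} individuals, {len(self.populations)} populations)"


@dataclass
class GenotypeMatrix:
    """SNP x individual reference-allele counts with ``9`` as missing."""

    values: np.ndarray
    snps: SnpTable
    individuals: IndividualTable

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.snps), len(self.individuals)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype value {self.values[tuple(bad)]} at SNP row {bad[0]}, "
                f"individual column {bad[1]} is not in {{0,1,2,{MISSING}}}"
            )

    @property
    def n_snps(self):
        return self.values.shape[0]

    @property
    def n_individuals(self):
        return self.values.shape[1]

    def as_float(self, columns=None) -> np.ndarray:
        """Genotypes as float with missing calls replaced by NaN."""
        vals = self.values if columns is None else self.values[:, columns]
        out = vals.astype(float)
        out[vals == MISSING] = np.nan
        return out

    def population_view(self, population: str) -> np.ndarray:
        return self.as_float(self.individuals.columns_for(population))


@dataclass
class FreqTable:
    """Per-SNP, per-population reference-allele frequencies.

    ``p`` holds frequencies (NaN where no allele was observed) and
    ``n_alleles`` the number of non-missing alleles behind each estimate;
    both are DataFrames indexed by SNP row with one column per population.
    """

    p: pd.DataFrame
    n_alleles: pd.DataFrame

    def __post_init__(self):
        if not self.p.columns.equals(self.n_alleles.columns):
            raise ValueError("p and n_alleles must have identical population columns")
        defined = self.p.to_numpy()
        defined = defined[~np.isnan(defined)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError("allele frequencies outside [0, 1]")

    @classmethod
    def from_arrays(cls, columns: dict) -> "FreqTable":
        """Build from ``{population: (p_array, n_alleles_array)}``."""
        p = pd.DataFrame({k: v[0] for k, v in columns.items()})
        n = pd.DataFrame({k: np.broadcast_to(v[1], len(v[0])) for k, v in columns.items()})
        return cls(p, n)

    @property
    def populations(self):
        return list(self.p.columns)

    def __len__(self):
        return len(self.p)

    def freq(self, population: str) -> np.ndarray:
        return self.p[population].to_numpy()

    def counts(self, population: str) -> np.ndarray:
        return self.n_alleles[population].to_numpy()

    def defined_mask(self, populations=None) -> np.ndarray:
        """True where every requested population has a defined frequency."""
        pops = self.populations if populations is None else list(populations)
        return ~np.isnan(self.p[pops].to_numpy()).any(axis=1)


def allele_frequencies(
    genotypes: GenotypeMatrix, populations=None
) -> FreqTable:
    """Per-population allele frequencies from a genotype matrix.

    For each SNP and population, ``p`` is the mean reference-allele count
    over non-missing genotypes divided by two and ``n_alleles`` is twice the
    number of non-missing genotypes. SNPs with no data in a population get
    ``p = NaN, n_alleles = 0``.
    """
    inds = genotypes.individuals
    if populations is None:
        populations = list(inds.populations)
    p_cols = {}
    n_cols = {}
    for pop in populations:
        cols = inds.columns_for(pop)  # raises if the label is absent
        sub = genotypes.values[:, cols]
        mask = sub != MISSING
        counts = np.where(mask, sub, 0).sum(axis=1)
        n_alleles = 2 * mask.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)
        p_cols[pop] = p
        n_cols[pop] = n_alleles
    return FreqTable(pd.DataFrame(p_cols), pd.DataFrame(n_cols))
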