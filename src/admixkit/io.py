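"""Readers and writers for EIGENSTRAT text triplets, genetic maps and VCF.

The EIGENSTRAT format stores genotypes as one text row per SNP with one
character per individual ('0'/'1'/'2' reference-allele counts, '9'
missing), alongside a ``.snp`` file (snp id, chromosome, genetic position
in Morgans, physical position) and a ``.ind`` file (individual id, sex,
population label).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, IndividualTable, SnpTable

__all__ = [
    "read_eigenstrat",
    "write_eigenstrat",
    "read_genetic_map",
    "interpolate_genetic_map",
    "read_vcf",
]

_GENO_BYTE_MAP = {ord("0"): 0, ord("1"): 1, ord("2"): 2, ord("9"): MISSING}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read an EIGENSTRAT geno/snp/ind triplet into a :class:`GenotypeMatrix`."""
    snp_df = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "chromosome", "genetic_pos", "physical_pos"],
        dtype={"snp_id": str},
    )
    snps = SnpTable(
        snp_df["snp_id"],
        snp_df["chromosome"],
        snp_df["physical_pos"],
        snp_df["genetic_pos"],
    )

    ind_df = pd.read_csv(
        ind_path,
        sep=r"\s+",
        header=None,
        names=["individual_id", "sex", "population"],
        dtype=str,
    )
    individuals = IndividualTable(ind_df["individual_id"], ind_df["population"])

    n_ind = len(individuals)
    rows = []
    with open(geno_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise FormatError(
                    f"geno row {i + 1} has {len(line)} characters, expected "
                    f"{n_ind} individuals"
                )
            row = np.frombuffer(line.encode("ascii"), dtype=np.uint8)
            decoded = np.full(n_ind, 255, dtype=np.uint8)
            for byte, value in _GENO_BYTE_MAP.items():
                decoded[row == byte] = value
            if (decoded == 255).any():
                bad = chr(row[int(np.argmax(decoded == 255))])
                raise FormatError(
                    f"geno row {i + 1} contains invalid character {bad!r}"
                )
            rows.append(decoded)
    if len(rows) != len(snps):
        raise FormatError(
            f"geno file has {len(rows)} SNP rows but snp file lists {len(snps)}"
        )
    values = np.asarray(rows, dtype=np.int8).reshape(len(rows), n_ind)
    return GenotypeMatrix(values, snps, individuals)


def write_eigenstrat(genotypes: GenotypeMatrix, geno_path, snp_path, ind_path):
    """Write a :class:`GenotypeMatrix` as an EIGENSTRAT triplet."""
    chars = np.array(["0", "1", "2"] + [""] * 6 + ["9"], dtype="U1")
    with open(geno_path, "w") as fh:
        for row in genotypes.values:
            fh.write("".join(chars[row]) + "\n")
    snp_df = genotypes.snps.df
    with open(snp_path, "w") as fh:
        for rec in snp_df.itertuples(index=False):
            fh.write(
                f"{rec.snp_id}\t{rec.chromosome}\t{rec.genetic_pos:.8f}"
                f"\t{rec.physical_pos}\n"
            )
    ind_df = genotypes.individuals.df
    with open(ind_path, "w") as fh:
        for rec in ind_df.itertuples(index=False):
            fh.write(f"{rec.individual_id}\tU\t{rec.population}\n")


def read_genetic_map(path) -> pd.DataFrame:
    """Read a whitespace-delimited (chromosome, bp, cM) genetic map file."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "physical_pos", "cm"],
    )
    return df


def interpolate_genetic_map(snps: SnpTable, map_points) -> SnpTable:
    """Fill genetic positions by linear interpolation in physical position.

    *map_points* is a DataFrame with columns chromosome / physical_pos / cm
    (or any iterable of such triples). Positions beyond the map ends are
    clamped to the terminal map value rather than extrapolated, so genetic
    distances stay non-negative and bounded.
    """
    if not isinstance(map_points, pd.DataFrame):
        map_points = pd.DataFrame(
            list(map_points), columns=["chromosome", "physical_pos", "cm"]
        )
    out = snps.df.copy()
    for chrom, sub in out.groupby("chromosome", sort=False):
        pts = map_points[map_points["chromosome"] == chrom]
        if len(pts) == 0:
            raise ValueError(f"chromosome {chrom} missing from the genetic map")
        pts = pts.sort_values("physical_pos")
        # np.interp clamps outside the abscissa range, matching the contract
        cm = np.interp(
            sub["physical_pos"].to_numpy(),
            pts["physical_pos"].to_numpy(),
            pts["cm"].to_numpy(),
        )
        out.loc[sub.index, "genetic_pos"] = cm / 100.0  # cM -> Morgans
    return SnpTable(
        out["snp_id"], out["chromosome"], out["physical_pos"], out["genetic_pos"]
    )


def read_vcf(path, populations=None) -> GenotypeMatrix:
    """Import biallelic SNPs from a VCF via cyvcf2.

    Multi-allelic records are dropped. The reference allele is counted, so a
    0/0 call maps to genotype 2. Population labels default to ``"pop0"``
    for every sample unless a mapping ``{sample_id: population}`` is given;
    genetic positions are left NaN for a later genetic-map pass.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        row = np.empty(len(samples), dtype=np.int8)
        row[gt == 0] = 2
        row[gt == 1] = 1
        row[gt == 3] = 0
        row[gt == 2] = MISSING
        rows.append(row)
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(int(str(var.CHROM).removeprefix("chr")))
        pos.append(var.POS)
    snps = SnpTable(snp_ids, chroms, pos, np.full(len(rows), np.nan))
    if populations is None:
        pops = ["pop0"] * len(samples)
    else:
        pops = [populations.get(s, "pop0") for s in samples]
    individuals = IndividualTable(samples, pops)
    return GenotypeMatrix(np.asarray(rows, dtype=np.int8), snps, individuals)
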