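"""Readers and writers for the plain-text formats the pipeline consumes.

* EIGENSTRAT geno/snp/ind triplets (``.geno``: one line per SNP, one
  character per individual in 0/1/2/9; ``.snp``: id, chrom, genetic position,
  physical position, ref, alt — the geno digit counts the *alt* allele;
  ``.ind``: id, sex, population).
* A TSV pileup dialect: chrom, pos (1-based), ref, then one
  ``base:qual:dist5:dist3:strand`` field per read.
* Component-frequency tables as TSV (components x sites).
* Small TSVs: individual->population maps, radiocarbon dates, per-chromosome
  read counts, and trait genotype tables.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotypes import (MISSING, GenotypeMatrix, Observation, PileupSite,
                        SiteTable)
from .phenotrait import TraitGenotype, TraitGenotypeTable
from .radiocarbon import C14Date
from .simgen import FrequencyTable

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# EIGENSTRAT


def write_eigenstrat(prefix: PathLike, genotypes: GenotypeMatrix,
                     sites: SiteTable,
                     sexes: Optional[Sequence[str]] = None,
                     populations: Optional[Sequence[str]] = None) -> None:
    prefix = Path(prefix)
    if len(sites) != genotypes.n_sites:
        raise ValueError("site table does not match genotype matrix")
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for j in range(genotypes.n_sites):
            col = genotypes.counts[:, j]
            fh.write("".join("9" if g == MISSING else str(g) for g in col))
            fh.write("\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for i in range(len(sites)):
            s = sites.row(i)
            fh.write(f"{s.site_id}\t{s.chrom}\t0.0\t{s.pos}\t{s.ref}\t{s.alt}\n")
    sexes = sexes or ["U"] * genotypes.n_individuals
    populations = populations or ["Unknown"] * genotypes.n_individuals
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for iid, sex, pop in zip(genotypes.individual_ids, sexes, populations):
            fh.write(f"{iid}\t{sex}\t{pop}\n")


def read_snp(path: PathLike) -> SiteTable:
    """Read a 6-column EIGENSTRAT .snp file into a :class:`SiteTable`."""
    snp = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["site_id", "chrom", "gen_pos", "pos", "ref", "alt"],
                      dtype={"site_id": str, "chrom": str})
    return SiteTable(list(snp.site_id), list(snp.chrom),
                     snp.pos.to_numpy(), list(snp.ref), list(snp.alt))


def read_eigenstrat(prefix: PathLike,
                    ploidy_mode: str = "diploid"
                    ) -> tuple[GenotypeMatrix, SiteTable, pd.DataFrame]:
    """Returns (genotypes, sites, ind table with columns id/sex/population)."""
    prefix = Path(prefix)
    sites = read_snp(prefix.with_suffix(".snp"))
    ind = pd.read_csv(prefix.with_suffix(".ind"), sep=r"\s+", header=None,
                      names=["id", "sex", "population"], dtype=str)
    with open(prefix.with_suffix(".geno")) as fh:
        rows = [line.strip() for line in fh if line.strip()]
    if len(rows) != len(sites):
        raise ValueError(".geno line count does not match .snp")
    mat = np.full((len(ind), len(sites)), MISSING, dtype=np.int8)
    for j, line in enumerate(rows):
        for i, ch in enumerate(line):
            if ch != "9":
                mat[i, j] = int(ch)
    return (GenotypeMatrix(mat, list(ind.id), list(sites.site_id), ploidy_mode),
            sites, ind)


# ---------------------------------------------------------------------------
# pileup TSV dialect


def write_pileups(path: PathLike, pileups: Sequence[PileupSite]) -> None:
    with open(path, "w") as fh:
        for p in pileups:
            fields = [p.site.chrom, str(p.site.pos), p.site.ref]
            fields += [f"{o.base}:{o.quality}:{o.dist5}:{o.dist3}:{o.strand}"
                       for o in p.observations]
            fh.write("\t".join(fields) + "\n")


def read_pileups(path: PathLike, sites: SiteTable) -> list[PileupSite]:
    """Reads the pileup dialect, matching rows to ``sites`` by chrom+pos."""
    lookup = {(sites.chrom[i], int(sites.pos[i])): i
              for i in range(len(sites))}
    out: list[PileupSite] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            chrom, pos = parts[0], int(parts[1])
            key = (chrom, pos)
            if key not in lookup:
                raise ValueError(f"pileup row {chrom}:{pos} not in panel")
            site = sites.row(lookup[key])
            obs = []
            for f in parts[3:]:
                if not f:
                    continue
                base, qual, d5, d3, strand = f.split(":")
                obs.append(Observation(base, int(qual), int(d5), int(d3),
                                       strand))
            out.append(PileupSite(site, obs))
    return out


# ---------------------------------------------------------------------------
# frequency tables, population maps


def write_frequency_table(path: PathLike, table: FrequencyTable) -> None:
    df = pd.DataFrame(table.frequencies, index=table.component_labels,
                      columns=table.site_ids)
    df.to_csv(path, sep="\t", index_label="component")


def read_frequency_table(path: PathLike) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FrequencyTable(df.to_numpy(dtype=float), list(df.index.astype(str)),
                          list(df.columns.astype(str)))


def read_pop_map(path: PathLike) -> dict[str, str]:
    """TSV of individual<TAB>population."""
    out = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


# ---------------------------------------------------------------------------
# small TSVs


def read_c14_dates(path: PathLike) -> list[C14Date]:
    """TSV with columns lab_code, mean, sigma (header optional)."""
    dates = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            try:
                mean, sigma = float(row[1]), float(row[2])
            except ValueError:
                continue  # header line
            dates.append(C14Date(mean, sigma, row[0]))
    return dates


def read_read_counts(path: PathLike) -> dict[str, int]:
    """TSV of chrom<TAB>n_reads (e.g. from `samtools idxstats`)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            try:
                out[row[0]] = int(row[1])
            except ValueError:
                continue
    return out


def read_trait_table(path: PathLike
                     ) -> tuple[TraitGenotypeTable, TraitGenotypeTable]:
    """TSV: rsid, genotype, depth, imputed_genotype, imputed_prob.

    '.' marks a missing field.  Returns (observed, imputed) tables ready for
    :func:`paleoproject.phenotrait.resolve_genotypes`.
    """
    observed = TraitGenotypeTable()
    imputed = TraitGenotypeTable()
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "rsid":
                continue
            rsid, gt, depth, igt, iprob = (row + ["."] * 5)[:5]
            if gt != ".":
                observed.entries[rsid] = TraitGenotype(
                    rsid, gt, depth=None if depth == "." else int(depth))
            if igt != ".":
                imputed.entries[rsid] = TraitGenotype(
                    rsid, igt, provenance="imputed",
                    imputation_probability=float(iprob))
    return observed, imputed
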