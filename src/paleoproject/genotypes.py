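"""Genotype calling and site/sample filtering for low-coverage ancient genomes.

Low-coverage ancient samples are genotyped *pseudo-haploid*: at each SNP one
sequenced base is drawn at random (with probability equal to its frequency in
the local pileup) and duplicated into a homozygous diploid call.  This avoids
ever asserting heterozygosity from a handful of damaged reads.  The module
also implements the standard aDNA hygiene filters: base quality >= 30, no
calls within 2 bp of read ends, triallelic-site removal, transversions-only
panels, and a minimum number of called SNPs per sample.

Coordinates are 1-based inclusive throughout (pileup convention).  The
missing-genotype sentinel is :data:`MISSING` (-1); EIGENSTRAT I/O translates
it to the character ``9``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")
#: The two transition allele pairs; everything else biallelic is a transversion.
_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


class Site(NamedTuple):
    """A single biallelic SNP: id, chromosome, 1-based position, ref/alt."""

    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


class Observation(NamedTuple):
    """One read base at a site.

    dist5/dist3 are the base's distances (in bp, 0-based) from the read's own
    5' and 3' ends; strand is '+' or '-'.
    """

    base: str
    quality: int
    dist5: int
    dist3: int
    strand: str


@dataclass
class PileupSite:
    """All read observations overlapping one SNP."""

    site: Site
    observations: list[Observation] = field(default_factory=list)

    def surviving(self, min_quality: int = 30, end_exclusion: int = 2,
                  restrict_to_alleles: bool = False) -> list[Observation]:
        """Observations passing the quality and read-end filters.

        With ``restrict_to_alleles`` also drops bases matching neither ref
        nor alt.
        """
        obs = [o for o in self.observations
               if o.quality >= min_quality
               and o.dist5 >= end_exclusion and o.dist3 >= end_exclusion]
        if restrict_to_alleles:
            alleles = {self.site.ref, self.site.alt}
            obs = [o for o in obs if o.base in alleles]
        return obs


@dataclass
class SiteTable:
    """Per-SNP metadata for a genotyping panel.

    Positions must be sorted within each chromosome; ref != alt and both in
    {A, C, G, T}.
    """

    site_id: list[str]
    chrom: list[str]
    pos: np.ndarray
    ref: list[str]
    alt: list[str]

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.site_id)
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise ValueError("SiteTable columns have mismatched lengths")
        for r, a in zip(self.ref, self.alt):
            if r not in _VALID_BASES or a not in _VALID_BASES:
                raise ValueError(f"alleles must be in A/C/G/T, got {r}/{a}")
            if r == a:
                raise ValueError(f"ref and alt must differ, got {r}/{a}")
        for c in set(self.chrom):
            p = self.pos[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    def __len__(self) -> int:
        return len(self.site_id)

    def row(self, i: int) -> Site:
        return Site(self.site_id[i], self.chrom[i], int(self.pos[i]),
                    self.ref[i], self.alt[i])

    def rows(self) -> Iterable[Site]:
        return (self.row(i) for i in range(len(self)))

    def is_transversion(self) -> np.ndarray:
        """Boolean mask: True where the ref/alt pair is not a transition."""
        return np.array([frozenset((r, a)) not in _TRANSITION_PAIRS
                         for r, a in zip(self.ref, self.alt)])

    def subset(self, mask: np.ndarray) -> "SiteTable":
        idx = np.flatnonzero(np.asarray(mask))
        return SiteTable(
            site_id=[self.site_id[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
        )


@dataclass
class GenotypeMatrix:
    """Individuals x sites matrix of allele-1 (alt) counts.

    Entries are 0/1/2 or :data:`MISSING`; pseudo-haploid matrices contain no
    1s by construction.
    """

    counts: np.ndarray
    individual_ids: list[str]
    site_ids: list[str]
    ploidy_mode: str = "diploid"  # "diploid" | "pseudo_haploid"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n, j = self.counts.shape
        if n != len(self.individual_ids) or j != len(self.site_ids):
            raise ValueError("counts shape does not match id lists")
        valid = {0, 1, 2, MISSING}
        if not set(np.unique(self.counts)).issubset(valid):
            raise ValueError("genotype entries must be 0/1/2/missing")
        if self.ploidy_mode == "pseudo_haploid" and np.any(self.counts == 1):
            raise ValueError("pseudo-haploid matrix contains heterozygous calls")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def n_called(self) -> np.ndarray:
        """Number of non-missing calls per individual."""
        return (self.counts != MISSING).sum(axis=1)


class DiploidCall(NamedTuple):
    """A diploid genotype call with an optional reason when missing."""

    genotype: int  # 0 / 1 / 2 / MISSING
    reason: Optional[str]  # None | "low_depth" | "inconclusive" | "no_data"


def call_pseudohaploid(site: PileupSite, rng: Union[np.random.Generator, int],
                       min_quality: int = 30, end_exclusion: int = 2) -> int:
    """Pseudo-haploid call: one surviving base sampled by its pileup frequency.

    Observations below ``min_quality`` or within ``end_exclusion`` bp of either
    read end are dropped, as are bases matching neither ref nor alt.  If no
    observation survives the call is :data:`MISSING`; otherwise a single base
    is chosen with probability equal to its frequency among survivors and
    duplicated into a homozygous genotype (alt -> 2, ref -> 0).

    Exactly one uniform draw is consumed from ``rng`` per called (non-missing)
    site, so batch calls are reproducible independent of pileup internals.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    obs = site.surviving(min_quality, end_exclusion, restrict_to_alleles=True)
    if not obs:
        return MISSING
    n_alt = sum(1 for o in obs if o.base == site.site.alt)
    return 2 if rng.random() < n_alt / len(obs) else 0


def call_pseudohaploid_panel(pileups: Sequence[PileupSite], seed: int,
                             min_quality: int = 30,
                             end_exclusion: int = 2) -> np.ndarray:
    """Pseudo-haploid calls over a panel, consuming RNG draws in site order."""
    rng = np.random.default_rng(seed)
    return np.array([call_pseudohaploid(p, rng, min_quality, end_exclusion)
                     for p in pileups], dtype=np.int8)


def call_diploid_site(site: PileupSite, min_depth: int = 3,
                      min_quality: int = 30) -> DiploidCall:
    """Diploid call for trait SNPs: quality >= 30 and depth >= 3.

    After quality filtering (and dropping bases matching neither allele), a
    site with surviving depth below ``min_depth`` is missing.  All-ref reads
    give 0, all-alt give 2; a heterozygote is called only when each allele is
    seen at least twice.  Anything else (e.g. 3 ref + 1 alt) is returned as
    missing with reason ``"inconclusive"``.
    """
    obs = site.surviving(min_quality, end_exclusion=0, restrict_to_alleles=True)
    if len(obs) < min_depth:
        return DiploidCall(MISSING, "low_depth" if obs or site.observations else "no_data")
    n_alt = sum(1 for o in obs if o.base == site.site.alt)
    n_ref = len(obs) - n_alt
    if n_alt == 0:
        return DiploidCall(0, None)
    if n_ref == 0:
        return DiploidCall(2, None)
    if n_ref >= 2 and n_alt >= 2:
        return DiploidCall(1, None)
    return DiploidCall(MISSING, "inconclusive")


def filter_transversions(sites: SiteTable) -> SiteTable:
    """Keep only transversion SNPs (drops the A/G and C/T pairs).

    Deamination damage manifests as C->T / G->A, i.e. transitions, so
    transversion-only panels are immune to it.
    """
    return sites.subset(sites.is_transversion())


def drop_triallelic(sites: SiteTable, pileups: Sequence[PileupSite],
                    min_quality: int = 30, end_exclusion: int = 2) -> SiteTable:
    """Remove sites whose surviving observations show three or more bases.

    ``pileups`` must be aligned with ``sites`` row-for-row.  Survivors are
    defined by the same quality/read-end filters as calling but *without*
    restricting to ref/alt (a third base is exactly the evidence sought).
    """
    if len(pileups) != len(sites):
        raise ValueError("pileups must align with the site table")
    keep = np.ones(len(sites), dtype=bool)
    for i, p in enumerate(pileups):
        bases = {o.base for o in p.surviving(min_quality, end_exclusion)}
        if len(bases) >= 3:
            keep[i] = False
    return sites.subset(keep)


def apply_sample_inclusion(g: GenotypeMatrix,
                           min_snps: int = 15000) -> GenotypeMatrix:
    """Drop individuals with fewer than ``min_snps`` non-missing calls.

    Raises :class:`InsufficientDataError` if nobody survives.  Dropped ids are
    logged at INFO level.
    """
    called = g.n_called()
    keep = called >= min_snps
    if not keep.any():
        raise InsufficientDataError(
            f"no individual reaches {min_snps} called SNPs")
    dropped = [iid for iid, k in zip(g.individual_ids, keep) if not k]
    if dropped:
        logger.info("sample inclusion (>=%d SNPs) dropped: %s",
                    min_snps, ", ".join(dropped))
    return GenotypeMatrix(
        counts=g.counts[keep],
        individual_ids=[iid for iid, k in zip(g.individual_ids, keep) if k],
        site_ids=list(g.site_ids),
        ploidy_mode=g.ploidy_mode,
    )


def mt_variant_filter(depth: int,
                      support_distances: Iterable[tuple[int, int]],
                      min_depth: int = 3, end_exclusion: int = 4) -> bool:
    """Accept/reject a mitochondrial variant call.

    Rejects variants with ``depth < min_depth`` or supported only by calls
    within ``end_exclusion`` bases of either read end (likely deamination).
    Returns True to accept.
    """
    if depth < min_depth:
        return False
    return any(d5 >= end_exclusion and d3 >= end_exclusion
               for d5, d3 in support_distances)
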