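"""Synthetic data with known truth for the whole pipeline.

The generators invert the statistical models the analysis modules assume:

* allele frequencies of K ancestral components follow a Balding-Nichols
  model around a shared ancestral frequency;
* genotypes of an admixed individual are Binomial(2, q'F) (diploid) or a
  doubled Bernoulli draw (pseudo-haploid);
* sequencing reads carry terminal cytosine-deamination damage (C->T from the
  5' end, G->A from the 3' end) decaying geometrically with distance from the
  read end, plus uniform sequencing error;
* mitochondrial pileups mix an endogenous and a contaminant haplotype at a
  known read-level fraction, retaining true-source labels for testing;
* X/Y read counts are binomial at a chosen Y-read fraction (Ry).

Everything is bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParameterError
from .fstats import PopFrequencySeries, assign_blocks
from .genotypes import (MISSING, GenotypeMatrix, Observation, PileupSite,
                        Site, SiteTable)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FrequencyTable:
    """K ancestral components x J sites of allele-1 (alt) frequencies."""

    frequencies: np.ndarray
    component_labels: list[str]
    site_ids: list[str]

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2:
            raise ParameterError("frequencies must be a K x J matrix")
        k, j = self.frequencies.shape
        if k < 1 or j < 1:
            raise ParameterError("need K >= 1 and J >= 1")
        if k != len(self.component_labels) or j != len(self.site_ids):
            raise ParameterError("labels do not match matrix shape")
        if len(set(self.component_labels)) != k:
            raise ParameterError("component labels must be unique")
        if not np.all(np.isfinite(self.frequencies)):
            raise ParameterError("frequencies must be finite")
        if self.frequencies.min() < 0 or self.frequencies.max() > 1:
            raise ParameterError("frequencies must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_sites(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class AdmixtureVector:
    """Ancestry proportions on the K-simplex (sum to 1 within 1e-9)."""

    proportions: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 1:
            raise ParameterError("proportions must be a vector")
        if self.proportions.min() < 0 or self.proportions.max() > 1:
            raise ParameterError("proportions must lie in [0, 1]")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ParameterError("proportions must sum to 1 within 1e-9")


@dataclass
class DamageParams:
    """Terminal deamination model: rate delta*decay^d at distance d from
    the relevant read end (C->T from 5', G->A from 3')."""

    delta5: float = 0.0
    delta3: float = 0.0
    decay: float = 0.5

    def __post_init__(self):
        for name in ("delta5", "delta3"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if not np.isfinite(self.decay) or not 0 < self.decay <= 1:
            raise ParameterError("decay must be in (0, 1]")


@dataclass
class SimulatedRead:
    """A simulated sequencing read with its provenance retained.

    Bases are stored in reference orientation; dist-from-end bookkeeping uses
    the read's own 5'/3' ends according to ``strand``.
    """

    bases: str
    base_qualities: np.ndarray
    strand: str  # '+' | '-'
    true_source: str  # 'endogenous' | 'contaminant'
    aligned_start: int  # 1-based reference coordinate

    def __post_init__(self):
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.int16)
        if len(self.bases) != len(self.base_qualities):
            raise ParameterError("bases and qualities differ in length")
        if self.base_qualities.size and (
                self.base_qualities.min() < 0 or self.base_qualities.max() > 60):
            raise ParameterError("base qualities must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    def dist5(self, i: int) -> int:
        """Distance of base ``i`` (0-based in stored order) from the 5' end."""
        return i if self.strand == "+" else len(self) - 1 - i

    def dist3(self, i: int) -> int:
        return len(self) - 1 - self.dist5(i)


class MtObservation:
    """One read base in a mitochondrial pileup column."""

    __slots__ = ("base", "quality", "dist5", "dist3", "strand", "source")

    def __init__(self, base, quality, dist5, dist3, strand, source):
        self.base = base
        self.quality = quality
        self.dist5 = dist5
        self.dist3 = dist3
        self.strand = strand
        self.source = source


@dataclass
class MtPileup:
    """Reads over a mitochondrial reference, with per-read source labels."""

    reference_length: int
    reads: list[SimulatedRead] = field(default_factory=list)
    _columns: Optional[dict] = field(default=None, repr=False, compare=False)

    def columns(self) -> dict[int, list[MtObservation]]:
        """Pileup columns keyed by 1-based reference position."""
        if self._columns is None:
            cols: dict[int, list[MtObservation]] = {}
            for r in self.reads:
                for i, b in enumerate(r.bases):
                    pos = r.aligned_start + i
                    cols.setdefault(pos, []).append(MtObservation(
                        b, int(r.base_qualities[i]), r.dist5(i), r.dist3(i),
                        r.strand, r.true_source))
            self._columns = cols
        return self._columns

    def column(self, pos: int) -> list[MtObservation]:
        return self.columns().get(pos, [])

    def consensus(self) -> str:
        """Majority base per position ('N' where uncovered)."""
        cols = self.columns()
        out = []
        for pos in range(1, self.reference_length + 1):
            obs = cols.get(pos)
            if not obs:
                out.append("N")
                continue
            bases, counts = np.unique([o.base for o in obs], return_counts=True)
            out.append(str(bases[np.argmax(counts)]))
        return "".join(out)


# ---------------------------------------------------------------------------
# generators


def gen_frequencies(K: int, J: int, divergence: float, seed: int,
                    labels: Optional[Sequence[str]] = None) -> FrequencyTable:
    """Balding-Nichols component frequencies.

    Per site an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn; each
    component then draws f ~ Beta(p(1-c)/c, (1-p)(1-c)/c) with c the
    ``divergence`` (so E[f] = p and Var[f] = c p (1-p)).  divergence=0
    returns identical rows (no drift).
    """
    if K < 1 or J < 1:
        raise ParameterError("need K >= 1 and J >= 1")
    if not np.isfinite(divergence) or not 0 <= divergence < 1:
        raise ParameterError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=J)
    if divergence == 0:
        f = np.tile(p, (K, 1))
    else:
        scale = (1 - divergence) / divergence
        f = rng.beta(p * scale, (1 - p) * scale, size=(K, J))
    if labels is None:
        labels = [f"K{k}" for k in range(1, K + 1)]
    return FrequencyTable(f, list(labels), [f"snp{j}" for j in range(1, J + 1)])


def balding_nichols(p: np.ndarray, divergence: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step away from frequencies ``p``."""
    if divergence == 0:
        return np.array(p, dtype=float, copy=True)
    scale = (1 - divergence) / divergence
    p = np.clip(np.asarray(p, dtype=float), 1e-9, 1 - 1e-9)
    return rng.beta(p * scale, (1 - p) * scale)


def gen_genotypes(Q: Union[Sequence[AdmixtureVector], np.ndarray],
                  F: FrequencyTable, mode: str, seed: int,
                  individual_ids: Optional[Sequence[str]] = None
                  ) -> GenotypeMatrix:
    """Genotypes of admixed individuals: g ~ Binomial(2, q'F) per site.

    ``mode='pseudo_haploid'`` instead doubles a single Bernoulli(q'F) draw,
    so entries are restricted to {0, 2}.
    """
    if mode not in ("diploid", "pseudo_haploid"):
        raise ParameterError(f"unknown ploidy mode {mode!r}")
    qmat = np.vstack([q.proportions if isinstance(q, AdmixtureVector) else q
                      for q in Q]).astype(float)
    if qmat.shape[1] != F.n_components:
        raise ParameterError("Q length does not match number of components")
    rng = np.random.default_rng(seed)
    p = qmat @ F.frequencies  # N x J
    if mode == "diploid":
        counts = rng.binomial(2, p).astype(np.int8)
    else:
        counts = (2 * rng.binomial(1, p)).astype(np.int8)
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(1, qmat.shape[0] + 1)]
    return GenotypeMatrix(counts, list(individual_ids), list(F.site_ids), mode)


def _apply_damage_and_error(base: str, dist5: int, dist3: int,
                            damage: DamageParams, error_rate: float,
                            rng: np.random.Generator) -> str:
    # deamination happens on the molecule, before the sequencer sees it
    if base == "C" and damage.delta5 > 0:
        if rng.random() < damage.delta5 * damage.decay ** dist5:
            base = "T"
    elif base == "G" and damage.delta3 > 0:
        if rng.random() < damage.delta3 * damage.decay ** dist3:
            base = "A"
    if error_rate > 0 and rng.random() < error_rate:
        base = str(rng.choice(_BASES[_BASES != base]))
    return base


def gen_pileup(genotypes: GenotypeMatrix, site_table: SiteTable,
               mean_depth: float, error_rate: float = 0.0,
               damage: Optional[DamageParams] = None, seed: int = 0,
               mean_read_length: float = 80.0, sd_read_length: float = 15.0,
               quality_range: tuple[int, int] = (30, 41),
               ) -> dict[str, list[PileupSite]]:
    """Per-site read pileups for each individual in ``genotypes``.

    Depth is Poisson(``mean_depth``) per site.  Each observation samples one
    of the individual's two chromosomes, places the site uniformly within a
    read of Gaussian length, applies terminal deamination (C->T with prob
    delta5*decay^dist5, G->A with delta3*decay^dist3) and then uniform
    sequencing error.  Returns ``{individual_id: [PileupSite, ...]}`` in site
    order.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if not 0 <= error_rate < 1:
        raise ParameterError("error_rate must be in [0, 1)")
    if damage is None:
        damage = DamageParams(0.0, 0.0, 1.0)
    if len(site_table) != genotypes.n_sites:
        raise ParameterError("site table does not match genotype matrix")
    rng = np.random.default_rng(seed)
    out: dict[str, list[PileupSite]] = {}
    qlo, qhi = quality_range
    for n, iid in enumerate(genotypes.individual_ids):
        pileups = []
        for j in range(genotypes.n_sites):
            site = site_table.row(j)
            g = int(genotypes.counts[n, j])
            obs: list[Observation] = []
            if g != MISSING:
                depth = rng.poisson(mean_depth)
                for _ in range(depth):
                    carries_alt = rng.random() < g / 2.0
                    base = site.alt if carries_alt else site.ref
                    length = max(35, int(round(rng.normal(mean_read_length,
                                                          sd_read_length))))
                    i = int(rng.integers(0, length))
                    strand = "+" if rng.random() < 0.5 else "-"
                    d5 = i if strand == "+" else length - 1 - i
                    d3 = length - 1 - d5
                    base = _apply_damage_and_error(base, d5, d3, damage,
                                                   error_rate, rng)
                    q = int(rng.integers(qlo, qhi))
                    obs.append(Observation(base, q, d5, d3, strand))
            pileups.append(PileupSite(site, obs))
        out[iid] = pileups
    return out


def gen_sex_read_counts(sex: str, n_total: int, ry_xy: float = 0.098,
                        ry_xx: float = 0.0046, seed: int = 0
                        ) -> tuple[int, int]:
    """X/Y read counts at the empirical Y-read fraction of the chosen sex.

    Defaults are the observed shotgun values Ry = 0.098 (XY) and Ry = 0.0046
    (XX).  Returns (nX, nY) with nY ~ Binomial(n_total, ry).
    """
    if sex not in ("XX", "XY"):
        raise ParameterError("sex must be 'XX' or 'XY'")
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    for v in (ry_xy, ry_xx):
        if not 0 <= v < 1:
            raise ParameterError("Ry levels must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ry = ry_xy if sex == "XY" else ry_xx
    n_y = int(rng.binomial(n_total, ry))
    return n_total - n_y, n_y


def gen_mt_pileup(consensus: str, contaminant: str, c: float, depth: int,
                  damage: Optional[DamageParams] = None, seed: int = 0,
                  error_rate: float = 0.0, mean_read_length: float = 60.0,
                  sd_read_length: float = 10.0,
                  quality_range: tuple[int, int] = (30, 41)) -> MtPileup:
    """Mitochondrial pileup mixing endogenous and contaminant haplotypes.

    Each read is drawn from the contaminant haplotype with probability ``c``
    (read-level contamination), else from the endogenous consensus; terminal
    deamination and sequencing error are applied as in :func:`gen_pileup`.
    ``depth`` is the target mean per-position coverage.
    """
    if len(consensus) != len(contaminant):
        raise ParameterError("haplotypes must have equal length")
    if not 0 <= c <= 1:
        raise ParameterError("contamination fraction must be in [0, 1]")
    if depth <= 0:
        raise ParameterError("depth must be positive")
    if damage is None:
        damage = DamageParams(0.0, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    L = len(consensus)
    n_reads = max(1, int(round(depth * L / mean_read_length)))
    qlo, qhi = quality_range
    reads: list[SimulatedRead] = []
    for _ in range(n_reads):
        source = "contaminant" if rng.random() < c else "endogenous"
        template = contaminant if source == "contaminant" else consensus
        rl = max(20, int(round(rng.normal(mean_read_length, sd_read_length))))
        rl = min(rl, L)
        start = int(rng.integers(1, L - rl + 2))  # 1-based
        strand = "+" if rng.random() < 0.5 else "-"
        bases = []
        for i in range(rl):
            d5 = i if strand == "+" else rl - 1 - i
            d3 = rl - 1 - d5
            bases.append(_apply_damage_and_error(template[start - 1 + i],
                                                 d5, d3, damage, error_rate,
                                                 rng))
        quals = rng.integers(qlo, qhi, size=rl)
        reads.append(SimulatedRead("".join(bases), quals, strand, source, start))
    return MtPileup(L, reads)


# ---------------------------------------------------------------------------
# frequency-series scenarios for the f-statistics


def gen_null_frequency_series(J: int, seed: int, n_pops: int = 4,
                              n_chromosomes: int = 20,
                              block_size: int = 700) -> "PopFrequencySeries":
    """Four (or ``n_pops``) populations drawn iid around one frequency series.

    Every population is an independent binomial sample (``n_chromosomes``
    draws) around the same per-site frequency, so all D/f4 statistics are
    zero in expectation: the null for Z-score calibration checks.
    Populations are named ``pop1..popN``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=J)
    cols = {f"pop{i + 1}": rng.binomial(n_chromosomes, p) / n_chromosomes
            for i in range(n_pops)}
    return PopFrequencySeries(pd.DataFrame(cols),
                              assign_blocks(J, block_size))


def gen_f4ratio_frequency_series(J: int, alpha: float, seed: int,
                                 drift: float = 0.05,
                                 chimp_drift: float = 0.2,
                                 test_drift: float = 0.01,
                                 block_size: int = 700
                                 ) -> "PopFrequencySeries":
    """Archaic-admixture scenario with known mixing proportion ``alpha``.

    Tree: an ancestral frequency drifts independently into a chimp outgroup
    and a human stem; the stem splits into an archaic ('altai') branch and a
    modern branch whose shared drift segment ('africans' and 'dinka' both
    descend from it) gives the f4-ratio its denominator.  The 'test'
    population is the frequency mixture (1-alpha)*dinka + alpha*altai with a
    small private drift ``test_drift`` of its own, so
    f4(africans, chimp; test, altai) / f4(africans, chimp; dinka, altai)
    has expectation 1 - alpha and the ratio estimator should recover alpha.
    """
    import pandas as pd

    if not 0 <= alpha <= 1:
        raise ParameterError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=J)
    chimp = balding_nichols(p, chimp_drift, rng)
    stem = balding_nichols(p, drift, rng)
    altai = balding_nichols(stem, drift, rng)
    modern = balding_nichols(stem, drift, rng)  # shared drift: the denominator
    africans = balding_nichols(modern, drift, rng)
    dinka = balding_nichols(modern, drift, rng)
    test = balding_nichols((1 - alpha) * dinka + alpha * altai,
                           test_drift, rng)
    cols = {"africans": africans, "chimp": chimp, "test": test,
            "altai": altai, "dinka": dinka}
    return PopFrequencySeries(pd.DataFrame(cols),
                              assign_blocks(J, block_size))
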