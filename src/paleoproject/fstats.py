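"""f3 / D / f4 statistics with weighted block-jackknife standard errors.

All statistics are computed from per-site population allele-1 frequencies
(complete-case per statistic: a site enters only if every population involved
has a defined frequency there).  Standard errors come from a delete-one-block
jackknife over contiguous genomic blocks (default 700 SNPs per block), with
block weights proportional to the number of sites per block, which is robust
to linkage disequilibrium.  Point estimates are always the full-data
ratio-of-sums, independent of the blocking.

Sign conventions: D(A,B;X,Y) > 0 indicates excess allele sharing between B
and Y (equivalently A and X).  f4(A,B;C,D) is the mean of
(a_j - b_j)(c_j - d_j).  Outgroup f3(target; A, B) is the mean of
(t_j - a_j)(t_j - b_j) with no heterozygosity correction, as appropriate for
pseudo-haploid data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .genotypes import MISSING, GenotypeMatrix

#: |Z| at or above this is flagged significant (the usual 3-sigma rule).
Z_SIGNIFICANT = 3.0


@dataclass
class FStatResult:
    """Point estimate with block-jackknife uncertainty and bookkeeping."""

    statistic: str
    populations: tuple[str, ...]
    estimate: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_loci: int

    @property
    def significant(self) -> bool:
        """True when |Z| >= 3 (treeness/cladality rejected)."""
        return bool(np.isfinite(self.z) and abs(self.z) >= Z_SIGNIFICANT)


@dataclass
class PopFrequencySeries:
    """Per-site allele-1 frequencies for named populations, plus block ids.

    ``frequencies`` is a sites x populations DataFrame with NaN for missing;
    ``blocks`` labels each site with a non-decreasing block index.
    """

    frequencies: pd.DataFrame
    blocks: np.ndarray

    def __post_init__(self):
        self.blocks = np.asarray(self.blocks)
        if len(self.blocks) != len(self.frequencies):
            raise ValueError("block index length does not match sites")
        vals = self.frequencies.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.columns)

    def get(self, *pops: str) -> np.ndarray:
        missing = [p for p in pops if p not in self.frequencies.columns]
        if missing:
            raise KeyError(f"unknown population(s): {missing}")
        return self.frequencies[list(pops)].to_numpy(dtype=float).T

    @classmethod
    def from_genotypes(cls, g: GenotypeMatrix, pop_map: dict[str, str],
                       block_size: int = 700,
                       chroms: Optional[Sequence[str]] = None
                       ) -> "PopFrequencySeries":
        """Per-population sample frequencies from a genotype matrix.

        ``pop_map`` maps individual id -> population name.  Frequencies are
        means of g/2 over individuals with non-missing calls; a site with no
        calls in a population is NaN there.  Blocks are contiguous runs of
        ``block_size`` SNPs (restarting at chromosome boundaries when
        ``chroms`` is given).
        """
        pops: dict[str, list[int]] = {}
        for i, iid in enumerate(g.individual_ids):
            if iid in pop_map:
                pops.setdefault(pop_map[iid], []).append(i)
        if not pops:
            raise InsufficientDataError("population map matches no individual")
        cols = {}
        counts = g.counts
        for pop, idx in pops.items():
            sub = counts[idx].astype(float)
            sub[sub == MISSING] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cols[pop] = np.nanmean(sub, axis=0) / 2.0
        df = pd.DataFrame(cols, index=list(g.site_ids))
        return cls(df, assign_blocks(g.n_sites, block_size, chroms))


def assign_blocks(n_sites: int, block_size: int = 700,
                  chroms: Optional[Sequence[str]] = None) -> np.ndarray:
    """Contiguous-run block labels: ``block_size`` SNPs per block.

    With ``chroms`` given, blocks never span a chromosome boundary.
    """
    if block_size < 1:
        raise ValueError("block_size must be positive")
    if chroms is None:
        return np.arange(n_sites) // block_size
    blocks = np.empty(n_sites, dtype=np.int64)
    label = -1
    prev_chrom = None
    in_block = block_size  # force a new block at the start
    for i, c in enumerate(chroms):
        if c != prev_chrom or in_block >= block_size:
            label += 1
            in_block = 0
            prev_chrom = c
        blocks[i] = label
        in_block += 1
    return blocks


def block_jackknife(numerators: np.ndarray, denominators: np.ndarray,
                    block_index: np.ndarray) -> tuple[float, float, float]:
    """Weighted delete-one-block jackknife for a ratio-of-sums estimator.

    Returns (estimate, se, z).  The estimate is the full-data ratio; the
    variance uses the delete-m jackknife with block weights proportional to
    sites per block (Busing et al. 1999), which reduces to the textbook
    delete-one formula for equal-sized blocks.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    blocks = np.asarray(block_index)
    if not (len(num) == len(den) == len(blocks)):
        raise ValueError("numerators/denominators/blocks length mismatch")
    uniq, inv = np.unique(blocks, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise InsufficientDataError("block jackknife needs >= 2 blocks")
    s_num, s_den = num.sum(), den.sum()
    if s_den == 0:
        raise UndefinedStatisticError("denominator sum is zero")
    est = s_num / s_den
    bn = np.bincount(inv, weights=num, minlength=G)
    bd = np.bincount(inv, weights=den, minlength=G)
    m = np.bincount(inv, minlength=G).astype(float)
    loo_den = s_den - bd
    if np.any(loo_den == 0):
        raise UndefinedStatisticError(
            "denominator vanishes when a block is deleted")
    theta_loo = (s_num - bn) / loo_den
    n = m.sum()
    h = n / m
    tau = h * est - (h - 1.0) * theta_loo
    est_j = G * est - np.sum((1.0 - m / n) * theta_loo)
    var = np.sum((tau - est_j) ** 2 / (h - 1.0)) / G
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = est / se
    else:
        z = 0.0 if est == 0 else np.nan
    return float(est), se, float(z)


def _jackknife_or_nan(name: str, num: np.ndarray, den: np.ndarray,
                      blocks: np.ndarray) -> tuple[float, float, float, int]:
    """Jackknife wrapper that degrades to se=nan on tiny/degenerate input."""
    s_den = den.sum()
    if s_den == 0:
        raise UndefinedStatisticError(f"{name}: denominator sum is zero")
    try:
        est, se, z = block_jackknife(num, den, blocks)
        n_blocks = len(np.unique(blocks))
    except (InsufficientDataError, UndefinedStatisticError) as exc:
        warnings.warn(f"{name}: jackknife unavailable ({exc}); "
                      "reporting point estimate with se=nan", stacklevel=3)
        est, se, z = float(num.sum() / s_den), float("nan"), float("nan")
        n_blocks = len(np.unique(blocks))
    return est, se, z, n_blocks


def _complete(series: PopFrequencySeries, *pops: str
              ) -> tuple[np.ndarray, np.ndarray]:
    freqs = series.get(*pops)
    mask = np.all(np.isfinite(freqs), axis=0)
    return freqs[:, mask], series.blocks[mask]


def compute_f3(target: str, a: str, b: str,
               series: PopFrequencySeries) -> FStatResult:
    """Outgroup f3(target; a, b): mean of (t - a)(t - b) over complete sites.

    With the target an outgroup, larger values mean more drift shared by
    ``a`` and ``b`` since their divergence from it.  No heterozygosity
    correction is applied (outgroup mode, pseudo-haploid-safe).
    """
    (t, fa, fb), blocks = _complete(series, target, a, b)
    if t.size == 0:
        raise InsufficientDataError("no complete site for f3")
    num = (t - fa) * (t - fb)
    den = np.ones_like(num)
    est, se, z, n_blocks = _jackknife_or_nan("f3", num, den, blocks)
    return FStatResult("f3", (target, a, b), est, se, z, n_blocks, t.size)


def compute_D(a: str, b: str, x: str, y: str,
              series: PopFrequencySeries) -> FStatResult:
    """Patterson's D(A,B;X,Y) (normalized ABBA-BABA).

    D = sum (a-b)(x-y) / sum (a+b-2ab)(x+y-2xy) over complete sites;
    positive D = excess affinity between B and Y (equivalently A and X).
    """
    (fa, fb, fx, fy), blocks = _complete(series, a, b, x, y)
    if fa.size == 0:
        raise InsufficientDataError("no complete site for D")
    num = (fa - fb) * (fx - fy)
    den = (fa + fb - 2 * fa * fb) * (fx + fy - 2 * fx * fy)
    est, se, z, n_blocks = _jackknife_or_nan("D", num, den, blocks)
    return FStatResult("D", (a, b, x, y), est, se, z, n_blocks, fa.size)


def compute_f4(a: str, b: str, c: str, d: str,
               series: PopFrequencySeries) -> FStatResult:
    """f4(A,B;C,D): mean of (a - b)(c - d) over complete sites."""
    (fa, fb, fc, fd), blocks = _complete(series, a, b, c, d)
    if fa.size == 0:
        raise InsufficientDataError("no complete site for f4")
    num = (fa - fb) * (fc - fd)
    den = np.ones_like(num)
    est, se, z, n_blocks = _jackknife_or_nan("f4", num, den, blocks)
    return FStatResult("f4", (a, b, c, d), est, se, z, n_blocks, fa.size)


def f4_ratio_neanderthal(africans: str, chimp: str, test: str, altai: str,
                         dinka: str, series: PopFrequencySeries
                         ) -> FStatResult:
    """Archaic-ancestry proportion via the f4 ratio.

    Q = 1 - f4(africans, chimp; test, altai) / f4(africans, chimp; dinka,
    altai).  The jackknife is run on the ratio itself (per-site numerator and
    denominator products over blocks); Q's SE equals the ratio's SE since the
    map is affine.
    """
    (fa, fc, ft, fn, fd), blocks = _complete(
        series, africans, chimp, test, altai, dinka)
    if fa.size == 0:
        raise InsufficientDataError("no complete site for f4 ratio")
    num = (fa - fc) * (ft - fn)
    den = (fa - fc) * (fd - fn)
    if den.sum() == 0:
        raise UndefinedStatisticError("f4-ratio denominator is zero")
    est_r, se, z_r, n_blocks = _jackknife_or_nan("f4_ratio", num, den, blocks)
    q = 1.0 - est_r
    z = q / se if se and np.isfinite(se) and se > 0 else (
        0.0 if q == 0 else float("nan"))
    return FStatResult("f4_ratio_Q", (africans, chimp, test, altai, dinka),
                       q, se, z, n_blocks, fa.size)
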