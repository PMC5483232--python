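"""Ancient-DNA authentication statistics.

Four independent lines of evidence that a sequencing library is ancient and
endogenous:

* **Molecular sex (Ry)** — the fraction of sex-chromosome reads aligning to
  Y, Ry = nY / (nX + nY).  Shotgun data from XX individuals show Ry near
  0.005 (Y reads are mismapped X/autosome reads), XY individuals near 0.1
  (the Y being smaller and repeat-rich).  Assignment uses the binomial 95% CI
  against the standard thresholds (XX when the CI is entirely below 0.016,
  XY when entirely above 0.075).
* **Mitochondrial contamination** — the fraction of non-consensus read calls
  at haplogroup-defining (polymorphic) positions: %(C+MD) counts every
  mismatch (contamination + molecular damage); %C excludes the deamination
  classes (consensus C read as T, consensus G read as A) from numerator and
  denominator.
* **Deamination profile** — C->T rates by distance from the 5' read end and
  G->A by distance from the 3' end; genuine aDNA shows elevated terminal
  rates (tens of percent) declining into the read.
* **Read length** — authentic ancient fragments are short (means of roughly
  60-110 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .simgen import MtPileup, SimulatedRead

#: Upper Ry CI bound below which a library is called XX.
XX_CI_MAX = 0.016
#: Lower Ry CI bound above which a library is called XY.
XY_CI_MIN = 0.075


@dataclass
class RyResult:
    ry: float
    se: float
    ci_low: float
    ci_high: float
    n_total: int
    assignment: str  # 'XX' | 'XY' | 'ambiguous'


@dataclass
class ContaminationEstimate:
    pct_c_plus_md: float  # % non-consensus calls (contamination + damage)
    pct_c: float          # % non-consensus excluding C->T / G->A classes
    n_reads_checked: int
    n_positions: int
    n_positions_skipped: int = 0


@dataclass
class DamageProfile:
    ct_rate_by_dist5: np.ndarray  # NaN where a cell had no opportunity
    ga_rate_by_dist3: np.ndarray
    n_opportunities_5: np.ndarray
    n_opportunities_3: np.ndarray


@dataclass
class ReadLengthStats:
    mean: float
    median: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray  # 5-bp bins


def compute_ry(n_x: int, n_y: int, xx_ci_max: float = XX_CI_MAX,
               xy_ci_min: float = XY_CI_MIN) -> RyResult:
    """Sex assignment from X/Y read counts via Ry = nY/(nX+nY).

    The 95% CI is ry +/- 1.96 * sqrt(ry(1-ry)/n), truncated to [0, 1];
    assignment is XX if the CI lies below ``xx_ci_max``, XY if above
    ``xy_ci_min``, otherwise ambiguous.
    """
    n = n_x + n_y
    if n <= 0:
        raise InsufficientDataError("no sex-chromosome reads")
    ry = n_y / n
    se = float(np.sqrt(ry * (1.0 - ry) / n))
    lo = max(0.0, ry - 1.96 * se)
    hi = min(1.0, ry + 1.96 * se)
    if hi < xx_ci_max:
        assignment = "XX"
    elif lo > xy_ci_min:
        assignment = "XY"
    else:
        assignment = "ambiguous"
    return RyResult(ry, se, lo, hi, n, assignment)


def mt_contamination(pileup: MtPileup, positions: Sequence[int],
                     min_quality: int = 30) -> ContaminationEstimate:
    """Non-consensus call fractions at haplogroup-defining positions.

    The consensus at each listed position is the majority base among
    quality-passing calls; a position with an exact tie is skipped (majority
    undefined) and counted in ``n_positions_skipped`` with a warning.
    %(C+MD) aggregates mismatching calls over all positions; %C removes the
    potentially deaminated classes (consensus C read as T, consensus G read
    as A) from both numerator and denominator.
    """
    if not positions:
        raise ParameterError("empty position list")
    total = 0
    mismatch = 0
    total_c = 0
    mismatch_c = 0
    skipped = 0
    used = 0
    for pos in positions:
        obs = [o for o in pileup.column(pos) if o.quality >= min_quality]
        if not obs:
            raise InsufficientDataError(f"position {pos} has no coverage")
        bases, counts = np.unique([o.base for o in obs], return_counts=True)
        top = counts.max()
        if (counts == top).sum() > 1:
            skipped += 1
            continue
        consensus = str(bases[np.argmax(counts)])
        used += 1
        for o in obs:
            total += 1
            is_mismatch = o.base != consensus
            if is_mismatch:
                mismatch += 1
            damage_class = ((consensus == "C" and o.base == "T")
                            or (consensus == "G" and o.base == "A"))
            if not damage_class:
                total_c += 1
                if is_mismatch:
                    mismatch_c += 1
    if skipped:
        warnings.warn(f"{skipped} position(s) skipped: consensus tie")
    if used == 0:
        raise InsufficientDataError("no position with a defined consensus")
    pct_all = 100.0 * mismatch / total
    pct_c = 100.0 * mismatch_c / total_c if total_c else 0.0
    return ContaminationEstimate(pct_all, pct_c, total, used, skipped)


def damage_profile(reads: Union[Iterable[SimulatedRead], MtPileup],
                   reference: str, window: int = 25) -> DamageProfile:
    """Terminal misincorporation rates against a known reference.

    For d = 0..window-1, the C->T rate at 5'-distance d is (#calls of T at a
    reference-C position whose distance from the read's 5' end is d) over
    (#calls overlapping a reference C at that distance); G->A symmetrically
    from the 3' end.  Cells with zero opportunities are NaN, not 0.
    """
    if isinstance(reads, MtPileup):
        reads = reads.reads
    ct_num = np.zeros(window)
    ct_den = np.zeros(window)
    ga_num = np.zeros(window)
    ga_den = np.zeros(window)
    n_reads = 0
    for r in reads:
        n_reads += 1
        start = r.aligned_start
        for i, b in enumerate(r.bases):
            refbase = reference[start - 1 + i]
            if refbase == "C":
                d5 = r.dist5(i)
                if d5 < window:
                    ct_den[d5] += 1
                    if b == "T":
                        ct_num[d5] += 1
            elif refbase == "G":
                d3 = r.dist3(i)
                if d3 < window:
                    ga_den[d3] += 1
                    if b == "A":
                        ga_num[d3] += 1
    if n_reads == 0:
        raise InsufficientDataError("no reads")
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan)
        ga = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan)
    return DamageProfile(ct, ga, ct_den.astype(int), ga_den.astype(int))


def read_length_stats(reads: Union[Iterable[SimulatedRead], MtPileup],
                      lengths: Optional[Sequence[int]] = None
                      ) -> ReadLengthStats:
    """Mean/median read length and a 5-bp-binned histogram.

    Accepts reads, an :class:`MtPileup`, or raw ``lengths``.
    """
    if lengths is None:
        if isinstance(reads, MtPileup):
            reads = reads.reads
        lengths = [len(r) for r in reads]
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no reads")
    lo = 5 * int(np.floor(arr.min() / 5))
    hi = 5 * int(np.ceil((arr.max() + 1) / 5))
    edges = np.arange(lo, hi + 1, 5)
    counts, _ = np.histogram(arr, bins=edges)
    return ReadLengthStats(float(arr.mean()), float(np.median(arr)),
                           counts, edges)
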