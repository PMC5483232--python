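"""Ancestry projection: likelihood-based admixture proportions for one
individual against fixed ancestral allele frequencies.

Given a genotype vector g_j in {0, 1, 2} and a fixed K x J matrix of
ancestral allele frequencies f_kj (e.g. from a supervised or unsupervised
clustering fit), the admixture vector q is estimated by maximizing

    L(q) = sum_j { g_j ln(sum_k q_k f_kj) + (2 - g_j) ln(sum_k q_k (1 - f_kj)) }

over the simplex, i.e. the binomial likelihood of the genotypes at the
individual's mixed allele frequency p_j = sum_k q_k f_kj.  The simplex
constraint is handled by optimizing the first K-1 components box-bounded in
[1e-5, 1 - 1e-5] with q_K = 1 - sum (a quadratic penalty keeps q_K inside the
same box), using bounded L-BFGS-B with an analytic gradient and a handful of
restarts.  L(q) is concave in q, so restarts only guard against boundary
stalls.

Uncertainty comes from a nonparametric bootstrap over SNPs: sites are
resampled with replacement (missing sites resampled like any other, then
dropped), the projection is re-run per replicate with f fixed, and percentile
confidence intervals are read off the replicate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, InsufficientDataError, ParameterError
from .genotypes import MISSING
from .simgen import AdmixtureVector, FrequencyTable

#: Box bounds on each admixture proportion during optimization.
DEFAULT_BOUNDS = (1e-5, 1.0 - 1e-5)
#: Frequencies are clamped away from {0,1} by this before taking logs.
F_CLAMP = 1e-6


@dataclass
class ProjectionProblem:
    """One individual's genotypes against fixed component frequencies."""

    g: np.ndarray  # length J, values in {0,1,2} or MISSING
    F: FrequencyTable
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    tolerance: float = 1e-8

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.int64)
        if self.g.ndim != 1 or self.g.size != self.F.n_sites:
            raise ParameterError("genotype vector does not match F's sites")
        valid = {0, 1, 2, MISSING}
        if not set(np.unique(self.g)).issubset(valid):
            raise ParameterError("genotypes must be 0/1/2/missing")
        lo, hi = self.bounds
        if not (0 < lo < hi < 1):
            raise ParameterError("bounds must satisfy 0 < lo < hi < 1")

    @property
    def K(self) -> int:
        return self.F.n_components

    def observed_mask(self) -> np.ndarray:
        return self.g != MISSING


@dataclass
class BootstrapResult:
    """Point estimate plus the bootstrap replicate distribution."""

    point: AdmixtureVector
    replicates: np.ndarray  # B x K
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    seed: int
    n_sites_used: int

    @property
    def replicate_sd(self) -> np.ndarray:
        """Per-component standard deviation over replicates."""
        return self.replicates.std(axis=0, ddof=1)


def _prepare(problem: ProjectionProblem):
    mask = problem.observed_mask()
    if not mask.any():
        raise InsufficientDataError("all genotypes missing")
    g = problem.g[mask].astype(float)
    f = np.clip(problem.F.frequencies[:, mask], F_CLAMP, 1.0 - F_CLAMP)
    return g, f


def loglik(q, problem: ProjectionProblem,
           weights: Optional[np.ndarray] = None) -> float:
    """The projection log-likelihood L(q) over non-missing sites.

    ``weights`` (length J, aligned with ``problem.g``) allow bootstrap
    resampling to be expressed as per-site multiplicities.
    """
    qv = q.proportions if isinstance(q, AdmixtureVector) else np.asarray(q, float)
    mask = problem.observed_mask()
    if not mask.any():
        raise InsufficientDataError("all genotypes missing")
    g = problem.g[mask].astype(float)
    f = np.clip(problem.F.frequencies[:, mask], F_CLAMP, 1.0 - F_CLAMP)
    w = None if weights is None else np.asarray(weights, float)[mask]
    p = qv @ f
    terms = g * np.log(p) + (2.0 - g) * np.log1p(-p)
    return float(terms.sum() if w is None else (w * terms).sum())


def _neg_loglik_grad(theta, g, f, lo, hi, w):
    """Negative weighted log-likelihood and gradient in the K-1 free
    components; quadratic penalty keeps the implied q_K inside [lo, hi]."""
    q_last = 1.0 - theta.sum()
    q = np.append(theta, q_last)
    p = np.clip(q @ f, 1e-12, 1.0 - 1e-12)
    gw = g if w is None else w * g
    tw = (2.0 - g) if w is None else w * (2.0 - g)
    ll = gw @ np.log(p) + tw @ np.log1p(-p)
    # L = sum gw ln(q.f) + tw ln(q.(1-f));  d/dq_k ln(q.(1-f)) = (1-f_k)/(1-p)
    grad_q = f @ (gw / p) + (1.0 - f) @ (tw / (1.0 - p))
    grad = -(grad_q[:-1] - grad_q[-1])
    nll = -ll
    penalty = 1e7
    if q_last < lo:
        nll += penalty * (lo - q_last) ** 2
        grad += 2.0 * penalty * (lo - q_last)
    elif q_last > hi:
        nll += penalty * (q_last - hi) ** 2
        grad -= 2.0 * penalty * (q_last - hi)
    return nll, grad


def project_individual(problem: ProjectionProblem,
                       weights: Optional[np.ndarray] = None,
                       n_starts: int = 5, seed: int = 0) -> AdmixtureVector:
    """Maximum-likelihood admixture vector for one individual.

    Runs bounded L-BFGS-B from ``n_starts`` starting points (the simplex
    barycenter plus seeded Dirichlet(1) draws) and returns the best; the
    result sums to 1 exactly and respects the box bounds.  Deterministic for
    fixed ``seed``.
    """
    g, f = _prepare(problem)
    K = problem.K
    lo, hi = problem.bounds
    w = None
    if weights is not None:
        w = np.asarray(weights, float)[problem.observed_mask()]
        used = w > 0
        if not used.any():
            raise InsufficientDataError("bootstrap replicate has no sites")
    if (g if w is None else w[w > 0]).size < K:
        raise InsufficientDataError("need at least K non-missing sites")
    if K == 1:
        return AdmixtureVector(np.array([1.0]))

    rng = np.random.default_rng(seed)
    starts = [np.full(K, 1.0 / K)]
    starts += [rng.dirichlet(np.ones(K)) for _ in range(n_starts - 1)]

    best = None
    best_nll = np.inf
    any_success = False
    for s in starts:
        theta0 = np.clip(s[:-1], lo, hi)
        res = minimize(_neg_loglik_grad, theta0, args=(g, f, lo, hi, w),
                       method="L-BFGS-B", jac=True,
                       bounds=[(lo, hi)] * (K - 1),
                       options={"ftol": problem.tolerance, "maxiter": 500})
        if res.fun < best_nll:
            best_nll = res.fun
            best = res.x
        any_success = any_success or res.success
    if not any_success:
        raise ConvergenceError("L-BFGS-B failed from every start",
                               best=np.append(best, 1.0 - best.sum()))
    theta = np.clip(best, lo, hi)
    q = np.append(theta, 1.0 - theta.sum())
    q[-1] = min(max(q[-1], lo), hi)
    q = q / q.sum()  # renormalize the (at most 1e-5-sized) boundary clip
    return AdmixtureVector(q)


def bootstrap_projection(problem: ProjectionProblem, B: int = 1000,
                         level: float = 0.95, seed: int = 0,
                         n_starts: int = 5) -> BootstrapResult:
    """SNP bootstrap of the projection: resample sites with replacement
    ``B`` times, re-run the projection per replicate with F fixed, and take
    percentile confidence intervals at ``level``.

    A replicate whose optimization fails is logged and redrawn; after
    ``10 * B`` total attempts a :class:`ConvergenceError` is raised.
    """
    if B < 2:
        raise ParameterError("need B >= 2 bootstrap replicates")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    J = problem.g.size
    point = project_individual(problem, seed=seed, n_starts=n_starts)
    reps = np.empty((B, problem.K))
    done = 0
    attempts = 0
    while done < B:
        if attempts >= 10 * B:
            raise ConvergenceError(
                f"bootstrap exceeded {10 * B} attempts ({done}/{B} done)")
        attempts += 1
        idx = rng.integers(0, J, size=J)
        w = np.bincount(idx, minlength=J).astype(float)
        try:
            reps[done] = project_individual(problem, weights=w, seed=seed,
                                            n_starts=n_starts).proportions
        except (ConvergenceError, InsufficientDataError):
            continue
        done += 1
    alpha = (1.0 - level) / 2.0
    ci_low = np.quantile(reps, alpha, axis=0)
    ci_high = np.quantile(reps, 1.0 - alpha, axis=0)
    return BootstrapResult(point=point, replicates=reps, ci_low=ci_low,
                           ci_high=ci_high, level=level, seed=seed,
                           n_sites_used=int(problem.observed_mask().sum()))
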