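# Methods

This note documents the statistical models behind `paleoproject`, the
defaults and why, what the synthetic-data generators do and do not emulate,
and the numerical choices that were genuinely open.

## Genotype calling and filters (`genotypes`)

Low-coverage ancient samples are represented pseudo-haploid: among reads
passing base quality ≥ 30 (`min_quality`) and lying ≥ 2 bp from either read
end (`end_exclusion`, where deamination concentrates), one base matching ref
or alt is drawn with probability equal to its frequency in the pileup and
duplicated into a homozygous genotype. Exactly one RNG draw is consumed per
called site, in site order, so batch calls are reproducible regardless of
pileup internals and invariant to observation order. Ties need no special
rule: the frequency-weighted draw already gives equal-frequency alleles
equal probability.

Diploid calls for trait SNPs require quality ≥ 30 and surviving depth ≥ 3;
a heterozygote additionally requires each allele seen at least twice — a
deliberately strict standard borrowed from run-of-homozygosity practice,
because depth-3 pileups with a singleton second allele cannot distinguish a
heterozygote from damage or error. Such sites return missing with reason
`inconclusive` rather than a guess; this includes the genuinely undecidable
2-vs-1 and 1-vs-1 configurations at minimum depth.

Panel hygiene: triallelic sites (≥ 3 distinct surviving bases) are dropped;
transversions-only panels remove the A/G and C/T classes (of the six
unordered allele pairs, the two transition classes go, four transversion
classes stay); samples need ≥ 15,000 called SNPs. All filters are
idempotent. Mitochondrial variants additionally require depth ≥ 3 and at
least one supporting call ≥ 4 bp from both read ends.

Coordinates are 1-based throughout; the missing sentinel is −1 in memory
and `9` in EIGENSTRAT files; allele-1 (the counted allele) is always the alt
allele of the site table.

## f-statistics (`fstats`)

All statistics are complete-case per statistic: a site contributes only when
every involved population has a defined frequency there, which is why
different tests over the same panel report different locus counts.
Pseudo-haploid individuals contribute frequencies of 0 or 1; no small-sample
heterozygosity correction is applied anywhere (outgroup-f3 and D as used on
ancient panels).

Standard errors use a weighted delete-one-block jackknife over contiguous
blocks of 700 SNPs (configurable; blocks restart at chromosome boundaries),
with block weights proportional to sites per block — the delete-m formula
that reduces to the textbook delete-one jackknife for equal blocks. The
block size absorbs linkage disequilibrium; 700 SNPs of a genome-wide panel
is of the order of a few cM. Point estimates are always the full-data
ratio-of-sums, independent of blocking. |Z| ≥ 3 is flagged significant; no
multiple-testing correction.

Degenerate inputs: a bare `block_jackknife` call with < 2 blocks raises;
the statistic wrappers instead return the point estimate with `se = nan`
and a warning, so tiny hand-checkable tables (e.g. the two-site D = 1
example, where one delete-one denominator vanishes) are still computable.

The f4-ratio estimator Q = 1 − f4(Afr, Chimp; test, Archaic)/f4(Afr, Chimp;
Ref, Archaic) jackknifes the ratio itself; Q's SE equals the ratio's because
the map is affine.

## Ancestry projection (`ancestry`)

The likelihood treats each non-missing genotype as Binomial(2, p_j) with
p_j = Σ_k q_k f_kj and the frequency matrix F fixed and known. The simplex
constraint is enforced by optimizing the first K−1 components, box-bounded
in [1e-5, 1−1e-5], with q_K = 1 − Σ and a quadratic penalty if q_K leaves
the same box — a bounded quasi-Newton formulation rather than a softmax
reparameterization, keeping the box bounds exact. F is clamped to
[1e-6, 1−1e-6] before logs so fixed alleles cannot produce −∞. L(q) is
concave in q; five starts (barycenter + 4 seeded Dirichlet(1) draws) guard
against boundary stalls. Convergence tolerance is 1e-8 on the relative
log-likelihood change — far below bootstrap noise. The returned estimate
sums to 1 within 1e-6.

The bootstrap resamples site indices with replacement (missing sites
resampled like any other, then dropped — the multiplicity-weights
implementation makes the two orderings equivalent), re-runs the projection
per replicate with F fixed, and reports percentile CIs; the replicate SD is
also exposed since percentile-vs-normal interval conventions differ between
analyses. Failed replicates are redrawn, with a hard stop at 10·B attempts.

Two modeling caveats. First, the binomial likelihood is correct for diploid
genotype calls; applied to pseudo-haploid calls (g ∈ {0, 2} = twice a
Bernoulli draw) it double-counts each site's information and narrows CIs by
√2 — a property of this likelihood family generally, worth remembering when
projecting pseudo-haploid samples. Second, the CI is conditional on F: it
reflects genotype sampling noise given the frequencies, not uncertainty in
the clustering fit that produced them.

## Authentication (`authsex`)

**Ry sexing**: Ry = nY/(nX+nY) with a binomial 95% CI; XX when the CI lies
entirely below 0.016, XY when entirely above 0.075 (the standard shotgun
thresholds, config-exposed), otherwise ambiguous. At the empirically
observed levels (≈0.0046 for XX, ≈0.098 for XY) and ≥ 50,000
sex-chromosome reads the assignment is essentially deterministic.

**Mitochondrial contamination**: at polymorphic (haplogroup-defining)
positions, the consensus is the majority base; %(C+MD) is the percentage of
non-consensus calls aggregated over all calls at the listed positions
(per-call aggregation, not per-position averaging), and %C removes the
deamination classes (consensus C read as T, consensus G read as A) from both
numerator and denominator. A consensus tie skips the position with a
warning. %C ≤ %(C+MD) by construction.

**Deamination profile**: C→T rates by distance from the read's 5′ end and
G→A from the 3′ end, over a 25 bp window (the standard display range);
cells with no opportunities are NaN, never 0.

## Phenotype rules (`phenotrait`)

Only hard published rules are encoded: the two-marker lactase rule (a
confidently called derived allele suffices for persistence; non-persistence
requires ancestral homozygosity at both markers, single-locus ancestral
evidence stays unknown), the 8-plex non-dark (any 2 of 6 genotypes) and
non-white (GG at rs6119471 plus any 1 of the 6) skin rules, and the HERC2
brown-eye exclusion. Heterozygotes at the 8-plex SNPs count toward nothing.
Observed genotypes win when covered by ≥ 3 reads; otherwise imputed
genotypes are used at probability ≥ 0.85, else missing. Probabilistic
predictors (full HirisPlex/8-plex eye models) are out of scope.

## Radiocarbon combination (`radiocarbon`)

Inverse-variance weighted mean with χ² consistency on n−1 df. Display
rounding is to the nearest year; context-dependent rounding to multiples of
5, as some calibration software applies, is deliberately not replicated —
combined values can therefore differ by a few years from software-rounded
published numbers. Calibration curves and freshwater-reservoir corrections
are out of scope; corrected dates are treated as inputs.

## Synthetic data (`simgen`)

The generators invert the analysis models, so recovery tests are exact
consistency checks:

- **Frequencies**: ancestral p ~ U(0.05, 0.95) per site; each component
  f ~ Beta(p(1−c)/c, (1−p)(1−c)/c), the Balding–Nichols model with
  divergence c (E f = p, Var f = c·p(1−p)). Default divergence 0.2 gives
  component differentiation of the order seen between hunter-gatherer and
  farmer ancestry components.
- **Genotypes**: Binomial(2, q'F) (diploid) or doubled Bernoulli
  (pseudo-haploid).
- **Reads**: Poisson depth; Gaussian read length (default mean 80 bp,
  within the 62–109 bp range typical of ancient libraries); terminal
  damage C→T with probability δ5·decay^d from the 5′ end and G→A
  symmetrically from the 3′ end. The geometric decay (default 0.5) is a
  modeling choice — empirical damage curves are monotone declining but
  their functional form is not identified by terminal rates alone; default
  δ of 0.1–0.25 matches observed terminal rates of 14–25%.
- **Contamination**: read-level mixture — each mitochondrial read is
  contaminant with probability c — matching how %(C+MD) counts reads.
- **f-statistic scenarios**: a null series (four populations binomially
  sampled around one frequency series) for Z calibration, and an
  archaic-admixture tree whose test population is the frequency mixture
  (1−α)·reference + α·archaic with a small private drift (0.01), so the
  f4-ratio's expectation is exactly α while the check is not a per-site
  algebraic identity. The test population enters as population frequencies,
  not a single sampled genome: at the 1e5 synthetic sites used here a single
  pseudo-haploid genome would contribute ratio noise (~0.03) larger than the
  recovery band, whereas real analyses of this kind lean on millions of
  capture sites.

What the generators do **not** emulate: linkage disequilibrium (sites are
independent, so jackknife blocks only check the machinery, not LD
robustness), realistic fragment-length mixtures, strand-specific library
chemistry (damage is simulated in molecule coordinates without
reverse-complementing minus-strand reads), index hopping, and reference
bias. Passing tests therefore demonstrate correctness of the estimators
under their own assumptions, not robustness to these real-data features.

## Problem sizes and seeds

Simulation sizes in the test suite and acceptance script are chosen so each
check's Monte-Carlo error is small against its tolerance: ancestry recovery
at J = 100,000 (estimator SE ≈ 0.004 against a ±0.02 band); bootstrap
coverage with the frequency matrix fixed and genotypes redrawn —
J = 20,000, 200 outer replicates, B = 200 in the acceptance script and
J = 10,000 / 150 / 100 in the tests (binomial SE on the coverage proportion
≈ 1.5–2 points against a 90–99% band); D-statistic null calibration with
200 replicates of 20,000 sites; f4-ratio recovery at J = 100,000 (ratio
SE ≈ 0.004 against ±0.01); deamination recovery from ≈ 17,000 reads
(terminal-cell SE ≈ 0.6 points against ±2). All generators take explicit
seeds and are bit-reproducible; the acceptance script derives every seed
from its `--seed` argument.

## Known limitations

- The projection CI is conditional on the ancestral frequencies (above).
- Jackknife block size is a convention (700 SNPs); with the synthetic iid
  sites any blocking is valid, and on real data block size should be chosen
  against the LD scale of the panel.
- The X-chromosome contamination likelihood, haplogroup assignment against
  external databases, PCA projection, unsupervised clustering fits,
  imputation and probabilistic phenotype prediction are intentionally not
  implemented; their outputs are consumed as inputs where relevant.
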