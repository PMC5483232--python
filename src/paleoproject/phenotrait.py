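"""Rule-based phenotype classification from trait-SNP genotypes.

Encodes only hard, published single-rule classifiers that can be evaluated
from a handful of genotypes:

* **Lactase persistence** (MCM6 regulatory SNPs): homozygous ancestral C at
  rs182549 *and* G at rs4988235 predicts lactose intolerance in adulthood; a
  confidently called derived allele (T at rs182549 or A at rs4988235)
  predicts persistence.
* **8-plex skin color**: any two of {GG rs12913832, TT rs1545397,
  GG rs16891982, AA rs1426654, AA rs885479, TT rs12203592} predict non-dark
  skin; GG at rs6119471 together with any one of those six predicts
  non-white skin; anything else is inconclusive.
* **Eye color**: GG at rs12913832 (HERC2) excludes brown eyes; everything
  else is left undetermined (full probabilistic predictors are out of scope).

Observed genotypes take priority when covered by >= 3 reads; otherwise an
imputed genotype is accepted if its posterior probability is >= 0.85, else
the genotype is treated as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

_VALID_BASES = frozenset("ACGT")

#: The six non-dark 8-plex genotypes (rsid -> required unordered genotype).
NON_DARK_GENOTYPES = {
    "rs12913832": "GG",
    "rs1545397": "TT",
    "rs16891982": "GG",
    "rs1426654": "AA",
    "rs885479": "AA",
    "rs12203592": "TT",
}
NON_WHITE_MARKER = ("rs6119471", "GG")

LACTASE_SNPS = {"rs182549": ("C", "T"), "rs4988235": ("G", "A")}  # (anc, der)


@dataclass
class TraitGenotype:
    """One rsID's genotype call with provenance.

    ``genotype`` is an unordered allele pair like ``"CT"`` (stored sorted) or
    None when missing.  Imputed entries must carry a probability.
    """

    rsid: str
    genotype: Optional[str]
    depth: Optional[int] = None
    provenance: str = "observed"  # 'observed' | 'imputed'
    imputation_probability: Optional[float] = None

    def __post_init__(self):
        if self.genotype is not None:
            alleles = sorted(self.genotype)
            if len(alleles) != 2 or not set(alleles) <= _VALID_BASES:
                raise ValueError(f"bad genotype {self.genotype!r} at {self.rsid}")
            self.genotype = "".join(alleles)
        if self.provenance not in ("observed", "imputed"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if (self.provenance == "imputed" and self.genotype is not None
                and self.imputation_probability is None):
            raise ValueError(f"imputed genotype at {self.rsid} lacks probability")


@dataclass
class TraitGenotypeTable:
    """Mapping rsID -> :class:`TraitGenotype`."""

    entries: dict[str, TraitGenotype] = field(default_factory=dict)

    def genotype(self, rsid: str) -> Optional[str]:
        e = self.entries.get(rsid)
        return e.genotype if e else None

    def has(self, rsid: str, genotype: str) -> bool:
        return self.genotype(rsid) == "".join(sorted(genotype))

    def carries(self, rsid: str, allele: str) -> bool:
        g = self.genotype(rsid)
        return g is not None and allele in g

    def set(self, rsid: str, genotype: Optional[str], **kw) -> None:
        self.entries[rsid] = TraitGenotype(rsid, genotype, **kw)


def resolve_genotypes(observed: TraitGenotypeTable,
                      imputed: TraitGenotypeTable,
                      min_depth_reads: int = 3,
                      min_prob: float = 0.85) -> TraitGenotypeTable:
    """Merge observed and imputed calls by the depth/probability rule.

    An observed genotype covered by >= ``min_depth_reads`` reads is kept
    regardless of imputation; otherwise the imputed genotype is used if its
    probability is >= ``min_prob``; otherwise the site is missing.
    Idempotent: resolving a resolved table against itself changes nothing.
    """
    out = TraitGenotypeTable()
    for rsid in sorted(set(observed.entries) | set(imputed.entries)):
        obs = observed.entries.get(rsid)
        imp = imputed.entries.get(rsid)
        if obs and obs.genotype is not None and (
                obs.depth is None or obs.depth >= min_depth_reads):
            out.entries[rsid] = obs
        elif imp and imp.genotype is not None and (
                imp.imputation_probability is not None
                and imp.imputation_probability >= min_prob):
            out.entries[rsid] = imp
        else:
            if (obs and obs.genotype is not None and imp
                    and imp.genotype is not None
                    and obs.genotype != imp.genotype):
                warnings.warn(f"{rsid}: low-depth observed {obs.genotype} "
                              f"conflicts with low-probability imputed "
                              f"{imp.genotype}; left missing")
            out.entries[rsid] = TraitGenotype(rsid, None)
    return out


def classify_lactase(genotypes: TraitGenotypeTable) -> str:
    """'non_persistent' | 'persistent' | 'unknown'.

    A called derived allele at either marker is sufficient for persistence;
    non-persistence requires ancestral homozygosity at *both* markers (single
    -locus ancestral evidence alone stays 'unknown').
    """
    for rsid, (_anc, der) in LACTASE_SNPS.items():
        if genotypes.carries(rsid, der):
            return "persistent"
    if genotypes.has("rs182549", "CC") and genotypes.has("rs4988235", "GG"):
        return "non_persistent"
    return "unknown"


def classify_skin_8plex(genotypes: TraitGenotypeTable) -> str:
    """'non_dark' | 'non_white' | 'inconclusive' per the 8-plex rules."""
    n_light = sum(1 for rsid, gt in NON_DARK_GENOTYPES.items()
                  if genotypes.has(rsid, gt))
    if genotypes.has(*NON_WHITE_MARKER) and n_light >= 1:
        return "non_white"
    if n_light >= 2:
        return "non_dark"
    return "inconclusive"


def eye_color_rules(genotypes: TraitGenotypeTable) -> str:
    """'excluded_brown' when GG at rs12913832, else 'undetermined'."""
    return "excluded_brown" if genotypes.has("rs12913832", "GG") \
        else "undetermined"


def trait_report(genotypes: TraitGenotypeTable) -> dict:
    """All rule-based calls for one sample, as a JSON-ready dict."""
    return {
        "lactase": classify_lactase(genotypes),
        "skin_8plex": classify_skin_8plex(genotypes),
        "eye_color": eye_color_rules(genotypes),
        "genotypes": {rsid: e.genotype
                      for rsid, e in sorted(genotypes.entries.items())},
    }
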