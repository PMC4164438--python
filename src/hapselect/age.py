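"""Haplotype-decay allele-age estimation.

The clock: right after a selective sweep lifts a founder haplotype to high
frequency, every derived-allele chromosome carries the intact founder.
Each generation a carrier haplotype is broken by recombination (probability
``r``, the genetic length of the block as a crossover probability) or by a
new mutation (probability ``mu``, the ascertained mutation rate of the
region), so the probability that a chromosome is still intact after G
generations is P = e^{-G (r + mu)}. Observing P — approximated by P', the
share of derived-carrying haplotype mass still on the most frequent
(ancestral) derived haplotype — inverts to

    G = -ln(P) / (r + mu),    age in years = G x generation time.

``AlleleAgeModel`` wires the chain together from a haplotype matrix, a
recombination map and block bounds; ``fit`` returns an
:class:`AlleleAgeResults` carrying every intermediate quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import (ancestral_haplotype_fraction, derived_carrier_spectrum,
                         enumerate_haplotypes)
from .io import HaplotypeMatrix, RecombinationMap, genetic_distance

__all__ = [
    "AgeModelInputs",
    "AgeEstimate",
    "region_mutation_rate",
    "block_recombination_fraction",
    "estimate_generations",
    "generations_to_years",
    "round_2sf",
    "AlleleAgeModel",
    "AlleleAgeResults",
    "allele_age_pipeline",
]

#: Haploid per-base per-generation mutation rate.
PER_BASE_MUTATION_RATE = 1.1e-8
#: Probability that a true polymorphism was ascertained into the SNP panel.
DEFAULT_ASCERTAINMENT = 1e-3
#: Years per human generation.
DEFAULT_GENERATION_TIME = 25.0


@dataclass(frozen=True)
class AgeModelInputs:
    """Inputs of the decay clock: P in (0,1], r and mu per generation."""

    p: float
    r: float
    mu: float
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"P must be in (0, 1], got {self.p}")
        if self.r < 0 or self.mu < 0:
            raise ValueError("r and mu must be non-negative")
        if self.p < 1 and self.r + self.mu == 0:
            raise ValueError("r + mu must be positive when P < 1")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")


@dataclass(frozen=True)
class AgeEstimate:
    generations: float
    years: float
    inputs: AgeModelInputs

    @property
    def generations_int(self) -> int:
        return int(round(self.generations))

    @property
    def years_2sf(self) -> float:
        return round_2sf(self.years)


def region_mutation_rate(per_base_rate: float = PER_BASE_MUTATION_RATE,
                         ascertainment_prob: float = DEFAULT_ASCERTAINMENT,
                         region_length: int = 0) -> float:
    """Ascertained per-generation mutation rate of a region:
    per-base rate x ascertainment probability x length (bp)."""
    if per_base_rate < 0 or ascertainment_prob < 0 or region_length < 0:
        raise ValueError("inputs must be non-negative")
    return per_base_rate * ascertainment_prob * region_length


def block_recombination_fraction(rmap: RecombinationMap, block_start: int,
                                 block_end: int, edge: str = "clamp") -> float:
    """Per-generation crossover probability across a block: its genetic
    length in cM divided by 100."""
    return genetic_distance(rmap, block_start, block_end, edge=edge) / 100.0


def estimate_generations(inputs: AgeModelInputs | None = None, *, p=None,
                         r=None, mu=None) -> float:
    """Invert the decay law: G = -ln(P) / (r + mu); G = 0 when P = 1."""
    if inputs is None:
        inputs = AgeModelInputs(p=p, r=r, mu=mu)
    if inputs.p == 1:
        return 0.0
    return -math.log(inputs.p) / (inputs.r + inputs.mu)


def generations_to_years(generations: float,
                         generation_time: float = DEFAULT_GENERATION_TIME) -> float:
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations * generation_time


def round_2sf(x: float) -> float:
    """Round to two significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 1)


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class AlleleAgeResults:
    """Fitted haplotype-decay age with full provenance of intermediates."""

    pprime: float
    r: float
    mu: float
    generations: float
    years: float
    inputs: AgeModelInputs
    block_bounds_bp: tuple[int, int]
    block_length_bp: int
    block_cm: float
    n_derived_haplotypes: int
    n_carrier_chromosomes: int
    tie_warning: bool = False
    model: "AlleleAgeModel | None" = field(default=None, repr=False)

    @property
    def generations_int(self) -> int:
        return int(round(self.generations))

    @property
    def years_2sf(self) -> float:
        return round_2sf(self.years)

    def bootstrap(self, n_boot: int = 200, seed: int | None = None,
                  alpha: float = 0.05) -> dict:
        """Percentile bootstrap interval for G and years, resampling
        haplotype rows. An extension beyond the point estimator: the decay
        clock itself carries no analytic uncertainty."""
        if self.model is None:
            raise ValueError("bootstrap requires the originating model")
        rng = np.random.default_rng(seed)
        m = self.model
        gens = []
        for _ in range(n_boot):
            idx = rng.integers(0, m.matrix.n_hap, m.matrix.n_hap)
            resampled = HaplotypeMatrix(m.matrix.variants,
                                        m.matrix.alleles[idx],
                                        m.matrix.population)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = AlleleAgeModel(
                        resampled, m.rmap, m.core, m.block,
                        per_base_rate=m.per_base_rate,
                        ascertainment_prob=m.ascertainment_prob,
                        generation_time=m.generation_time).fit()
                gens.append(res.generations)
            except ValueError:
                continue
        gens = np.array(gens)
        lo, hi = np.quantile(gens, [alpha / 2, 1 - alpha / 2])
        gt = self.inputs.generation_time
        return {"generations_ci": (float(lo), float(hi)),
                "years_ci": (float(lo * gt), float(hi * gt)),
                "n_effective": int(gens.size)}

    def to_dict(self) -> dict:
        return {
            "pprime": self.pprime, "r": self.r, "mu": self.mu,
            "generations": self.generations,
            "generations_int": self.generations_int,
            "years": self.years, "years_2sf": self.years_2sf,
            "generation_time": self.inputs.generation_time,
            "block_bounds_bp": list(self.block_bounds_bp),
            "block_length_bp": self.block_length_bp,
            "block_cm": self.block_cm,
            "n_derived_haplotypes": self.n_derived_haplotypes,
            "n_carrier_chromosomes": self.n_carrier_chromosomes,
            "tie_warning": self.tie_warning,
        }

    def summary(self) -> str:
        lines = [
            "Haplotype-decay allele age",
            "==========================",
            f"block span             {self.block_bounds_bp[0]}-{self.block_bounds_bp[1]} bp"
            f" ({self.block_length_bp} bp, {self.block_cm:.4f} cM)",
            f"derived haplotypes     {self.n_derived_haplotypes} distinct"
            f" on {self.n_carrier_chromosomes} chromosomes",
            f"P' (intact fraction)   {self.pprime:.4f}",
            f"r  (recomb/gen)        {self.r:.3e}",
            f"mu (mutation/gen)      {self.mu:.3e}",
            f"G  (generations)       {self.generations:.1f}  (~{self.generations_int})",
            f"age                    {self.years:.0f} y  (~{self.years_2sf:.0f} y at "
            f"{self.inputs.generation_time:g} y/generation)",
        ]
        if self.tie_warning:
            lines.append("note: tie for most frequent derived haplotype (lexicographic pick)")
        return "\n".join(lines)


class AlleleAgeModel:
    """Haplotype-decay age model for a core SNP inside an LD block.

    Parameters
    ----------
    matrix
        Phased, ancestral-polarized haplotypes covering the block.
    rmap
        Recombination map spanning the block (interpolated at the bounds).
    core
        Column index of the core SNP, or its variant id.
    block
        (start, end) column indices of the block, inclusive, or a pair of
        variant ids naming the boundary SNPs.
    """

    def __init__(self, matrix: HaplotypeMatrix, rmap: RecombinationMap,
                 core, block,
                 per_base_rate: float = PER_BASE_MUTATION_RATE,
                 ascertainment_prob: float = DEFAULT_ASCERTAINMENT,
                 generation_time: float = DEFAULT_GENERATION_TIME,
                 edge: str = "clamp"):
        self.matrix = matrix
        self.rmap = rmap
        self.core = matrix.index_of(core) if isinstance(core, str) else int(core)
        start, end = block
        start = matrix.index_of(start) if isinstance(start, str) else int(start)
        end = matrix.index_of(end) if isinstance(end, str) else int(end)
        if not start <= self.core <= end:
            raise ValueError("core SNP must lie inside the block")
        self.block = (start, end)
        self.per_base_rate = per_base_rate
        self.ascertainment_prob = ascertainment_prob
        self.generation_time = generation_time
        self.edge = edge

    def fit(self) -> AlleleAgeResults:
        start, end = self.block
        spectrum = enumerate_haplotypes(self.matrix, self.block)
        sub = derived_carrier_spectrum(spectrum, self.core - start)
        tie = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pprime = ancestral_haplotype_fraction(sub)
            tie = any("tie" in str(w.message) for w in caught)
        if tie:
            warnings.warn("P' tie-break fired: most frequent derived haplotype not unique")
        pos = self.matrix.positions
        b_start, b_end = int(pos[start]), int(pos[end])
        block_cm = genetic_distance(self.rmap, b_start, b_end, edge=self.edge)
        r = block_cm / 100.0
        length = b_end - b_start + 1
        mu = region_mutation_rate(self.per_base_rate, self.ascertainment_prob, length)
        inputs = AgeModelInputs(p=pprime, r=r, mu=mu,
                                generation_time=self.generation_time)
        g = estimate_generations(inputs)
        years = generations_to_years(g, self.generation_time)
        return AlleleAgeResults(
            pprime=pprime, r=r, mu=mu, generations=g, years=years, inputs=inputs,
            block_bounds_bp=(b_start, b_end), block_length_bp=length,
            block_cm=block_cm, n_derived_haplotypes=len(sub.entries),
            n_carrier_chromosomes=sum(e.count for e in sub.entries),
            tie_warning=tie, model=self)


def allele_age_pipeline(matrix: HaplotypeMatrix, rmap: RecombinationMap,
                        core, block,
                        per_base_rate: float = PER_BASE_MUTATION_RATE,
                        ascertainment_prob: float = DEFAULT_ASCERTAINMENT,
                        generation_time: float = DEFAULT_GENERATION_TIME,
                        edge: str = "clamp") -> AlleleAgeResults:
    """Functional form of :class:`AlleleAgeModel`: build and fit in one call."""
    return AlleleAgeModel(matrix, rmap, core, block,
                          per_base_rate=per_base_rate,
                          ascertainment_prob=ascertainment_prob,
                          generation_time=generation_time, edge=edge).fit()
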