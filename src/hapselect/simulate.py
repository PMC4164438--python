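"""Synthetic-data generators with the statistical structure the selection
and association analyses assume.

Four generators are provided:

* neutral coalescent haplotype matrices conditioned on an exact number of
  segregating sites (the locus-matched null of the iHS test);
* sweep-shaped haplotype matrices built by copy-and-erode: a founder
  haplotype is copied to the target derived-allele frequency and then
  eroded for a known number of generations by recombination break-ins and
  mutations, which is exactly the decay process the allele-age clock
  inverts;
* a forward haplotype-decay oracle returning the fraction of lineages with
  no recombination/mutation event after G generations (expectation
  e^{-G(r+mu)});
* genotype-phenotype cohorts with Hardy-Weinberg genotypes and per-genotype
  truncated-normal hormone levels.

All generators are deterministic under a fixed seed. The coalescent engine
is msprime for the general case (recombination, bottleneck demography); a
minimal built-in Kingman sampler serves the no-recombination constant-size
case, where only a single marginal genealogy is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, HaplotypeMatrix, Variant

__all__ = [
    "DemographyModel",
    "SweepModel",
    "CohortModel",
    "simulate_neutral_haplotypes",
    "simulate_sweep_haplotypes",
    "haplotype_decay_forward",
    "simulate_cohort",
    "GIP_RS7754840",
    "STUDY_COHORT",
]


@dataclass(frozen=True)
class DemographyModel:
    """Bottleneck demography: ancestral size N1 shrinks instantaneously to
    N2 at T2 generations ago, stays constant until T1, then grows
    exponentially to the present size N3."""

    n1: float
    n2: float
    n3: float
    t1: float
    t2: float

    def __post_init__(self):
        if min(self.n1, self.n2, self.n3) <= 0:
            raise ValueError("population sizes must be positive")
        if not self.t2 > self.t1 >= 0:
            raise ValueError("need T2 > T1 >= 0")

    def to_msprime(self):
        import msprime

        demog = msprime.Demography()
        growth = math.log(self.n3 / self.n2) / self.t1 if self.t1 > 0 else 0.0
        demog.add_population(name="pop0", initial_size=self.n3, growth_rate=growth)
        demog.add_population_parameters_change(
            time=self.t1, initial_size=self.n2, growth_rate=0.0)
        demog.add_population_parameters_change(time=self.t2, initial_size=self.n1)
        return demog


def _int_positions(pos_float: np.ndarray, length: int) -> np.ndarray:
    """Map continuous positions to strictly increasing 1-based integers."""
    p = np.floor(np.sort(np.asarray(pos_float))).astype(np.int64) + 1
    for i in range(1, len(p)):
        if p[i] <= p[i - 1]:
            p[i] = p[i - 1] + 1
    if len(p) and p[-1] > length:
        raise ValueError("more segregating sites than available positions")
    return p


def _variants_for(positions, chrom="sim") -> list[Variant]:
    return [Variant(f"s{k + 1}", chrom, int(p), "A", "G")
            for k, p in enumerate(positions)]


def _kingman_fixed_s(n_hap: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Single-tree Kingman coalescent with exactly ``s`` mutations placed
    uniformly on total branch length (fixed-S conditioning, rho = 0)."""
    n_nodes = 2 * n_hap - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    t_birth = np.zeros(n_nodes)
    ks = np.arange(n_hap, 1, -1)
    waits = rng.exponential(2.0 / (ks * (ks - 1.0)))
    u_i = rng.random(n_hap - 1)
    u_j = rng.random(n_hap - 1)
    active = list(range(n_hap))
    t = 0.0
    nxt = n_hap
    for step in range(n_hap - 1):
        k = n_hap - step
        t += waits[step]
        i = int(u_i[step] * k)
        j = int(u_j[step] * (k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        left[nxt], right[nxt] = a, b
        t_birth[nxt] = t
        hi, lo = max(i, j), min(i, j)
        active[hi] = active[-1]
        active.pop()
        active[lo] = nxt
        nxt += 1
    bl = np.zeros(n_nodes)
    has_par = parent >= 0
    bl[has_par] = t_birth[parent[has_par]] - t_birth[has_par]
    nodes = rng.choice(n_nodes, size=s, p=bl / bl.sum())
    mat = np.zeros((n_hap, s), dtype=np.int8)
    for col, v in enumerate(nodes):
        stack = [int(v)]
        while stack:
            u = stack.pop()
            if u < n_hap:
                mat[u, col] = 1
            else:
                stack.append(int(left[u]))
                stack.append(int(right[u]))
    return mat


def _msprime_fixed_s(n_hap, s, rho, demography, seed, length, ne):
    """Sample a genealogy with msprime and place exactly ``s`` mutations
    with probability proportional to branch length x genomic span."""
    import msprime

    rng = np.random.default_rng(seed)
    kwargs = dict(samples=n_hap, ploidy=1,
                  random_seed=int(rng.integers(1, 2**31 - 1)))
    if demography is not None:
        kwargs["demography"] = demography.to_msprime()
    else:
        kwargs["population_size"] = ne
    if rho > 0:
        kwargs["sequence_length"] = length
        kwargs["recombination_rate"] = rho / (4.0 * ne * length)
    ts = msprime.sim_ancestry(**kwargs)
    edges = ts.tables.edges
    times = ts.tables.nodes.time
    e_left = np.asarray(edges.left)
    e_right = np.asarray(edges.right)
    e_child = np.asarray(edges.child)
    e_parent = np.asarray(edges.parent)
    w = (e_right - e_left) * (times[e_parent] - times[e_child])
    pick = rng.choice(len(w), size=s, p=w / w.sum())
    if rho > 0:
        pos = e_left[pick] + rng.random(s) * (e_right[pick] - e_left[pick])
    else:
        # single marginal tree; mutation positions are independent of it
        pos = rng.random(s) * length
    order = np.argsort(pos, kind="stable")
    mat = np.zeros((n_hap, s), dtype=np.int8)
    for col, k in enumerate(order):
        tree = ts.at(pos[k]) if rho > 0 else ts.first()
        for leaf in tree.samples(int(e_child[pick[k]])):
            mat[leaf, col] = 1
    return mat, np.sort(pos)


def simulate_neutral_haplotypes(n_hap: int, s: int, rho: float = 0.0,
                                demography: DemographyModel | None = None,
                                seed: int | None = None,
                                sequence_length: int = 151_000,
                                population: str = "SIM",
                                ne: float = 10_000,
                                engine: str = "auto") -> HaplotypeMatrix:
    """Neutral coalescent haplotypes with exactly ``s`` segregating sites.

    ``rho`` is the population-scaled recombination parameter 4*Ne*r for
    the whole region (0 = no recombination, a single marginal genealogy).
    Fixed-S conditioning places exactly ``s`` mutations on the sampled
    genealogy with probability proportional to branch length; the root
    state is ancestral, so every column is polymorphic and polarized.

    ``engine='auto'`` uses the built-in Kingman sampler when ``rho == 0``
    with constant population size, and msprime otherwise.
    """
    if n_hap < 4:
        raise ValueError("need at least 4 haplotypes")
    if s < 1:
        raise ValueError("need at least 1 segregating site")
    rng = np.random.default_rng(seed)
    if engine == "auto":
        engine = "kingman" if (rho == 0 and demography is None) else "msprime"
    if engine == "kingman":
        if rho != 0 or demography is not None:
            raise ValueError("kingman engine supports rho=0, constant size only")
        mat = _kingman_fixed_s(n_hap, s, rng)
        pos = _int_positions(rng.random(s) * sequence_length, sequence_length)
    elif engine == "msprime":
        mat, raw_pos = _msprime_fixed_s(n_hap, s, rho, demography, seed,
                                        sequence_length, ne)
        pos = _int_positions(raw_pos, sequence_length)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return HaplotypeMatrix(_variants_for(pos), mat, population)


# ---------------------------------------------------------------------------
# Sweep haplotypes (copy-and-erode)


@dataclass(frozen=True)
class SweepModel:
    """Parameters of a copy-and-erode sweep of known age.

    ``r`` and ``mu`` are per-generation probabilities of a recombination
    break-in and of a mutation anywhere in the block, respectively;
    ``age`` (G*) is the number of generations of erosion after the founder
    haplotype reached ``target_freq``.
    """

    core_position: int
    target_freq: float
    age: float
    r: float
    mu: float
    core_id: str = "core"

    def __post_init__(self):
        if not 0 < self.target_freq < 1:
            raise ValueError("target frequency must be in (0, 1)")
        if self.age < 0 or self.r < 0 or self.mu < 0:
            raise ValueError("age and rates must be non-negative")


def simulate_sweep_haplotypes(background: HaplotypeMatrix, sweep: SweepModel,
                              seed: int | None = None) -> HaplotypeMatrix:
    """Overlay a sweep of known age on a background haplotype matrix.

    A random background haplotype is taken as the founder and copied onto
    ``round(target_freq * n_hap)`` randomly chosen rows; each copy then
    independently accumulates Poisson(age * r) recombination break-ins
    (splicing in a random background haplotype beyond a uniform breakpoint,
    on the side of the breakpoint away from the core) and Poisson(age * mu)
    in-block mutations. A new core column carrying the derived allele on
    exactly the swept rows is inserted at ``core_position``.
    """
    rng = np.random.default_rng(seed)
    n = background.n_hap
    k = int(round(sweep.target_freq * n))
    if not 1 <= k < n:
        raise ValueError(f"target frequency {sweep.target_freq} infeasible for {n} haplotypes")
    pos = background.positions
    founder = background.alleles[rng.integers(n)].copy()
    carriers = rng.choice(n, size=k, replace=False)
    alleles = background.alleles.copy()
    lo, hi = int(pos[0]), int(pos[-1])
    for row in carriers:
        hap = founder.copy()
        for _ in range(rng.poisson(sweep.age * sweep.r)):
            # The decay clock this generator feeds assumes every break-in
            # destroys identity with the founder, so a splice that would
            # leave the haplotype unchanged (donor identical over the
            # spliced tail) is redrawn; capped to stay safe on
            # near-monomorphic backgrounds.
            for _attempt in range(100):
                bkpt = rng.uniform(lo, hi)
                donor = background.alleles[rng.integers(n)]
                if bkpt >= sweep.core_position:
                    mask = pos > bkpt
                else:
                    mask = pos < bkpt
                if (hap[mask] != donor[mask]).any():
                    hap[mask] = donor[mask]
                    break
        for _ in range(rng.poisson(sweep.age * sweep.mu)):
            j = rng.integers(background.n_var)
            hap[j] = 1 - hap[j] if hap[j] != -1 else -1
        alleles[row] = hap
    core_pos = int(sweep.core_position)
    while core_pos in pos:
        core_pos += 1
    insert_at = int(np.searchsorted(pos, core_pos))
    core_col = np.zeros((n, 1), dtype=np.int8)
    core_col[carriers] = 1
    alleles = np.concatenate(
        [alleles[:, :insert_at], core_col, alleles[:, insert_at:]], axis=1)
    chrom = background.variants[0].chrom if background.variants else "sim"
    variants = list(background.variants)
    variants.insert(insert_at, Variant(sweep.core_id, chrom, core_pos, "G", "C"))
    return HaplotypeMatrix(variants, alleles, background.population)


def haplotype_decay_forward(n_founders: int, g: float, r: float, mu: float,
                            seed: int | None = None) -> float:
    """Fraction of founder lineages with no recombination or mutation event
    by generation ``g``, under independent Poisson processes with rates
    ``r`` and ``mu``. Expectation e^{-g (r + mu)}."""
    if n_founders < 1:
        raise ValueError("need at least one founder lineage")
    rng = np.random.default_rng(seed)
    t_rec = rng.exponential(1.0 / r, n_founders) if r > 0 else np.full(n_founders, np.inf)
    t_mut = rng.exponential(1.0 / mu, n_founders) if mu > 0 else np.full(n_founders, np.inf)
    return float(((t_rec > g) & (t_mut > g)).mean())


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortModel:
    """Generator model for a genotype-phenotype cohort.

    ``hormones`` maps phenotype name to ((mean_anc_hom, mean_het,
    mean_der_hom), (sd_anc_hom, sd_het, sd_der_hom)). Genotypes are drawn
    at Hardy-Weinberg proportions for ``derived_freq`` unless exact
    per-genotype counts are fixed via ``genotype_counts``. Phenotypes are
    truncated-at-zero normals (hormone concentrations cannot be negative);
    missingness is applied independently per subject and hormone.
    """

    n_subjects: int
    derived_freq: float
    hormones: dict[str, tuple[tuple, tuple]] = field(default_factory=dict)
    missing_rate: float = 0.0
    genotype_counts: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0 < self.derived_freq < 1:
            raise ValueError("derived allele frequency must be in (0, 1)")
        for name, (means, sds) in self.hormones.items():
            if len(means) != 3 or len(sds) != 3 or any(s < 0 for s in sds):
                raise ValueError(f"{name}: need 3 means and 3 non-negative SDs")
        if self.genotype_counts is not None and sum(self.genotype_counts) != self.n_subjects:
            raise ValueError("genotype_counts must sum to n_subjects")


#: GIP response at the CDKAL1 rs7754840 locus: per-genotype means/SDs
#: (pg/ml) and the exact per-genotype sample sizes of the assayed subjects.
GIP_RS7754840 = CohortModel(
    n_subjects=119, derived_freq=0.331,
    hormones={"gip_pg_ml": ((68.9, 78.0, 98.9), (32.8, 34.4, 37.4))},
    genotype_counts=(54, 50, 15))

#: Full 131-subject glucose-challenge cohort at rs7754840: insulin (mU/L),
#: GIP (pg/ml) and C-peptide (ng/ml) per genotype class, with a 7%
#: per-assay missingness rate emulating failed assays.
STUDY_COHORT = CohortModel(
    n_subjects=131, derived_freq=0.331,
    hormones={
        "insulin_mU_L": ((36.1, 42.0, 37.6), (29.7, 36.4, 23.5)),
        "gip_pg_ml": ((68.9, 78.0, 98.9), (32.8, 34.4, 37.4)),
        "c_peptide_ng_ml": ((2.02, 2.19, 1.84), (0.95, 1.21, 0.83)),
    },
    missing_rate=0.07)

_DEFAULT_VARIANT = Variant("rs7754840", "6", 20769000, "G", "C")


def simulate_cohort(model: CohortModel, seed: int | None = None,
                    variant: Variant = _DEFAULT_VARIANT) -> Cohort:
    """Draw a cohort from a :class:`CohortModel` (deterministic under seed)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    p = model.derived_freq
    if model.genotype_counts is not None:
        counts = model.genotype_counts
    else:
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        counts = rng.multinomial(model.n_subjects, probs)
    dosages = np.repeat([0, 1, 2], counts)
    rng.shuffle(dosages)
    letters = {0: variant.ancestral * 2,
               1: variant.ancestral + variant.derived,
               2: variant.derived * 2}
    df = pd.DataFrame({
        "subject_id": [f"S{i + 1}" for i in range(model.n_subjects)],
        variant.id: [letters[int(d)] for d in dosages],
    })
    for name, (means, sds) in model.hormones.items():
        vals = np.empty(model.n_subjects)
        for cls in (0, 1, 2):
            mask = dosages == cls
            m, s = means[cls], sds[cls]
            if s == 0:
                vals[mask] = m
            else:
                vals[mask] = stats.truncnorm.rvs(
                    -m / s, np.inf, loc=m, scale=s, size=int(mask.sum()),
                    random_state=rng)
        if model.missing_rate > 0:
            vals[rng.random(model.n_subjects) < model.missing_rate] = np.nan
        df[name] = vals
    return Cohort(df, {variant.id: variant})
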