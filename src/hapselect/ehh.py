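"""Extended haplotype homozygosity (EHH) decay, integrated EHH and the
unstandardized iHS statistic, with significance against a locus-matched
coalescent null.

EHH at a target SNP is the probability that two randomly drawn carriers of
a core allele are identical over the contiguous SNP interval between the
core and the target. Around a recently selected allele the carrier
haplotypes are unusually long and homogeneous, so the area under the EHH
curve (iHH) for the selected allele exceeds that of the other allele;
uiHS = ln(iHH_ancestral / iHH_derived) is strongly negative when the
derived allele rode a recent sweep.

Significance here follows the locus-matched simulation approach: neutral
coalescent replicates conditioned on the observed sample size, number of
segregating sites and recombination rate provide the null distribution of
uiHS, and the p-value is the two-sided empirical tail probability. No
genome-wide frequency-bin standardization is performed, so uiHS values are
not comparable to standardized iHS scores from genome scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, HaplotypeMatrix, RecombinationMap

__all__ = [
    "IHSUndetermined",
    "EHHPoint",
    "EHHProfile",
    "UIHS",
    "IHSNull",
    "IHSResult",
    "ehh_at",
    "ehh_profile",
    "integrated_ehh",
    "unstandardized_ihs",
    "ihs_null",
    "ihs_significance",
    "ihs_test",
]


class IHSUndetermined(ValueError):
    """iHS cannot be determined (too few carriers or zero EHH area)."""


def _allele_code(allele) -> int:
    if allele in (0, 1):
        return int(allele)
    name = str(allele).lower()
    if name.startswith("anc"):
        return 0
    if name.startswith("der"):
        return 1
    raise ValueError(f"allele must be ancestral/derived or 0/1, got {allele!r}")


# ---------------------------------------------------------------------------
# Core EHH computation


def ehh_at(matrix: HaplotypeMatrix, core: int, allele, target: int) -> float:
    """EHH of ``allele`` carriers at the core, evaluated at ``target``.

    Carriers are grouped by identity over the contiguous SNP interval
    between core and target (inclusive); EHH is the homozygous-pair
    fraction sum_i C(e_i,2) / C(c,2) over group sizes e_i. Haplotypes with
    missing data anywhere in the interval are dropped and the carrier
    count recomputed.
    """
    code = _allele_code(allele)
    lo, hi = min(core, target), max(core, target)
    sub = matrix.alleles[:, lo:hi + 1]
    carriers = matrix.alleles[:, core] == code
    complete = (sub != MISSING).all(axis=1)
    rows = sub[carriers & complete]
    c = rows.shape[0]
    if c < 2:
        raise ValueError(f"fewer than 2 carriers of allele {allele} observed over the interval")
    _, counts = np.unique(rows, axis=0, return_counts=True)
    pairs = (counts * (counts - 1) // 2).sum()
    return float(pairs) / (c * (c - 1) // 2)


def _ehh_walk_py(sub, core, thresh, out_j, out_e):
    """Group-refinement EHH walk (complete-data fast path).

    Walks outward from the core one SNP at a time in each direction,
    refining the carrier partition incrementally; stops when EHH drops
    below ``thresh`` or the matrix edge is reached. Fills (out_j, out_e)
    and returns the number of points written.
    """
    c, w = sub.shape
    tot = c * (c - 1) / 2.0
    m = 0
    gid = np.empty(c, np.int64)
    cnt = np.empty(2 * c, np.int64)
    remap = np.empty(2 * c, np.int64)
    for step in (1, -1):
        for i in range(c):
            gid[i] = 0
        ng = 1
        j = core
        while True:
            j += step
            if j < 0 or j >= w:
                break
            for k in range(2 * ng):
                cnt[k] = 0
            for i in range(c):
                key = gid[i] * 2 + sub[i, j]
                gid[i] = key
                cnt[key] += 1
            ns = 0
            pairs = 0.0
            for k in range(2 * ng):
                if cnt[k] > 0:
                    remap[k] = ns
                    ns += 1
                    pairs += cnt[k] * (cnt[k] - 1) / 2.0
            for i in range(c):
                gid[i] = remap[gid[i]]
            ng = ns
            e = pairs / tot
            if e < thresh:
                break
            out_j[m] = j
            out_e[m] = e
            m += 1
    return m


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _ehh_walk = njit(cache=False)(_ehh_walk_py)
except ImportError:  # pragma: no cover
    _ehh_walk = _ehh_walk_py


@dataclass(frozen=True)
class EHHPoint:
    index: int
    position: int
    ehh: float
    distance_cm: float | None = None


@dataclass
class EHHProfile:
    """EHH decay profile for one core allele, ordered by position."""

    core: int
    allele: str
    points: list[EHHPoint]
    n_carriers: int

    @property
    def core_position(self) -> int:
        return next(p.position for p in self.points if p.index == self.core)

    def side(self, which: str) -> list[EHHPoint]:
        if which == "left":
            return [p for p in self.points if p.index <= self.core]
        return [p for p in self.points if p.index >= self.core]


def ehh_profile(matrix: HaplotypeMatrix, core: int, allele,
                threshold: float = 0.05,
                rmap: RecombinationMap | None = None) -> EHHProfile:
    """EHH decay profile extending both directions from the core SNP.

    Walks outward SNP by SNP until EHH falls below ``threshold`` (points
    below the threshold are excluded) or the matrix edge is reached. EHH
    at the core itself is 1 by construction. When a recombination map is
    supplied each point also carries its genetic distance (cM) from the
    core.
    """
    code = _allele_code(allele)
    positions = matrix.positions
    carriers_mask = matrix.alleles[:, core] == code
    c_total = int(carriers_mask.sum())
    if c_total < 2:
        raise ValueError(f"fewer than 2 carriers of allele {allele} at core {core}")
    pts = {core: 1.0}
    if not matrix.has_missing:
        sub = np.ascontiguousarray(matrix.alleles[carriers_mask])
        out_j = np.empty(2 * matrix.n_var, np.int64)
        out_e = np.empty(2 * matrix.n_var, np.float64)
        m = _ehh_walk(sub, core, threshold, out_j, out_e)
        for k in range(m):
            pts[int(out_j[k])] = float(out_e[k])
    else:
        for step in (1, -1):
            j = core
            while True:
                j += step
                if j < 0 or j >= matrix.n_var:
                    break
                try:
                    e = ehh_at(matrix, core, code, j)
                except ValueError:
                    break
                if e < threshold:
                    break
                pts[j] = e
    cm0 = rmap.cumulative_at(positions[core]) if rmap is not None else None
    points = []
    for j in sorted(pts):
        dist = None
        if rmap is not None:
            dist = abs(rmap.cumulative_at(positions[j]) - cm0)
        points.append(EHHPoint(index=j, position=int(positions[j]), ehh=pts[j],
                               distance_cm=dist))
    name = "derived" if code == 1 else "ancestral"
    return EHHProfile(core=core, allele=name, points=points, n_carriers=c_total)


def integrated_ehh(profile: EHHProfile, rmap: RecombinationMap | None = None) -> float:
    """Trapezoidal area under the EHH curve, summed over both sides.

    The x-axis is genetic distance from the core (cM) when distances are
    available (either on the profile's points or through ``rmap``), else
    physical distance (bp). Raises when the profile has no side with at
    least two points.
    """
    has_cm = all(p.distance_cm is not None for p in profile.points) and rmap is None
    core_pos = profile.core_position
    total = 0.0
    sides_ok = 0
    for which in ("left", "right"):
        pts = profile.side(which)
        if len(pts) < 2:
            continue
        sides_ok += 1
        if has_cm:
            x = np.array([p.distance_cm for p in pts])
        elif rmap is not None:
            cm0 = rmap.cumulative_at(core_pos)
            x = np.array([abs(rmap.cumulative_at(p.position) - cm0) for p in pts])
        else:
            x = np.array([abs(p.position - core_pos) for p in pts], dtype=float)
        y = np.array([p.ehh for p in pts])
        order = np.argsort(x)
        total += float(np.trapezoid(y[order], x[order]))
    if sides_ok == 0:
        raise ValueError("profile has no side with at least two points")
    return total


@dataclass
class UIHS:
    ihh_ancestral: float
    ihh_derived: float
    uihs: float
    units: str


def unstandardized_ihs(matrix: HaplotypeMatrix, core: int,
                       rmap: RecombinationMap | None = None,
                       threshold: float = 0.05) -> UIHS:
    """uiHS = ln(iHH_ancestral / iHH_derived) at the core SNP.

    Negative values indicate longer/more homogeneous haplotypes around the
    derived allele (the selected-derived-allele signature). Raises
    :class:`IHSUndetermined` when either allele has fewer than two
    carriers or a zero EHH area.
    """
    ihh = {}
    for allele in (0, 1):
        try:
            prof = ehh_profile(matrix, core, allele, threshold=threshold, rmap=rmap)
            ihh[allele] = integrated_ehh(prof)
        except ValueError as exc:
            raise IHSUndetermined(f"allele {allele} at core {core}: {exc}") from exc
        if ihh[allele] <= 0:
            raise IHSUndetermined(f"zero iHH for allele {allele} at core {core}")
    return UIHS(ihh_ancestral=ihh[0], ihh_derived=ihh[1],
                uihs=float(np.log(ihh[0] / ihh[1])),
                units="cM" if rmap is not None else "bp")


# ---------------------------------------------------------------------------
# Simulation null


@dataclass
class IHSNull:
    """Empirical null distribution of uiHS from matched neutral replicates."""

    values: np.ndarray
    seed: int | None
    n_requested: int
    n_undetermined: int
    params: dict = field(default_factory=dict)

    def quantiles(self, q=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict[float, float]:
        return {float(x): float(np.quantile(self.values, x)) for x in q}


def select_matched_core(matrix: HaplotypeMatrix, core_freq: float,
                        min_carriers: int = 2) -> int | None:
    """Column whose derived-allele frequency is nearest ``core_freq`` among
    columns where both alleles have at least ``min_carriers`` carriers."""
    a = matrix.alleles
    der = (a == 1).sum(axis=0)
    anc = (a == 0).sum(axis=0)
    elig = np.flatnonzero((der >= min_carriers) & (anc >= min_carriers))
    if elig.size == 0:
        return None
    freq = der[elig] / (der[elig] + anc[elig])
    return int(elig[np.argmin(np.abs(freq - core_freq))])


def ihs_null(n_hap: int, s: int, rho: float, core_freq: float,
             n_reps: int = 1000, seed: int | None = None, demography=None,
             threshold: float = 0.05, sequence_length: int = 151_000) -> IHSNull:
    """Null distribution of uiHS from neutral replicates matched on the
    observed sample size, segregating-site count and recombination rate.

    Each replicate simulates ``n_hap`` haplotypes with exactly ``s``
    segregating sites at population recombination parameter ``rho``,
    takes the simulated SNP nearest the observed core frequency as the
    core, and records uiHS. Replicates where uiHS is undetermined are
    skipped and counted.
    """
    from .simulate import simulate_neutral_haplotypes

    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    values = []
    n_und = 0
    for k in range(n_reps):
        mat = simulate_neutral_haplotypes(
            n_hap=n_hap, s=s, rho=rho, demography=demography,
            seed=int(child_seeds[k]), sequence_length=sequence_length)
        core = select_matched_core(mat, core_freq)
        if core is None:
            n_und += 1
            continue
        try:
            values.append(unstandardized_ihs(mat, core, threshold=threshold).uihs)
        except IHSUndetermined:
            n_und += 1
    if not values:
        raise ValueError("no replicate produced a determinable uiHS")
    return IHSNull(values=np.array(values), seed=seed, n_requested=n_reps,
                   n_undetermined=n_und,
                   params={"n_hap": n_hap, "s": s, "rho": rho,
                           "core_freq": core_freq, "threshold": threshold})


def ihs_significance(observed: float, null: IHSNull | np.ndarray) -> tuple[float, bool]:
    """Two-sided empirical p-value of an observed uiHS against the null.

    p = (1 + #{|null| >= |observed|}) / (1 + n); significant at p < 0.05.
    """
    values = null.values if isinstance(null, IHSNull) else np.asarray(null, dtype=float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    exceed = int((np.abs(values) >= abs(observed)).sum())
    p = (1 + exceed) / (1 + values.size)
    return float(p), p < 0.05


@dataclass
class IHSResult:
    core: int
    ihh_ancestral: float
    ihh_derived: float
    uihs: float
    units: str
    p_value: float
    significant: bool
    null_quantiles: dict
    null_size: int
    seed: int | None


def ihs_test(matrix: HaplotypeMatrix, core: int, rho: float,
             n_reps: int = 1000, seed: int | None = None,
             rmap: RecombinationMap | None = None, demography=None,
             threshold: float = 0.05) -> IHSResult:
    """uiHS at ``core`` with empirical significance from a matched null."""
    obs = unstandardized_ihs(matrix, core, rmap=rmap, threshold=threshold)
    pos = matrix.positions
    null = ihs_null(
        n_hap=matrix.n_hap, s=matrix.n_var, rho=rho,
        core_freq=matrix.derived_allele_frequency(core),
        n_reps=n_reps, seed=seed, demography=demography, threshold=threshold,
        sequence_length=int(pos[-1] - pos[0] + 1))
    p, sig = ihs_significance(obs.uihs, null)
    return IHSResult(core=core, ihh_ancestral=obs.ihh_ancestral,
                     ihh_derived=obs.ihh_derived, uihs=obs.uihs, units=obs.units,
                     p_value=p, significant=sig, null_quantiles=null.quantiles(),
                     null_size=int(null.values.size), seed=seed)
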