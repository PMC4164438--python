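"""Pairwise LD, haplotype spectra within an LD block, and the ancestral
derived-carrying haplotype fraction P'.

P' — the share of all derived-allele-carrying haplotype mass held by the
most frequent derived-carrying haplotype — feeds the haplotype-decay allele
age clock: it approximates the probability that a derived chromosome still
carries the unbroken founding haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MISSING, HaplotypeMatrix

__all__ = [
    "LDPair",
    "SpectrumEntry",
    "HaplotypeSpectrum",
    "pairwise_ld",
    "enumerate_haplotypes",
    "derived_carrier_spectrum",
    "ancestral_haplotype_fraction",
]


@dataclass(frozen=True)
class LDPair:
    i: int
    j: int
    d: float
    d_prime: float
    r2: float


@dataclass(frozen=True)
class SpectrumEntry:
    haplotype: str  # '0'/'1' string over the block SNPs
    count: int
    frequency: float


@dataclass
class HaplotypeSpectrum:
    """Distinct haplotype strings over a block, sorted by descending
    frequency with lexicographic tie-break.

    ``n_used`` is the number of haplotypes without missing data in the
    block (the frequency denominator); ``n_dropped`` were excluded for
    in-block missingness.
    """

    block: tuple[int, int]
    entries: list[SpectrumEntry]
    n_used: int
    n_dropped: int = 0

    def __post_init__(self):
        if self.entries:
            total = sum(e.frequency for e in self.entries)
            # frequencies may be on the full-sample scale for sub-spectra,
            # so only enforce they do not exceed 1
            if total > 1 + 1e-9:
                raise ValueError("spectrum frequencies sum above 1")

    @classmethod
    def from_frequencies(cls, frequencies, core_offset: int = 0,
                         n_sites: int = 1) -> "HaplotypeSpectrum":
        """Build a spectrum directly from known haplotype frequencies.

        Convenience for working from published haplotype tables when the
        underlying matrix is unavailable; synthesizes distinct derived-core
        haplotype strings. Counts are left at 0 (unknown).
        """
        freqs = sorted((float(f) for f in frequencies), reverse=True)
        entries = []
        for k, f in enumerate(freqs):
            hap = ["0"] * n_sites
            hap[core_offset] = "1"
            # make strings distinct by encoding rank in trailing bits
            label = format(k, "b")
            hap = hap + list(label)
            entries.append(SpectrumEntry("".join(hap), 0, f))
        return cls(block=(0, n_sites - 1), entries=entries, n_used=0)


def pairwise_ld(matrix: HaplotypeMatrix, i: int, j: int) -> LDPair:
    """D, D' and r^2 between columns ``i`` and ``j`` from phased gametes.

    Computed over haplotypes non-missing at both sites, with allele "A"/"B"
    taken as the derived allele at each site. Raises on columns that are
    monomorphic in that subset.
    """
    a = matrix.alleles[:, i]
    b = matrix.alleles[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    n = len(a)
    if n == 0:
        raise ValueError("no haplotypes observed at both sites")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError(f"column {i if p_a in (0, 1) else j} is monomorphic")
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    q_a, q_b = 1 - p_a, 1 - p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        d_max = 1.0
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return LDPair(i=i, j=j, d=float(d), d_prime=float(d_prime), r2=float(r2))


def enumerate_haplotypes(matrix: HaplotypeMatrix, block: tuple[int, int]) -> HaplotypeSpectrum:
    """Distinct haplotype strings over columns ``block`` (inclusive indices).

    Haplotypes with any missing allele inside the block are dropped (and
    counted in ``n_dropped``); ordering is deterministic: descending
    frequency, ties broken lexicographically on the haplotype string.
    """
    start, end = block
    if not (0 <= start <= end < matrix.n_var):
        raise ValueError(f"invalid block {block} for matrix with {matrix.n_var} variants")
    sub = matrix.alleles[:, start:end + 1]
    complete = (sub != MISSING).all(axis=1)
    used = sub[complete]
    n_used = used.shape[0]
    if n_used == 0:
        raise ValueError("all haplotypes have missing data inside the block")
    strings = ["".join(map(str, row)) for row in used.astype(int)]
    uniq, counts = np.unique(strings, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda k: (-counts[k], uniq[k]))
    entries = [
        SpectrumEntry(uniq[k], int(counts[k]), counts[k] / n_used) for k in order
    ]
    return HaplotypeSpectrum(block=(start, end), entries=entries, n_used=n_used,
                             n_dropped=int(matrix.n_hap - n_used))


def derived_carrier_spectrum(spectrum: HaplotypeSpectrum, core_offset: int,
                             derived_symbol: str = "1") -> HaplotypeSpectrum:
    """Sub-spectrum of haplotypes carrying the derived allele at the core.

    ``core_offset`` indexes the core SNP within the block (0-based offset
    from block start). Frequencies are retained on the full-sample scale.
    """
    start, end = spectrum.block
    if not 0 <= core_offset <= end - start:
        raise ValueError(f"core offset {core_offset} outside block {spectrum.block}")
    entries = [e for e in spectrum.entries if e.haplotype[core_offset] == derived_symbol]
    if not entries:
        raise ValueError("no derived carriers at the core SNP")
    return HaplotypeSpectrum(block=spectrum.block, entries=entries,
                             n_used=spectrum.n_used, n_dropped=spectrum.n_dropped)


def ancestral_haplotype_fraction(sub_spectrum: HaplotypeSpectrum) -> float:
    """P': frequency share of the most frequent derived-carrying haplotype.

    The most frequent derived-carrying haplotype is taken to be the
    ancestral (founding) haplotype; P' is its frequency divided by the
    total frequency of all derived-carrying haplotypes. A tie for most
    frequent is resolved lexicographically and flagged with a warning.
    """
    if not sub_spectrum.entries:
        raise ValueError("empty derived-carrier spectrum")
    freqs = [e.frequency for e in sub_spectrum.entries]
    top = max(freqs)
    if sum(abs(f - top) < 1e-12 for f in freqs) > 1:
        warnings.warn("tie for most frequent derived haplotype; "
                      "lexicographically smallest taken as ancestral")
    return top / sum(freqs)
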