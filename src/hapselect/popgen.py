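"""Allele frequencies, pairwise F_ST and the empirical-percentile outlier rule.

Three standard two-population F_ST estimators are provided; which one a
given published table used is often unknowable, so results always carry the
estimator name. Outlier calling follows the common empirical rule: a value
is a selection signal candidate when it exceeds the 95th percentile of a
user-supplied background distribution of common-SNP F_ST values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HaplotypeMatrix

ESTIMATORS = ("hudson", "nei-gst", "weir-cockerham")

__all__ = [
    "AlleleCounts",
    "FstResult",
    "derived_allele_frequency",
    "fst_pairwise",
    "fst_outlier_rank",
    "maf_screen",
]


@dataclass(frozen=True)
class AlleleCounts:
    """Per-population derived-allele counts: population -> (derived, total)."""

    counts: dict[str, tuple[int, int]]

    def __post_init__(self):
        for pop, (d, n) in self.counts.items():
            if n <= 0:
                raise ValueError(f"{pop}: total chromosome count must be positive")
            if not 0 <= d <= n:
                raise ValueError(f"{pop}: derived count {d} outside [0, {n}]")

    def __getitem__(self, pop):
        return self.counts[pop]

    @classmethod
    def from_matrices(cls, matrices, j_by_pop) -> "AlleleCounts":
        """Count derived alleles at one variant across population matrices.

        ``matrices`` maps population label to HaplotypeMatrix; ``j_by_pop``
        is a column index or a per-population map of column indices.
        """
        out = {}
        for pop, m in matrices.items():
            j = j_by_pop[pop] if isinstance(j_by_pop, dict) else j_by_pop
            col = m.alleles[:, j]
            ok = col != -1
            out[pop] = (int(col[ok].sum()), int(ok.sum()))
        return cls(out)


@dataclass
class FstResult:
    pair: tuple[str, str]
    estimator: str
    value: float
    percentile: float | None = None
    significant: bool | None = None


def derived_allele_frequency(matrix: HaplotypeMatrix, j: int) -> float:
    """Derived count / non-missing count for column ``j``."""
    return matrix.derived_allele_frequency(j)


def _freqs(a, b):
    (d1, n1), (d2, n2) = a, b
    if n1 <= 0 or n2 <= 0:
        raise ValueError("total chromosome counts must be positive")
    return d1 / n1, d2 / n2, n1, n2


def fst_pairwise(a, b, estimator: str = "hudson", pair=("pop1", "pop2"),
                 truncate: bool = False) -> FstResult:
    """Two-population F_ST from (derived, total) chromosome counts.

    hudson
        1 - Hw/Hb with Hw the mean within-population heterozygosity
        (2 p_i q_i) and Hb = p1 q2 + p2 q1 the between-population
        heterozygosity.
    nei-gst
        (Ht - Hs)/Ht with Hs the mean within heterozygosity and
        Ht = 2 p̄ q̄ at the unweighted mean frequency.
    weir-cockerham
        The sample-size-corrected variance-components estimator (haploid
        allele-frequency form); can be slightly negative at equal sample
        frequencies by construction.

    Negative estimates are reported as computed unless ``truncate=True``.
    """
    p1, p2, n1, n2 = _freqs(a, b)
    q1, q2 = 1 - p1, 1 - p2
    if estimator == "hudson":
        hw = (2 * p1 * q1 + 2 * p2 * q2) / 2
        hb = p1 * q2 + p2 * q1
        value = 0.0 if hb == 0 else 1 - hw / hb
    elif estimator == "nei-gst":
        hs = (2 * p1 * q1 + 2 * p2 * q2) / 2
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        value = 0.0 if ht == 0 else (ht - hs) / ht
    elif estimator == "weir-cockerham":
        r = 2
        nbar = (n1 + n2) / r
        ntot = n1 + n2
        nc = (ntot - (n1 * n1 + n2 * n2) / ntot) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / ntot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a_comp = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b_comp = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        denom = a_comp + b_comp
        value = 0.0 if denom == 0 else a_comp / denom
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if truncate:
        value = max(value, 0.0)
    return FstResult(pair=tuple(pair), estimator=estimator, value=float(value))


def fst_outlier_rank(value: float, background) -> tuple[float, bool]:
    """Empirical percentile of ``value`` within a background distribution.

    Percentile counts strictly smaller background entries (ties rank
    below); the value is flagged significant when its percentile exceeds
    the 95th — the standard common-SNP outlier rule.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background distribution is empty")
    percentile = 100.0 * float((bg < value).sum()) / bg.size
    return percentile, percentile > 95.0


def maf_screen(counts: AlleleCounts, populations, threshold: float = 0.30):
    """Pooled minor-allele-frequency screen across a population subset.

    Pooling is chromosome-weighted: derived and total counts are summed
    over the requested populations before folding to the minor allele.
    Passes only on a strict ``MAF > threshold``.
    """
    der = tot = 0
    for pop in populations:
        if pop not in counts.counts:
            raise ValueError(f"population {pop!r} absent from counts")
        d, n = counts[pop]
        der += d
        tot += n
    p = der / tot
    maf = min(p, 1 - p)
    return maf, maf > threshold
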