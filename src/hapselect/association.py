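"""Genotype-hormone association stage.

Per-genotype summaries (n, mean, SD, SEM), exact pooling of summaries,
homozygote-vs-carrier two-sample tests computed from summary statistics,
Hardy-Weinberg equilibrium, and an additive (per-allele-copy) linear
regression. The default two-sample test is Welch's (unequal variances);
the pooled-variance Student test is available — group SDs in cohorts like
this differ enough that the choice matters, and both are reported by the
model object.

No multiple-testing correction is applied by default (two-sided alpha =
0.05 per comparison); an optional Bonferroni report is available on the
results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Cohort

__all__ = [
    "GroupSummary",
    "AssociationResult",
    "RegressionResult",
    "HWEResult",
    "group_summaries",
    "pool_summaries",
    "two_group_test",
    "hwe_test",
    "additive_regression",
    "homozygote_vs_carriers",
    "GenotypePhenotypeModel",
    "GenotypePhenotypeResults",
]

GENOTYPE_CLASSES = ("anc-hom", "het", "der-hom")


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD / SEM of one genotype (or pooled-carrier) group."""

    label: str
    n: int
    mean: float
    sd: float | None  # None when undefined (n == 1)

    @property
    def sem(self) -> float | None:
        return None if self.sd is None else self.sd / math.sqrt(self.n)

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"group {label!r} has no non-missing values")
        sd = float(np.std(x, ddof=1)) if x.size > 1 else None
        return cls(label=label, n=int(x.size), mean=float(x.mean()), sd=sd)


@dataclass(frozen=True)
class AssociationResult:
    comparison: tuple[str, str]
    t: float
    df: float
    p: float
    method: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p: float


def group_summaries(cohort: Cohort, variant_id: str, phenotype: str
                    ) -> dict[str, GroupSummary]:
    """Per-genotype-class summaries of a phenotype.

    Sample SD uses the n-1 denominator; classes with no phenotyped
    subjects are absent from the result (not zero-filled).
    """
    dosage = cohort.dosage(variant_id)
    values = np.asarray(cohort.data[phenotype], dtype=float)
    v = cohort.variants[variant_id]
    letter_labels = (v.ancestral * 2, v.ancestral + v.derived, v.derived * 2)
    out = {}
    for cls, (key, label) in enumerate(zip(GENOTYPE_CLASSES, letter_labels)):
        mask = dosage == cls
        vals = values[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        out[key] = GroupSummary.from_values(label, vals)
    return out


def pool_summaries(a: GroupSummary, b: GroupSummary,
                   label: str | None = None) -> GroupSummary:
    """Exact summary of the concatenation of two summarized samples.

    The combined mean is the weighted mean; the combined variance uses the
    within+between sum-of-squares decomposition with the n-1 denominator,
    so pooling summaries equals summarizing the concatenated raw values to
    machine precision.
    """
    n = a.n + b.n
    mean = (a.n * a.mean + b.n * b.mean) / n
    sa = 0.0 if a.sd is None else a.sd
    sb = 0.0 if b.sd is None else b.sd
    if a.sd is None and a.n > 1 or b.sd is None and b.n > 1:
        raise ValueError("cannot pool a multi-subject group with missing SD")
    ss = ((a.n - 1) * sa**2 + (b.n - 1) * sb**2
          + a.n * (a.mean - mean) ** 2 + b.n * (b.mean - mean) ** 2)
    sd = math.sqrt(ss / (n - 1)) if n > 1 else None
    return GroupSummary(label=label or f"{a.label}+{b.label}", n=n,
                        mean=float(mean), sd=sd)


def two_group_test(a: GroupSummary, b: GroupSummary,
                   method: str = "welch") -> AssociationResult:
    """Two-sample t-test from summary statistics only.

    ``method='welch'`` uses unequal variances with Welch-Satterthwaite
    degrees of freedom; ``method='student'`` pools the variance with
    n_a + n_b - 2 df. Two-sided p.
    """
    if a.sd is None or b.sd is None:
        raise ValueError("both groups need a defined SD (n >= 2)")
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if method not in ("welch", "student"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n,
        equal_var=(method == "student"))
    df = (a.n + b.n - 2) if method == "student" else _welch_df(a, b)
    return AssociationResult(comparison=(a.label, b.label),
                             t=float(res.statistic), df=float(df),
                             p=float(res.pvalue), method=method)


def _welch_df(a: GroupSummary, b: GroupSummary) -> float:
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    return (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))


def hwe_test(counts: tuple[int, int, int]) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df, no
    continuity correction) from (anc-hom, het, der-hom) genotype counts."""
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("no genotyped subjects")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    ok = expected > 0
    chi2 = float((((observed - expected) ** 2)[ok] / expected[ok]).sum())
    return HWEResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def additive_regression(cohort: Cohort, variant_id: str, phenotype: str
                        ) -> RegressionResult:
    """OLS of phenotype on derived-allele count (0/1/2): slope per copy,
    R^2 and the two-sided p-value for the slope."""
    x = cohort.dosage(variant_id)
    y = np.asarray(cohort.data[phenotype], dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 subjects with complete data")
    if np.ptp(x) == 0:
        raise ValueError("genotype is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue**2), p=float(res.pvalue),
                            n=int(x.size))


def homozygote_vs_carriers(cohort: Cohort, variant_id: str, phenotype: str,
                           homozygote: str = "der-hom",
                           method: str = "welch") -> AssociationResult:
    """Dominance-grouped comparison: one homozygote class against the
    pooled union of the other two genotype classes."""
    groups = group_summaries(cohort, variant_id, phenotype)
    if homozygote not in groups:
        raise ValueError(f"no subjects in class {homozygote!r}")
    others = [g for key, g in groups.items() if key != homozygote]
    if not others:
        raise ValueError("no carrier subjects to compare against")
    pooled = others[0] if len(others) == 1 else pool_summaries(*others)
    return two_group_test(groups[homozygote], pooled, method=method)


# ---------------------------------------------------------------------------
# Model / Results


class GenotypePhenotypeModel:
    """Association model for one variant across one or more phenotypes.

    ``fit`` computes, per phenotype: the per-genotype summaries, both
    homozygote-vs-carrier comparisons, and the additive regression; plus
    the Hardy-Weinberg test of the genotype counts.
    """

    def __init__(self, cohort: Cohort, variant_id: str, phenotypes=None):
        if variant_id not in cohort.variants:
            raise KeyError(f"variant {variant_id!r} not in cohort")
        self.cohort = cohort
        self.variant_id = variant_id
        self.phenotypes = list(phenotypes) if phenotypes else cohort.phenotypes

    def fit(self, method: str = "welch") -> "GenotypePhenotypeResults":
        cohort, vid = self.cohort, self.variant_id
        per_pheno = {}
        for pheno in self.phenotypes:
            groups = group_summaries(cohort, vid, pheno)
            tests = {}
            for homozygote in ("anc-hom", "der-hom"):
                try:
                    tests[homozygote] = homozygote_vs_carriers(
                        cohort, vid, pheno, homozygote=homozygote, method=method)
                except ValueError:
                    tests[homozygote] = None
            try:
                reg = additive_regression(cohort, vid, pheno)
            except ValueError:
                reg = None
            per_pheno[pheno] = {"groups": groups, "tests": tests, "regression": reg}
        hwe = hwe_test(cohort.genotype_counts(vid))
        dosage = cohort.dosage(vid)
        n_typed = int((~np.isnan(dosage)).sum())
        freq = float(np.nansum(dosage) / (2 * n_typed)) if n_typed else float("nan")
        return GenotypePhenotypeResults(
            variant_id=vid, method=method, per_phenotype=per_pheno, hwe=hwe,
            derived_freq=freq, n_typed=n_typed, model=self)


@dataclass
class GenotypePhenotypeResults:
    variant_id: str
    method: str
    per_phenotype: dict
    hwe: HWEResult
    derived_freq: float
    n_typed: int
    model: GenotypePhenotypeModel | None = None

    def bonferroni(self, alpha: float = 0.05) -> dict[str, float]:
        """Optional Bonferroni-adjusted per-comparison threshold report."""
        n_tests = sum(1 for d in self.per_phenotype.values()
                      for t in d["tests"].values() if t is not None)
        return {"n_tests": n_tests,
                "adjusted_alpha": alpha / n_tests if n_tests else float("nan")}

    def summary(self) -> str:
        lines = [
            f"Genotype-phenotype association: {self.variant_id}",
            f"derived allele frequency {self.derived_freq:.3f} "
            f"(n={self.n_typed} typed subjects)",
            f"HWE chi2={self.hwe.chi2:.3f} (df=1, p={self.hwe.p:.3f})",
            f"two-sample test: {self.method}",
            "",
        ]
        for pheno, d in self.per_phenotype.items():
            lines.append(pheno)
            for key in GENOTYPE_CLASSES:
                if key not in d["groups"]:
                    continue
                g = d["groups"][key]
                sd = f"{g.sd:.1f}" if g.sd is not None else "NA"
                lines.append(f"  {g.label:<4} {g.mean:8.2f} +- {sd:>6} [{g.n}]")
            for homozygote, t in d["tests"].items():
                if t is not None:
                    lines.append(f"  {homozygote} vs carriers: t={t.t:.3f} "
                                 f"df={t.df:.1f} p={t.p:.4f}")
            if d["regression"] is not None:
                r = d["regression"]
                lines.append(f"  additive: slope={r.slope:.3f}/copy "
                             f"R2={r.r2:.3f} p={r.p:.4f} (n={r.n})")
            lines.append("")
        return "\n".join(lines)
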