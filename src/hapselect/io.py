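"""Readers, writers and core data structures for phased haplotype panels.

The data model mirrors what haplotype-based selection scans consume: a
phased 0/1 matrix polarized to ancestral (0) / derived (1) allele states,
a monotone cumulative recombination map supporting interpolation at
arbitrary base-pair positions, and a cohort table of per-subject genotype
classes with quantitative phenotypes (serum hormone levels).

Coordinates are 1-based inclusive throughout the public surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
_BASES = frozenset("ACGT")

__all__ = [
    "MISSING",
    "Variant",
    "HaplotypeMatrix",
    "RecombinationMap",
    "Cohort",
    "read_phased_haplotypes",
    "write_phased_haplotypes",
    "read_recombination_map",
    "write_recombination_map",
    "genetic_distance",
    "read_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with ancestral/derived polarity."""

    id: str
    chrom: str
    position: int
    ancestral: str
    derived: str

    def __post_init__(self):
        anc = self.ancestral.upper()
        der = self.derived.upper()
        object.__setattr__(self, "ancestral", anc)
        object.__setattr__(self, "derived", der)
        if anc not in _BASES or der not in _BASES:
            raise ValueError(f"{self.id}: alleles must be in A/C/G/T, got {anc}/{der}")
        if anc == der:
            raise ValueError(f"{self.id}: ancestral and derived allele are identical")
        if self.position <= 0:
            raise ValueError(f"{self.id}: position must be positive (1-based)")


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes over ordered variants.

    ``alleles`` is an ``n_hap x n_var`` int8 matrix with entries
    0 (ancestral), 1 (derived) or :data:`MISSING`.
    """

    variants: list[Variant]
    alleles: np.ndarray
    population: str = ""
    skipped_records: list[tuple[str, str]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant count")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele entries must be 0, 1 or MISSING")
        pos = self.positions
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_var(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants], dtype=np.int64)

    @property
    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def index_of(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not in matrix")

    def derived_allele_frequency(self, j: int) -> float:
        """Derived count / non-missing count for column ``j``."""
        col = self.alleles[:, j]
        ok = col != MISSING
        n = int(ok.sum())
        if n == 0:
            raise ValueError(f"column {j} is entirely missing")
        return float(col[ok].sum()) / n

    def flip_polarity(self, j: int) -> "HaplotypeMatrix":
        """Return a copy with ancestral/derived swapped at column ``j``."""
        v = self.variants[j]
        variants = list(self.variants)
        variants[j] = Variant(v.id, v.chrom, v.position, v.derived, v.ancestral)
        alleles = self.alleles.copy()
        col = alleles[:, j]
        obs = col != MISSING
        col[obs] = 1 - col[obs]
        return HaplotypeMatrix(variants, alleles, self.population)


class RecombinationMap:
    """Monotone cumulative genetic map (HapMap text format).

    Parameters are parallel arrays of physical position (bp), local rate
    (cM/Mb) and cumulative map position (cM).
    """

    def __init__(self, positions, rates, cumulative_cm):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.rates = np.asarray(rates, dtype=float)
        self.cumulative_cm = np.asarray(cumulative_cm, dtype=float)
        if not (len(self.positions) == len(self.rates) == len(self.cumulative_cm)):
            raise ValueError("map columns have unequal lengths")
        if len(self.positions) < 1:
            raise ValueError("empty recombination map")
        dp = np.diff(self.positions)
        if (dp <= 0).any():
            row = int(np.argmax(dp <= 0)) + 1
            raise ValueError(f"map positions not strictly increasing at row {row}")
        dc = np.diff(self.cumulative_cm)
        if (dc < 0).any():
            row = int(np.argmax(dc < 0)) + 1
            raise ValueError(f"cumulative cM decreases at row {row}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def cumulative_at(self, pos, edge: str = "clamp") -> float:
        """Cumulative cM at ``pos`` by linear interpolation between map points.

        ``edge='clamp'`` takes the boundary cumulative value outside the map
        span; ``edge='strict'`` raises instead.
        """
        pos = float(pos)
        lo, hi = self.span
        if edge == "strict" and not (lo <= pos <= hi):
            raise ValueError(f"position {pos:.0f} outside map span [{lo}, {hi}]")
        elif edge not in ("clamp", "strict"):
            raise ValueError(f"unknown edge policy {edge!r}")
        return float(np.interp(pos, self.positions, self.cumulative_cm))


def genetic_distance(rmap: RecombinationMap, pos_a, pos_b, edge: str = "clamp") -> float:
    """Absolute genetic distance (cM) between two physical positions."""
    return abs(rmap.cumulative_at(pos_b, edge) - rmap.cumulative_at(pos_a, edge))


def read_recombination_map(path) -> RecombinationMap:
    """Read a HapMap-style recombination map (position bp, rate cM/Mb, map cM).

    Whitespace- or tab-delimited; a single header line is tolerated.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            try:
                rows.append((int(float(parts[0])), float(parts[1]), float(parts[2])))
            except (ValueError, IndexError):
                if lineno == 1 or (not rows and lineno <= 2):
                    continue  # header
                raise ValueError(f"{path}: unparseable map row at line {lineno}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    pos, rate, cm = zip(*rows)
    return RecombinationMap(pos, rate, cm)


def write_recombination_map(rmap: RecombinationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\trate_cM_Mb\tmap_cM\n")
        for p, r, c in zip(rmap.positions, rmap.rates, rmap.cumulative_cm):
            fh.write(f"{int(p)}\t{float(r)!r}\t{float(c)!r}\n")


# ---------------------------------------------------------------------------
# Phased haplotype readers


def read_phased_haplotypes(
    path,
    dialect: str = "vcf",
    legend=None,
    population: str = "",
    ancestral_tag: str = "AA",
) -> HaplotypeMatrix:
    """Read phased haplotypes into an ancestral-polarized matrix.

    dialect='vcf'
        Phased VCF with a per-record ancestral-allele INFO annotation
        (key ``ancestral_tag``, default "AA", matched case-insensitively).
        Unphased, multi-allelic, non-SNP records, and records whose
        ancestral annotation matches neither allele are skipped; the skipped
        record ids and reasons are reported on ``matrix.skipped_records``.
    dialect='hapmap-phased'
        Whitespace text with one haplotype per row and one column per SNP
        (alleles as 0/1, allele letters, or '?'/'N'/'.' for missing), plus a
        legend file (``legend=``) of id/position/ancestral/derived rows.
    """
    if dialect == "vcf":
        return _read_vcf(path, population, ancestral_tag)
    if dialect == "hapmap-phased":
        if legend is None:
            raise ValueError("hapmap-phased dialect requires legend=")
        return _read_hapmap_phased(path, legend, population)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path, population, ancestral_tag) -> HaplotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    columns, variants, skipped = [], [], []
    n_hap = None
    saw_tag = False
    for rec in vcf:
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped.append((rid, "not a biallelic SNP"))
            continue
        aa = rec.INFO.get(ancestral_tag)
        if aa is None:
            skipped.append((rid, f"no {ancestral_tag} annotation"))
            continue
        saw_tag = True
        aa = str(aa).upper()
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if aa not in (ref, alt):
            skipped.append((rid, f"ancestral allele {aa} matches neither REF nor ALT"))
            continue
        gts = rec.genotypes  # [allele_a, allele_b, phased]
        if any((len(g) > 2 and not g[2]) and g[0] >= 0 and g[1] >= 0 for g in gts):
            skipped.append((rid, "unphased genotype"))
            continue
        col = []
        for g in gts:
            for a in g[:-1]:
                col.append(MISSING if a < 0 else int(a))
        col = np.array(col, dtype=np.int8)
        if (col == MISSING).all():
            skipped.append((rid, "all genotypes missing"))
            continue
        if aa == alt:  # polarity flip: ALT is ancestral
            obs = col != MISSING
            col[obs] = 1 - col[obs]
            anc, der = alt, ref
        else:
            anc, der = ref, alt
        if n_hap is None:
            n_hap = len(col)
        variants.append(Variant(rid, rec.CHROM, rec.POS, anc, der))
        columns.append(col)
    if not saw_tag and skipped:
        raise ValueError(f"{path}: no record carries the {ancestral_tag} ancestral annotation")
    if not columns:
        raise ValueError(f"{path}: no usable phased biallelic records")
    order = np.argsort([v.position for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    alleles = np.stack([columns[i] for i in order], axis=1)
    # drop duplicate positions (strict-increase invariant)
    pos = np.array([v.position for v in variants])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    if not keep.all():
        for i in np.flatnonzero(~keep):
            skipped.append((variants[i].id, "duplicate position"))
        variants = [v for v, k in zip(variants, keep) if k]
        alleles = alleles[:, keep]
    return HaplotypeMatrix(variants, alleles, population, skipped_records=skipped)


def _read_hapmap_phased(path, legend, population) -> HaplotypeMatrix:
    variants = []
    with open(legend) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() in ("id", "rsid", "#id"):
                continue
            if len(parts) < 4:
                raise ValueError(f"{legend}: legend line {lineno} needs id/position/anc/der")
            variants.append(Variant(parts[0], "NA", int(parts[1]), parts[2], parts[3]))
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != len(variants):
                raise ValueError(
                    f"{path}: line {lineno} has {len(toks)} columns, expected {len(variants)}"
                )
            row = np.empty(len(toks), dtype=np.int8)
            for j, (tok, v) in enumerate(zip(toks, variants)):
                t = tok.upper()
                if t in ("0", v.ancestral):
                    row[j] = 0
                elif t in ("1", v.derived):
                    row[j] = 1
                elif t in ("?", "N", "."):
                    row[j] = MISSING
                else:
                    raise ValueError(
                        f"{path}: line {lineno}, column {j + 1}: token {tok!r} is not a "
                        f"phased {v.ancestral}/{v.derived} allele"
                    )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no haplotype rows")
    return HaplotypeMatrix(variants, np.stack(rows), population)


def write_phased_haplotypes(matrix: HaplotypeMatrix, hap_path, legend_path) -> None:
    """Write the hapmap-phased text dialect (0/1/? tokens plus a legend)."""
    with open(legend_path, "w") as fh:
        fh.write("id\tposition\tancestral\tderived\n")
        for v in matrix.variants:
            fh.write(f"{v.id}\t{v.position}\t{v.ancestral}\t{v.derived}\n")
    with open(hap_path, "w") as fh:
        for row in matrix.alleles:
            fh.write(" ".join("?" if a == MISSING else str(int(a)) for a in row) + "\n")


# ---------------------------------------------------------------------------
# Cohort tables

_GENOTYPE_CLASSES = ("anc-hom", "het", "der-hom")


@dataclass
class Cohort:
    """Per-subject genotype classes and quantitative phenotypes.

    ``data`` holds one row per subject; genotype columns are named by
    variant id and store raw two-letter genotypes; ``variants`` maps variant
    id to its :class:`Variant` (the source of ancestral/derived polarity).
    """

    data: pd.DataFrame
    variants: dict[str, Variant]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def phenotypes(self) -> list[str]:
        skip = set(self.variants) | {"subject_id"}
        return [c for c in self.data.columns if c not in skip]

    def dosage(self, variant_id: str) -> np.ndarray:
        """Derived-allele count per subject (0/1/2; NaN = missing)."""
        v = self.variants[variant_id]
        out = np.full(len(self.data), np.nan)
        for i, cell in enumerate(self.data[variant_id]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                continue
            out[i] = _dosage_from_letters(str(cell), v)
        return out

    def genotype_class(self, variant_id: str) -> np.ndarray:
        """Per-subject class among anc-hom/het/der-hom (object array, None missing)."""
        d = self.dosage(variant_id)
        out = np.full(len(d), None, dtype=object)
        for i, x in enumerate(d):
            if not np.isnan(x):
                out[i] = _GENOTYPE_CLASSES[int(x)]
        return out

    def genotype_counts(self, variant_id: str) -> tuple[int, int, int]:
        d = self.dosage(variant_id)
        d = d[~np.isnan(d)].astype(int)
        return tuple(int((d == k).sum()) for k in (0, 1, 2))


def _dosage_from_letters(cell: str, v: Variant) -> int:
    letters = [c for c in cell.upper() if c.isalpha()]
    if len(letters) != 2:
        raise ValueError(f"{v.id}: genotype {cell!r} is not two alleles")
    n_der = 0
    for a in letters:
        if a == v.derived:
            n_der += 1
        elif a != v.ancestral:
            raise ValueError(
                f"{v.id}: genotype {cell!r} contains allele {a}, expected "
                f"{v.ancestral}/{v.derived}"
            )
    return n_der


def read_cohort(path, variants, id_column: str = "subject_id") -> Cohort:
    """Read a cohort CSV (one genotype column per variant, hormone columns).

    ``variants`` supplies the ancestral/derived polarity used to map the
    two-letter genotype cells onto genotype classes; cells whose letters do
    not match a variant's alleles raise. Missing cells are preserved.
    """
    df = pd.read_csv(path)
    vmap = {v.id: v for v in variants}
    missing_cols = [vid for vid in vmap if vid not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing genotype columns {missing_cols}")
    if id_column not in df.columns:
        df.insert(0, "subject_id", [f"S{i + 1}" for i in range(len(df))])
    elif id_column != "subject_id":
        df = df.rename(columns={id_column: "subject_id"})
    cohort = Cohort(df, vmap)
    for vid in vmap:  # validate all genotype cells eagerly
        cohort.dosage(vid)
    for col in cohort.phenotypes:
        vals = pd.to_numeric(cohort.data[col], errors="coerce")
        if (vals.dropna() < 0).any():
            warnings.warn(f"{col}: negative phenotype values present")
        cohort.data[col] = vals
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    cohort.data.to_csv(path, index=False)
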