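"""Config-driven orchestration of the analysis stages.

A run is described by a single YAML file (paths to haplotype panels, a
recombination map and a cohort table; candidate core SNPs with their block
bounds; which stages to run; simulation constants). Stages execute in
dependency order, each writing its own TSV/JSON report into the output
directory; failures are isolated per stage and surfaced in the manifest.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .age import AlleleAgeModel
from .association import GenotypePhenotypeModel
from .ehh import ehh_profile, ihs_test
from .haplotypes import pairwise_ld
from .io import (Variant, read_cohort, read_phased_haplotypes,
                 read_recombination_map)
from .popgen import AlleleCounts, fst_pairwise

log = logging.getLogger("hapselect")

STAGES = ("fst", "ld", "ehh", "ihs", "age", "assoc")


@dataclass
class Candidate:
    id: str
    population: str
    block: tuple[str, str] | tuple[int, int] | None = None
    rho: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    n_reps: int = 10_000
    analyses: list[str] = field(default_factory=list)
    haplotypes: dict[str, dict] = field(default_factory=dict)
    recombination_map: str | None = None
    cohort: str | None = None
    variants: list[dict] = field(default_factory=list)
    candidates: list[Candidate] = field(default_factory=list)
    constants: dict = field(default_factory=dict)
    fst_estimator: str = "hudson"

    def __post_init__(self):
        if self.n_reps < 100:
            raise ValueError("n_reps must be at least 100")
        unknown = set(self.analyses) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.pop("inputs", {})
        cands = [Candidate(id=c["id"], population=c.get("population", ""),
                           block=tuple(c["block"]) if c.get("block") else None,
                           rho=float(c.get("rho", 0.0)))
                 for c in raw.pop("candidates", [])]
        return cls(seed=int(raw.get("seed", 0)),
                   n_reps=int(raw.get("n_reps", 10_000)),
                   analyses=list(raw.get("analyses", [])),
                   haplotypes=inputs.get("haplotypes", {}),
                   recombination_map=inputs.get("recombination_map"),
                   cohort=inputs.get("cohort"),
                   variants=raw.get("variants", []),
                   candidates=cands,
                   constants=raw.get("constants", {}),
                   fst_estimator=raw.get("fst_estimator", "hudson"))


def _load_haplotypes(config: RunConfig):
    mats = {}
    for pop, spec in config.haplotypes.items():
        mats[pop] = read_phased_haplotypes(
            spec["path"], dialect=spec.get("dialect", "hapmap-phased"),
            legend=spec.get("legend"), population=pop)
    return mats


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages; returns the manifest (also written as
    ``manifest.json``). Re-running with the same config and seed
    reproduces byte-identical stage reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "analyses": list(config.analyses),
        "inputs": {"haplotypes": config.haplotypes,
                   "recombination_map": config.recombination_map,
                   "cohort": config.cohort},
        "constants": dict(config.constants),
        "stages": {},
    }
    mats = rmap = None
    if any(s in config.analyses for s in ("fst", "ld", "ehh", "ihs", "age")):
        mats = _load_haplotypes(config)
    if config.recombination_map and any(s in config.analyses for s in ("age",)):
        rmap = read_recombination_map(config.recombination_map)

    for stage in STAGES:
        if stage not in config.analyses:
            continue
        try:
            path = _STAGE_FNS[stage](config, mats, rmap, out)
            manifest["stages"][stage] = {"status": "ok", "output": str(path)}
        except Exception as exc:  # stage isolation
            log.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "error", "error": f"{stage}: {exc}"}
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_fst(config, mats, rmap, out):
    rows = []
    pops = sorted(mats)
    for cand in config.candidates:
        idx = {p: mats[p].index_of(cand.id) for p in pops if _has(mats[p], cand.id)}
        counts = AlleleCounts.from_matrices(
            {p: mats[p] for p in idx}, {p: idx[p] for p in idx})
        ps = sorted(idx)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                res = fst_pairwise(counts[ps[i]], counts[ps[j]],
                                   estimator=config.fst_estimator,
                                   pair=(ps[i], ps[j]))
                rows.append((cand.id, ps[i], ps[j], res.estimator, res.value))
    path = out / "fst.tsv"
    with open(path, "w") as fh:
        fh.write("variant\tpop_a\tpop_b\testimator\tfst\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r[:4]) + f"\t{r[4]:.6f}\n")
    return path


def _has(matrix, vid):
    try:
        matrix.index_of(vid)
        return True
    except KeyError:
        return False


def _resolve_block(matrix, cand):
    if cand.block is None:
        return (0, matrix.n_var - 1)
    s, e = cand.block
    s = matrix.index_of(s) if isinstance(s, str) else int(s)
    e = matrix.index_of(e) if isinstance(e, str) else int(e)
    return (s, e)


def _stage_ld(config, mats, rmap, out):
    path = out / "ld.tsv"
    with open(path, "w") as fh:
        fh.write("candidate\tpopulation\ti\tj\tD\tD_prime\tr2\n")
        for cand in config.candidates:
            m = mats[cand.population]
            s, e = _resolve_block(m, cand)
            for i in range(s, e + 1):
                for j in range(i + 1, e + 1):
                    try:
                        ld = pairwise_ld(m, i, j)
                    except ValueError:
                        continue
                    fh.write(f"{cand.id}\t{cand.population}\t{i}\t{j}\t"
                             f"{ld.d:.6f}\t{ld.d_prime:.6f}\t{ld.r2:.6f}\n")
    return path


def _stage_ehh(config, mats, rmap, out):
    path = out / "ehh.tsv"
    with open(path, "w") as fh:
        fh.write("candidate\tpopulation\tallele\tposition\tdistance_cM\tehh\n")
        for cand in config.candidates:
            m = mats[cand.population]
            core = m.index_of(cand.id)
            for allele in ("ancestral", "derived"):
                prof = ehh_profile(m, core, allele, rmap=rmap)
                for p in prof.points:
                    d = "" if p.distance_cm is None else f"{p.distance_cm:.6f}"
                    fh.write(f"{cand.id}\t{cand.population}\t{allele}\t"
                             f"{p.position}\t{d}\t{p.ehh:.6f}\n")
    return path


def _stage_ihs(config, mats, rmap, out):
    results = {}
    for cand in config.candidates:
        m = mats[cand.population]
        res = ihs_test(m, m.index_of(cand.id), rho=cand.rho,
                       n_reps=config.n_reps, seed=config.seed, rmap=rmap)
        results[cand.id] = {
            "population": cand.population, "uihs": res.uihs,
            "ihh_ancestral": res.ihh_ancestral, "ihh_derived": res.ihh_derived,
            "units": res.units, "p_value": res.p_value,
            "significant": res.significant, "null_size": res.null_size,
            "null_quantiles": res.null_quantiles, "seed": res.seed,
        }
    path = out / "ihs.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return path


def _stage_age(config, mats, rmap, out):
    if rmap is None:
        raise ValueError("age stage requires a recombination map")
    c = config.constants
    results = {}
    for cand in config.candidates:
        m = mats[cand.population]
        model = AlleleAgeModel(
            m, rmap, cand.id, _resolve_block(m, cand),
            per_base_rate=float(c.get("per_base_rate", 1.1e-8)),
            ascertainment_prob=float(c.get("ascertainment_prob", 1e-3)),
            generation_time=float(c.get("generation_time", 25)))
        results[cand.id] = model.fit().to_dict()
        results[cand.id]["population"] = cand.population
    path = out / "age.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return path


def _stage_assoc(config, mats, rmap, out):
    if config.cohort is None:
        raise ValueError("assoc stage requires a cohort CSV")
    variants = [Variant(**v) for v in config.variants]
    cohort = read_cohort(config.cohort, variants)
    path = out / "assoc.tsv"
    with open(path, "w") as fh:
        fh.write("variant\tphenotype\tgroup\tn\tmean\tsd\tsem\t"
                 "p_vs_carriers\thwe_p\tadditive_r2\tadditive_p\n")
        for v in variants:
            res = GenotypePhenotypeModel(cohort, v.id).fit()
            for pheno, d in res.per_phenotype.items():
                reg = d["regression"]
                for key, g in d["groups"].items():
                    test = d["tests"].get(key)
                    p_cmp = f"{test.p:.4g}" if test is not None else ""
                    sd = f"{g.sd:.4g}" if g.sd is not None else ""
                    sem = f"{g.sem:.4g}" if g.sem is not None else ""
                    r2 = f"{reg.r2:.4g}" if reg else ""
                    rp = f"{reg.p:.4g}" if reg else ""
                    fh.write(f"{v.id}\t{pheno}\t{g.label}\t{g.n}\t{g.mean:.4g}\t"
                             f"{sd}\t{sem}\t{p_cmp}\t{res.hwe.p:.4g}\t{r2}\t{rp}\n")
    return path


_STAGE_FNS = {"fst": _stage_fst, "ld": _stage_ld, "ehh": _stage_ehh,
              "ihs": _stage_ihs, "age": _stage_age, "assoc": _stage_assoc}


def configure_logging(level=logging.INFO):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)
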