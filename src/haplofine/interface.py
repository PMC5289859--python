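"""File I/O, configuration and the end-to-end pipeline driver.

TSV is the interchange format between stages so every intermediate is
auditable; VCF appears only at the boundary (phased GT, one sample per
individual).  All randomness flows from a single root seed through
per-stage derived streams, and every run writes a manifest (config, seed,
package versions, stage counts) whose hash is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__, assoc, exclusion, haplo, ldstats, mediation, phaseem, synthio
from .synthio import (
    GeneratorConfig,
    HaplotypeMatrix,
    PhenotypeTable,
    VariantMap,
    load_variant_map,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF boundary


def write_phased_vcf(
    path: str | Path,
    hm: HaplotypeMatrix,
    vm: VariantMap,
    sample_ids: list[str] | None = None,
) -> None:
    """Write a phased VCF (FORMAT GT only), REF = nonrisk, ALT = risk allele."""
    n = hm.n_individuals
    samples = sample_ids or [f"I{i:06d}" for i in range(n)]
    header = pysam.VariantHeader()
    header.contigs.add(vm.chrom, length=int(vm.pos[-1]) + 10_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(len(vm)):
            row = vm.table.iloc[j]
            rec = vf.new_record(
                contig=vm.chrom,
                start=int(row["pos"]) - 1,
                id=str(row["id"]),
                alleles=(str(row["nonrisk_allele"]), str(row["risk_allele"])),
            )
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(hm.alleles[2 * i, j]), int(hm.alleles[2 * i + 1, j]))
                rec.samples[s].phased = True
            vf.write(rec)


def read_phased_vcf(path: str | Path, vm: VariantMap) -> HaplotypeMatrix:
    """Read phased GTs and map them onto risk orientation via the map.

    REF/ALT equal to nonrisk/risk reads straight through; the swapped
    orientation is flipped (logged); any other allele pair is an error.
    Unphased genotypes are an error — route them through EM phasing
    instead.  Missing variants or GTs are errors.
    """
    by_key: dict[tuple[str, int], int] = {
        (str(vm.table["chrom"].iloc[j]), int(vm.pos[j])): j for j in range(len(vm))
    }
    seen = np.zeros(len(vm), dtype=bool)
    rows: np.ndarray | None = None
    try:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            rows = np.full((2 * len(samples), len(vm)), -1, dtype=np.int8)
            for rec in vf:
                key = (str(rec.contig), int(rec.pos))
                if key not in by_key:
                    continue
                j = by_key[key]
                row = vm.table.iloc[j]
                nonrisk, risk = str(row["nonrisk_allele"]), str(row["risk_allele"])
                alts = rec.alts or ()
                if rec.ref == nonrisk and alts[:1] == (risk,):
                    flip = False
                elif rec.ref == risk and alts[:1] == (nonrisk,):
                    flip = True
                    logger.info("variant %s: REF/ALT swapped relative to map, flipping", row["id"])
                else:
                    raise ValueError(
                        f"allele mismatch at {row['id']}: VCF {rec.ref}/{alts} vs "
                        f"map {nonrisk}/{risk}"
                    )
                for i, s in enumerate(samples):
                    call = rec.samples[s]
                    gt = call["GT"]
                    if gt is None or None in gt:
                        raise ValueError(f"missing GT for sample {s} at {row['id']}")
                    if not call.phased:
                        raise ValueError(
                            f"unphased genotype for sample {s} at {row['id']}; "
                            "phase the input or use EM phasing on genotypes"
                        )
                    a, b = (1 - gt[0], 1 - gt[1]) if flip else (gt[0], gt[1])
                    rows[2 * i, j] = a
                    rows[2 * i + 1, j] = b
                seen[j] = True
    except (OSError, ValueError) as e:
        if isinstance(e, ValueError) and ("mismatch" in str(e) or "GT" in str(e) or "unphased" in str(e)):
            raise
        raise ValueError(f"failed to parse VCF {path}: {e}") from e
    if not seen.all():
        missing = [str(v) for v in vm.ids[~seen]]
        raise ValueError(f"variants missing from VCF: {missing}")
    return HaplotypeMatrix(rows)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with the published settings as
    defaults (LD filters at 0.8, 99% credible level, 0.05% haplotype
    frequency floor, alpha 0.05, 1000 bootstrap replicates, 100 phasing
    replicates)."""

    vcf: str | None = None
    phenotype: str | None = None
    variant_map: str = "table1"
    out_dir: str = "haplofine_out"
    r2_candidate: float = 0.8
    dprime_mediation: float = 0.8
    credible_level: float = 0.99
    min_hap_freq: float = 0.0005
    alpha: float = 0.05
    condscan_p: float = 5e-8
    W: float = 0.04
    n_boot: int = 1000
    phase_replicates: int = 100
    run_mediation: bool = True
    run_dosage: bool = True
    seed: int = 0
    simulate: GeneratorConfig | None = None

    def validate(self) -> None:
        for name, lo, hi in (
            ("r2_candidate", 0, 1), ("dprime_mediation", 0, 1),
            ("credible_level", 0, 1), ("min_hap_freq", 0, 1), ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name} must be in ({lo},{hi}), got {v}")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.phase_replicates < 1:
            raise ValueError("phase_replicates must be at least 1")
        if self.vcf is None and self.simulate is None:
            raise ValueError("config needs either an input VCF or a simulation block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = GeneratorConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            if sim.get("founders") is not None:
                sim["founders"] = [list(map(int, f)) for f in self.simulate.founders]
        return d

    def config_hash(self) -> str:
        """Hash of the analytic configuration (paths excluded, so runs on
        the same data and settings hash identically wherever they live)."""
        d = self.to_dict()
        for path_field in ("vcf", "phenotype", "variant_map", "out_dir"):
            d.pop(path_field, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _derive_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class PipelineResult:
    variant_map: VariantMap
    haplotypes: HaplotypeMatrix
    phenotypes: PhenotypeTable
    assoc_results: list[assoc.AssocResult]
    ppa: assoc.PPATable
    credible: assoc.CredibleSet
    candidate_ids: list[str]
    conditional_hits: list[str]
    mediation_results: list[mediation.MediationResult] | None
    haplotype_table: haplo.HaplotypeTable
    filter_result: haplo.FilterResult
    haplo_assoc: haplo.HaploAssocTable
    dosage_assoc: haplo.HaploAssocTable | None
    report: exclusion.ExclusionReport
    minimal_set: list[str]
    interval: tuple[int, int] | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis in published order.

    simulate-or-load -> single-variant scan -> PPA / credible set ->
    candidate selection (r^2 to lead above threshold, union with the
    credible set) -> stepwise conditional scan -> mediation screen ->
    haplotype enumeration / count filter / joint regression (counts, and
    optionally phase-uncertainty dosages) -> allele-on-haplotype exclusion
    -> minimal risk-associated variant set.  Writes per-stage TSVs and a
    JSON manifest under ``cfg.out_dir``.
    """
    cfg.validate()
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(cfg.seed, 4)
    stage_log: dict[str, object] = {}

    vm = load_variant_map(cfg.variant_map)
    if cfg.vcf is not None:
        hm = read_phased_vcf(cfg.vcf, vm)
        pheno = read_phenotypes(cfg.phenotype)
    else:
        sim = cfg.simulate
        sim.seed = seeds[0]
        pool = synthio.generate_haplotype_pool(vm, sim)
        hm, pheno = synthio.sample_case_control(pool, vm, sim)
    if len(pheno) != hm.n_individuals:
        raise RuntimeError("stage load: phenotype rows do not match VCF samples")
    stage_log["n_individuals"] = hm.n_individuals
    stage_log["n_variants"] = hm.n_variants

    genotypes = synthio.unphase(hm)
    y, cov = pheno.y, pheno.covariates

    results = assoc.scan_variants(genotypes, y, cov, vm)
    if not results:
        raise RuntimeError("stage assoc: no polymorphic variants to test")
    ppa = assoc.compute_ppa(results, W=cfg.W)
    credible = assoc.credible_set(ppa, level=cfg.credible_level)

    ld_ids = ldstats.ld_to_lead(hm, vm, threshold=cfg.r2_candidate, stat="r2")
    candidate_ids = [str(v) for v in vm.ids if str(v) in set(ld_ids) | set(credible.members)]
    stage_log["n_candidates"] = len(candidate_ids)

    cond_hits = assoc.conditional_scan(genotypes, y, cov, vm, p_threshold=cfg.condscan_p)
    stage_log["conditional_hits"] = cond_hits

    med_results = None
    if cfg.run_mediation:
        med_results = mediation.mediation_screen(
            genotypes, y, cov, hm, vm,
            dprime_threshold=cfg.dprime_mediation, n_boot=cfg.n_boot, seed=seeds[1],
        )
        stage_log["mediation_pairs"] = len(med_results)

    cand_idx = [vm.index_of(v) for v in candidate_ids]
    table = haplo.enumerate_haplotypes(hm, cand_idx, case_status=y)
    min_count = haplo.min_count_threshold(hm.n_individuals, cfg.min_hap_freq)
    filt = haplo.filter_haplotypes(table, min_count)
    stage_log["haplotypes_total"] = len(table)
    stage_log["haplotypes_retained"] = len(filt.retained)
    stage_log["individuals_excluded"] = int(filt.excluded_individuals.sum())
    keep = ~filt.excluded_individuals
    hassoc = haplo.haplotype_regression(
        filt.retained, y, cov, reference="H0", alpha=cfg.alpha, include_individuals=keep
    )

    dassoc = None
    if cfg.run_dosage:
        posterior = phaseem.em_phase(genotypes[:, cand_idx])
        reps = phaseem.sample_phasing_replicates(posterior, R=cfg.phase_replicates, seed=seeds[2])
        dm = phaseem.haplotype_dosages(reps, filt.retained.haplotypes, labels=filt.retained.labels)
        dassoc = haplo.dosage_regression(dm, y, cov, reference="H0", alpha=cfg.alpha)

    report = exclusion.exclude_variants(filt.retained, hassoc, variant_ids=candidate_ids)
    minimal, interval = exclusion.minimal_risk_set(report, vm)
    stage_log["n_retained"] = len(minimal)

    manifest = {
        "package": "haplofine",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": stage_log,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    result = PipelineResult(
        variant_map=vm, haplotypes=hm, phenotypes=pheno, assoc_results=results,
        ppa=ppa, credible=credible, candidate_ids=candidate_ids,
        conditional_hits=cond_hits, mediation_results=med_results,
        haplotype_table=table, filter_result=filt, haplo_assoc=hassoc,
        dosage_assoc=dassoc, report=report, minimal_set=minimal,
        interval=interval, manifest=manifest,
    )
    _write_outputs(result, out, cfg)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline done: %d candidates -> %d retained", len(candidate_ids), len(minimal))
    return result


def _header_comment(cfg: PipelineConfig) -> str:
    return f"# haplofine {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(cfg))
        df.to_csv(fh, sep="\t", index=False)


def _write_outputs(res: PipelineResult, out: Path, cfg: PipelineConfig) -> None:
    vm = res.variant_map
    ppa_map = dict(zip(res.ppa.variant_ids, res.ppa.ppa))
    arec = []
    for r in res.assoc_results:
        lo, hi = r.ci95
        arec.append(
            {
                "id": r.variant_id, "pos": r.pos, "beta": r.beta, "se": r.se,
                "Z": r.Z, "OR": r.OR, "ci_lo": lo, "ci_hi": hi,
                "neglog10p": r.neglog10p, "ppa": ppa_map.get(r.variant_id, np.nan),
            }
        )
    _write_tsv(pd.DataFrame(arec), out / "assoc.tsv", cfg)
    _write_tsv(
        pd.DataFrame({"id": res.credible.members, "cum_ppa": res.credible.cumulative_ppa}),
        out / "credset.tsv", cfg,
    )
    if res.mediation_results is not None:
        mrec = [
            {
                "v1": r.pair[0], "v2": r.pair[1], "beta_unadj": r.beta_unadj,
                "beta_adj": r.beta_adj, "delta": r.delta, "p_boot": r.p_boot,
                "q": r.q, "n_boot": r.n_boot, "flagged": r.flagged or "",
            }
            for r in res.mediation_results
        ]
        _write_tsv(pd.DataFrame(mrec), out / "mediation.tsv", cfg)
    hf = res.filter_result.retained.to_frame()
    cls = res.haplo_assoc.to_frame()
    _write_tsv(hf.merge(cls, on="label", how="left"), out / "haplo.tsv", cfg)
    if res.dosage_assoc is not None:
        _write_tsv(res.dosage_assoc.to_frame(), out / "haplo_dosage.tsv", cfg)
    erec = []
    for vid, excl, ev in zip(res.report.variant_ids, res.report.excluded, res.report.evidence):
        erec.append(
            {
                "id": vid,
                "pos": int(vm.pos[vm.index_of(vid)]),
                "excluded": int(excl),
                "rules": ";".join(sorted({e.rule for e in ev})),
                "evidence_haplotypes": ";".join(e.haplotype for e in ev),
                "evidence_counts": ";".join(str(e.haplotype_count) for e in ev),
            }
        )
    _write_tsv(pd.DataFrame(erec), out / "exclusion.tsv", cfg)
    _write_tsv(
        pd.DataFrame({"id": res.minimal_set,
                      "pos": [int(vm.pos[vm.index_of(v)]) for v in res.minimal_set]}),
        out / "minimal_set.tsv", cfg,
    )
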