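"""Synthetic phased case-control data for a strong-LD locus.

The generator emulates the haplotype structure that recombinant-haplotype
fine-mapping exploits: two founder haplotypes (one carrying the nonrisk
allele at every candidate variant, one carrying every risk allele), a small
admixture of single-crossover recombinants between them, a logistic disease
model with one causal variant, and nuisance covariates (a DNA-preparation
batch flag and two ancestry principal components).

Allele coding is risk-oriented throughout: 1 means the risk allele of the
variant map, 0 the nonrisk allele.  This is deliberate — every downstream
rule (haplotype labels, the exclusion rule) is stated in risk/nonrisk terms,
so the coordinate frame is fixed here once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

REQUIRED_MAP_COLUMNS = ("chrom", "pos", "id", "nonrisk_allele", "risk_allele")

_FIXTURES = {"table1": "table1.tsv"}


class VariantMap:
    """Ordered locus variants with risk-allele orientation.

    Wraps a DataFrame with columns ``chrom, pos, id, nonrisk_allele,
    risk_allele, annotation, lead`` (plus any auxiliary columns such as the
    published per-variant statistics in the packaged fixture).  Positions are
    1-based and strictly increasing; exactly one variant carries the lead
    flag.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.reset_index(drop=True).copy()
        for col in REQUIRED_MAP_COLUMNS:
            if col not in table.columns:
                raise ValueError(f"variant map missing required column {col!r}")
        if "annotation" not in table.columns:
            table["annotation"] = ""
        if "lead" not in table.columns:
            raise ValueError("variant map missing lead flag column")
        table["pos"] = table["pos"].astype(np.int64)
        table["lead"] = table["lead"].astype(int)
        pos = table["pos"].to_numpy()
        if len(table) == 0:
            raise ValueError("variant map is empty")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("variant positions must be strictly increasing (no duplicates)")
        for _, row in table.iterrows():
            a, b = str(row["nonrisk_allele"]), str(row["risk_allele"])
            if not a or not b or a == b:
                raise ValueError(f"invalid allele pair for {row['id']}: {a!r}/{b!r}")
        n_lead = int(table["lead"].sum())
        if n_lead != 1:
            raise ValueError(f"variant map must flag exactly one lead variant (found {n_lead})")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chrom(self) -> str:
        return str(self.table["chrom"].iloc[0])

    @property
    def lead_index(self) -> int:
        return int(np.flatnonzero(self.table["lead"].to_numpy())[0])

    @property
    def lead_id(self) -> str:
        return str(self.table["id"].iloc[self.lead_index])

    def index_of(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.ids == variant_id)
        if len(hits) == 0:
            raise KeyError(f"variant {variant_id!r} not in map")
        return int(hits[0])

    def subset(self, indices: Sequence[int]) -> "VariantMap":
        """Restrict to the given variant indices (genomic order preserved).

        The lead flag is kept if the lead is among the indices; otherwise the
        first retained variant is flagged so the result is still a valid map.
        """
        idx = sorted(int(i) for i in indices)
        sub = self.table.iloc[idx].reset_index(drop=True).copy()
        if sub["lead"].sum() != 1:
            sub["lead"] = 0
            sub.loc[0, "lead"] = 1
        return VariantMap(sub)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_variant_map(source: str | Path) -> VariantMap:
    """Load a variant map from a TSV path or a packaged fixture name.

    The fixture ``"table1"`` holds the 25 published candidate variants of the
    ARMS2/HTRA1 locus with their printed association statistics (-log10 P,
    posterior probability of association, R^2 and D' to the lead variant,
    odds ratio with 95% CI) and exclusion status as auxiliary columns.
    """
    if isinstance(source, str) and source in _FIXTURES:
        ref = resources.files("haplofine.data").joinpath(_FIXTURES[source])
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", dtype={"chrom": str, "id": str})
    else:
        table = pd.read_csv(source, sep="\t", dtype={"chrom": str, "id": str})
    return VariantMap(table)


@dataclass
class HaplotypeMatrix:
    """Phased chromosomes-by-variants binary allele matrix.

    Rows 2i and 2i+1 are the two chromosomes of individual i; entries are 0
    (nonrisk allele) or 1 (risk allele), columns in variant-map order.
    """

    alleles: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=np.int8)
        if a.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        if a.shape[0] % 2 != 0:
            raise ValueError("allele matrix must have an even number of chromosome rows")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("allele entries must be 0 or 1")
        self.alleles = a

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def individual(self, i: int) -> np.ndarray:
        return self.alleles[2 * i : 2 * i + 2]


@dataclass
class PhenotypeTable:
    """Per-individual phenotype and covariates, aligned to a HaplotypeMatrix."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("iid", "y", "WGA", "PC1", "PC2"):
            if col not in self.table.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        y = self.table["y"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("case-control status must be 0/1")

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=np.int8)

    @property
    def covariates(self) -> np.ndarray:
        """The standard adjustment set: WGA batch flag, PC1, PC2."""
        return self.table[["WGA", "PC1", "PC2"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic locus and disease model.

    Founders default to the all-nonrisk and all-risk haplotypes; their
    frequencies default to 0.7 / 0.3 (risk-haplotype frequency 0.3).
    ``recomb_rate`` is the per-chromosome probability that the drawn
    haplotype is a single-crossover recombinant between two founders
    (default 0.02 total recombinant mass).  The disease model is logistic:
    logit P(case) = beta0 + beta_causal * x_causal + WGA/PC terms, with
    beta_causal defaulting to ln(2.787) at the locus lead and beta0 set for
    a baseline prevalence of roughly 5%.
    """

    founders: list[np.ndarray] | None = None
    founder_freqs: Sequence[float] = (0.7, 0.3)
    recomb_rate: float = 0.02
    causal_variant: str = "rs10490924"
    beta_causal: float = math.log(2.787)
    beta0: float = math.log(0.05 / 0.95)
    wga_frac: float = 0.2
    beta_wga: float = 0.2
    beta_pc1: float = 0.1
    beta_pc2: float = 0.1
    pc_sd: float = 1.0
    n_cases: int = 1000
    n_controls: int = 1000
    seed: int = 0
    max_batches: int = 2000
    batch_size: int = 20000

    def validate(self, n_variants: int) -> None:
        if not (0.0 <= self.recomb_rate <= 1.0):
            raise ValueError(f"recomb_rate must be in [0,1], got {self.recomb_rate}")
        freqs = np.asarray(self.founder_freqs, dtype=float)
        if freqs.min() < 0 or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("founder_freqs must be nonnegative and sum to 1")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control quotas must be positive")
        if not math.isfinite(self.beta_causal):
            raise ValueError("beta_causal must be finite")
        founders = self.resolved_founders(n_variants)
        if len(founders) != len(freqs):
            raise ValueError("founders and founder_freqs lengths differ")
        for f in founders:
            if f.shape != (n_variants,) or not np.isin(f, (0, 1)).all():
                raise ValueError("founder haplotypes must be binary vectors of map length")

    def resolved_founders(self, n_variants: int) -> list[np.ndarray]:
        if self.founders is None:
            return [np.zeros(n_variants, dtype=np.int8), np.ones(n_variants, dtype=np.int8)]
        return [np.asarray(f, dtype=np.int8) for f in self.founders]


@dataclass
class HaplotypePool:
    """Enumerable haplotype distribution: founders plus single-crossover recombinants."""

    haplotypes: np.ndarray  # K x M, binary
    freqs: np.ndarray  # K, sums to 1

    def __post_init__(self) -> None:
        assert abs(float(self.freqs.sum()) - 1.0) < 1e-9

    def __len__(self) -> int:
        return self.haplotypes.shape[0]


def generate_haplotype_pool(vm: VariantMap, cfg: GeneratorConfig) -> HaplotypePool:
    """Enumerate the haplotype pool implied by the generator configuration.

    A chromosome is a founder draw with probability 1 - recomb_rate; with
    probability recomb_rate it is a crossover product: two founders are drawn
    independently from the founder frequencies and joined at a breakpoint
    chosen uniformly among the M-1 inter-variant intervals (prefix from the
    first founder, suffix from the second).  Frequencies are computed
    analytically, so the pool is fully deterministic.
    """
    m = len(vm)
    cfg.validate(m)
    founders = cfg.resolved_founders(m)
    freqs = np.asarray(cfg.founder_freqs, dtype=float)
    r = float(cfg.recomb_rate)

    acc: dict[bytes, float] = {}

    def add(vec: np.ndarray, p: float) -> None:
        if p <= 0:
            return
        key = vec.tobytes()
        acc[key] = acc.get(key, 0.0) + p

    for f, p in zip(founders, freqs):
        add(f, (1.0 - r) * p)
    if r > 0 and m > 1:
        per_break = r / (m - 1)
        for fa, pa in zip(founders, freqs):
            for fb, pb in zip(founders, freqs):
                for k in range(1, m):
                    add(np.concatenate([fa[:k], fb[k:]]), per_break * pa * pb)
    elif r > 0:  # single-variant map: no crossover interval exists
        for f, p in zip(founders, freqs):
            add(f, r * p)

    haps = np.array([np.frombuffer(k, dtype=np.int8) for k in acc], dtype=np.int8)
    fr = np.array(list(acc.values()), dtype=float)
    order = np.lexsort(haps.T[::-1])  # deterministic order
    return HaplotypePool(haplotypes=haps[order], freqs=fr[order])


def sample_case_control(
    pool: HaplotypePool, vm: VariantMap, cfg: GeneratorConfig
) -> tuple[HaplotypeMatrix, PhenotypeTable]:
    """Quota-sample a case-control study from the population model.

    Individuals are drawn as two independent pool haplotypes; disease status
    follows the logistic model; sampling continues (rejection against the
    quotas) until ``n_cases`` cases and ``n_controls`` controls are
    collected.  Because the disease model is logistic, outcome-dependent
    sampling leaves all per-allele odds ratios intact.  Deterministic given
    the config seed.
    """
    cfg.validate(len(vm))
    causal = vm.index_of(cfg.causal_variant)
    rng = np.random.default_rng(cfg.seed)

    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    kept_rows: list[np.ndarray] = []
    kept_pheno: list[np.ndarray] = []

    for _ in range(cfg.max_batches):
        if need_cases <= 0 and need_controls <= 0:
            break
        b = cfg.batch_size
        hap_idx = rng.choice(len(pool), size=(b, 2), p=pool.freqs)
        h1 = pool.haplotypes[hap_idx[:, 0]]
        h2 = pool.haplotypes[hap_idx[:, 1]]
        x = (h1[:, causal] + h2[:, causal]).astype(float)
        wga = (rng.random(b) < cfg.wga_frac).astype(float)
        pc1 = rng.standard_normal(b) * cfg.pc_sd
        pc2 = rng.standard_normal(b) * cfg.pc_sd
        eta = (
            cfg.beta0
            + cfg.beta_causal * x
            + cfg.beta_wga * wga
            + cfg.beta_pc1 * pc1
            + cfg.beta_pc2 * pc2
        )
        y = (rng.random(b) < expit(eta)).astype(np.int8)
        for i in range(b):
            if y[i] == 1 and need_cases > 0:
                need_cases -= 1
            elif y[i] == 0 and need_controls > 0:
                need_controls -= 1
            else:
                continue
            kept_rows.append(h1[i])
            kept_rows.append(h2[i])
            kept_pheno.append(np.array([y[i], wga[i], pc1[i], pc2[i]]))
        if need_cases <= 0 and need_controls <= 0:
            break
    else:
        raise RuntimeError(
            "case-control quotas unreachable: after "
            f"{cfg.max_batches * cfg.batch_size} draws still missing "
            f"{need_cases} cases and {need_controls} controls; "
            "check beta0/beta_causal for a degenerate disease model"
        )
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError(
            f"case-control quotas unreachable within the attempt cap "
            f"({cfg.max_batches} batches of {cfg.batch_size}); "
            f"missing {need_cases} cases and {need_controls} controls"
        )

    hm = HaplotypeMatrix(np.vstack(kept_rows))
    ph = np.vstack(kept_pheno)
    n = hm.n_individuals
    pheno = pd.DataFrame(
        {
            "iid": [f"I{i:06d}" for i in range(n)],
            "y": ph[:, 0].astype(int),
            "WGA": ph[:, 1].astype(int),
            "PC1": ph[:, 2],
            "PC2": ph[:, 3],
        }
    )
    logger.info("sampled %d cases and %d controls", cfg.n_cases, cfg.n_controls)
    return hm, PhenotypeTable(pheno)


def unphase(hm: HaplotypeMatrix) -> np.ndarray:
    """Collapse a phased matrix to an N x M genotype matrix (0/1/2 risk-allele counts)."""
    a = hm.alleles
    return (a[0::2] + a[1::2]).astype(np.int8)
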