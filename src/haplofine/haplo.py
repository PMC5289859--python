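"""Best-guess haplotype enumeration, count filtering, and haplotype
logistic regression against the all-nonrisk reference.

The central model is a single multivariable logistic regression of
case-control status on the per-individual copy counts (or fractional
dosages) of every retained haplotype except the reference H0, which
carries exclusively nonrisk alleles.  Each non-reference haplotype's odds
ratio is therefore measured against chromosomes carrying H0, which is what
the downstream allele-on-haplotype exclusion rule needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import RankDeficientError, fit_logistic, neglog10_p_from_z, safe_exp
from .phaseem import DosageMatrix
from .synthio import HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over the candidate variants with counts and
    per-group chromosome frequencies.

    Labels are deterministic: haplotypes sorted by ascending risk-allele
    count, ties by lexicographic order of the allele vector, and named
    H0, H1, ... — so the all-nonrisk haplotype, when observed, is always H0.
    """

    haplotypes: np.ndarray  # K x M over candidate variants
    labels: list[str]
    counts: np.ndarray  # chromosome counts, sum = 2N
    freq_cases: np.ndarray
    freq_controls: np.ndarray
    chrom_assignment: np.ndarray  # 2N -> row index into haplotypes

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_individuals(self) -> int:
        return len(self.chrom_assignment) // 2

    def label_index(self, label: str) -> int:
        return self.labels.index(label)

    def allele_strings(self) -> list[str]:
        return ["".join(map(str, h)) for h in self.haplotypes]

    def copy_counts(self) -> np.ndarray:
        """N x K matrix of per-individual haplotype copy counts (0/1/2)."""
        n, k = self.n_individuals, len(self)
        cc = np.zeros((n, k), dtype=np.int8)
        for i in range(n):
            for a in (self.chrom_assignment[2 * i], self.chrom_assignment[2 * i + 1]):
                if a >= 0:  # -1 marks chromosomes of filtered-out haplotypes
                    cc[i, a] += 1
        return cc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "allele_string": self.allele_strings(),
                "N": self.counts,
                "freq_cases": self.freq_cases,
                "freq_controls": self.freq_controls,
            }
        )


def enumerate_haplotypes(
    hm: HaplotypeMatrix,
    candidate_idx: np.ndarray | list[int] | None = None,
    case_status: np.ndarray | None = None,
) -> HaplotypeTable:
    """Distinct allele vectors over the candidate columns, with counts.

    ``case_status`` (one entry per individual) yields chromosome
    frequencies within case and control groups; without it both frequency
    columns are overall frequencies.
    """
    cols = np.asarray(candidate_idx, dtype=int) if candidate_idx is not None else np.arange(hm.n_variants)
    sub = hm.alleles[:, cols]
    uniq, inverse, counts = np.unique(sub, axis=0, return_inverse=True, return_counts=True)
    # deterministic labelling: ascending risk count, then lexicographic
    order = sorted(range(len(uniq)), key=lambda k: (int(uniq[k].sum()), tuple(uniq[k])))
    rank = np.empty(len(uniq), dtype=int)
    for new, old in enumerate(order):
        rank[old] = new
    uniq = uniq[order]
    counts = counts[order]
    assignment = rank[inverse]

    n_chrom = sub.shape[0]
    if case_status is not None:
        y = np.repeat(np.asarray(case_status, dtype=int), 2)
        case_counts = np.bincount(assignment[y == 1], minlength=len(uniq))
        ctrl_counts = np.bincount(assignment[y == 0], minlength=len(uniq))
        freq_cases = case_counts / max(int((y == 1).sum()), 1)
        freq_controls = ctrl_counts / max(int((y == 0).sum()), 1)
    else:
        freq_cases = freq_controls = counts / n_chrom
    return HaplotypeTable(
        haplotypes=uniq.astype(np.int8),
        labels=[f"H{k}" for k in range(len(uniq))],
        counts=counts,
        freq_cases=np.asarray(freq_cases, dtype=float),
        freq_controls=np.asarray(freq_controls, dtype=float),
        chrom_assignment=assignment,
    )


def min_count_threshold(n_individuals: int, f_min: float) -> int:
    """Smallest chromosome count c with c / (2 n) >= f_min."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if not (0.0 < f_min < 1.0):
        raise ValueError(f"f_min must be in (0,1), got {f_min}")
    # tolerate float representation fuzz in f_min (e.g. 0.05 * 2000)
    return max(1, math.ceil(2 * n_individuals * f_min - 1e-9))


@dataclass
class FilterResult:
    retained: HaplotypeTable
    dropped_labels: list[str]
    excluded_individuals: np.ndarray  # bool mask, True = carries a dropped haplotype
    pooled_label: str | None = None


def filter_haplotypes(
    table: HaplotypeTable,
    min_count: int,
    reference: str = "H0",
    mode: str = "exclude",
) -> FilterResult:
    """Drop haplotypes observed fewer than ``min_count`` times.

    ``mode='exclude'`` (default) marks individuals carrying any dropped
    haplotype for exclusion from the count-based regression;
    ``mode='pool'`` instead collapses all dropped haplotypes into a single
    pooled class that stays in the design.  The reference haplotype must
    itself survive the filter.
    """
    if min_count < 1:
        raise ValueError("min_count must be at least 1")
    if mode not in ("exclude", "pool"):
        raise ValueError(f"mode must be 'exclude' or 'pool', got {mode!r}")
    keep = table.counts >= min_count
    ref_idx = table.label_index(reference)
    if not keep[ref_idx]:
        raise ValueError(
            f"reference haplotype {reference} has count {table.counts[ref_idx]} "
            f"below min_count={min_count}; the baseline must be estimable"
        )
    dropped = [table.labels[k] for k in np.flatnonzero(~keep)]
    if not dropped:
        return FilterResult(
            retained=table,
            dropped_labels=[],
            excluded_individuals=np.zeros(table.n_individuals, dtype=bool),
        )

    old_to_new = -np.ones(len(table), dtype=int)
    kept_idx = np.flatnonzero(keep)
    for new, old in enumerate(kept_idx):
        old_to_new[old] = new
    carries_dropped = np.zeros(table.n_individuals, dtype=bool)
    assign = table.chrom_assignment.copy()
    if mode == "pool":
        pool_row = len(kept_idx)
        new_assign = np.where(keep[assign], old_to_new[assign], pool_row)
        pooled_count = int((~keep[assign]).sum())
        haps = np.vstack([table.haplotypes[kept_idx], -np.ones((1, table.haplotypes.shape[1]), dtype=np.int8)])
        counts = np.concatenate([table.counts[kept_idx], [pooled_count]])
        fc = np.concatenate([table.freq_cases[kept_idx], [table.freq_cases[~keep].sum()]])
        fo = np.concatenate([table.freq_controls[kept_idx], [table.freq_controls[~keep].sum()]])
        labels = [table.labels[k] for k in kept_idx] + ["Hpool"]
        retained = HaplotypeTable(haps, labels, counts, fc, fo, new_assign)
        logger.info("pooled %d rare haplotypes (%d chromosomes) into Hpool", len(dropped), pooled_count)
        return FilterResult(retained, dropped, carries_dropped, pooled_label="Hpool")

    chrom_dropped = ~keep[assign]
    carries_dropped = chrom_dropped.reshape(-1, 2).any(axis=1)
    retained = HaplotypeTable(
        haplotypes=table.haplotypes[kept_idx],
        labels=[table.labels[k] for k in kept_idx],
        counts=table.counts[kept_idx],
        freq_cases=table.freq_cases[kept_idx],
        freq_controls=table.freq_controls[kept_idx],
        chrom_assignment=old_to_new[assign],  # rows of excluded carriers contain -1
    )
    logger.info(
        "dropped %d rare haplotypes; %d carrier individuals excluded from the count-based fit",
        len(dropped),
        int(carries_dropped.sum()),
    )
    return FilterResult(retained, dropped, carries_dropped)


@dataclass
class HaploAssocRow:
    label: str
    beta: float
    se: float
    cls: str  # risk / protective / null / reference

    @property
    def OR(self) -> float:
        return safe_exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (safe_exp(self.beta - 1.96 * self.se), safe_exp(self.beta + 1.96 * self.se))

    @property
    def Z(self) -> float:
        return self.beta / self.se

    @property
    def neglog10p(self) -> float:
        return neglog10_p_from_z(self.Z)

    @property
    def p(self) -> float:
        return min(max(10.0 ** (-self.neglog10p), 5e-324), 1.0)


@dataclass
class HaploAssocTable:
    """Joint haplotype regression results with risk/protective/null classes."""

    rows: list[HaploAssocRow]
    reference: str
    alpha: float

    def classes(self) -> dict[str, str]:
        return {r.label: r.cls for r in self.rows}

    def row(self, label: str) -> HaploAssocRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            if r.cls == "reference":
                recs.append({"label": r.label, "class": "reference"})
            else:
                lo, hi = r.ci95
                recs.append(
                    {
                        "label": r.label, "beta": r.beta, "se": r.se, "OR": r.OR,
                        "ci_lo": lo, "ci_hi": hi, "neglog10p": r.neglog10p, "class": r.cls,
                    }
                )
        return pd.DataFrame(recs)


def _classify(beta: float, p: float, alpha: float) -> str:
    if p > alpha:
        return "null"
    return "risk" if beta > 0 else "protective"


def _joint_fit(
    design_cols: list[np.ndarray],
    names: list[str],
    y: np.ndarray,
    covariates: np.ndarray | None,
    reference: str,
    alpha: float,
) -> HaploAssocTable:
    n = len(y)
    cols = [np.ones(n)] + design_cols
    all_names = ["intercept"] + names
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        for k in range(cov.shape[1]):
            cols.append(cov[:, k])
            all_names.append(f"cov{k}")
    X = np.column_stack(cols)
    try:
        fit = fit_logistic(X, y, column_names=all_names)
    except RankDeficientError as e:
        if any(name in names for name in e.columns):
            raise RankDeficientError(e.columns) from ValueError(
                "haplotype copy columns are collinear; ensure the reference "
                "haplotype's column is omitted from the design"
            )
        raise
    rows = [HaploAssocRow(label=reference, beta=0.0, se=float("nan"), cls="reference")]
    for k, name in enumerate(names, start=1):
        beta, se = float(fit.beta[k]), float(fit.se[k])
        row = HaploAssocRow(label=name, beta=beta, se=se, cls="")
        row.cls = _classify(beta, row.p, alpha)
        rows.append(row)
    return HaploAssocTable(rows=rows, reference=reference, alpha=alpha)


def haplotype_regression(
    table: HaplotypeTable,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    reference: str = "H0",
    alpha: float = 0.05,
    include_individuals: np.ndarray | None = None,
) -> HaploAssocTable:
    """One joint logistic fit of status on per-individual copy counts of
    every non-reference haplotype (plus covariates).

    ``include_individuals`` restricts the fit (e.g. to non-carriers of
    dropped haplotypes after filtering).  Classes at level ``alpha``:
    risk if OR > 1 and p <= alpha, protective if OR < 1 and p <= alpha,
    null otherwise.
    """
    if reference not in table.labels:
        raise ValueError(f"reference haplotype {reference!r} not present")
    cc = table.copy_counts()
    y = np.asarray(y, dtype=float)
    mask = np.ones(len(y), dtype=bool) if include_individuals is None else np.asarray(include_individuals, bool)
    ref_idx = table.label_index(reference)
    names = [lab for k, lab in enumerate(table.labels) if k != ref_idx]
    design = [cc[mask, k].astype(float) for k in range(len(table)) if k != ref_idx]
    cov = np.asarray(covariates, float)[mask] if covariates is not None else None
    return _joint_fit(design, names, y[mask], cov, reference, alpha)


def dosage_regression(
    dm: DosageMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    reference: str = "H0",
    alpha: float = 0.05,
) -> HaploAssocTable:
    """Haplotype regression on fractional dosages from repeated phasing.

    Identical model to :func:`haplotype_regression` with the integer copy
    counts replaced by per-individual dosages in [0, 2]; the reference
    haplotype's dosage column is omitted.
    """
    if dm.labels is None:
        raise ValueError("DosageMatrix must carry haplotype labels")
    conservation = dm.d.sum(axis=1) + dm.unmapped_mass
    if np.max(np.abs(conservation - 2.0)) > 1e-9:
        raise ValueError("dosage conservation violated: rows must sum to 2 incl. unmapped mass")
    if reference not in dm.labels:
        raise ValueError(f"reference haplotype {reference!r} not present")
    ref_idx = dm.labels.index(reference)
    names = [lab for k, lab in enumerate(dm.labels) if k != ref_idx]
    design = [dm.d[:, k] for k in range(dm.d.shape[1]) if k != ref_idx]
    cov = np.asarray(covariates, float) if covariates is not None else None
    return _joint_fit(design, names, np.asarray(y, float), cov, reference, alpha)
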