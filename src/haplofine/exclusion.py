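"""Allele-on-haplotype exclusion: the locus-narrowing inference.

A candidate variant cannot be driving the disease association if the
haplotype-level evidence is discordant with it:

* its nonrisk allele rides on a haplotype classified as risk-increasing
  (rule ``nonrisk-on-risk``) — a haplotype can raise risk without the
  variant's risk allele, or
* its risk allele rides on a protective or non-associated haplotype
  (rule ``risk-on-nonassociated``) — the risk allele can be present
  without raising risk.

Variants triggering neither rule form the minimal set of risk-associated
variants.  The reference haplotype (the all-nonrisk baseline the classes
are measured against) never contributes evidence.  A "null" class can
reflect nothing more than low haplotype count, so each evidence entry
carries the haplotype's chromosome count for power auditing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .haplo import HaploAssocTable, HaplotypeTable
from .synthio import VariantMap

logger = logging.getLogger(__name__)

RULE_NONRISK_ON_RISK = "nonrisk-on-risk"
RULE_RISK_ON_NONASSOC = "risk-on-nonassociated"


@dataclass
class Evidence:
    haplotype: str
    haplotype_class: str  # risk / protective / null
    allele: str  # "risk" or "nonrisk" allele carried by the haplotype
    rule: str
    haplotype_count: int | None = None


@dataclass
class ExclusionReport:
    variant_ids: list[str]
    excluded: np.ndarray  # bool per variant
    evidence: list[list[Evidence]] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        return [v for v, x in zip(self.variant_ids, self.excluded) if not x]

    @property
    def excluded_ids(self) -> list[str]:
        return [v for v, x in zip(self.variant_ids, self.excluded) if x]


def exclude_variants(
    haplotypes: np.ndarray | HaplotypeTable,
    classes: list[str] | HaploAssocTable,
    variant_ids: list[str] | None = None,
    counts: np.ndarray | None = None,
) -> ExclusionReport:
    """Apply the allele-on-haplotype exclusion rule.

    ``haplotypes`` is a K x M binary matrix (or a HaplotypeTable) and
    ``classes`` a per-haplotype class list (or the HaploAssocTable from the
    joint regression), with classes in {risk, protective, null, reference}.
    Reference haplotypes are skipped.  A variant is excluded iff at least
    one non-reference haplotype triggers a rule; every trigger is recorded.
    """
    if isinstance(haplotypes, HaplotypeTable):
        table = haplotypes
        hap_matrix = table.haplotypes
        labels = table.labels
        if counts is None:
            counts = table.counts
    else:
        hap_matrix = np.asarray(haplotypes, dtype=int)
        labels = [f"H{k}" for k in range(hap_matrix.shape[0])]
        table = None
    if isinstance(classes, HaploAssocTable):
        cls_map = classes.classes()
        cls_list = []
        for lab in labels:
            if lab not in cls_map:
                raise ValueError(f"haplotype {lab} present in the table but unclassified")
            cls_list.append(cls_map[lab])
    else:
        cls_list = list(classes)
        if len(cls_list) != hap_matrix.shape[0]:
            raise ValueError("one class per haplotype required")
    for c in cls_list:
        if c not in ("risk", "protective", "null", "reference"):
            raise ValueError(f"unknown haplotype class {c!r}")

    m = hap_matrix.shape[1]
    ids = list(variant_ids) if variant_ids is not None else [f"v{j}" for j in range(m)]
    excluded = np.zeros(m, dtype=bool)
    evidence: list[list[Evidence]] = [[] for _ in range(m)]
    for k, (hap, cls) in enumerate(zip(hap_matrix, cls_list)):
        if cls == "reference":
            continue
        if np.any(hap < 0):  # pooled pseudo-haplotype carries no allele information
            continue
        cnt = int(counts[k]) if counts is not None else None
        for j in range(m):
            carries_risk = hap[j] == 1
            if not carries_risk and cls == "risk":
                excluded[j] = True
                evidence[j].append(
                    Evidence(labels[k], cls, "nonrisk", RULE_NONRISK_ON_RISK, cnt)
                )
            elif carries_risk and cls in ("null", "protective"):
                excluded[j] = True
                evidence[j].append(
                    Evidence(labels[k], cls, "risk", RULE_RISK_ON_NONASSOC, cnt)
                )
    logger.info("exclusion: %d of %d candidates excluded", int(excluded.sum()), m)
    return ExclusionReport(variant_ids=ids, excluded=excluded, evidence=evidence)


def minimal_risk_set(
    report: ExclusionReport, vm: VariantMap
) -> tuple[list[str], tuple[int, int] | None]:
    """Retained variants in genomic order plus the spanned bp interval.

    Returns (ordered ids, (start, end)) or (..., None) when everything was
    excluded (logged as a warning).
    """
    retained = set(report.retained_ids)
    ordered = [str(v) for v in vm.ids if str(v) in retained]
    if not ordered:
        logger.warning("minimal risk set is empty: every candidate was excluded")
        return [], None
    positions = [int(vm.pos[vm.index_of(v)]) for v in ordered]
    return ordered, (min(positions), max(positions))
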