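"""Linkage-disequilibrium statistics from phased haplotypes.

D, D' and r^2 are computed by direct haplotype counting on the phased
chromosome-by-variant matrix, not by EM from genotypes: phased input is the
contract of this pipeline, and counting is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthio import HaplotypeMatrix, VariantMap

logger = logging.getLogger(__name__)


class UndefinedLDError(ValueError):
    """Raised when LD is requested for a monomorphic variant."""


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two variants.

    ``D`` keeps its sign (positive when risk alleles co-occur more often
    than expected); ``dprime`` is reported as |D'| in [0, 1] and ``r2`` is
    the squared allelic correlation in [0, 1].
    """

    D: float
    dprime: float
    r2: float


def pairwise_ld(hm: HaplotypeMatrix, i: int, j: int) -> LDStats:
    """LD between variant columns i and j by haplotype counting.

    With pA, pB the risk-allele frequencies and pAB the joint frequency:
    D = pAB - pA*pB; D' = D / Dmax with Dmax = min(pA(1-pB), (1-pA)pB) for
    D > 0 and min(pA*pB, (1-pA)(1-pB)) for D < 0; r^2 = D^2 / (pA(1-pA)pB(1-pB)).
    """
    a = hm.alleles[:, i].astype(float)
    b = hm.alleles[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedLDError(
            f"LD undefined: variant column {i if pa in (0.0, 1.0) else j} is monomorphic"
        )
    pab = float((a * b).mean())
    d = pab - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0  # D = 0: D' defined as 0
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    # clip numerical spill just above 1 from float accumulation
    return LDStats(D=d, dprime=min(dprime, 1.0), r2=min(r2, 1.0))


def ld_to_lead(
    hm: HaplotypeMatrix,
    vm: VariantMap,
    threshold: float,
    stat: str = "r2",
) -> list[str]:
    """Variants whose LD with the lead strictly exceeds ``threshold``.

    ``stat`` selects r^2 (candidate-variant filter) or |D'| (the mediation
    prefilter).  The lead itself is included (its r^2 and |D'| are 1).
    Monomorphic variants have undefined LD and are excluded with a warning.
    """
    if stat not in ("r2", "dprime"):
        raise ValueError(f"stat must be 'r2' or 'dprime', got {stat!r}")
    lead = vm.lead_index
    out: list[str] = []
    for j, vid in enumerate(vm.ids):
        if j == lead:
            out.append(str(vid))
            continue
        try:
            ld = pairwise_ld(hm, lead, j)
        except UndefinedLDError:
            logger.warning("variant %s monomorphic: LD to lead undefined, excluded", vid)
            continue
        value = ld.r2 if stat == "r2" else ld.dprime
        if value > threshold:
            out.append(str(vid))
    return out


def printed_ld_candidates(vm: VariantMap, threshold: float = 0.8, stat: str = "r2") -> list[str]:
    """Threshold a variant map's published LD-to-lead column (strict >).

    Useful with the packaged fixture, whose auxiliary ``r2``/``dprime``
    columns carry the published pairwise LD to the lead variant.
    """
    col = {"r2": "r2", "dprime": "dprime"}[stat]
    if col not in vm.table.columns:
        raise ValueError(f"variant map has no published {col!r} column")
    mask = vm.table[col].to_numpy(dtype=float) > threshold
    return [str(v) for v in vm.ids[mask]]
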