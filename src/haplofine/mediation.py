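"""Pairwise mediation screen for the lead-variant signal.

Tests whether any pair of locus variants jointly explains the lead signal:
the lead coefficient from a logistic model without the pair is compared to
the coefficient with both pair members added as covariates.  The difference
(delta) is assessed with a case-status-stratified nonparametric bootstrap
and the resulting P-values are FDR-adjusted (Benjamini-Hochberg).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import ldstats
from .assoc import RankDeficientError, fit_logistic
from .synthio import HaplotypeMatrix, VariantMap

logger = logging.getLogger(__name__)


def prefilter_pairs(
    hm: HaplotypeMatrix,
    vm: VariantMap,
    lead_id: str | None = None,
    dprime_threshold: float = 0.8,
) -> list[tuple[str, str]]:
    """All unordered pairs of distinct non-lead variants in strong linkage
    with the lead (|D'| strictly above the threshold)."""
    lead_id = lead_id or vm.lead_id
    lead_j = vm.index_of(lead_id)
    passing: list[str] = []
    for j, vid in enumerate(vm.ids):
        if j == lead_j:
            continue
        try:
            ld = ldstats.pairwise_ld(hm, lead_j, j)
        except ldstats.UndefinedLDError:
            logger.warning("variant %s monomorphic: skipped from mediation prefilter", vid)
            continue
        if ld.dprime > dprime_threshold:
            passing.append(str(vid))
    return list(itertools.combinations(passing, 2))


@dataclass
class MediationResult:
    pair: tuple[str, str]
    beta_unadj: float
    beta_adj: float
    delta: float
    p_boot: float
    n_boot: int
    q: float | None = None
    flagged: str | None = None

    @property
    def relative_drop(self) -> float:
        return self.delta / self.beta_unadj if self.beta_unadj != 0 else 0.0


def _lead_beta(y, lead, extra_cols, covariates, check_rank=True):
    cols = [np.ones(len(y)), lead]
    cols.extend(extra_cols)
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, float).T)
    X = np.column_stack(cols)
    fit = fit_logistic(X, y, check_rank=check_rank)
    if not check_rank and "singular-information" in fit.flags:
        raise RankDeficientError(["bootstrap-design"])
    return float(fit.beta[1])


def mediation_test(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vm: VariantMap,
    pair: tuple[str, str],
    lead_id: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Bootstrap test of the drop in the lead coefficient when adjusting
    for a pair of variants.

    delta = beta(lead | covariates) - beta(lead | pair, covariates) on the
    full sample.  The bootstrap resamples individuals with replacement
    within case and control strata (preserving the quota design), recomputes
    delta each replicate, and reports the +1-corrected two-sided percentile
    P-value of delta = 0.  A pair that jointly determines the lead dosage
    makes the adjusted model collinear; such results are flagged
    "full-collinearity" and must be excluded from FDR adjustment.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    lead_id = lead_id or vm.lead_id
    if lead_id in pair:
        raise ValueError("pair members must be distinct from the lead variant")
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    lead = g[:, vm.index_of(lead_id)]
    v1 = g[:, vm.index_of(pair[0])]
    v2 = g[:, vm.index_of(pair[1])]
    cov = np.asarray(covariates, float) if covariates is not None else None

    try:
        beta_u = _lead_beta(y, lead, [], cov)
        beta_a = _lead_beta(y, lead, [v1, v2], cov)
    except RankDeficientError:
        logger.warning("pair %s collinear with lead: flagged, excluded from FDR", pair)
        return MediationResult(
            pair=pair, beta_unadj=np.nan, beta_adj=np.nan, delta=np.nan,
            p_boot=np.nan, n_boot=n_boot, flagged="full-collinearity",
        )
    delta = beta_u - beta_a

    rng = np.random.default_rng(seed)
    # canonicalize each stratum by row content so the bootstrap draw (and
    # hence p_boot) does not depend on the order individuals arrive in
    data = np.column_stack([lead, v1, v2] + ([cov] if cov is not None else []))
    def _stratum(mask):
        idx = np.flatnonzero(mask)
        return idx[np.lexsort(data[idx].T)]
    cases = _stratum(y == 1)
    controls = _stratum(y == 0)
    exceed = 0
    done = 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(cases, size=len(cases)), rng.choice(controls, size=len(controls))]
        )
        yb = y[idx]
        lb, v1b, v2b = lead[idx], v1[idx], v2[idx]
        cb = cov[idx] if cov is not None else None
        try:
            db = _lead_beta(yb, lb, [], cb, check_rank=False) - _lead_beta(
                yb, lb, [v1b, v2b], cb, check_rank=False
            )
        except RankDeficientError:
            continue
        done += 1
        if abs(db - delta) >= abs(delta):
            exceed += 1
    p_boot = (1 + exceed) / (done + 1)
    return MediationResult(
        pair=pair, beta_unadj=beta_u, beta_adj=beta_a, delta=delta,
        p_boot=p_boot, n_boot=done,
    )


def fdr_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mediation_screen(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    hm: HaplotypeMatrix,
    vm: VariantMap,
    lead_id: str | None = None,
    dprime_threshold: float = 0.8,
    n_boot: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    drop_threshold: float = 0.5,
) -> list[MediationResult]:
    """Run the full screen: prefilter pairs by |D'| to the lead, bootstrap
    each pair, FDR-adjust, and mark significant mediation as q below the
    threshold together with a relative drop in the lead beta above the drop
    threshold.  Flagged (collinear) pairs are excluded from FDR."""
    pairs = prefilter_pairs(hm, vm, lead_id, dprime_threshold)
    rng = np.random.default_rng(seed)
    results = [
        mediation_test(
            genotypes, y, covariates, vm, pair, lead_id,
            n_boot=n_boot, seed=int(rng.integers(2**31 - 1)),
        )
        for pair in pairs
    ]
    clean = [r for r in results if r.flagged is None]
    if clean:
        qs = fdr_adjust([r.p_boot for r in clean])
        for r, q in zip(clean, qs):
            r.q = float(q)
    n_sig = sum(
        1 for r in clean if r.q is not None and r.q < q_threshold and r.relative_drop > drop_threshold
    )
    logger.info("mediation screen: %d pairs tested, %d significant", len(clean), n_sig)
    return results


def significant_mediators(
    results: list[MediationResult], q_threshold: float = 0.05, drop_threshold: float = 0.5
) -> list[MediationResult]:
    return [
        r
        for r in results
        if r.flagged is None
        and r.q is not None
        and r.q < q_threshold
        and r.relative_drop > drop_threshold
    ]
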