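"""Case-control association: logistic fits, credible sets, conditional scans.

The fitting engine is a Newton-Raphson (IRLS) maximizer of the Bernoulli
log-likelihood with step-halving, written for speed on the many small
refits the bootstrap machinery performs.  Standard errors come from the
observed information at the optimum.  P-values at this locus's signal
strength (hundreds of -log10 units) underflow double precision, so all
tail probabilities are carried in log space and reported as -log10 P.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr as _qr
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


def safe_exp(x: float) -> float:
    """exp clipped at the double-precision overflow boundary."""
    return math.exp(min(x, 709.0))


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix rank deficient; collinear columns: {columns}")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic coefficients with Wald standard errors."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    flags: tuple[str, ...] = ()


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = piv[rank:]
        labels = [names[k] if names else f"col{k}" for k in sorted(bad)]
        raise RankDeficientError(labels)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    column_names: list[str] | None = None,
    check_rank: bool = True,
) -> LogisticFit:
    """Fit y ~ X by Newton-Raphson with step halving.

    Converges when the maximal score component falls below ``score_tol`` or
    the relative log-likelihood change falls below ``ll_tol``.  A fit that
    has not converged after ``max_iter`` iterations (typically separation)
    is returned flagged rather than raised, so callers can exclude it with
    a warning.  Rank deficiency is an error naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    if check_rank:
        _check_rank(X, column_names)

    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = float(y @ log_expit(eta) + (1 - y) @ log_expit(-eta))
    converged = False
    flags: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = mu * (1 - mu)
        h = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(h, score)
        except np.linalg.LinAlgError:
            flags.append("singular-information")
            break
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = float(y @ log_expit(eta_c) + (1 - y) @ log_expit(-eta_c))
            if ll_c >= ll - 1e-12:
                break
            t /= 2.0
        beta, eta = cand, eta_c
        if abs(ll_c - ll) < ll_tol * (abs(ll) + 1e-12):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    if not converged:
        flags.append("non-convergence")
        logger.debug("logistic fit did not converge after %d iterations", it)
    if np.max(np.abs(beta[1:] if p > 1 else beta)) > 12.0:
        # a log-OR beyond ~12 with a vanishing score is (quasi-)separation
        flags.append("separation")

    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-300, None)
    h = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(h)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("singular-information")
    return LogisticFit(beta=beta, se=se, loglik=ll, converged=converged, n_iter=it, flags=tuple(flags))


def neglog10_p_from_z(z: float) -> float:
    """Two-sided normal -log10 P computed in log space (safe for |z| ~ 60)."""
    return -(math.log(2.0) + norm.logsf(abs(z))) / _LN10


@dataclass
class AssocResult:
    """Per-variant additive logistic association, Wald inference."""

    variant_id: str
    pos: int
    beta: float
    se: float
    flags: tuple[str, ...] = ()

    @property
    def Z(self) -> float:
        return self.beta / self.se

    @property
    def OR(self) -> float:
        return safe_exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (safe_exp(self.beta - 1.96 * self.se), safe_exp(self.beta + 1.96 * self.se))

    @property
    def p(self) -> float:
        # floors at the smallest positive double; use neglog10p for reporting
        return max(2.0 * norm.sf(abs(self.Z)), 5e-324)

    @property
    def neglog10p(self) -> float:
        return neglog10_p_from_z(self.Z)


def _design(dosage: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    n = dosage.shape[0]
    cols = [np.ones(n), dosage.astype(float)]
    names = ["intercept", "dosage"]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        for k in range(cov.shape[1]):
            cols.append(cov[:, k])
            names.append(f"cov{k}")
    return np.column_stack(cols), names


def scan_variants(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vm,
) -> list[AssocResult]:
    """Single-variant additive scan: one covariate-adjusted fit per variant.

    Genotypes may be hard calls (0/1/2) or imputed dosages in [0, 2].
    Monomorphic variants are skipped with a log entry; non-converged fits
    are returned flagged.
    """
    g = np.asarray(genotypes, dtype=float)
    results: list[AssocResult] = []
    for j in range(g.shape[1]):
        col = g[:, j]
        if col.min() == col.max():
            logger.warning("variant %s monomorphic: skipped from scan", vm.ids[j])
            continue
        X, names = _design(col, covariates)
        fit = fit_logistic(X, y, column_names=names)
        results.append(
            AssocResult(
                variant_id=str(vm.ids[j]),
                pos=int(vm.pos[j]),
                beta=float(fit.beta[1]),
                se=float(fit.se[1]),
                flags=fit.flags,
            )
        )
    return results


@dataclass
class PPATable:
    """Posterior probabilities of association over a locus (normalized to 1)."""

    variant_ids: list[str]
    pos: np.ndarray
    log_abf: np.ndarray
    ppa: np.ndarray
    W: float


def compute_ppa(results: list[AssocResult], W: float = 0.04) -> PPATable:
    """Wakefield approximate Bayes factors from per-variant Z-scores.

    For each variant with V = se^2 the log-ABF in favor of association is
    0.5*log(V/(V+W)) + Z^2 * W / (2 V (V+W)), with W the prior variance of
    the log odds ratio; PPA is the ABF normalized over the locus (equal
    prior weight per variant).  Evaluated in log space throughout.
    """
    if W <= 0:
        raise ValueError(f"prior variance W must be positive, got {W}")
    ok = [r for r in results if not r.flags]
    if len(ok) < len(results):
        logger.warning("compute_ppa: dropped %d flagged fits", len(results) - len(ok))
    if not ok:
        raise ValueError("no usable association results")
    v = np.array([r.se**2 for r in ok])
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("all results must have finite positive standard errors")
    z = np.array([r.Z for r in ok])
    log_abf = 0.5 * np.log(v / (v + W)) + z * z * W / (2 * v * (v + W))
    ppa = np.exp(log_abf - logsumexp(log_abf))
    ppa /= ppa.sum()  # exact renormalization
    return PPATable(
        variant_ids=[r.variant_id for r in ok],
        pos=np.array([r.pos for r in ok]),
        log_abf=log_abf,
        ppa=ppa,
        W=W,
    )


@dataclass
class CredibleSet:
    """Smallest variant set whose cumulative PPA reaches the requested level."""

    level: float
    members: list[str]
    cumulative_ppa: np.ndarray


def credible_set(ppa: PPATable, level: float = 0.99) -> CredibleSet:
    """Greedy credible set: include variants by decreasing PPA until the
    cumulative mass reaches ``level``; ties broken by genomic position."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"credible level must be in (0,1), got {level}")
    order = sorted(range(len(ppa.ppa)), key=lambda k: (-ppa.ppa[k], ppa.pos[k]))
    members: list[str] = []
    cum: list[float] = []
    total = 0.0
    for k in order:
        members.append(ppa.variant_ids[k])
        total += float(ppa.ppa[k])
        cum.append(total)
        if total >= level:
            break
    return CredibleSet(level=level, members=members, cumulative_ppa=np.array(cum))


def conditional_scan(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vm,
    lead_id: str | None = None,
    p_threshold: float = 5e-8,
    max_rounds: int = 10,
) -> list[str]:
    """Step-wise conditional scan for secondary independent signals.

    Each round refits every remaining variant with the lead (and any
    previously detected signals) added as covariates; the most significant
    variant below ``p_threshold`` joins the conditioning set.  Variants
    collinear with the conditioning set are skipped with a log entry.
    Returns detected secondary signals (the lead itself excluded).
    """
    g = np.asarray(genotypes, dtype=float)
    lead_id = lead_id or vm.lead_id
    lead_j = vm.index_of(lead_id)
    cond = [lead_j]
    detected: list[str] = []
    if p_threshold <= 0:
        return []
    for _ in range(max_rounds):
        best: tuple[float, int] | None = None
        for j in range(g.shape[1]):
            if j in cond:
                continue
            col = g[:, j]
            if col.min() == col.max():
                continue
            base = [np.ones(len(y)), col]
            base.extend(g[:, k] for k in cond)
            if covariates is not None and covariates.size:
                base.extend(np.asarray(covariates, float).T)
            X = np.column_stack(base)
            try:
                fit = fit_logistic(X, y)
            except RankDeficientError:
                logger.info("variant %s collinear with conditioning set: skipped", vm.ids[j])
                continue
            if fit.flags:
                continue
            zj = fit.beta[1] / fit.se[1]
            nlp = neglog10_p_from_z(zj)
            if nlp > -math.log10(p_threshold) and (best is None or nlp > best[0]):
                best = (nlp, j)
        if best is None:
            break
        detected.append(str(vm.ids[best[1]]))
        cond.append(best[1])
    return detected
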