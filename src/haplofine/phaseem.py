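"""EM haplotype phasing and phase-uncertainty-aware haplotype dosages.

Haplotype frequencies are estimated with the classic EM scheme for
multilocus genotype data (gene counting over diplotypes): the E-step
assigns each individual's compatible haplotype pairs probability
proportional to f_a * f_b (doubled for heterozygous pairs), the M-step
re-estimates the frequency vector from the expected pair counts.

The haplotype space is never the full 2^M cube.  It is restricted to
haplotypes supportable by the sample: seeded from near-unambiguous
individuals (at most ``seed_cap`` heterozygous sites, default 1, whose
resolutions are certain or both real), then closed under genotype
complementation (if a is in the space and g - a is a valid haplotype for
some observed genotype g, g - a joins the space); individuals that still
have no compatible pair are fully enumerated as a fallback.  For the
step-like haplotypes of a strong-LD locus this closure is small and
near-exact; EM then drives the frequency of any spurious member toward
zero.

Phase uncertainty is propagated by drawing R full phasings from the
per-individual diplotype posteriors and mapping each drawn haplotype onto
the best-guess haplotype set, giving per-individual haplotype dosages in
[0, 2] (plus explicit unmapped mass for draws matching no best-guess
haplotype).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .synthio import HaplotypeMatrix

logger = logging.getLogger(__name__)


class PhasingError(ValueError):
    pass


def _enumerate_compatible(g: np.ndarray) -> list[np.ndarray]:
    """All haplotypes compatible with genotype g (2^h for h het sites)."""
    het = np.flatnonzero(g == 1)
    base = (g // 2).astype(np.int8)
    base[g == 2] = 1
    base[het] = 0
    out = []
    for bits in itertools.product((0, 1), repeat=len(het)):
        h = base.copy()
        h[het] = bits
        out.append(h)
    return out


def _candidate_haplotypes(G: np.ndarray, seed_cap: int, full_cap: int) -> np.ndarray:
    """Build the restricted haplotype space (see module docstring)."""
    n, m = G.shape
    space: dict[bytes, np.ndarray] = {}

    def add(h: np.ndarray) -> bool:
        key = h.tobytes()
        if key in space:
            return False
        space[key] = h.astype(np.int8)
        return True

    het_counts = (G == 1).sum(axis=1)
    for i in range(n):
        if het_counts[i] <= seed_cap:
            for h in _enumerate_compatible(G[i]):
                add(h)
    # closure under complementation against every observed genotype
    for _ in range(4 * m + 4):
        changed = False
        haps = list(space.values())
        for g in np.unique(G, axis=0):
            for a in haps:
                b = g - a
                if b.min() >= 0 and b.max() <= 1:
                    changed |= add(b.astype(np.int8))
        if not changed:
            break
    # fallback: individuals still without any compatible pair in the space
    for i in range(n):
        if not _pairs_for(G[i], space):
            if het_counts[i] <= full_cap:
                for h in _enumerate_compatible(G[i]):
                    add(h)
            else:
                raise PhasingError(
                    f"individual {i} has {het_counts[i]} heterozygous sites and no "
                    "compatible haplotype pair in the restricted space; raise full_cap "
                    "or reduce the candidate set"
                )
    return np.array(list(space.values()), dtype=np.int8)


def _pairs_for(g: np.ndarray, space: dict[bytes, np.ndarray]) -> list[tuple[bytes, bytes]]:
    pairs = []
    for key, a in space.items():
        b = g - a
        if b.min() < 0 or b.max() > 1:
            continue
        bkey = b.astype(np.int8).tobytes()
        if bkey in space and key <= bkey:
            pairs.append((key, bkey))
    return pairs


@dataclass
class DiplotypePosterior:
    """Converged EM state: haplotype frequencies plus per-individual
    posteriors over compatible (unordered) haplotype pairs."""

    haplotypes: np.ndarray  # K x M
    freqs: np.ndarray  # K
    pair_indices: list[np.ndarray]  # per individual: P_i x 2 rows into haplotypes
    pair_probs: list[np.ndarray]  # per individual: P_i posteriors summing to 1
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def marginal_dosage(self, i: int) -> np.ndarray:
        """Posterior expected copies (0-2) of each haplotype in individual i."""
        d = np.zeros(len(self.freqs))
        for (a, b), w in zip(self.pair_indices[i], self.pair_probs[i]):
            d[a] += w
            d[b] += w
        return d


def em_phase(
    genotypes: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
    seed_cap: int = 1,
    full_cap: int = 18,
) -> DiplotypePosterior:
    """Estimate haplotype frequencies and diplotype posteriors by EM.

    ``genotypes`` is N x M with entries in {0, 1, 2} (risk-allele counts).
    Initialization is the uniform frequency vector, so the run is
    deterministic; ``seed`` is accepted for interface symmetry but unused.
    Convergence: max |change in f| below ``tol`` or ``max_iter`` sweeps.
    """
    G = np.asarray(genotypes)
    if not np.isin(G, (0, 1, 2)).all():
        bad = int(np.flatnonzero(~np.isin(G, (0, 1, 2)).all(axis=1))[0])
        raise PhasingError(f"individual {bad} has a corrupt genotype (entries outside 0/1/2)")
    G = G.astype(np.int8)
    n, m = G.shape
    space_arr = _candidate_haplotypes(G, seed_cap, full_cap)
    key_to_idx = {h.tobytes(): k for k, h in enumerate(space_arr)}
    space = {h.tobytes(): h for h in space_arr}

    pair_indices: list[np.ndarray] = []
    for i in range(n):
        prs = _pairs_for(G[i], space)
        if not prs:
            raise PhasingError(f"individual {i} is incompatible with every candidate haplotype")
        pair_indices.append(
            np.array([(key_to_idx[a], key_to_idx[b]) for a, b in prs], dtype=np.int64)
        )

    k = len(space_arr)
    f = np.full(k, 1.0 / k)
    loglik_trace: list[float] = []
    converged = False
    it = 0
    probs: list[np.ndarray] = [np.empty(0)] * n
    for it in range(1, max_iter + 1):
        ll = 0.0
        counts = np.zeros(k)
        for i in range(n):
            pi = pair_indices[i]
            w = f[pi[:, 0]] * f[pi[:, 1]]
            w = np.where(pi[:, 0] != pi[:, 1], 2.0 * w, w)
            tot = w.sum()
            ll += np.log(max(tot, 1e-300))
            post = w / tot if tot > 0 else np.full(len(w), 1.0 / len(w))
            probs[i] = post
            np.add.at(counts, pi[:, 0], post)
            np.add.at(counts, pi[:, 1], post)
        loglik_trace.append(ll)
        f_new = counts / (2.0 * n)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM phasing stopped at max_iter=%d without convergence", max_iter)
    # final E-step at the converged frequencies
    ll = 0.0
    for i in range(n):
        pi = pair_indices[i]
        w = f[pi[:, 0]] * f[pi[:, 1]]
        w = np.where(pi[:, 0] != pi[:, 1], 2.0 * w, w)
        tot = w.sum()
        ll += np.log(max(tot, 1e-300))
        probs[i] = w / tot if tot > 0 else np.full(len(w), 1.0 / len(w))
    loglik_trace.append(ll)
    return DiplotypePosterior(
        haplotypes=space_arr,
        freqs=f,
        pair_indices=pair_indices,
        pair_probs=probs,
        loglik_trace=np.array(loglik_trace),
        n_iter=it,
        converged=converged,
    )


def sample_phasing_replicates(
    posterior: DiplotypePosterior, R: int = 100, seed: int = 0
) -> list[HaplotypeMatrix]:
    """Draw R full phasings, one diplotype per individual per replicate,
    independently from the per-individual posteriors."""
    if R < 1:
        raise ValueError(f"R must be at least 1, got {R}")
    rng = np.random.default_rng(seed)
    n = len(posterior.pair_indices)
    m = posterior.haplotypes.shape[1]
    out: list[HaplotypeMatrix] = []
    choice_idx = [
        rng.choice(len(posterior.pair_probs[i]), size=R, p=posterior.pair_probs[i])
        if len(posterior.pair_probs[i]) > 1
        else np.zeros(R, dtype=int)
        for i in range(n)
    ]
    for r in range(R):
        rows = np.empty((2 * n, m), dtype=np.int8)
        for i in range(n):
            a, b = posterior.pair_indices[i][choice_idx[i][r]]
            rows[2 * i] = posterior.haplotypes[a]
            rows[2 * i + 1] = posterior.haplotypes[b]
        out.append(HaplotypeMatrix(rows))
    return out


@dataclass
class DosageMatrix:
    """Per-individual best-guess haplotype dosages aggregated over phasing
    replicates; Sum_h d[i,h] + unmapped_mass[i] = 2 for every individual."""

    d: np.ndarray  # N x K in [0, 2]
    unmapped_mass: np.ndarray  # N
    R: int
    haplotypes: np.ndarray  # K x M best-guess haplotypes
    labels: list[str] | None = None


def haplotype_dosages(
    replicates: list[HaplotypeMatrix],
    best_guess: np.ndarray,
    labels: list[str] | None = None,
) -> DosageMatrix:
    """Map replicate chromosomes onto the best-guess haplotype set.

    d[i, h] is the per-replicate average count of exact matches of
    individual i's two chromosomes to best-guess haplotype h; draws that
    match no best-guess haplotype accumulate in ``unmapped_mass``.
    """
    if not replicates:
        raise ValueError("at least one phasing replicate is required")
    bg = np.asarray(best_guess, dtype=np.int8)
    R = len(replicates)
    n = replicates[0].n_individuals
    idx = {h.tobytes(): k for k, h in enumerate(bg)}
    d = np.zeros((n, len(bg)))
    unmapped = np.zeros(n)
    for rep in replicates:
        if rep.n_individuals != n or rep.n_variants != bg.shape[1]:
            raise ValueError("replicates and best-guess haplotypes are misaligned")
        for row in range(2 * n):
            k = idx.get(rep.alleles[row].tobytes())
            i = row // 2
            if k is None:
                unmapped[i] += 1.0
            else:
                d[i, k] += 1.0
    return DosageMatrix(d=d / R, unmapped_mass=unmapped / R, R=R, haplotypes=bg, labels=labels)
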