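"""Ribosome-traffic simulation: footprint-aware TASEP over the ORF codons.

The totally asymmetric simple exclusion process models ribosomes as
particles of footprint ``l`` codons hopping along the ORF lattice with
site-specific exponential rates.  A ribosome enters at rate ``alpha`` when
the first ``l`` sites are free, advances from site i to i+1 at the site's
hop rate when site i+l is free (or beyond the lattice), and terminates from
the last site at rate ``beta``.  The steady-state termination current J is
the model's protein-production-rate prediction and is the per-gene TASEP
feature, with hop rates proportional to the codon adaptation weights along
the ORF — which is what makes the feature sensitive to codon *order*, not
just content.

``exact_tasep_small`` solves the full 2^n-state generator for l=1 lattices
of up to 10 sites and serves as the in-repo oracle for the Monte-Carlo
estimator.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .adaptation import CodonWeights
from .sequence_features import orf_codon_indices

log = logging.getLogger(__name__)


@dataclass
class TasepConfig:
    """Rates and horizons for one simulation.

    Defaults put initiation in the rate-limiting regime (alpha well below
    the mean elongation rate of 1) with a 9-codon ribosome footprint.
    """

    hop_rates: np.ndarray = field(default_factory=lambda: np.ones(1))
    alpha: float = 0.1
    beta: float = 10.0
    footprint: int = 9
    burn_in: int = 100_000
    n_events: int = 1_000_000
    seed: int = 0
    n_batches: int = 20

    def __post_init__(self) -> None:
        self.hop_rates = np.asarray(self.hop_rates, dtype=float)
        if np.any(self.hop_rates <= 0) or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("all rates must be positive")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")


#: Reduced horizons for per-gene feature extraction and unit tests.
FAST_PROFILE = {"burn_in": 10_000, "n_events": 60_000}


@dataclass
class TasepResult:
    current: float
    current_se: float
    density: np.ndarray
    n_terminations: int
    low_confidence: bool = False


@njit(cache=False)
def _gillespie(rates, alpha, beta, ell, burn_in, n_events, seed, n_batches,
               track_density):
    np.random.seed(seed)
    n = rates.shape[0]
    cap = n // ell + 2
    pos = np.empty(cap, dtype=np.int64)  # pos[0] = front ribosome
    m = 0
    density = np.zeros(n)
    batch_ex = np.zeros(n_batches)
    batch_t = np.zeros(n_batches)
    per_batch = max(1, n_events // n_batches)
    t_total = 0.0
    exits = 0
    for ev in range(burn_in + n_events):
        can_init = m < cap and (m == 0 or pos[m - 1] >= ell)
        total = alpha if can_init else 0.0
        for k in range(m):
            p = pos[k]
            if p == n - 1:
                total += beta
            elif k == 0 or pos[k - 1] - p > ell:
                total += rates[p]
        if total <= 0.0:
            break
        dt = np.random.exponential(1.0 / total)
        in_sample = ev >= burn_in
        b = 0
        if in_sample:
            b = min((ev - burn_in) // per_batch, n_batches - 1)
            t_total += dt
            batch_t[b] += dt
            if track_density:
                for k in range(m):
                    p = pos[k]
                    hi = min(p + ell, n)
                    for s in range(p, hi):
                        density[s] += dt
        u = np.random.random() * total
        chosen = -1  # -2 = initiation
        acc = 0.0
        if can_init:
            acc = alpha
            if u < acc:
                chosen = -2
        if chosen == -1:
            for k in range(m):
                p = pos[k]
                if p == n - 1:
                    r = beta
                elif k == 0 or pos[k - 1] - p > ell:
                    r = rates[p]
                else:
                    r = 0.0
                acc += r
                if u < acc:
                    chosen = k
                    break
        if chosen == -2:
            pos[m] = 0
            m += 1
        elif chosen >= 0:
            p = pos[chosen]
            if p == n - 1:
                for k in range(chosen, m - 1):
                    pos[k] = pos[k + 1]
                m -= 1
                if in_sample:
                    exits += 1
                    batch_ex[b] += 1
            else:
                pos[chosen] = p + 1
    return exits, t_total, batch_ex, batch_t, density


def simulate_tasep(config: TasepConfig, track_density: bool = True) -> TasepResult:
    """Continuous-time Monte-Carlo estimate of the steady-state current.

    The current is terminations per unit time after burn-in; its standard
    error comes from batch means over ``n_batches`` equal event-count
    stretches of the sampling window.  Densities are time-averaged site
    coverages.  Fewer than 100 termination events flags the result as
    low-confidence.
    """
    exits, t_total, batch_ex, batch_t, density = _gillespie(
        config.hop_rates, config.alpha, config.beta, config.footprint,
        config.burn_in, config.n_events, config.seed, config.n_batches,
        track_density,
    )
    if t_total <= 0:
        return TasepResult(0.0, np.inf, np.zeros_like(density), 0, True)
    current = exits / t_total
    ok = batch_t > 0
    if ok.sum() >= 2:
        rates_b = batch_ex[ok] / batch_t[ok]
        se = float(np.std(rates_b, ddof=1) / np.sqrt(ok.sum()))
    else:
        se = np.inf
    low = exits < 100
    if low:
        log.warning("only %d termination events; current estimate is low-confidence",
                    exits)
    return TasepResult(current, se, density / t_total, int(exits), low)


def exact_tasep_small(config: TasepConfig) -> TasepResult:
    """Exact stationary current and density for l=1 lattices of <= 10 sites.

    Builds the full 2^n-state generator and solves the stationary linear
    system; used as the independent oracle for the Monte-Carlo estimator.
    """
    if config.footprint != 1:
        raise ValueError("exact solver supports footprint 1 only")
    n = len(config.hop_rates)
    if n > 10:
        raise ValueError("exact solver limited to n_sites <= 10")
    rates, alpha, beta = config.hop_rates, config.alpha, config.beta
    ns = 1 << n
    Q = np.zeros((ns, ns))
    for s in range(ns):
        if not s & 1:
            Q[s, s | 1] += alpha
        for i in range(n - 1):
            if (s >> i) & 1 and not (s >> (i + 1)) & 1:
                Q[s, s & ~(1 << i) | (1 << (i + 1))] += rates[i]
        if (s >> (n - 1)) & 1:
            Q[s, s & ~(1 << (n - 1))] += beta
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(ns)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    occupied_last = np.array([(s >> (n - 1)) & 1 for s in range(ns)], dtype=float)
    current = float(beta * (pi * occupied_last).sum())
    density = np.array([
        sum(pi[s] for s in range(ns) if (s >> i) & 1) for i in range(n)
    ])
    return TasepResult(current, 0.0, density, 0, False)


def gene_seed(gene_id: str, global_seed: int) -> int:
    """Stable per-gene seed: CRC32 of the id XORed with the run seed."""
    return (zlib.crc32(gene_id.encode()) ^ global_seed) & 0x7FFFFFFF


def tasep_feature(orf: str, weights: CodonWeights, config: TasepConfig,
                  gene_id: str = "", global_seed: int = 0) -> float:
    """Per-gene translation-rate feature: estimated current J.

    Hop rates are the codon adaptation weights along the ORF (stop codon
    excluded), rescaled to mean 1 so that J differences across genes come
    from rate *profiles* — slow-codon placement and ribosome interference —
    rather than overall scale.
    """
    idx = orf_codon_indices(orf)
    sense = idx[idx >= 0]
    rates = weights.w[sense]
    rates = rates / rates.mean()
    cfg = replace(config, hop_rates=rates,
                  seed=gene_seed(gene_id, global_seed) if gene_id else config.seed)
    return simulate_tasep(cfg, track_density=False).current
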