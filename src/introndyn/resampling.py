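"""Monte-Carlo resampling tests.

Three procedures:

- shared parallel loss: the probability that two lineages, each losing n1
  and n2 introns drawn without replacement from a shared ancestral pool,
  share at least k loss positions.  Estimated by simulation (optionally
  with per-intron loss weights, lineages sampling positions proportional
  to how often they are actually lost) and, for the uniform case, computed
  exactly as a hypergeometric tail.

- spacing regularity: whether intron positions partition the coding
  sequence more evenly than random insertion, measured by the effective
  number of exons Ne = exp(Shannon entropy of exon-length fractions)
  (inverse Simpson available as an alternative); one-sided p-value from
  genes simulated with the same number of uniform random insertions.

- positional homogeneity: chi-square of intron counts in equal-length
  alignment bins against uniform, with the p-value taken from multinomial
  simulation rather than the asymptotic distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SharedLossResult",
    "SpacingResult",
    "HomogeneityResult",
    "shared_loss_mc",
    "shared_loss_exact",
    "spacing_regularity",
    "positional_homogeneity",
    "effective_exon_number",
]


# ----------------------------------------------------------------------
# parallel losses
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SharedLossResult:
    estimate: float
    se: float  # binomial standard error
    trials: int
    pool: int
    n1: int
    n2: int
    k_min: int
    weighted: bool
    seed: Optional[int]


def _check_shared_loss_args(pool, n1, n2, k_min, trials=1):
    if pool <= 0 or n1 < 0 or n2 < 0 or k_min < 0:
        raise ValueError("counts must be non-negative (pool positive)")
    if n1 > pool or n2 > pool:
        raise ValueError("cannot lose more introns than the pool contains")
    if k_min > min(n1, n2):
        raise ValueError("k_min cannot exceed min(n1, n2)")
    if trials < 1:
        raise ValueError("need at least one trial")


def shared_loss_mc(
    pool: int,
    n1: int,
    n2: int,
    k_min: int,
    trials: int = 100_000,
    weights: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> SharedLossResult:
    """Monte-Carlo estimate of P(overlap >= k_min) between two independent
    without-replacement draws of n1 and n2 losses from a pool.

    ``weights`` makes loss-prone positions more likely to be drawn
    (successive sampling proportional to weight, via Gumbel top-k, which
    with equal weights reduces exactly to uniform sampling — same seed,
    same draws).
    """
    _check_shared_loss_args(pool, n1, n2, k_min, trials)
    if weights is None:
        logw = np.zeros(pool)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (pool,):
            raise ValueError(f"weights must have length {pool}")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        logw = np.log(w)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 20_000
    for start in range(0, trials, batch):
        m = min(batch, trials - start)
        keys1 = logw + rng.gumbel(size=(m, pool))
        keys2 = logw + rng.gumbel(size=(m, pool))
        top1 = np.argpartition(keys1, pool - n1, axis=1)[:, pool - n1:]
        top2 = np.argpartition(keys2, pool - n2, axis=1)[:, pool - n2:]
        sel1 = np.zeros((m, pool), dtype=bool)
        sel2 = np.zeros((m, pool), dtype=bool)
        np.put_along_axis(sel1, top1, True, axis=1)
        np.put_along_axis(sel2, top2, True, axis=1)
        overlap = (sel1 & sel2).sum(axis=1)
        hits += int((overlap >= k_min).sum())
    p = hits / trials
    se = math.sqrt(p * (1 - p) / trials)
    return SharedLossResult(p, se, trials, pool, n1, n2, k_min,
                            weights is not None, seed)


def shared_loss_exact(pool: int, n1: int, n2: int, k_min: int) -> float:
    """Exact P(overlap >= k_min) for uniform draws: the hypergeometric tail
    sum_{k >= k_min} C(n1, k) C(pool - n1, n2 - k) / C(pool, n2)."""
    _check_shared_loss_args(pool, n1, n2, k_min)
    return float(sps.hypergeom.sf(k_min - 1, pool, n1, n2))


# ----------------------------------------------------------------------
# spacing regularity
# ----------------------------------------------------------------------
def _exon_lengths(coords: np.ndarray, gene_length: float) -> np.ndarray:
    c = np.sort(coords)
    return np.diff(np.concatenate(([0.0], c, [gene_length])))


def effective_exon_number(
    intron_coordinates: Sequence[float],
    gene_length: float,
    statistic: str = "effective_exons",
) -> float:
    """Effective number of exons: exp(entropy) of exon-length fractions
    (``statistic="inverse_simpson"`` for 1 / sum p_i^2).  Equals the exon
    count k when all k exons are equal, and is scale invariant."""
    coords = np.asarray(intron_coordinates, dtype=float)
    if len(coords) == 0:
        raise ValueError("need at least one intron")
    if len(np.unique(coords)) != len(coords):
        raise ValueError("duplicate intron coordinates")
    if coords.min() <= 0 or coords.max() >= gene_length:
        raise ValueError("intron coordinates must lie strictly inside the gene")
    p = _exon_lengths(coords, gene_length) / gene_length
    if statistic == "effective_exons":
        nz = p[p > 0]
        return float(np.exp(-(nz * np.log(nz)).sum()))
    if statistic == "inverse_simpson":
        return float(1.0 / (p ** 2).sum())
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class SpacingResult:
    ne_obs: float
    p_value: float  # fraction of simulations with Ne >= observed
    n_sims: int
    n_introns: int
    gene_length: float
    statistic: str
    ne_sim_mean: float
    ne_sim_q05: float
    ne_sim_q95: float
    seed: Optional[int]


def spacing_regularity(
    intron_coordinates: Sequence[float],
    gene_length: float,
    n_sims: int = 10_000,
    seed: Optional[int] = None,
    statistic: str = "effective_exons",
) -> SpacingResult:
    """One-sided regularity test: are the introns spaced more evenly than
    the same number of uniform random insertions?"""
    ne_obs = effective_exon_number(intron_coordinates, gene_length, statistic)
    n = len(intron_coordinates)
    rng = np.random.default_rng(seed)
    sites = rng.random((n_sims, n)) * gene_length
    sites.sort(axis=1)
    lengths = np.diff(
        np.concatenate(
            [np.zeros((n_sims, 1)), sites, np.full((n_sims, 1), float(gene_length))],
            axis=1,
        ),
        axis=1,
    )
    p = lengths / gene_length
    if statistic == "effective_exons":
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        ne_sim = np.exp(-plogp.sum(axis=1))
    else:
        ne_sim = 1.0 / (p ** 2).sum(axis=1)
    pval = float((ne_sim >= ne_obs).mean())
    return SpacingResult(
        ne_obs=ne_obs,
        p_value=pval,
        n_sims=n_sims,
        n_introns=n,
        gene_length=float(gene_length),
        statistic=statistic,
        ne_sim_mean=float(ne_sim.mean()),
        ne_sim_q05=float(np.quantile(ne_sim, 0.05)),
        ne_sim_q95=float(np.quantile(ne_sim, 0.95)),
        seed=seed,
    )


# ----------------------------------------------------------------------
# positional homogeneity
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HomogeneityResult:
    chi2: float
    p_value: float
    bin_counts: tuple[int, ...]
    n_bins: int
    n_sims: int
    seed: Optional[int]


def positional_homogeneity(
    intron_coordinates: Sequence[float],
    alignment_length: float,
    n_bins: int = 10,
    n_sims: int = 10_000,
    seed: Optional[int] = None,
) -> HomogeneityResult:
    """Chi-square test of intron positions against uniform occupancy of
    ``n_bins`` equal-length alignment segments; p by multinomial simulation."""
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if alignment_length < n_bins:
        raise ValueError("alignment shorter than the number of bins")
    coords = np.asarray(intron_coordinates, dtype=float)
    if coords.min() < 0 or coords.max() > alignment_length:
        raise ValueError("coordinates outside the alignment")
    n = len(coords)
    idx = np.minimum((coords / alignment_length * n_bins).astype(int), n_bins - 1)
    obs = np.bincount(idx, minlength=n_bins)
    expected = n / n_bins
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    sim = rng.multinomial(n, np.full(n_bins, 1.0 / n_bins), size=n_sims)
    chi2_sim = ((sim - expected) ** 2 / expected).sum(axis=1)
    pval = float((chi2_sim >= chi2 - 1e-12).mean())
    return HomogeneityResult(chi2, pval, tuple(int(c) for c in obs),
                             n_bins, n_sims, seed)
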