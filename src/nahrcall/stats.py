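"""Stand-alone reliability statistics: Efron-style local fdr on the depth
ratio, the breakpoint log-odds, and supporting-read counts.

The local fdr works on z = log(gamma) pooled across all tested loci (and
samples) of a run: an empirical null N(mu0, sigma0) is fitted by central
matching (median and interquartile range, robust to the enrichment tails
the test is meant to find), the marginal density f is a Gaussian kernel
estimate, and fdr(z) = min(1, pi0 * f0(z) / f(z)).

The breakpoint log-odds contrasts the likelihood of the reads near a called
breakpoint under the region set with the hybrid segment (the pair of
regions forming it removed) against the null region set; natural log,
threshold 6 for a high-confidence breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from nahrcall.readmodel import logmeanexp


@dataclass
class FdrFit:
    mu0: float
    sigma0: float
    pi0: float
    z: np.ndarray
    fdr: np.ndarray


def local_fdr(gamma_values, config=None, return_fit: bool = False):
    """Per-locus local false discovery rates from pooled gamma statistics."""
    from nahrcall.config import CallerConfig

    config = config or CallerConfig()
    gamma = np.asarray(list(gamma_values), dtype=float)
    if len(gamma) < config.min_fdr_loci:
        raise ValueError(
            f"{len(gamma)} loci < min_fdr_loci={config.min_fdr_loci}: "
            "pool more loci/samples before fitting the empirical null")
    pos = gamma[gamma > 0]
    if len(pos) == 0:
        raise ValueError("all gamma values are zero")
    floor = pos.min() / 2.0
    z = np.log(np.where(gamma > 0, gamma, floor))
    mu0 = float(np.median(z))
    q75, q25 = np.percentile(z, [75, 25])
    sigma0 = float((q75 - q25) / (2 * sps.norm.ppf(0.75)))
    if sigma0 <= 1e-12:
        raise ValueError("degenerate null variance: gamma values are (near) constant")
    kde = sps.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    f0 = sps.norm.pdf(z, mu0, sigma0)
    pi0 = min(1.0, float(kde(mu0)[0] / sps.norm.pdf(mu0, mu0, sigma0)))
    fdr = np.minimum(1.0, pi0 * f0 / f)
    if return_fit:
        return fdr, FdrFit(mu0, sigma0, pi0, z, fdr)
    return fdr


def log_odds_from_likelihoods(null_likelihoods, alt_likelihoods) -> float:
    """ln(P_A / P_0) from per-read candidate-location likelihoods.

    ``null_likelihoods``: one sequence per read of pair likelihoods across
    the null region set (the breakpoint's windows in every paralog);
    ``alt_likelihoods``: the same reads across the modified set (hybrid
    window included, the pair of windows forming it removed).  Each read
    contributes ln(mean alt / mean null); zero reads give 0.
    """
    null_likelihoods = list(null_likelihoods)
    alt_likelihoods = list(alt_likelihoods)
    if len(null_likelihoods) != len(alt_likelihoods):
        raise ValueError("null and alternative read sets must match")
    if not null_likelihoods:
        return 0.0
    total = 0.0
    for nl, al in zip(null_likelihoods, alt_likelihoods):
        nl = np.asarray(list(nl), dtype=float)
        al = np.asarray(list(al), dtype=float)
        if len(nl) == 0 or len(al) == 0:
            continue
        total += float(np.log(al.mean()) - np.log(nl.mean()))
    return total


def breakpoint_log_odds(null_log_liks, alt_log_liks) -> float:
    """As :func:`log_odds_from_likelihoods` but on log-space inputs
    (per-read sequences of log pair likelihoods)."""
    null_log_liks = list(null_log_liks)
    alt_log_liks = list(alt_log_liks)
    if not null_log_liks:
        return 0.0
    total = 0.0
    for nl, al in zip(null_log_liks, alt_log_liks):
        nl = np.asarray(list(nl), dtype=float)
        al = np.asarray(list(al), dtype=float)
        if len(nl) == 0 or len(al) == 0:
            continue
        total += logmeanexp(al) - logmeanexp(nl)
    return total


def count_support(hybrid_posteriors, proper_flags) -> tuple[int, int]:
    """Supporting-read counts for a call.

    ``hybrid_posteriors``: per scored read, the posterior probability that
    its generating location is a hybrid segment under the MAP hypothesis
    (n_hybrid counts those > 0.5).  ``proper_flags``: per recruited pair,
    whether its original mapping was a proper pair (n_discordant counts the
    rest)."""
    n_hybrid = int(sum(1 for p in hybrid_posteriors if p > 0.5))
    n_discordant = int(sum(1 for ok in proper_flags if not ok))
    return n_hybrid, n_discordant
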