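"""Repeat read depth: GC-corrected expected counts and count likelihoods.

Read depth is evaluated over *region sets*: a unique interval, or all the
members of a homology equivalence class pooled together, which sidesteps
within-class mapping ambiguity entirely — a fragment only needs to be
assigned to *some* paralog.  A fragment counts toward the region containing
its leftmost aligned base (half-open; deterministic, no double counting
across a partition).

Counts are modeled as negative binomial (an overdispersed Poisson),
approximated by a normal in large regions, with the standard deviation
never below 1.05% of the mean nor below the Poisson sqrt(mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GCCurve:
    """Fragment-rate multiplier per fragment-GC-fraction bin, normalized so
    the mean multiplier over observed fragments is 1."""

    multipliers: np.ndarray  # one per bin
    n_bins: int = 101

    def __post_init__(self):
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers < 0):
            raise ValueError("GC multipliers must be non-negative")

    @classmethod
    def uniform(cls, n_bins: int = 101) -> "GCCurve":
        return cls(np.ones(n_bins), n_bins)

    @property
    def is_uniform(self) -> bool:
        return bool(np.allclose(self.multipliers, 1.0))

    def rate(self, gc_fraction) -> np.ndarray:
        idx = np.clip((np.asarray(gc_fraction, dtype=float) * (self.n_bins - 1)).round().astype(int),
                      0, self.n_bins - 1)
        return self.multipliers[idx]


@dataclass
class DepthObservation:
    """Observed vs expected fragment count for one region set."""

    region_id: str
    observed: float
    expected: float  # mu under the hypothesis being scored
    copy_factor: float = 1.0

    def __post_init__(self):
        if self.observed < 0:
            raise ValueError("observed count must be non-negative")


def fit_gc_curve(fragment_gc: np.ndarray, expected_gc: np.ndarray,
                 n_bins: int = 101, smooth: int = 5) -> GCCurve:
    """Multiplier(bin) = observed fragment share / share expected under
    uniform placement, lightly smoothed and normalized to mean 1 over the
    observed fragments.

    ``expected_gc``: GC fractions of fragment-sized windows sampled
    uniformly from the reference.
    """
    edges = np.linspace(0, 1, n_bins + 1)
    obs, _ = np.histogram(fragment_gc, bins=edges)
    exp, _ = np.histogram(expected_gc, bins=edges)
    obs_share = obs / max(1, obs.sum())
    exp_share = exp / max(1, exp.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(exp_share > 0, obs_share / np.maximum(exp_share, 1e-12), 1.0)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        occupied = exp_share > 0
        sm = np.convolve(np.where(occupied, mult, 1.0), kernel, mode="same")
        mult = np.where(occupied, sm, 1.0)
    curve = GCCurve(mult, n_bins)
    # normalize: mean multiplier over the observed fragments = 1
    mean_rate = float(np.mean(curve.rate(fragment_gc))) if len(fragment_gc) else 1.0
    if mean_rate > 0:
        curve.multipliers = curve.multipliers / mean_rate
    return curve


def estimate_gc_curve(bam, unique_regions, reference, config=None,
                      rng: np.random.Generator | None = None) -> GCCurve:
    """Estimate the GC-bias curve from proper pairs in unique regions; falls
    back to a uniform curve (with a warning) when fragments are scarce."""
    import pysam

    from nahrcall.catalog import fetch_sequence
    from nahrcall.config import CallerConfig

    config = config or CallerConfig()
    rng = rng or np.random.default_rng(0)
    own = isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__")
    bam = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        frag_gc = []
        for chrom, start, end in unique_regions:
            seq = fetch_sequence(reference, chrom, start, end)
            gc_cum = np.concatenate([[0], np.cumsum(np.isin(list(seq), ["G", "C"]))])
            for aln in bam.fetch(chrom, start, end):
                if (aln.is_unmapped or aln.is_duplicate or not aln.is_proper_pair
                        or aln.is_reverse or aln.template_length <= 0):
                    continue
                f0 = aln.reference_start - start
                f1 = f0 + aln.template_length
                if f0 < 0 or f1 > len(seq):
                    continue
                frag_gc.append((gc_cum[f1] - gc_cum[f0]) / max(1, f1 - f0))
    finally:
        if own:
            bam.close()
    if len(frag_gc) < config.min_gc_fragments:
        logger.warning("only %d fragments in unique regions (< %d): using a uniform GC curve",
                       len(frag_gc), config.min_gc_fragments)
        return GCCurve.uniform(config.gc_bins)
    expected = _uniform_window_gc(reference, unique_regions,
                                  window=int(config.fragment_mean),
                                  n=len(frag_gc), rng=rng)
    return fit_gc_curve(np.array(frag_gc), expected, config.gc_bins)


def _uniform_window_gc(reference, regions, window: int, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    from nahrcall.catalog import fetch_sequence

    gcs = []
    lens = np.array([end - start - window for _, start, end in regions], dtype=float)
    lens = np.maximum(lens, 1)
    probs = lens / lens.sum()
    choices = rng.choice(len(regions), size=n, p=probs)
    for i in choices:
        chrom, start, end = regions[i]
        pos = int(rng.integers(start, max(start + 1, end - window)))
        seq = fetch_sequence(reference, chrom, pos, pos + window)
        gcs.append((seq.count("G") + seq.count("C")) / max(1, len(seq)))
    return np.array(gcs)


def region_gc_weight(reference, regions, gc_curve: GCCurve, fragment_length: int) -> float:
    """GC-weighted effective length of a region set: the sum over candidate
    fragment placements of the per-placement rate multiplier."""
    if gc_curve.is_uniform:
        return float(sum(end - start for _, start, end in regions))
    from nahrcall.catalog import fetch_sequence

    total = 0.0
    for chrom, start, end in regions:
        seq = fetch_sequence(reference, chrom, start, end + fragment_length)
        isgc = np.isin(list(seq), ["G", "C"]).astype(float)
        if len(isgc) < fragment_length:
            continue
        win = np.convolve(isgc, np.ones(fragment_length), mode="valid") / fragment_length
        total += float(np.sum(gc_curve.rate(win[: end - start])))
    return total


def expected_count(region_set, gc_curve: GCCurve, total_fragments: float,
                   genome_size: float, copy_factor: float,
                   reference=None, fragment_length: int = 400,
                   copy_factor_floor: float = 0.0) -> float:
    """Expected fragment count mu for a region set.

    ``copy_factor`` is in diploid-relative units (1 = the reference diploid
    dose; a heterozygous duplication of a unique interval gives 3/2).  With a
    uniform curve this is copy_factor * total_fragments * length/genome_size.
    ``genome_size`` is the haploid reference length.
    """
    cf = max(copy_factor, copy_factor_floor)
    if cf <= 0:
        raise ValueError("copy_factor (after flooring) must be positive")
    weight = region_gc_weight(reference, region_set, gc_curve, fragment_length) \
        if reference is not None and not gc_curve.is_uniform \
        else float(sum(end - start for _, start, end in region_set))
    return cf * total_fragments * weight / float(genome_size)


def count_loglik(observed: float, mu: float, config=None) -> float:
    """Log-probability of an observed count given expectation mu.

    Large regions (mu >= normal_threshold): normal with
    sd = max(sqrt(mu), 0.0105*mu) — the 1.05%-of-mean rule floored at the
    Poisson sd so the model is never tighter than Poisson.  Small regions:
    negative binomial with variance max(mu*(1+alpha), (0.0105*mu)^2).
    """
    from nahrcall.config import CallerConfig

    config = config or CallerConfig()
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if mu <= 0:
        raise ValueError("expected count must be positive")
    if mu >= config.normal_threshold:
        sd = max(np.sqrt(mu), config.depth_sd_frac * mu)
        return float(sps.norm.logpdf(observed, loc=mu, scale=sd))
    var = max(mu * (1.0 + config.nb_alpha), (config.depth_sd_frac * mu) ** 2)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return float(sps.nbinom.logpmf(int(round(observed)), r, p))


def gamma_statistic(observed: float, expected_null: float) -> float:
    """gamma = observed / expected-under-null; dimensionless, ~1 with no
    event, ~0.5 at a heterozygous deletion of a unique locus, ~1.5 at a
    one-copy duplication."""
    if expected_null <= 0:
        raise ValueError("expected_null must be positive")
    return float(observed) / float(expected_null)


def count_fragment_starts(bam, regions) -> int:
    """Observed fragment count for a region set: fragments whose leftmost
    aligned base lies in a region (counted once per pair, via the forward
    mate of a proper orientation or the lower-coordinate mate)."""
    import pysam

    own = isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__")
    bam = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        count = 0
        for chrom, start, end in regions:
            for aln in bam.fetch(chrom, start, end):
                if aln.is_unmapped or aln.is_duplicate or aln.is_supplementary or aln.is_secondary:
                    continue
                # leftmost base of the fragment: forward mate of FR pairs,
                # or the lower-coordinate mate otherwise
                if aln.is_paired:
                    if aln.reference_start > aln.next_reference_start:
                        continue
                    if aln.reference_start == aln.next_reference_start and aln.is_read2:
                        continue
                if start <= aln.reference_start < end:
                    count += 1
        return count
    finally:
        if own:
            bam.close()
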