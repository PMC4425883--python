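"""Exact Bayesian comparison of joint NAHR hypotheses.

The joint log-probability of a hypothesis combines, per the generative
model: the product over reads of the average pair likelihood across the
hypothesis's candidate locations; the count likelihood of observed read
depth in every affected region set; a uniform breakpoint prior per event;
and the event prior with P(e_j = 0) = 1 - 10^-6.  Posteriors are normalized
over the enumerated hypothesis space by log-sum-exp, and the
maximum-a-posteriori hypothesis is converted into calls for every event
whose MAP outcome is non-null with posterior at least the configured floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from nahrcall.catalog import EventGroup, PotentialEvent
from nahrcall.mechanics import CALLABLE_OUTCOMES, EventAssignment, Hypothesis


@dataclass
class Priors:
    """Event, breakpoint, and location priors.

    The non-null mass 10^-6 is split uniformly over the available
    (outcome, multiplicity) combinations, then uniformly over that outcome's
    breakpoint space; the location prior (uniform over candidates) lives in
    the read model's averaging.
    """

    p_event_null: float = 1.0 - 1e-6
    gene_conversion: bool = True
    max_gc_pairs: int = 10

    def _combos(self, event: PotentialEvent) -> list[tuple[str, int]]:
        combos = [(o, m) for o in CALLABLE_OUTCOMES if o in event.allowed_outcomes
                  for m in (1, 2)]
        if (self.gene_conversion and "gene_conversion" in event.allowed_outcomes
                and event.n_vps >= 2):
            combos.append(("gene_conversion", 1))
        return combos

    def _n_breakpoints(self, event: PotentialEvent, outcome: str) -> int:
        if outcome == "gene_conversion":
            n_pairs = min(self.max_gc_pairs, event.n_vps * (event.n_vps - 1) // 2)
            return 2 * n_pairs  # donor direction x tract
        return event.n_vps

    def log_prior(self, event: PotentialEvent, a: EventAssignment) -> float:
        if a.is_null:
            return math.log(self.p_event_null)
        combos = self._combos(event)
        if (a.outcome, a.multiplicity) not in combos:
            raise ValueError(f"assignment {a} outside the prior support of {event.id}")
        nb = self._n_breakpoints(event, a.outcome)
        return (math.log(1.0 - self.p_event_null) - math.log(len(combos)) - math.log(nb))

    @classmethod
    def from_config(cls, config) -> "Priors":
        return cls(p_event_null=config.p_event_null,
                   gene_conversion=config.gene_conversion,
                   max_gc_pairs=config.max_gc_pairs)


def joint_log_prob(group: EventGroup, hypothesis: Hypothesis,
                   read_logmeans, depth_obs, priors: Priors) -> float:
    """Sum of per-read log average-location likelihoods, per-region count
    log-likelihoods, breakpoint priors, and event priors for one hypothesis.

    ``read_logmeans``: iterable of log average pair likelihoods (one per
    recruited read pair, computed under this hypothesis).  ``depth_obs``:
    iterable of (observed, mu) pairs or DepthObservation, scored with
    :func:`nahrcall.depth.count_loglik`.
    """
    from nahrcall.depth import DepthObservation, count_loglik

    total = 0.0
    for lm in read_logmeans:
        if not np.isfinite(lm) and lm > 0:
            raise ValueError("invalid read log-likelihood")
        total += lm
    for obs in depth_obs:
        if isinstance(obs, DepthObservation):
            o, mu = obs.observed, obs.expected
        else:
            o, mu = obs
        if mu <= 0:
            raise ValueError("depth expectation must be positive (check copy_factor floor)")
        total += count_loglik(o, mu)
    by_id = {e.id: e for e in group.events}
    for a in hypothesis.assignments:
        total += priors.log_prior(by_id[a.event_id], a)
    return total


@dataclass
class PosteriorTable:
    """Normalized posterior over an enumerated hypothesis space."""

    group: EventGroup
    hypotheses: list[Hypothesis]
    log_joint: np.ndarray
    log_posterior: np.ndarray = field(init=False)

    def __post_init__(self):
        self.log_joint = np.asarray(self.log_joint, dtype=float)
        if not np.any(np.isfinite(self.log_joint)):
            raise ValueError("all joint probabilities are zero: degenerate model")
        z = logsumexp(self.log_joint)
        self.log_posterior = self.log_joint - z

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def map_index(self) -> int:
        return int(np.argmax(self.log_posterior))

    def map_hypothesis(self) -> Hypothesis:
        return self.hypotheses[self.map_index()]

    def event_map(self, event_id: str) -> tuple[EventAssignment, float]:
        """MAP assignment for one event with its marginal posterior mass."""
        mass: dict[EventAssignment, float] = {}
        for h, lp in zip(self.hypotheses, self.posterior):
            a = h[event_id]
            mass[a] = mass.get(a, 0.0) + lp
        best = max(mass, key=lambda a: mass[a])
        return best, mass[best]


def posterior(group: EventGroup, hypotheses, log_joints) -> PosteriorTable:
    """Normalize enumerated joint log-probabilities into a posterior table."""
    return PosteriorTable(group, list(hypotheses), np.asarray(log_joints, dtype=float))


@dataclass
class EventCall:
    """An emitted NAHR call with its reliability statistics."""

    event_id: str
    chrom: str
    outcome: str
    multiplicity: int
    breakpoint_index: int | tuple[int, int]
    # 1-based inclusive breakpoint regions (v_k + 1 .. v_{k+1}) on each LCR
    breakpoint_region_a: tuple[int, int] = (0, 0)
    breakpoint_region_b: tuple[int, int] = (0, 0)
    posterior: float = 0.0
    gamma: float = float("nan")
    fdr: float = float("nan")
    log_odds: float = float("nan")
    n_hybrid_reads: int = 0
    n_discordant_reads: int = 0
    pass_fdr: bool = False
    high_conf_breakpoint: bool = False
    flags: tuple = ()

    def __post_init__(self):
        if self.gamma == self.gamma and self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.fdr == self.fdr and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")


def breakpoint_region(event: PotentialEvent, k: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based inclusive breakpoint region [v_k + 1, v_{k+1}] on each LCR.

    The crossover lies strictly after VP k and no later than VP k+1; past the
    last VP the region extends to the repeat's end.
    """
    pos_a_k, pos_b_k = event.vp_ref_positions(k)
    if k + 1 < event.n_vps:
        pos_a_next, pos_b_next = event.vp_ref_positions(k + 1)
        end_a, end_b = pos_a_next + 1, pos_b_next + 1  # 1-based position of v_{k+1}
    else:
        end_a, end_b = event.lcr_a.end, event.lcr_b.end
    # +2: skip past v_k (1-based of v_k is pos+1; region starts one later)
    return ((pos_a_k + 2, end_a), (pos_b_k + 2, end_b))


def call_group(table: PosteriorTable, config=None, stats: dict | None = None) -> list[EventCall]:
    """Convert a posterior table into calls: one per event whose MAP outcome
    is non-null with posterior >= min_posterior.  ``stats`` optionally maps
    event id -> dict with gamma / fdr / log_odds / support counts; threshold
    flags (fdr <= 0.01, log-odds >= 6) are applied here."""
    from nahrcall.config import CallerConfig

    config = config or CallerConfig()
    stats = stats or {}
    by_id = {e.id: e for e in table.group.events}
    calls = []
    for event in table.group.events:
        a, mass = table.event_map(event.id)
        if a.is_null or mass < config.min_posterior:
            continue
        ev = by_id[a.event_id]
        if a.outcome in CALLABLE_OUTCOMES:
            region_a, region_b = breakpoint_region(ev, a.breakpoint)
        else:
            region_a = region_b = (0, 0)
        st = stats.get(event.id, {})
        fdr = st.get("fdr", float("nan"))
        lo = st.get("log_odds", float("nan"))
        calls.append(EventCall(
            event_id=event.id,
            chrom=ev.chrom,
            outcome=a.outcome,
            multiplicity=a.multiplicity,
            breakpoint_index=a.breakpoint,
            breakpoint_region_a=region_a,
            breakpoint_region_b=region_b,
            posterior=mass,
            gamma=st.get("gamma", float("nan")),
            fdr=fdr,
            log_odds=lo,
            n_hybrid_reads=st.get("n_hybrid_reads", 0),
            n_discordant_reads=st.get("n_discordant_reads", 0),
            pass_fdr=bool(fdr == fdr and fdr <= config.fdr_threshold),
            high_conf_breakpoint=bool(lo == lo and lo >= config.log_odds_threshold),
            flags=tuple(st.get("flags", ())),
        ))
    return calls
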