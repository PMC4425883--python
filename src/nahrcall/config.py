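"""Caller configuration: every tunable named by the model, with defaults.

The configuration is a flat key-value document (YAML on disk).  CLI flags
override file values; library callers pass a :class:`CallerConfig` directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class CallerConfig:
    # --- catalog filters ---
    min_identity: float = 0.90          # HSDD inclusion rule: pairs >= 90% identity
    min_lcr_length: int = 1000          # and length >= 1 kb
    max_locus_span: int = 250_000       # full potential-locus span cap (bp)

    # --- hypothesis enumeration ---
    max_joint_events: int = 3           # largest group enumerated exactly
    max_gc_pairs: int = 10              # widest-spaced (k1,k2) tracts per event
    gene_conversion: bool = True        # enumerate gene conversion as competing hypothesis
    tandem_duplication_same_homolog: bool = False  # m=2 as two tandem copies instead of two homologs

    # --- read / error model ---
    read_error: float = 0.02            # conservative per-base error floor
    gap_open: float = 0.01
    gap_extend: float = 0.02
    homopolymer_multiplier: float = 5.0  # error/gap elevation inside homopolymer runs
    homopolymer_min_run: int = 4
    use_quality: bool = True            # raise per-base error above the floor from qualities
    band: int = 12                      # pair-HMM band half-width (bp around the anchor)

    # --- fragment model ---
    fragment_mean: float = 400.0
    fragment_sd: float = 40.0
    read_length: int = 100

    # --- depth model ---
    normal_threshold: float = 1000.0    # expected count above which normal approximates the NB
    depth_sd_frac: float = 0.0105       # sd = 1.05% of the mean in large regions
    nb_alpha: float = 0.05              # NB overdispersion floor: var >= mu*(1+alpha)
    copy_factor_floor: float = 0.01     # residual rate for fully deleted regions (mismapping)
    gc_bins: int = 101
    min_gc_fragments: int = 100_000

    # --- priors and call rule ---
    p_event_null: float = 1.0 - 1e-6    # P(e_j = 0), identical for every event
    min_posterior: float = 0.5          # MAP posterior floor before a call is emitted
    fdr_threshold: float = 0.01         # conservative-set filter
    log_odds_threshold: float = 6.0     # high-confidence breakpoint flag (natural log)

    # --- fdr test ---
    min_fdr_loci: int = 50

    # --- recruitment ---
    flank_quantile: float = 0.975       # recruitment/window flank = this fragment-length quantile

    def flank(self) -> int:
        """Recruitment flank in bp (97.5th-percentile fragment length by default)."""
        from scipy.stats import norm

        return int(round(norm.ppf(self.flank_quantile, self.fragment_mean, self.fragment_sd)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        import hashlib
        import json

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
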