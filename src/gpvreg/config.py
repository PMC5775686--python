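"""Analysis configuration shared across the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    """Settings for a single-dataset analysis.

    Parameters
    ----------
    t_star : float
        Long-term horizon of interest, in years (survival is compared at t*).
    t_search : float
        Maximum waiting time at which a transition can still be observed
        (donor search window); must satisfy 0 < t_search <= t_star.
    grouping : str
        Risk-set convention for conditional pseudo-values:
        'exact-waiting-time' (discrete waiting times) or 'state1-risk-set'
        (continuous waiting times).
    imputations : int
        Number of Bernoulli-imputation repetitions used to correct standard
        errors; 1000 is recommended for a single-dataset analysis, 1 inside
        large simulation studies (the replication averages them already).
    seed : int
        Seed for the imputation draws.
    level : float
        Confidence level for intervals, in (0, 1).
    """

    t_star: float = 5.0
    t_search: float = 5.0
    grouping: str = "exact-waiting-time"
    imputations: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if not 0 < self.t_search <= self.t_star:
            raise ValueError("need 0 < t_search <= t_star")
        if self.imputations < 0:
            raise ValueError("imputations must be >= 0")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.grouping not in ("exact-waiting-time", "state1-risk-set"):
            raise ValueError(f"unknown grouping mode {self.grouping!r}")
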