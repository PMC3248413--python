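"""Run-level configuration for a learning run."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sampling settings shared across the pipeline.

    Counts from the two half-field treatments are turned into a geometric
    treatment ratio ``R = 10**(L2 - L1)`` with ``L = log10(count + 1)``.
    Only ratios strictly beyond the thresholds become *up* / *down*
    observations; a change of less than 50% in either direction is treated
    as no signal, hence the defaults 0.67 and 1.5.

    Parameters
    ----------
    down_threshold : float
        Ratios strictly below this are classed *down* (default 0.67).
    up_threshold : float
        Ratios strictly above this are classed *up* (default 1.5).
    site_filter_sum : int
        A species/site pair is dropped when the two half-field counts sum
        to at most this value (default 1).
    n_permutations : int
        Number of random reorderings of the training observations used to
        build the probability ensemble (default 10).
    rng_seed : int
        Master seed; every stream of randomness derives from it.
    """

    down_threshold: float = 0.67
    up_threshold: float = 1.5
    site_filter_sum: int = 1
    n_permutations: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.down_threshold <= 0 or self.up_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.down_threshold < self.up_threshold:
            raise ValueError(
                f"down_threshold ({self.down_threshold}) must be below "
                f"up_threshold ({self.up_threshold})"
            )
        if self.site_filter_sum < 0:
            raise ValueError("site_filter_sum must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)
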