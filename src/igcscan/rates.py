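"""Equilibrium interlocus gene-conversion rate estimation.

At mutation-conversion equilibrium the divergence d between a pair of
paralogs is set by the balance between mutational input (2 mu per site
per generation on the pair) and homogenisation by conversion from any of
the n-1 other paralogs, giving the per-site, per-generation pairwise
conversion rate

    c = 2 mu (n - 1) / d.

The estimate assumes every paralog is equally likely to be converted by
each of its n-1 partners, that conversion is the only exchange mechanism,
and that divergence is at steady state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: human per-base per-generation mutation rate used by default
DEFAULT_MU = 1.2e-8

FORMULA_ID = "equilibrium-2mu(n-1)/d"


@dataclass
class RateParams:
    mu: float = DEFAULT_MU
    d: float = 0.0  # mean pairwise divergence (1 - mean identity)
    n: int = 2  # paralog count

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if not 0 <= self.d < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if self.n < 2:
            raise ValueError("need at least 2 paralogs")


@dataclass
class IGCRateEstimate:
    c: float  # conversions / site / generation
    formula_id: str = FORMULA_ID


def estimate_igc_rate(p: RateParams) -> IGCRateEstimate:
    """Equilibrium pairwise conversion rate c = 2 mu (n-1) / d."""
    if p.d == 0:
        raise ValueError("divergence-free family: rate unidentifiable")
    return IGCRateEstimate(c=2.0 * p.mu * (p.n - 1) / p.d)


def converted_site_fraction(observed_discordant_pct: float,
                            expected_discordant_pct: float) -> float:
    """Fraction (percent) of duplicated sites with a historical conversion.

    A conversion flips the local topology of the acceptor only, so each
    converted site contributes twice its frequency to the discordant-block
    excess; the converted fraction is (observed - expected) / 2 on the
    percent scale.  Negative estimates clamp to zero with a warning.
    """
    if observed_discordant_pct < 0 or expected_discordant_pct < 0:
        raise ValueError("percentages must be nonnegative")
    est = (observed_discordant_pct - expected_discordant_pct) / 2.0
    if est < 0:
        warnings.warn("observed discordance below expectation; clamping to 0")
        return 0.0
    return est


def per_generation_loads(c_mean: float, mu: float, duplicated_bp: float
                         ) -> tuple[float, float]:
    """(expected converted sites, expected mutated sites) per individual
    per generation across ``duplicated_bp`` of duplicated sequence."""
    if c_mean < 0 or mu < 0 or duplicated_bp < 0:
        raise ValueError("inputs must be nonnegative")
    return c_mean * duplicated_bp, mu * duplicated_bp


def family_rate(mean_identity: float, n_paralogs: int, mu: float = DEFAULT_MU
                ) -> IGCRateEstimate:
    """Convenience wrapper taking a family's mean pairwise identity."""
    return estimate_igc_rate(RateParams(mu=mu, d=1.0 - mean_identity, n=n_paralogs))
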