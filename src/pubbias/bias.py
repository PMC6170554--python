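"""Publication-bias metrics and the literature bias test.

The central comparison is between the positive-evidence rate P a body of
research is *expected* to produce after a single test per hypothesis, and
the share L of positive findings actually observed in the literature
(about 90% in experimental psychology).  The bias is expressed as an odds
ratio

    B = ((1 - P) / P) / ((1 - L) / L)

read as "negative evidence was observed B times for every negative result
published".  B = 1 means the literature mirrors production; with L = 0.9
the expression simplifies to 9 (1 - P) / P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binomtest

__all__ = [
    "BiasResult",
    "BinomialBiasTest",
    "expected_positive_rate",
    "bias_odds",
    "studies_needed",
    "binomial_bias_test",
]


def expected_positive_rate(theta: float, mean_power: float, alpha_o: float) -> float:
    """Expected positive-evidence rate theta * mean_power + alpha_o (1 - theta).

    Valid under any variance in power: the positive rate is linear in
    power, so only the mean enters.
    """
    for name, x in (("theta", theta), ("mean_power", mean_power),
                    ("alpha_o", alpha_o)):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return theta * mean_power + alpha_o * (1.0 - theta)


def bias_odds(P: float, L: float = 0.90) -> float:
    """Odds of suppressing an observed negative result.

    Ratio of the produced negative odds (1-P)/P to the published negative
    odds (1-L)/L.
    """
    if not (0.0 < P < 1.0 and 0.0 < L < 1.0):
        raise ValueError("P and L must lie strictly in (0, 1)")
    return ((1.0 - P) / P) / ((1.0 - L) / L)


def studies_needed(n_published_positive: float, P: float) -> float:
    """Studies required to produce ``n_published_positive`` at positive rate P."""
    if P <= 0.0:
        raise ValueError("P must be positive")
    if n_published_positive < 0:
        raise ValueError("count must be non-negative")
    return n_published_positive / P


@dataclass(frozen=True)
class BiasResult:
    """Bias odds of a literature given an expected positive rate."""

    expected_positive_rate: float
    literature_positive_share: float
    bias_odds: float
    studies_needed: float

    @classmethod
    def from_rate(cls, P: float, L: float = 0.90,
                  n_published_positive: float | None = None) -> "BiasResult":
        return cls(
            expected_positive_rate=P,
            literature_positive_share=L,
            bias_odds=bias_odds(P, L),
            studies_needed=(math.nan if n_published_positive is None
                            else studies_needed(n_published_positive, P)),
        )


@dataclass(frozen=True)
class BinomialBiasTest:
    """One-sided exact binomial test of an observed replication count."""

    k: int
    n: int
    p0: float
    p_value: float


def binomial_bias_test(k: int, n: int = 97, p0: float = 0.90) -> BinomialBiasTest:
    """Exact lower-tail binomial test P(X <= k | n, p0).

    Tests whether ``k`` replications out of ``n`` could have been drawn
    from a literature replicating at rate ``p0``; the alternative of
    interest is one-sided (reproducibility below ``p0``), so the p-value
    is the lower tail.
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly in (0, 1)")
    p = binomtest(k, n, p0, alternative="less").pvalue
    return BinomialBiasTest(k=k, n=n, p0=p0, p_value=float(p))
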