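"""Closed-form identities for a single study under binary NHST.

The model treats a body of research as a stream of hypotheses, each true
with prior probability ``theta``.  A study testing a true hypothesis
reports positive evidence with probability equal to its statistical power
(1 - beta); a study testing a false hypothesis reports positive evidence
with probability alpha, the type-1 error rate.  From these three numbers
everything else follows: the total positive-evidence rate, the posterior
probability that a positive finding is true (Bayes' theorem), and the
probability that the finding replicates in an independent study.

All functions in this module are the zero-variance ("naive") forms: every
study is assumed to have the same power.  Variance-aware expectations live
in :mod:`pubbias.expectation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "PowerLink",
    "NaiveResult",
    "CorrelationPowerSpec",
    "prob_positive_true",
    "prob_positive_false",
    "prob_positive_total",
    "posterior",
    "reproducibility",
    "smallest_prior_for_positive_rate",
    "solve_naive",
    "correlation_power",
]


def _check_unit(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def _check_open_unit(name: str, x: float) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {x}")


@dataclass(frozen=True)
class PowerLink:
    """Assumed relation between replication power and original power.

    kind
        ``identical``: replication studies have the same power as the
        originals. ``perfect``: replication power is fixed at 1.
        ``offset``: replication power = original power + ``delta``
        (an additive bump of ``delta`` on the power scale).
    """

    kind: str
    delta: float = 0.0

    _KINDS = ("identical", "perfect", "offset")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown link kind {self.kind!r}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if self.kind != "offset" and self.delta != 0.0:
            raise ValueError("delta is only meaningful for offset links")

    @classmethod
    def identical(cls) -> "PowerLink":
        return cls("identical")

    @classmethod
    def perfect(cls) -> "PowerLink":
        return cls("perfect")

    @classmethod
    def offset(cls, delta: float) -> "PowerLink":
        return cls("offset", delta)

    @classmethod
    def parse(cls, spec: str) -> "PowerLink":
        """Parse ``"identical"``, ``"perfect"`` or ``"offset:<delta>"``."""
        if spec == "identical":
            return cls.identical()
        if spec == "perfect":
            return cls.perfect()
        if spec.startswith("offset:"):
            return cls.offset(float(spec.split(":", 1)[1]))
        raise ValueError(f"cannot parse power link {spec!r}")

    def __str__(self) -> str:
        if self.kind == "offset":
            return f"offset:{self.delta:g}"
        return self.kind

    def replication_power(self, power_original: float) -> float:
        """Replication power implied by this link (may exceed 1 for offsets)."""
        if self.kind == "identical":
            return power_original
        if self.kind == "perfect":
            return 1.0
        return power_original + self.delta


@dataclass(frozen=True)
class NaiveResult:
    """Solution of the zero-variance system for one (R, theta) pair."""

    posterior: float
    reproducibility: float
    power_original: float
    power_replication: float
    feasible: bool = True
    reason: str | None = None

    @classmethod
    def infeasible(cls, reason: str) -> "NaiveResult":
        return cls(math.nan, math.nan, math.nan, math.nan, False, reason)


@dataclass(frozen=True)
class CorrelationPowerSpec:
    """A two-sided test of zero Pearson correlation at n = df + 2."""

    r: float
    df: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.df < 3:
            raise ValueError("df must be at least 3")
        if not (abs(self.r) < 1.0):
            raise ValueError("|r| must be < 1")
        _check_open_unit("alpha", self.alpha)


def prob_positive_true(theta: float, power: float) -> float:
    """Probability of a true-positive result: theta * power."""
    _check_unit("theta", theta)
    _check_unit("power", power)
    return theta * power


def prob_positive_false(theta: float, alpha: float) -> float:
    """Probability of a false-positive result: alpha * (1 - theta)."""
    _check_unit("theta", theta)
    _check_unit("alpha", alpha)
    return alpha * (1.0 - theta)


def prob_positive_total(theta: float, power: float, alpha: float) -> float:
    """Total positive-evidence rate theta*power + alpha*(1 - theta)."""
    return prob_positive_true(theta, power) + prob_positive_false(theta, alpha)


def posterior(theta: float, power: float, alpha: float) -> float:
    """Posterior probability that a positive finding is true.

    Bayes' theorem with the prior ``theta``, likelihood of a positive
    under truth ``power`` and under falsehood ``alpha``:

        theta * power / (theta * power + alpha * (1 - theta))
    """
    num = prob_positive_true(theta, power)
    den = num + prob_positive_false(theta, alpha)
    if den == 0.0:
        raise ValueError(
            "posterior undefined: positive evidence has probability zero "
            f"(theta={theta}, power={power}, alpha={alpha})"
        )
    return num / den


def reproducibility(posterior_prob: float, power_r: float, alpha_r: float) -> float:
    """Probability a positive finding replicates in an independent study.

    The positive-rate identity applied with the posterior in place of the
    prior: posterior * power_r + alpha_r * (1 - posterior).
    """
    _check_unit("posterior", posterior_prob)
    _check_unit("power_r", power_r)
    _check_unit("alpha_r", alpha_r)
    return posterior_prob * power_r + alpha_r * (1.0 - posterior_prob)


def smallest_prior_for_positive_rate(
    target_rate: float, power: float, alpha: float
) -> float:
    """Invert the positive-rate identity in theta.

    Returns the prior producing ``target_rate`` positive evidence at the
    given power and alpha: (target_rate - alpha) / (power - alpha).
    """
    _check_unit("target_rate", target_rate)
    _check_unit("power", power)
    _check_unit("alpha", alpha)
    if power == alpha:
        raise ValueError("power equals alpha: every prior gives the same rate")
    theta = (target_rate - alpha) / (power - alpha)
    if not (0.0 <= theta <= 1.0):
        raise ValueError(
            f"no prior in [0, 1] yields rate {target_rate} "
            f"with power={power}, alpha={alpha}"
        )
    return theta


_EPS = 1e-9


def solve_naive(
    R: float,
    theta: float,
    alpha_o: float = 0.05,
    alpha_r: float = 0.025,
    link: PowerLink = PowerLink("identical"),
) -> NaiveResult:
    """Solve the zero-variance system for the original power.

    Finds the power ``p`` in (0, 1] such that feeding the posterior at
    (theta, p, alpha_o) through the replication identity with replication
    power ``link(p)`` returns exactly ``R``.  The map p -> R(p) is
    monotone increasing under all supported links, so a bracketed root
    search is safe; infeasibility (no root in range, or implied
    replication power above 1) is returned as a flagged result rather
    than raised.
    """
    _check_unit("R", R)
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must lie in (0, 1]")
    _check_open_unit("alpha_o", alpha_o)
    _check_open_unit("alpha_r", alpha_r)

    hi = 1.0 - link.delta if link.kind == "offset" else 1.0
    if hi <= _EPS:
        return NaiveResult.infeasible("offset leaves no admissible power")

    def g(p: float) -> float:
        post = posterior(theta, p, alpha_o)
        return reproducibility(post, link.replication_power(p), alpha_r) - R

    if g(hi) < 0.0:
        return NaiveResult.infeasible(
            "R unattainable: would require replication power above 1"
        )
    if g(_EPS) > 0.0:
        return NaiveResult.infeasible("R below the attainable range")

    p = brentq(g, _EPS, hi, xtol=1e-14, rtol=1e-15)
    post = posterior(theta, p, alpha_o)
    p_r = link.replication_power(p)
    return NaiveResult(
        posterior=post,
        reproducibility=reproducibility(post, p_r, alpha_r),
        power_original=p,
        power_replication=p_r,
    )


def correlation_power(spec: CorrelationPowerSpec) -> float:
    """Two-sided power of a test of zero correlation, Fisher z approximation.

    The sample correlation is transformed with atanh; under the Fisher
    approximation the transform is normal with standard error
    1/sqrt(n - 3), n = df + 2.  Returns alpha exactly when r = 0.
    """
    n = spec.df + 2
    zcrit = norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = math.atanh(spec.r) * math.sqrt(n - 3)
    return float(norm.sf(zcrit - ncp) + norm.cdf(-zcrit - ncp))
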