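"""Seeded simulator of the study -> publication -> replication process.

Serves two roles: an independent oracle for the closed forms, and a
"what-if" engine for the generative process the closed forms idealize.

Two coupling modes are offered because the closed-form expectations are
*mean-field*: they average the posterior uniformly over the power
distribution and multiply by a scalar replication power.  A faithful
simulation of the process instead selects studies into the positive pool
in proportion to their own power, which over-represents well-powered true
studies among positive findings and raises both the empirical share of
true positives and the empirical replication rate above the mean-field
expectations whenever power varies between studies.

``coupling="study"`` (default)
    the faithful process: each study's drawn power drives its outcome and
    (through the link, clipped at 1) its replication.
``coupling="mean_field"``
    a validator for the closed forms: positivity occurs at the marginal
    rate, truth-given-positive follows the per-study Bayes posterior, and
    true findings replicate at the scalar mean replication power.

Random draws are consumed in a fixed documented order — truth, power,
outcome, publication, replication — so seeds are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias import BiasResult
from .core import PowerLink
from .distributions import PowerDistribution
from .expectation import (
    expected_posterior,
    expected_reproducibility,
    selection_weighted_summaries,
)

__all__ = ["SimulationConfig", "SimulationResult", "simulate", "summarize_bias"]


@dataclass(frozen=True)
class SimulationConfig:
    n_studies: int
    theta: float
    dist: PowerDistribution
    alpha_o: float = 0.05
    alpha_r: float = 0.025
    link: PowerLink = PowerLink.identical()
    suppression_odds: float = 1.0
    seed: int = 0
    coupling: str = "study"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be at least 1")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if self.suppression_odds < 1.0:
            raise ValueError("suppression_odds must be >= 1 (1 = unbiased)")
        if self.coupling not in ("study", "mean_field"):
            raise ValueError("coupling must be 'study' or 'mean_field'")


@dataclass(frozen=True)
class SimulationResult:
    """Counts and empirical rates from one simulated literature.

    ``predictions`` carries the closed-form values the empirical rates
    should be compared against: the mean-field expectations and, for the
    study-coupled process, the selection-weighted forms.
    """

    n_studies: int
    n_true: int
    n_positive: int
    n_published_positive: int
    n_published_negative: int
    n_replicated: int
    empirical_positive_rate: float
    empirical_reproducibility: float
    empirical_posterior_share: float
    predictions: dict = field(default_factory=dict)


def _predictions(cfg: SimulationConfig) -> dict:
    e_post = expected_posterior(cfg.theta, cfg.alpha_o, cfg.dist)
    p_r = min(cfg.link.replication_power(cfg.dist.mean), 1.0)
    out = {
        "mean_field_posterior": e_post,
        "mean_field_reproducibility": expected_reproducibility(
            e_post, p_r, cfg.alpha_r),
        "positive_rate": cfg.theta * cfg.dist.mean
        + cfg.alpha_o * (1.0 - cfg.theta),
    }
    if cfg.coupling == "study":
        sw = selection_weighted_summaries(
            cfg.theta, cfg.alpha_o, cfg.alpha_r, cfg.dist, cfg.link)
        out["selection_posterior_share"] = sw["posterior_share"]
        out["selection_reproducibility"] = sw["reproducibility"]
    return out


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run one seeded literature; identical config implies identical output."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_studies

    truth = rng.random(n) < cfg.theta                      # 1: truth
    power = cfg.dist.sample(rng, n)                        # 2: power
    u_out = rng.random(n)                                  # 3: outcome

    if cfg.coupling == "study":
        positive = np.where(truth, u_out < power, u_out < cfg.alpha_o)
    else:
        marginal = cfg.theta * cfg.dist.mean + cfg.alpha_o * (1.0 - cfg.theta)
        positive = u_out < marginal
        # Truth is reassigned among positives from the per-study posterior,
        # so the true share among positives targets the mean-field E[post].
        fp = cfg.alpha_o * (1.0 - cfg.theta)
        post = cfg.theta * power / (cfg.theta * power + fp) if cfg.theta < 1.0 \
            else np.ones(n)
        truth = positive & (rng.random(n) < post)

    u_pub = rng.random(n)                                  # 4: publication
    published = positive | (u_pub < 1.0 / cfg.suppression_odds)

    u_rep = rng.random(n)                                  # 5: replication
    if cfg.coupling == "study":
        if cfg.link.kind == "identical":
            p_rep = power
        elif cfg.link.kind == "perfect":
            p_rep = np.ones(n)
        else:
            p_rep = np.clip(power + cfg.link.delta, 0.0, 1.0)
    else:
        p_rep = np.full(n, min(cfg.link.replication_power(cfg.dist.mean), 1.0))
    rep_success = np.where(truth, u_rep < p_rep, u_rep < cfg.alpha_r)

    pub_pos = positive  # positives are always published
    n_pub_pos = int(pub_pos.sum())
    n_replicated = int((pub_pos & rep_success).sum())
    n_pos = int(positive.sum())
    return SimulationResult(
        n_studies=n,
        n_true=int(truth.sum()),
        n_positive=n_pos,
        n_published_positive=n_pub_pos,
        n_published_negative=int((published & ~positive).sum()),
        n_replicated=n_replicated,
        empirical_positive_rate=n_pos / n,
        empirical_reproducibility=(n_replicated / n_pub_pos
                                   if n_pub_pos else float("nan")),
        empirical_posterior_share=(int((positive & truth).sum()) / n_pos
                                   if n_pos else float("nan")),
        predictions=_predictions(cfg),
    )


def summarize_bias(result: SimulationResult, L: float = 0.90) -> BiasResult:
    """Bias odds implied by the simulated positive rate."""
    if result.n_positive == 0:
        raise ValueError("no positive findings in the simulation")
    return BiasResult.from_rate(
        result.empirical_positive_rate, L,
        n_published_positive=result.n_published_positive,
    )
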