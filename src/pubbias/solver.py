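"""Solve for the mean original power consistent with a replication rate.

Given a prior theta, an observed replication rate R, the two test levels
and a power-linkage assumption, there is one unknown left: the mean power
of the original studies.  The expected-reproducibility map

    g(mu) = E[R](mu) - R

is monotone increasing in mu (a larger mean power raises both the
expected posterior and, under every link, the replication power), so a
bracketed root search on mu suffices.  Infeasibility — R unattainable
without better-than-perfect replication power, or a mixture mean outside
the component-mean interval — is reported as a flagged Solution, never an
exception, so sweeps over theta grids run to completion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bias import bias_odds
from .core import PowerLink
from .distributions import DistributionFamily, family_from_string
from .expectation import expected_posterior, expected_reproducibility

__all__ = [
    "Scenario",
    "Solution",
    "solve_scenario",
    "sweep_theta",
    "feasibility_bound",
    "envelope",
    "default_theta_grid",
    "SWEEP_COLUMNS",
    "LINK_PRESETS",
]

#: Power-linkage presets: identical power, perfect replications, and the
#: likely range of a 6-10 point power advantage for replications (midpoint 8).
LINK_PRESETS: dict[str, PowerLink] = {
    "identical": PowerLink.identical(),
    "perfect": PowerLink.perfect(),
    "likely_low": PowerLink.offset(0.06),
    "likely_mid": PowerLink.offset(0.08),
    "likely_high": PowerLink.offset(0.10),
}


@dataclass(frozen=True)
class Scenario:
    """One solvable configuration of the replication-rate system."""

    theta: float
    R: float = 0.36
    alpha_o: float = 0.05
    alpha_r: float = 0.025
    link: PowerLink = PowerLink.offset(0.08)
    family: DistributionFamily = family_from_string("beta:0.5")
    literature_share: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        if not (self.alpha_r < self.R < 1.0):
            raise ValueError("R must lie in (alpha_r, 1)")


@dataclass(frozen=True)
class Solution:
    """A solved scenario (or a flagged infeasibility)."""

    theta: float
    mean_power_original: float
    mean_power_replication: float
    expected_posterior: float
    expected_positive_rate: float
    bias_odds: float
    feasible: bool
    residual: float
    reason: str | None = None

    @classmethod
    def infeasible(cls, theta: float, reason: str) -> "Solution":
        nan = float("nan")
        return cls(theta, nan, nan, nan, nan, nan, False, nan, reason)


_EPS = 1e-9


def _bracket(sc: Scenario) -> tuple[float, float]:
    # Endpoint margins keep the derived Beta shape parameters in a range
    # the Jacobi quadrature handles; R in (alpha_r, 1) never puts the
    # root below a mean power of 1e-3.
    lo, hi = sc.family.mean_bounds
    if sc.family.family == "point":
        lo, hi = _EPS, 1.0
    else:
        lo = max(lo, 1e-3)
        hi = min(hi, 0.999)
    if sc.link.kind == "offset":
        hi = min(hi, 1.0 - sc.link.delta)
    return lo, hi


def solve_scenario(sc: Scenario, nodes: int = 64) -> Solution:
    """Root-find the mean original power reproducing ``sc.R``."""

    lo, hi = _bracket(sc)
    if hi <= lo:
        return Solution.infeasible(sc.theta, "no admissible mean power")

    def g(mu: float) -> float:
        e_post = expected_posterior(sc.theta, sc.alpha_o, sc.family.with_mean(mu),
                                    nodes=nodes)
        return expected_reproducibility(
            e_post, sc.link.replication_power(mu), sc.alpha_r) - sc.R

    g_hi = g(hi)
    if g_hi < 0.0:
        reason = ("replication power above 1 required"
                  if sc.link.kind == "offset" or hi >= 1.0 - 1e-6
                  else "mixture mean out of range")
        return Solution.infeasible(sc.theta, reason)
    g_lo = g(lo)
    if g_lo > 0.0:
        return Solution.infeasible(sc.theta, "R below the attainable range")

    mu = brentq(g, lo, hi, xtol=1e-13, rtol=1e-15)
    dist = sc.family.with_mean(mu)
    e_post = expected_posterior(sc.theta, sc.alpha_o, dist, nodes=nodes)
    p_r = sc.link.replication_power(mu)
    resid = abs(expected_reproducibility(e_post, p_r, sc.alpha_r) - sc.R)
    pos = sc.theta * mu + sc.alpha_o * (1.0 - sc.theta)
    return Solution(
        theta=sc.theta,
        mean_power_original=mu,
        mean_power_replication=p_r,
        expected_posterior=e_post,
        expected_positive_rate=pos,
        bias_odds=bias_odds(pos, sc.literature_share),
        feasible=True,
        residual=resid,
    )


SWEEP_COLUMNS = [
    "theta", "link", "dist", "mean_power_original", "mean_power_replication",
    "expected_posterior", "expected_positive_rate", "bias_odds",
    "feasible", "residual",
]


def default_theta_grid(n: int = 200, lo: float = 0.025, hi: float = 0.975
                       ) -> np.ndarray:
    """Log-spaced prior grid (the sweep x-axis is log scaled)."""
    return np.geomspace(lo, hi, n)


def _row(sc: Scenario, sol: Solution) -> dict:
    return {
        "theta": sol.theta,
        "link": str(sc.link),
        "dist": str(sc.family),
        "mean_power_original": sol.mean_power_original,
        "mean_power_replication": sol.mean_power_replication,
        "expected_posterior": sol.expected_posterior,
        "expected_positive_rate": sol.expected_positive_rate,
        "bias_odds": sol.bias_odds,
        "feasible": sol.feasible,
        "residual": sol.residual,
    }


def sweep_theta(template: Scenario, theta_grid=None) -> pd.DataFrame:
    """One Solution per prior on the grid; infeasible rows flagged, kept."""
    if theta_grid is None:
        theta_grid = default_theta_grid()
    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        sc = replace(template, theta=float(theta))
        rows.append(_row(sc, solve_scenario(sc)))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def feasibility_bound(template: Scenario, tol: float = 1e-4,
                      lo: float = 1e-4, hi: float = 0.5) -> float:
    """Smallest prior at which the scenario is feasible, by bisection.

    Feasibility is monotone in theta: a smaller prior demands more power,
    and below some prior the required power exceeds 1.
    """
    def ok(theta: float) -> bool:
        return solve_scenario(replace(template, theta=theta)).feasible

    if not ok(hi):
        raise ValueError("template infeasible even at the upper probe prior")
    if ok(lo):
        return lo  # feasible down to the probe edge
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


_ENVELOPE_FIELDS = [
    "mean_power_original", "mean_power_replication", "expected_posterior",
    "expected_positive_rate", "bias_odds",
]


def envelope(template: Scenario, variants, theta_grid=None) -> pd.DataFrame:
    """Per-theta min/max of each solved field across (link, family) variants.

    ``variants`` is an iterable of (PowerLink, DistributionFamily) pairs;
    rows where every variant is infeasible are flagged.
    """
    variants = [
        (v if isinstance(v, PowerLink) else PowerLink.parse(v),
         f if isinstance(f, DistributionFamily) else family_from_string(f))
        for v, f in variants
    ]
    if theta_grid is None:
        theta_grid = default_theta_grid()
    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        sols = [
            solve_scenario(replace(template, theta=float(theta), link=lk, family=fam))
            for lk, fam in variants
        ]
        feas = [s for s in sols if s.feasible]
        row: dict = {"theta": float(theta), "feasible": bool(feas),
                     "n_feasible": len(feas)}
        for f in _ENVELOPE_FIELDS:
            vals = [getattr(s, f) for s in feas]
            row[f"{f}_min"] = min(vals) if vals else float("nan")
            row[f"{f}_max"] = max(vals) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
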