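"""Machine-readable sweep tables for the headline analyses.

``run_headline_sweeps`` writes, for a given replication rate R, the
sweep-table twins of the standard four-panel figure: the likely band
(replication power 6-10 points above original, Beta s = 1/2), the
alternative-variance band, the extreme-variance and zero-variance
estimates, and the conservative outer boundaries.  ``run_rate_sweeps``
repeats the likely midpoint configuration (offset 0.08, Beta s = 1/2)
across a set of plausible replication rates.  Tables, not plots, are the
contract; every CSV is reproducible byte-for-byte from the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import PowerLink
from .distributions import family_from_string
from .solver import Scenario, default_theta_grid, envelope, sweep_theta

__all__ = ["RunConfig", "BAND_VARIANTS", "run_headline_sweeps", "run_rate_sweeps"]

log = logging.getLogger(__name__)

#: (link, family) variant lists behind each shaded band of the sweeps.
BAND_VARIANTS: dict[str, list[tuple[str, str]]] = {
    "likely": [("offset:0.06", "likely"), ("offset:0.1", "likely")],
    "alternative": [
        ("offset:0.06", "alt_small"), ("offset:0.1", "alt_small"),
        ("offset:0.06", "alt_large"), ("offset:0.1", "alt_large"),
    ],
    "extreme": [("offset:0.06", "extreme"), ("offset:0.1", "extreme")],
    "zero_variance": [("offset:0.06", "zero_variance"),
                      ("offset:0.1", "zero_variance")],
    "outer": [
        ("identical", "zero_variance"), ("perfect", "zero_variance"),
        ("identical", "extreme"), ("perfect", "extreme"),
    ],
}

#: Replication rates at the reported point estimate and the outer limits
#: of its 50, 75 and 95% confidence intervals.
DEFAULT_RATES = (0.27, 0.30, 0.32, 0.36, 0.40, 0.42, 0.46)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the sweep runners (JSON-loadable)."""

    R: float = 0.36
    rates: tuple = DEFAULT_RATES
    alpha_o: float = 0.05
    alpha_r: float = 0.025
    literature_share: float = 0.90
    theta_min: float = 0.025
    theta_max: float = 0.975
    n_points: int = 200
    bands: tuple = tuple(BAND_VARIANTS)
    out_dir: str = "sweeps"

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BAND_VARIANTS)
        if unknown:
            raise ValueError(f"unknown band preset(s): {sorted(unknown)}")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("rates", "bands"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def theta_grid(self) -> np.ndarray:
        return default_theta_grid(self.n_points, self.theta_min, self.theta_max)


def _template(cfg: RunConfig) -> Scenario:
    return Scenario(theta=0.5, R=cfg.R, alpha_o=cfg.alpha_o, alpha_r=cfg.alpha_r,
                    literature_share=cfg.literature_share)


def run_headline_sweeps(cfg: RunConfig) -> dict[str, Path]:
    """Write one envelope CSV per requested band; returns the paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.theta_grid()
    template = _template(cfg)
    paths: dict[str, Path] = {}
    for band in cfg.bands:
        table = envelope(template, BAND_VARIANTS[band], theta_grid=grid)
        path = out / f"band_{band}_R{cfg.R:g}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        log.info("band %s: %d/%d feasible rows -> %s",
                 band, int(table["feasible"].sum()), len(table), path)
        paths[band] = path
    return paths


def run_rate_sweeps(cfg: RunConfig) -> dict[float, Path]:
    """Likely-midpoint sweep (offset 0.08, Beta s=1/2) per replication rate."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.theta_grid()
    base = replace(_template(cfg), link=PowerLink.offset(0.08),
                   family=family_from_string("beta:0.5"))
    paths: dict[float, Path] = {}
    for R in cfg.rates:
        table = sweep_theta(replace(base, R=R), theta_grid=grid)
        path = out / f"rate_R{R:g}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        log.info("rate %s: %d/%d feasible rows -> %s",
                 R, int(table["feasible"].sum()), len(table), path)
        paths[R] = path
    return paths
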