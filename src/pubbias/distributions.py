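"""Distributions of per-study statistical power on the power scale [0, 1].

Three families are supported, matching the shapes used to model
between-study variance in power in meta-meta-analytic work:

``point``
    all studies share one power value (the zero-variance limit);
``beta``
    a Beta distribution specified by one shape parameter ``s`` and its
    mean ``mu``; the second shape parameter is derived so the mean comes
    out at ``mu``;
``bimodal``
    a two-component Beta mixture with *fixed* component means (defaults
    0.145 and 0.905; the "extreme variance" variant uses 0.0975 and
    0.9525) whose mixture weight is chosen so the overall mean is ``mu``.

Bimodality reflects the empirical observation that published literatures
contain many very under-powered and many very well-powered studies.

Densities are evaluated on the power scale (1 - beta), but the underlying
model describes a density over the type-2 error rate beta, so by default
the single shape parameter ``s`` attaches to the *beta-scale* Beta: with
mean power mu, power ~ Beta(s * mu / (1 - mu), s).  Set
``shape_scale="power"`` to attach ``s`` to the power scale instead
(power ~ Beta(s, s * (1 - mu) / mu)); the two conventions coincide at
mu = 1/2 and differ in how skew trades off against the mean elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "InfeasibleDistribution",
    "PowerDistribution",
    "DistributionFamily",
    "second_shape",
    "mixture_weight",
    "family_from_string",
    "FAMILY_PRESETS",
]


class InfeasibleDistribution(ValueError):
    """Raised when no member of a family has the requested mean."""


def second_shape(s: float, mu: float) -> float:
    """Second Beta shape parameter giving mean ``mu`` with first shape ``s``.

    The Beta(s1, s2) mean is s1/(s1+s2); solving for s2 gives
    s * (1 - mu) / mu.
    """
    if s <= 0:
        raise ValueError("shape parameter must be positive")
    if not (0.0 < mu < 1.0):
        raise ValueError("mean must lie strictly in (0, 1)")
    return s * (1.0 - mu) / mu


def mixture_weight(mu: float, m_lo: float, m_hi: float) -> float:
    """Weight on the low-mean component giving overall mean ``mu``.

    w * m_lo + (1 - w) * m_hi = mu  =>  w = (m_hi - mu) / (m_hi - m_lo).
    """
    if not (m_lo < m_hi):
        raise ValueError("component means must satisfy m_lo < m_hi")
    if not (m_lo <= mu <= m_hi):
        raise InfeasibleDistribution(
            f"mean {mu} outside the component-mean interval [{m_lo}, {m_hi}]"
        )
    return (m_hi - mu) / (m_hi - m_lo)


def _shapes(s: float, mu: float, shape_scale: str) -> tuple[float, float]:
    """Power-scale Beta shapes (a, b) for a component with mean ``mu``."""
    if shape_scale == "power":
        return s, second_shape(s, mu)
    # shape s fixed on the beta (type-2 error) scale; mirrored to power
    return second_shape(s, 1.0 - mu), s


@dataclass(frozen=True)
class PowerDistribution:
    """A distribution of per-study power with mean ``mu``.

    For the ``beta`` family ``s`` is the single free shape parameter.
    For ``bimodal``, ``s`` and ``s_hi`` are the shapes of the low- and
    high-mean components; ``m_lo``/``m_hi`` their fixed means.
    ``shape_scale`` selects whether the shapes attach to the beta-scale
    (default) or power-scale Beta; see the module docstring.
    """

    family: str
    mu: float
    s: float = 1.0
    s_hi: float = 1.0
    m_lo: float = 0.145
    m_hi: float = 0.905
    shape_scale: str = "type2"

    def __post_init__(self) -> None:
        if self.family not in ("point", "beta", "bimodal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.shape_scale not in ("type2", "power"):
            raise ValueError(f"unknown shape scale {self.shape_scale!r}")
        if self.family == "point":
            if not (0.0 <= self.mu <= 1.0):
                raise ValueError("point mass must lie in [0, 1]")
        elif not (0.0 < self.mu < 1.0):
            raise ValueError("mean must lie strictly in (0, 1)")
        if self.family == "bimodal":
            mixture_weight(self.mu, self.m_lo, self.m_hi)  # validates

    # -- constructors -------------------------------------------------

    @classmethod
    def point(cls, mu: float) -> "PowerDistribution":
        return cls("point", mu)

    @classmethod
    def beta(cls, s: float, mu: float,
             shape_scale: str = "type2") -> "PowerDistribution":
        second_shape(s, mu)  # validates s and mu
        return cls("beta", mu, s=s, shape_scale=shape_scale)

    @classmethod
    def bimodal(
        cls,
        mu: float,
        s_lo: float = 1.0,
        s_hi: float = 2.0,
        m_lo: float = 0.145,
        m_hi: float = 0.905,
        shape_scale: str = "type2",
    ) -> "PowerDistribution":
        return cls("bimodal", mu, s=s_lo, s_hi=s_hi, m_lo=m_lo, m_hi=m_hi,
                   shape_scale=shape_scale)

    # -- structure ----------------------------------------------------

    @property
    def mean(self) -> float:
        return self.mu

    def components(self) -> list[tuple[float, float, float]]:
        """Mixture decomposition as (weight, a, b) Beta components.

        The point family has no density and returns an empty list;
        callers handle it symbolically.
        """
        if self.family == "point":
            return []
        if self.family == "beta":
            return [(1.0, *_shapes(self.s, self.mu, self.shape_scale))]
        w = mixture_weight(self.mu, self.m_lo, self.m_hi)
        return [
            (w, *_shapes(self.s, self.m_lo, self.shape_scale)),
            (1.0 - w, *_shapes(self.s_hi, self.m_hi, self.shape_scale)),
        ]

    def density(self, power):
        """Density at ``power`` (vectorized). Point masses have none."""
        if self.family == "point":
            raise ValueError("a point mass has no finite density")
        p = np.asarray(power, dtype=float)
        out = np.zeros_like(p)
        for w, a, b in self.components():
            out = out + w * stats.beta.pdf(p, a, b)
        return out if out.shape else float(out)

    @property
    def variance(self) -> float:
        """Variance of power, by closed form.

        Beta(a, b) variance is mu(1-mu)/(a+b+1); the mixture variance adds
        the spread of the component means (law of total variance).
        """
        if self.family == "point":
            return 0.0
        second = 0.0
        for w, a, b in self.components():
            m = a / (a + b)
            v = m * (1.0 - m) / (a + b + 1.0)
            second += w * (v + m * m)
        return second - self.mu**2

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw per-study power values."""
        if self.family == "point":
            return np.full(size, self.mu)
        comps = self.components()
        if len(comps) == 1:
            _, a, b = comps[0]
            return rng.beta(a, b, size)
        w = comps[0][0]
        lo = rng.random(size) < w
        draws = rng.beta(comps[1][1], comps[1][2], size)
        draws[lo] = rng.beta(comps[0][1], comps[0][2], lo.sum())
        return draws

    def __str__(self) -> str:
        tag = "@power" if self.shape_scale == "power" else ""
        if self.family == "point":
            return "point"
        if self.family == "beta":
            return f"beta:{self.s:g}{tag}"
        return f"bimodal:{self.s:g},{self.s_hi:g}:{self.m_lo:g},{self.m_hi:g}{tag}"


@dataclass(frozen=True)
class DistributionFamily:
    """A power-distribution family with the mean left free.

    The solver treats the mean power as the unknown; a family pins every
    other parameter so that ``with_mean`` yields a concrete distribution.
    """

    family: str
    s: float = 1.0
    s_hi: float = 1.0
    m_lo: float = 0.145
    m_hi: float = 0.905
    shape_scale: str = "type2"

    def with_mean(self, mu: float) -> PowerDistribution:
        if self.family == "point":
            return PowerDistribution.point(mu)
        if self.family == "beta":
            return PowerDistribution.beta(self.s, mu, shape_scale=self.shape_scale)
        return PowerDistribution.bimodal(
            mu, s_lo=self.s, s_hi=self.s_hi, m_lo=self.m_lo, m_hi=self.m_hi,
            shape_scale=self.shape_scale,
        )

    @property
    def mean_bounds(self) -> tuple[float, float]:
        """Closed interval of attainable means."""
        if self.family == "bimodal":
            return (self.m_lo, self.m_hi)
        return (0.0, 1.0)

    def __str__(self) -> str:
        tag = "@power" if self.shape_scale == "power" else ""
        if self.family == "point":
            return "point"
        if self.family == "beta":
            return f"beta:{self.s:g}{tag}"
        return f"bimodal:{self.s:g},{self.s_hi:g}:{self.m_lo:g},{self.m_hi:g}{tag}"


def family_from_string(spec: str) -> DistributionFamily:
    """Parse ``point``, ``beta:<s>`` or ``bimodal:<s_lo>,<s_hi>:<m_lo>,<m_hi>``.

    A trailing ``@power`` switches the shape convention to the power
    scale (default: shapes attach to the type-2 error scale).
    """
    if spec in FAMILY_PRESETS:
        spec = FAMILY_PRESETS[spec]
    shape_scale = "type2"
    if spec.endswith("@power"):
        shape_scale = "power"
        spec = spec[: -len("@power")]
    if spec == "point":
        return DistributionFamily("point")
    kind, _, rest = spec.partition(":")
    if kind == "beta" and rest:
        return DistributionFamily("beta", s=float(rest), shape_scale=shape_scale)
    if kind == "bimodal" and rest:
        shapes, _, means = rest.partition(":")
        s_lo, s_hi = (float(x) for x in shapes.split(","))
        if means:
            m_lo, m_hi = (float(x) for x in means.split(","))
        else:
            m_lo, m_hi = 0.145, 0.905
        return DistributionFamily("bimodal", s=s_lo, s_hi=s_hi, m_lo=m_lo,
                                  m_hi=m_hi, shape_scale=shape_scale)
    raise ValueError(f"cannot parse distribution spec {spec!r}")


#: Named variance presets: the likely-range Beta(s=1/2); a smaller-variance
#: Beta(s=1) and a larger-variance bimodal mixture as alternatives; an
#: extreme-variance mixture with component means pushed to 0.0975/0.9525;
#: and the zero-variance point mass.  Mixture components sit at fixed
#: power-scale means near the endpoints, so their shapes attach to the
#: power scale (keeping the low-power component bounded at zero); the
#: free-mean single-shape family keeps the type-2-scale default.
FAMILY_PRESETS: dict[str, str] = {
    "likely": "beta:0.5",
    "alt_small": "beta:1",
    "alt_large": "bimodal:1,2:0.145,0.905@power",
    "extreme": "bimodal:1,1:0.0975,0.9525@power",
    "zero_variance": "point",
}
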