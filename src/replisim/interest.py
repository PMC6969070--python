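"""Community interest: citations and the stochastic replication decision.

Scientific interest in a finding is modelled through citations.  Each
finding receives a citation draw from a generalized Pareto distribution
fitted to psychology citation counts (shape k = 0.115, scale 8.71,
location 0); the draw is converted to a probability of being deemed
interesting by a logistic function centered on a percentile threshold q
(the 90th percentile, 22.96 citations, by default) with temperature t:

    P(interesting) = 1 / (1 + exp(-(n_k - q) / t))

Larger temperatures make the threshold more graded, so low-citation
findings are more likely to attract interest.  Citation draws are
independent of a finding's truth status — citations do not predict
replicability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

#: Generalized Pareto fit to citations of psychology articles (3 years).
GPD_SHAPE = 0.115
GPD_SCALE = 8.71
GPD_LOCATION = 0.0

_EXP_CLAMP = 700.0  # largest safe argument for math.exp in float64


def gpd_quantile(shape: float, scale: float, loc: float, p: float) -> float:
    """Closed-form generalized Pareto inverse CDF.

    q(p) = loc + scale/shape * ((1-p)^(-shape) - 1) for shape != 0, with
    the exponential limit loc - scale*log(1-p) at shape = 0.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if shape == 0.0:
        return loc - scale * math.log1p(-p)
    return loc + scale / shape * ((1.0 - p) ** (-shape) - 1.0)


def gpd_cdf(shape: float, scale: float, loc: float, x: float) -> float:
    """Generalized Pareto CDF (companion to :func:`gpd_quantile`)."""
    z = (x - loc) / scale
    if z < 0:
        return 0.0
    if shape == 0.0:
        return 1.0 - math.exp(-z)
    return 1.0 - (1.0 + shape * z) ** (-1.0 / shape)


@dataclass(frozen=True)
class InterestModel:
    """Citation distribution plus the logistic decision rule."""

    shape: float = GPD_SHAPE
    scale: float = GPD_SCALE
    loc: float = GPD_LOCATION
    threshold_percentile: float = 0.90
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 < self.threshold_percentile < 1.0:
            raise ValueError("threshold_percentile must lie in (0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def q(self) -> float:
        """Citation threshold: the configured percentile of the fit."""
        return gpd_quantile(self.shape, self.scale, self.loc, self.threshold_percentile)


@dataclass(frozen=True)
class InterestDraw:
    """One finding's citation draw and the resulting interest decision."""

    n_k: float
    p_interest: float
    interesting: bool


def sample_citation(model: InterestModel, rng: np.random.Generator) -> float:
    """One citation count: inverse-CDF draw from the fitted GPD."""
    return float(sample_citations(model, 1, rng)[0])


def sample_citations(
    model: InterestModel, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized iid citation draws via the inverse CDF."""
    u = rng.random(size)
    if model.shape == 0.0:
        return model.loc - model.scale * np.log1p(-u)
    return model.loc + model.scale / model.shape * ((1.0 - u) ** -model.shape - 1.0)


def interest_probability(
    n_k: Union[float, np.ndarray], q: float, t: float
) -> Union[float, np.ndarray]:
    """Logistic probability that a finding with n_k citations is interesting."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    z = np.clip((np.asarray(n_k, dtype=float) - q) / t, -_EXP_CLAMP, _EXP_CLAMP)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p) if np.isscalar(n_k) else p


def draw_interest(model: InterestModel, rng: np.random.Generator) -> InterestDraw:
    """Citation draw -> logistic probability -> Bernoulli interest decision."""
    n_k, p, flag = draw_interests(model, 1, rng)
    return InterestDraw(float(n_k[0]), float(p[0]), bool(flag[0]))


def draw_interests(
    model: InterestModel, size: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized interest decisions: (citations, probabilities, flags)."""
    n_k = sample_citations(model, size, rng)
    p = interest_probability(n_k, model.q, model.temperature)
    flags = rng.random(size) < p
    return n_k, np.asarray(p), flags
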