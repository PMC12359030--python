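"""The beta-Markov model of read depths along a sequence.

Read depths live between fixed bounds [d_min, d_max] and are modelled through
the scaled depth x = (d - d_min) / (d_max - d_min) in [0, 1].  The average
depth of a species is drawn once per dataset from a beta distribution with
concentration ``a_samples``; depths at sites along each sequence follow a
first-order Markov chain whose conditional distribution is beta with
concentration ``a_positions`` and mean p * x_prev + (1 - p) * x_species, where
x_prev is the scaled depth emitted at the previous site.  Emitted depths are
the latent value mapped back to [d_min, d_max] and rounded, floor(d + 0.5).

Two Markov variants are provided: ``conditional-mean`` (the default, used for
simulation) and ``copy`` (copy the previous depth with probability p, else
draw a fresh beta), kept for goodness-of-fit comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import MODEL_CONDITIONAL_MEAN, MODEL_COPY, beta_markov_latent

__all__ = [
    "DepthParams",
    "DEPTH_MODELS",
    "scale_depth",
    "unscale_depth",
    "round_depth",
    "sample_species_mean",
    "sample_depth_track",
    "sample_latent_track",
    "same_depth_probability",
]

DEPTH_MODELS = ("conditional-mean", "copy")
_MODEL_CODE = {"conditional-mean": MODEL_CONDITIONAL_MEAN, "copy": MODEL_COPY}


@dataclass(frozen=True)
class DepthParams:
    """Parameters of the read-depth model.

    mean_depth:  overall average depth d-bar (reads per site)
    a_samples:   beta concentration for between-species depth variation
    a_positions: beta concentration for between-site variation in a sequence
    corr_p:      adjacent-site depth correlation p in [0, 1)
    depth_min/depth_max: hard bounds on emitted depths
    model:       'conditional-mean' or 'copy'
    """

    mean_depth: float
    a_samples: float = 500.0
    a_positions: float = 1000.0
    corr_p: float = 0.9
    depth_min: int = 2
    depth_max: int = 100
    model: str = "conditional-mean"

    def __post_init__(self):
        if not self.depth_min <= self.mean_depth <= self.depth_max:
            raise ValueError("mean_depth must lie within [depth_min, depth_max]")
        if not 0.0 <= self.corr_p < 1.0:
            raise ValueError("corr_p must lie in [0, 1)")
        if self.a_samples <= 0 or self.a_positions <= 0:
            raise ValueError("concentration parameters must be positive")
        if self.depth_min >= self.depth_max:
            raise ValueError("depth_min must be below depth_max")
        if self.model not in DEPTH_MODELS:
            raise ValueError(f"model must be one of {DEPTH_MODELS}")

    @property
    def span(self) -> float:
        return float(self.depth_max - self.depth_min)

    @property
    def mean_scaled(self) -> float:
        """The overall mean depth on the scaled [0, 1] axis."""
        return scale_depth(self.mean_depth, self)


def scale_depth(d, params: DepthParams):
    """Map a depth in [depth_min, depth_max] to the scaled value x in [0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < params.depth_min) or np.any(d > params.depth_max):
        raise ValueError("depth outside [depth_min, depth_max]")
    x = (d - params.depth_min) / params.span
    return float(x) if x.ndim == 0 else x


def unscale_depth(x, params: DepthParams):
    """Inverse of :func:`scale_depth` on the continuous scale."""
    x = np.asarray(x, dtype=float)
    d = params.depth_min + x * params.span
    return float(d) if d.ndim == 0 else d


def round_depth(d):
    """Emit integer depths as floor(d + 0.5)."""
    return np.floor(np.asarray(d, dtype=float) + 0.5).astype(np.int64)


def sample_species_mean(params: DepthParams, rng: np.random.Generator) -> float:
    """Draw the scaled average depth x_s of one species.

    x_s ~ beta(x * a_samples, (1 - x) * a_samples) where x is the overall
    scaled mean, so E[x_s] = x and var[x_s] = x (1 - x) / (a_samples + 1).
    """
    x = params.mean_scaled
    if not 0.0 < x < 1.0:
        raise ValueError("overall scaled mean depth must lie strictly in (0, 1)")
    return float(rng.beta(x * params.a_samples, (1.0 - x) * params.a_samples))


def _chain_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def sample_latent_track(
    xbar_s: float,
    sites: int,
    params: DepthParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one sequence's depth track; returns (latent x, integer depths)."""
    if not 0.0 < xbar_s < 1.0:
        raise ValueError("species mean must lie strictly in (0, 1)")
    if sites < 1:
        raise ValueError("need at least one site")
    x = beta_markov_latent(
        float(xbar_s),
        params.corr_p,
        params.a_positions,
        float(params.depth_min),
        float(params.depth_max),
        int(sites),
        _chain_seed(rng),
        _MODEL_CODE[params.model],
    )
    return x, round_depth(unscale_depth(x, params))


def sample_depth_track(
    xbar_s: float,
    sites: int,
    params: DepthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the integer read depths for one sequence of ``sites`` sites."""
    return sample_latent_track(xbar_s, sites, params, rng)[1]


def same_depth_probability(
    mean_depth: float,
    params: DepthParams | None = None,
    chain_sites: int = 10_000_000,
    rng: np.random.Generator | None = None,
    burn_in: int = 1000,
) -> float:
    """Model-predicted probability that two adjacent sites share a read depth.

    A single long track is simulated at the given mean depth with no
    species-level noise (the chain mean is the scaled ``mean_depth`` itself)
    and the fraction of adjacent pairs with equal rounded depth is returned.
    Monte-Carlo error at the default 10^7 sites is about 0.0005.
    """
    if params is None:
        params = DepthParams(mean_depth=mean_depth)
    else:
        params = DepthParams(
            mean_depth=mean_depth,
            a_samples=params.a_samples,
            a_positions=params.a_positions,
            corr_p=params.corr_p,
            depth_min=params.depth_min,
            depth_max=params.depth_max,
            model=params.model,
        )
    if rng is None:
        rng = np.random.default_rng()
    if chain_sites <= burn_in + 1:
        raise ValueError("chain_sites must exceed burn_in + 1")
    xbar = params.mean_scaled
    _, d = sample_latent_track(xbar, chain_sites, params, rng)
    d = d[burn_in:]
    return float(np.mean(d[1:] == d[:-1]))
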