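"""Precision-weighted Gaussian generative model of single-trial pain ratings.

A participant's reported rating Y on trial i is modelled as arising from the
product of three Gaussian factors:

    p(Y | X, q, SD; theta)  ∝  N(X; Y, beta2) · N(q; Y + eta·SD, rho2)
                               · N(Y; mu, nu2)

where X is the rescaled delivered stimulation, q the rescaled cue mean, SD
the cue spread, and theta = (beta2, eta, rho2, mu, nu2) the participant's
parameters. Normalising the product over Y yields a Gaussian whose precision
is the sum of the three factor precisions and whose mean is the
precision-weighted average of X, (q - eta·SD) and mu — the standard
precision-weighting result for products of Gaussians. The reported rating is
treated as a draw from that collapsed Gaussian, which makes the collapsed
density the exact per-trial likelihood used for inference.

Interpretation of the precisions: 1/beta2 is the weight of somatosensory
input, 1/rho2 the weight of the cue (expectation), and (mu, 1/nu2) a
trait-like rating bias and the weight placed on it. eta is a signed scale
that maps cue spread into a shift of the expected cue value (positive:
uncertain cues raise the pain expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "ParticipantParams",
    "PrecisionWeights",
    "RatingObservation",
    "factor_logdensities",
    "collapse_posterior",
    "simulate_rating",
    "simulate_ratings",
    "joint_loglik",
]


@dataclass(frozen=True)
class PrecisionWeights:
    """Factor precisions: the weights the rating places on each source."""

    w_stim: float
    w_cue: float
    w_bias: float

    def to_variances(self) -> tuple[float, float, float]:
        return 1.0 / self.w_stim, 1.0 / self.w_cue, 1.0 / self.w_bias


@dataclass(frozen=True)
class ParticipantParams:
    """Participant-level parameters of the rating model (0-100 scale units).

    beta2, rho2, nu2 are the variances of the stimulation, cue and bias
    factors; mu is the trait-like bias mean; eta the signed cue-uncertainty
    scale.
    """

    beta2: float
    eta: float
    rho2: float
    mu: float
    nu2: float

    def __post_init__(self) -> None:
        for name in ("beta2", "rho2", "nu2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("eta", "mu"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def weights(self) -> PrecisionWeights:
        return PrecisionWeights(
            w_stim=1.0 / self.beta2, w_cue=1.0 / self.rho2, w_bias=1.0 / self.nu2
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "beta2": self.beta2,
            "eta": self.eta,
            "rho2": self.rho2,
            "mu": self.mu,
            "nu2": self.nu2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantParams":
        return cls(**{k: float(d[k]) for k in ("beta2", "eta", "rho2", "mu", "nu2")})


@dataclass(frozen=True)
class RatingObservation:
    """One trial's model inputs and the reported rating."""

    X: float
    q: float
    SD: float
    Y: float

    def __post_init__(self) -> None:
        if self.SD < 0:
            raise ValueError("SD must be non-negative")


def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def factor_logdensities(
    obs: RatingObservation, params: ParticipantParams
) -> tuple[float, float, float]:
    """Log-densities of the three Gaussian factors at the observed rating.

    Returns (stimulation, cue, bias) terms:
    log N(X; Y, beta2), log N(q; Y + eta·SD, rho2), log N(Y; mu, nu2).
    """
    l_stim = _norm_logpdf(obs.X, obs.Y, params.beta2)
    l_cue = _norm_logpdf(obs.q, obs.Y + params.eta * obs.SD, params.rho2)
    l_bias = _norm_logpdf(obs.Y, params.mu, params.nu2)
    return float(l_stim), float(l_cue), float(l_bias)


def collapse_posterior(X, q, SD, params: ParticipantParams):
    """Collapse the three-factor product over Y into its Gaussian (m, s2).

    The collapsed precision is the sum of the factor precisions,
    1/s2 = 1/beta2 + 1/rho2 + 1/nu2, and the mean is the precision-weighted
    convex combination m = s2·(X/beta2 + (q - eta·SD)/rho2 + mu/nu2).
    Accepts scalars or arrays (broadcast elementwise); s2 is scalar.
    """
    w_stim, w_cue, w_bias = (
        1.0 / params.beta2,
        1.0 / params.rho2,
        1.0 / params.nu2,
    )
    s2 = 1.0 / (w_stim + w_cue + w_bias)
    cue_val = np.asarray(q, dtype=float) - params.eta * np.asarray(SD, dtype=float)
    m = s2 * (np.asarray(X, dtype=float) * w_stim + cue_val * w_cue + params.mu * w_bias)
    if np.ndim(m) == 0:
        return float(m), float(s2)
    return m, float(s2)


def simulate_rating(
    X: float,
    q: float,
    SD: float,
    params: ParticipantParams,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 100.0,
) -> tuple[float, float]:
    """Draw one rating from the collapsed Gaussian; clip to the scale.

    Returns ``(rating, pre_clip)``: the clipped value reported on the 0-100
    scale and the raw Gaussian draw.
    """
    m, s2 = collapse_posterior(X, q, SD, params)
    raw = float(rng.normal(m, np.sqrt(s2)))
    return float(np.clip(raw, lo, hi)), raw


def simulate_ratings(
    X: np.ndarray,
    q: np.ndarray,
    SD: np.ndarray,
    params: ParticipantParams,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 100.0,
    clip_warn: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorised forward simulation over trials.

    Returns ``(ratings, pre_clip, clip_rate)`` and warns when more than
    ``clip_warn`` of the draws hit the scale boundaries — a sign the chosen
    population parameters push ratings off the 0-100 scale.
    """
    m, s2 = collapse_posterior(X, q, SD, params)
    raw = rng.normal(np.asarray(m, dtype=float), np.sqrt(s2))
    clipped = np.clip(raw, lo, hi)
    clip_rate = float(np.mean(raw != clipped))
    if clip_rate > clip_warn:
        warnings.warn(
            f"{clip_rate:.1%} of simulated ratings clipped to [{lo}, {hi}]",
            stacklevel=2,
        )
    return clipped, raw, clip_rate


def joint_loglik(
    trials: Sequence[RatingObservation] | None,
    params: ParticipantParams,
    X: Optional[np.ndarray] = None,
    q: Optional[np.ndarray] = None,
    SD: Optional[np.ndarray] = None,
    Y: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of observed ratings under the collapsed model.

    Each trial contributes log N(Y; m, s2) with (m, s2) from
    :func:`collapse_posterior`. Pass either a sequence of
    :class:`RatingObservation` or the four arrays directly.
    """
    if trials is not None:
        if len(trials) == 0:
            raise ValueError("joint_loglik requires at least one trial")
        X = np.array([t.X for t in trials])
        q = np.array([t.q for t in trials])
        SD = np.array([t.SD for t in trials])
        Y = np.array([t.Y for t in trials])
    else:
        X, q, SD, Y = (np.asarray(v, dtype=float) for v in (X, q, SD, Y))
        if X.size == 0:
            raise ValueError("joint_loglik requires at least one trial")
    m, s2 = collapse_posterior(X, q, SD, params)
    return float(np.sum(_norm_logpdf(Y, m, s2)))
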