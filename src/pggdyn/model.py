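"""Core model: parameters, expected producer counts, and sigmoidal growth rates.

A population of producer cells (cooperators, ``C``) and free-riders
(defectors, ``D``) interacts through a public good shared within finite
neighborhoods of ``n`` cells.  The expected fraction of producers among the
``n`` providers relevant to a focal individual is affine in the global
cooperator fraction ``y``; the benefit converting that fraction into an
intrinsic growth rate is sigmoidal, controlled by a frequency-dependent
strength ``beta`` and a frequency-independent background ``sigma``.
Producers pay a constant cost ``kappa``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Strategy = Literal["C", "D"]

__all__ = [
    "NeighborhoodSpec",
    "ModelParams",
    "PopulationState",
    "expected_producers",
    "sigmoid_benefit",
    "intrinsic_growth_rate",
    "growth_rate_difference",
    "inflection_point",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighborhood sizes experienced by each strategy.

    ``n_C`` and ``n_D`` may differ (e.g. anisotropic diffusion of the public
    good); the symmetric case ``n_C == n_D == n`` recovers the baseline
    model.  Non-integer sizes are allowed: the compartment model produces
    real-valued effective neighborhoods ``Y/N``.
    """

    n_C: float
    n_D: float

    def __post_init__(self) -> None:
        if self.n_C < 1 or self.n_D < 1:
            raise ValueError("neighborhood sizes must be >= 1")

    @classmethod
    def symmetric(cls, n: float) -> "NeighborhoodSpec":
        return cls(n_C=n, n_D=n)

    def size_for(self, focal: Strategy) -> float:
        return self.n_C if focal == "C" else self.n_D


@dataclass(frozen=True)
class ModelParams:
    """All rates and game parameters of the public-goods growth model.

    Parameters
    ----------
    alpha_C, alpha_D
        Baseline birth rates (per day); must be positive.
    delta_C, delta_D
        Density-independent death rates (per day).
    kappa
        Cost of public-good production (per day), paid only by cooperators.
    K
        Carrying capacity (cells); enters through the global density factor
        ``E_K = 1 - (x_C + x_D)/K`` multiplying birth rates.
    beta
        Strength of the frequency-dependent benefit (dimensionless).
    sigma
        Frequency-independent background parameter (dimensionless).
    neighborhood
        Neighborhood sizes; see :class:`NeighborhoodSpec`.
    """

    alpha_C: float = 1.0
    alpha_D: float = 1.0
    delta_C: float = 0.1
    delta_D: float = 0.1
    kappa: float = 0.5
    K: float = 1000.0
    beta: float = 2.0
    sigma: float = 3.0
    neighborhood: NeighborhoodSpec = field(
        default_factory=lambda: NeighborhoodSpec.symmetric(10.0)
    )

    def __post_init__(self) -> None:
        if self.alpha_C <= 0 or self.alpha_D <= 0:
            raise ValueError("baseline birth rates must be positive")
        if self.delta_C < 0 or self.delta_D < 0:
            raise ValueError("death rates must be nonnegative")
        if self.kappa < 0:
            raise ValueError("cost kappa must be nonnegative")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.beta < 0 or self.sigma < 0:
            raise ValueError("beta and sigma must be nonnegative")

    # -- convenience -------------------------------------------------------
    @property
    def n_C(self) -> float:
        return self.neighborhood.n_C

    @property
    def n_D(self) -> float:
        return self.neighborhood.n_D

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced.

        ``n`` sets both neighborhood sizes; ``n_C``/``n_D`` set them
        individually.
        """
        n = kwargs.pop("n", None)
        n_C = kwargs.pop("n_C", None)
        n_D = kwargs.pop("n_D", None)
        nbhd = self.neighborhood
        if n is not None:
            nbhd = NeighborhoodSpec.symmetric(float(n))
        if n_C is not None or n_D is not None:
            nbhd = NeighborhoodSpec(
                n_C=float(n_C) if n_C is not None else nbhd.n_C,
                n_D=float(n_D) if n_D is not None else nbhd.n_D,
            )
        return replace(self, neighborhood=nbhd, **kwargs)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha_C": self.alpha_C,
            "alpha_D": self.alpha_D,
            "delta_C": self.delta_C,
            "delta_D": self.delta_D,
            "kappa": self.kappa,
            "K": self.K,
            "beta": self.beta,
            "sigma": self.sigma,
            "n_C": self.n_C,
            "n_D": self.n_D,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "n" in d:
            n = float(d.pop("n"))
            d.setdefault("n_C", n)
            d.setdefault("n_D", n)
        nbhd = NeighborhoodSpec(n_C=float(d.pop("n_C", 10.0)), n_D=float(d.pop("n_D", 10.0)))
        allowed = {"alpha_C", "alpha_D", "delta_C", "delta_D", "kappa", "K", "beta", "sigma"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(neighborhood=nbhd, **{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class PopulationState:
    """Abundances of cooperators and defectors (cells, nonnegative)."""

    x_C: float
    x_D: float

    def __post_init__(self) -> None:
        if self.x_C < 0 or self.x_D < 0:
            raise ValueError("abundances must be nonnegative")

    @property
    def total(self) -> float:
        return self.x_C + self.x_D

    @property
    def fraction_C(self) -> float:
        """Cooperator fraction y; 1 if only C present, 0 if only D.

        Undefined at total extinction — raises there, since no dynamical
        quantity should be evaluated on an empty population.
        """
        if self.total == 0:
            raise ValueError("cooperator fraction undefined at total extinction")
        if self.x_D == 0:
            return 1.0
        if self.x_C == 0:
            return 0.0
        return self.x_C / self.total


def _check_y_n(y, n) -> None:
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("cooperator fraction y must lie in [0, 1]")
    if np.any(np.asarray(n, dtype=float) < 1):
        raise ValueError("neighborhood size n must be >= 1")


def expected_producers(y, n, focal: Strategy):
    """Expected fraction of producers among the ``n`` public-good providers.

    A focal cooperator always counts itself, so it sees
    ``N_C = [1 + (n-1) y] / n``; a focal defector sees
    ``N_D = (n-1) y / n``.  Both are the large-population means of sampling
    ``n - 1`` neighbors at cooperator frequency ``y``; the self-contribution
    gives the exact identity ``N_C - N_D = 1/n``.

    Accepts scalars or arrays in ``y`` (and broadcastable ``n``).
    """
    _check_y_n(y, n)
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if focal == "C":
        out = (1.0 + (n - 1.0) * y) / n
    elif focal == "D":
        out = (n - 1.0) * y / n
    else:
        raise ValueError(f"focal strategy must be 'C' or 'D', got {focal!r}")
    return out if out.ndim else float(out)


def sigmoid_benefit(N, sigma: float, beta: float):
    """Sigmoidal benefit factor ``(1 + e^sigma) / (1 + e^(sigma - beta N))``.

    Equals 1 at ``N = 0`` and saturates toward ``1 + e^sigma`` for large
    ``beta N``; its inflection in ``N`` sits at ``sigma/beta``.  This is the
    single dispatch point for the benefit functional form (a Hill-type
    variant could be slotted in here).
    """
    N = np.asarray(N, dtype=float)
    out = (1.0 + np.exp(sigma)) / (1.0 + np.exp(sigma - beta * N))
    return out if out.ndim else float(out)


def intrinsic_growth_rate(y, params: ModelParams, focal: Strategy):
    """Frequency-dependent intrinsic growth rate of the focal strategy (per day).

    ``r_C = alpha_C * benefit(N_C) - kappa`` and
    ``r_D = alpha_D * benefit(N_D)``, with ``N_C`` evaluated at the
    cooperator neighborhood size ``n_C`` and ``N_D`` at ``n_D``.  The cost
    can exceed the benefit, so ``r_C`` may be negative; clamping to
    nonnegative propensities happens only in the stochastic layer.
    """
    n = params.neighborhood.size_for(focal)
    N = expected_producers(y, n, focal)
    b = sigmoid_benefit(N, params.sigma, params.beta)
    if focal == "C":
        return params.alpha_C * b - params.kappa
    return params.alpha_D * b


def growth_rate_difference(y, params: ModelParams):
    """``r_C(y) - r_D(y)`` (per day); constant ``-kappa`` when beta = 0."""
    return intrinsic_growth_rate(y, params, "C") - intrinsic_growth_rate(y, params, "D")


def inflection_point(params: ModelParams) -> float:
    """Producer-fraction location ``sigma/beta`` of maximal benefit increase.

    Below it additional producers create synergy (increasing returns); above
    it returns diminish.  Undefined for ``beta = 0`` (no frequency
    dependence).
    """
    if params.beta == 0:
        raise ValueError("inflection point undefined for beta = 0")
    return params.sigma / params.beta
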