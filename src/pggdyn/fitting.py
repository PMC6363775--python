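"""Maximum-likelihood estimation of the benefit parameters (beta, sigma).

Cell-competition assays report the change in cooperator fraction over a
fixed duration for a panel of initial fractions.  We model each observed
change as the solution of the reduced cooperator-fraction equation plus iid
Gaussian observation noise with unknown common scale; profiling the noise
variance makes maximum likelihood equivalent to least squares in
(beta, sigma).  Because the interaction range of a secreted factor is not
directly observable, fits are repeated over a range of neighborhood sizes
``n`` and summarized by per-condition medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dynamics import frequency_change
from .equilibria import Equilibrium, find_interior_equilibria
from .model import ModelParams

__all__ = [
    "DEFAULT_FIXED",
    "FrequencyChangeDataset",
    "FitResult",
    "predict_delta_y",
    "fit_beta_sigma",
    "fit_across_n",
    "equilibrium_prediction_from_fit",
]

#: per-condition fixed parameters used unless overridden: unit background
#: growth rate, production cost of a quarter of it, equal deaths, and the
#: near-exponential early-growth regime of short in vitro assays
DEFAULT_FIXED = {
    "alpha": 1.0,
    "kappa": 0.25,
    "delta_C": 0.1,
    "delta_D": 0.1,
    "density_mode": "exponential_regime",
    "Y0": None,
    "K": 1000.0,
}

DEFAULT_BOUNDS = ((0.0, 20.0), (0.0, 10.0))
DEFAULT_N_RANGE = tuple(range(4, 41))


@dataclass
class FrequencyChangeDataset:
    """Table of frequency-change observations.

    Columns: ``condition`` (label, e.g. an FBS percentage), ``y0`` (initial
    cooperator fraction), ``delta_y`` (observed change over the assay),
    ``duration_days``, ``replicate``.
    """

    frame: pd.DataFrame

    REQUIRED = ("condition", "y0", "delta_y", "duration_days", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        f = self.frame
        if ((f["y0"] < 0) | (f["y0"] > 1)).any():
            raise ValueError("y0 must lie in [0, 1]")
        final = f["y0"] + f["delta_y"]
        if ((final < -1e-9) | (final > 1 + 1e-9)).any():
            raise ValueError("y0 + delta_y must lie in [0, 1]")
        if (f["duration_days"] <= 0).any():
            raise ValueError("duration must be positive")

    @property
    def conditions(self) -> list:
        return sorted(self.frame["condition"].unique().tolist())

    def slice(self, condition) -> "FrequencyChangeDataset":
        return FrequencyChangeDataset(self.frame[self.frame["condition"] == condition].copy())

    @classmethod
    def from_csv(cls, path) -> "FrequencyChangeDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class FitResult:
    """ML estimate of (beta, sigma) at one neighborhood size."""

    condition: object
    n: float
    beta_hat: float
    sigma_hat: float
    nll: float
    noise_sd: float
    converged: bool
    at_bound: bool
    n_obs: int
    starts: list[dict] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "beta_hat": self.beta_hat,
            "sigma_hat": self.sigma_hat,
            "nll": self.nll,
            "noise_sd": self.noise_sd,
            "converged": self.converged,
            "at_bound": self.at_bound,
            "n_obs": self.n_obs,
        }


def _params_from_fixed(beta: float, sigma: float, n: float, fixed: dict) -> ModelParams:
    fx = {**DEFAULT_FIXED, **(fixed or {})}
    alpha = fx["alpha"]
    return ModelParams(
        alpha_C=alpha,
        alpha_D=alpha,
        delta_C=fx["delta_C"],
        delta_D=fx["delta_D"],
        kappa=fx["kappa"],
        K=fx["K"],
        beta=beta,
        sigma=sigma,
    ).with_(n=n)


def predict_delta_y(
    beta: float,
    sigma: float,
    n: float,
    fixed: dict | None,
    y0,
    duration: float,
):
    """Model-predicted frequency change(s); vectorized over ``y0``."""
    fx = {**DEFAULT_FIXED, **(fixed or {})}
    params = _params_from_fixed(beta, sigma, n, fx)
    return frequency_change(
        params,
        y0,
        duration,
        density_mode=fx["density_mode"],
        Y0=fx["Y0"],
        rtol=1e-8,
        atol=1e-10,
    )


def _nll_from_ssr(ssr: float, m: int) -> float:
    """Gaussian NLL with the noise variance profiled out (sigma^2 = SSR/m)."""
    s2 = max(ssr / m, 1e-300)
    return 0.5 * m * (math.log(2 * math.pi * s2) + 1.0)


def fit_beta_sigma(
    data: FrequencyChangeDataset | pd.DataFrame,
    n: float,
    fixed: dict | None = None,
    bounds: tuple = DEFAULT_BOUNDS,
    n_grid_starts: int = 8,
    n_refine: int = 3,
    tol: float = 1e-8,
) -> FitResult:
    """Maximize the profiled Gaussian likelihood of the observed changes.

    The negative log-likelihood is evaluated on an ``n_grid_starts`` x
    ``n_grid_starts`` grid over the bounds; the best ``n_refine`` grid
    points seed Nelder-Mead refinements and the best optimum is returned.
    Estimates landing on a bound are flagged via ``at_bound`` rather than
    silently reported.
    """
    frame = data.frame if isinstance(data, FrequencyChangeDataset) else data
    if frame.empty:
        raise ValueError("empty dataset slice")
    if frame["y0"].nunique() < 3:
        raise ValueError("need >= 3 distinct initial fractions to identify (beta, sigma)")
    durations = frame["duration_days"].unique()
    if len(durations) != 1:
        raise ValueError("mixed assay durations in one fit are not supported")
    duration = float(durations[0])

    y0_unique, inverse = np.unique(frame["y0"].to_numpy(), return_inverse=True)
    observed = frame["delta_y"].to_numpy()
    m = observed.size

    def ssr(theta) -> float:
        b, s = theta
        if not (bounds[0][0] <= b <= bounds[0][1] and bounds[1][0] <= s <= bounds[1][1]):
            return np.inf
        pred = predict_delta_y(b, s, n, fixed, y0_unique, duration)
        resid = observed - np.asarray(pred)[inverse]
        return float(resid @ resid)

    betas = np.linspace(bounds[0][0], bounds[0][1], n_grid_starts)
    sigmas = np.linspace(bounds[1][0], bounds[1][1], n_grid_starts)
    grid = [(ssr((b, s)), b, s) for s in sigmas for b in betas]
    grid.sort(key=lambda t: t[0])
    if not np.isfinite(grid[0][0]):
        raise RuntimeError("objective not finite anywhere on the start grid")

    starts_log = []
    best = None
    for g_ssr, b0, s0 in grid[:n_refine]:
        res = minimize(
            ssr,
            x0=[b0, s0],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 2000},
        )
        starts_log.append(
            {"start": (b0, s0), "ssr0": g_ssr, "ssr": float(res.fun), "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all optimizer starts failed: {starts_log}")

    b_hat, s_hat = float(best.x[0]), float(best.x[1])
    b_hat = min(max(b_hat, bounds[0][0]), bounds[0][1])
    s_hat = min(max(s_hat, bounds[1][0]), bounds[1][1])
    edge = 1e-6
    at_bound = (
        b_hat <= bounds[0][0] + edge
        or b_hat >= bounds[0][1] - edge
        or s_hat <= bounds[1][0] + edge
        or s_hat >= bounds[1][1] - edge
    )
    cond = frame["condition"].iloc[0] if frame["condition"].nunique() == 1 else None
    return FitResult(
        condition=cond,
        n=float(n),
        beta_hat=b_hat,
        sigma_hat=s_hat,
        nll=_nll_from_ssr(float(best.fun), m),
        noise_sd=math.sqrt(max(float(best.fun) / m, 0.0)),
        converged=bool(best.success),
        at_bound=at_bound,
        n_obs=m,
        starts=starts_log,
    )


def fit_across_n(
    dataset: FrequencyChangeDataset,
    n_values: Sequence[float] = DEFAULT_N_RANGE,
    fixed: dict | None = None,
    bounds: tuple = DEFAULT_BOUNDS,
) -> dict:
    """Fit each condition at every neighborhood size; summarize by medians.

    The neighborhood size of a secreted public good is rarely measured, so
    it is treated as unknown and marginalized crudely: one fit per ``n``,
    then the per-condition median and interquartile range of the estimates.
    Individual-``n`` failures are recorded and excluded from the medians.
    """
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be nonempty")
    results: list[FitResult] = []
    failures: list[dict] = []
    for cond in dataset.conditions:
        sl = dataset.slice(cond)
        for n in n_values:
            try:
                results.append(fit_beta_sigma(sl, n, fixed=fixed, bounds=bounds))
            except Exception as exc:  # recorded, not fatal
                failures.append({"condition": cond, "n": n, "error": str(exc)})

    rows = [r.to_dict() for r in results]
    frame = pd.DataFrame(rows)
    summaries = {}
    for cond, grp in frame.groupby("condition"):
        summaries[cond] = {
            "beta_median": float(grp["beta_hat"].median()),
            "sigma_median": float(grp["sigma_hat"].median()),
            "beta_iqr": tuple(np.percentile(grp["beta_hat"], [25, 75])),
            "sigma_iqr": tuple(np.percentile(grp["sigma_hat"], [25, 75])),
            "n_fits": int(len(grp)),
        }
    return {
        "fits": results,
        "frame": frame,
        "summaries": summaries,
        "failures": failures,
        "n_failures": len(failures),
    }


def equilibrium_prediction_from_fit(
    beta_median: float, sigma_median: float, n_ref: float, fixed: dict | None = None
) -> list[Equilibrium]:
    """Interior equilibria implied by fitted medians at a reference n."""
    params = _params_from_fixed(beta_median, sigma_median, n_ref, {**DEFAULT_FIXED, **(fixed or {})})
    return find_interior_equilibria(params)
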