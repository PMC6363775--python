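"""Exact stochastic simulation of the individual-based birth-death process.

Each cooperator divides at per-capita rate ``max(0, r_C(y) E_K)`` and dies
at rate ``delta_C`` (and analogously for defectors), where
``E_K = 1 - (C + D)/K`` is the global density factor.  Sample paths are
generated with the Gillespie direct method, so the trajectories are
statistically exact realizations of the continuous-time Markov jump
process.  Negative effective birth rates clamp to zero propensity — deaths
still occur, so populations above carrying capacity decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .model import ModelParams

__all__ = [
    "IBMConfig",
    "EnsembleOutcome",
    "gillespie_run",
    "run_ensemble",
    "classify_outcome",
    "sampled_neighborhood_rates",
]

RateMode = Literal["mean_field", "sampled_neighborhood"]

#: default horizon (units of 1/alpha) used when classifying ensemble outcomes
OUTCOME_HORIZON = 200.0


@dataclass(frozen=True)
class IBMConfig:
    """Configuration of a single stochastic run."""

    params: ModelParams
    init: tuple[int, int]  # (x_C, x_D), integer counts
    t_max: float
    seed: int | np.random.SeedSequence = 0
    record_grid: Sequence[float] | None = None
    rate_mode: RateMode = "mean_field"

    def __post_init__(self) -> None:
        c, d = self.init
        if c < 0 or d < 0 or c != int(c) or d != int(d):
            raise ValueError("initial counts must be nonnegative integers")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class EnsembleOutcome:
    """Summary of independent replicate runs."""

    n_runs: int
    labels: list[str]
    final_states: list[tuple[int, int]]
    frequencies: dict[str, float]
    frequency_se: dict[str, float]
    record_grid: np.ndarray
    mean_x_C: np.ndarray
    mean_x_D: np.ndarray
    se_x_C: np.ndarray
    se_x_D: np.ndarray
    config: IBMConfig | None = None

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "frequencies": self.frequencies,
            "frequency_se": self.frequency_se,
        }

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.record_grid,
                "mean_x_C": self.mean_x_C,
                "mean_x_D": self.mean_x_D,
                "se_x_C": self.se_x_C,
                "se_x_D": self.se_x_D,
            }
        )


def sampled_neighborhood_rates(
    x_C: int, x_D: int, params: ModelParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Per-capita intrinsic growth rates with the neighborhood drawn explicitly.

    For each strategy the ``n - 1`` neighbors of a focal individual are
    sampled without replacement (hypergeometric) from the rest of the
    population; the realized producer fraction, including the focal's own
    contribution for a cooperator, replaces the mean-field expectation in
    the sigmoidal benefit.  If fewer than ``n - 1`` other individuals
    exist, the neighborhood truncates to the whole remaining population.
    Rates are returned unclamped (the caller converts them to propensities).
    """
    Y = x_C + x_D
    if Y < 1:
        raise ValueError("population must contain at least one individual")
    exp_sigma = math.exp(params.sigma)
    rates = []
    for focal, n_f in (("C", params.n_C), ("D", params.n_D)):
        present = (x_C > 0) if focal == "C" else (x_D > 0)
        if not present:
            rates.append(0.0)
            continue
        n_int = max(int(round(n_f)), 1)
        draw = min(n_int - 1, Y - 1)
        n_good = x_C - 1 if focal == "C" else x_C  # producers among the others
        producers = int(rng.hypergeometric(n_good, Y - 1 - n_good, draw)) if draw > 0 else 0
        self_contrib = 1 if focal == "C" else 0
        n_eff = draw + 1  # focal plus realized neighbors
        N = (producers + self_contrib) / n_eff
        benefit = (1.0 + exp_sigma) / (1.0 + math.exp(params.sigma - params.beta * N))
        if focal == "C":
            rates.append(params.alpha_C * benefit - params.kappa)
        else:
            rates.append(params.alpha_D * benefit)
    return rates[0], rates[1]


def _gillespie_mean_field(
    x_C: int,
    x_D: int,
    t_max: float,
    params: ModelParams,
    rng: np.random.Generator,
    record: np.ndarray,
):
    """Tight event loop for the mean-field rate mode.

    The sigmoid factors depend only on the cooperator fraction; everything
    is kept in local floats and the uniforms are drawn in batches to keep
    per-event overhead low.
    """
    aC, aD = params.alpha_C, params.alpha_D
    dC, dD = params.delta_C, params.delta_D
    kappa, K, beta, sigma = params.kappa, params.K, params.beta, params.sigma
    nC, nD = params.n_C, params.n_D
    one_plus_es = 1.0 + math.exp(sigma)
    exp_fn, log_fn = math.exp, math.log

    rec_C = np.empty(record.size, dtype=float)
    rec_D = np.empty(record.size, dtype=float)
    ri = 0  # next record index
    t = 0.0
    BATCH = 4096
    u = rng.random(BATCH)
    ui = 0

    while True:
        Y = x_C + x_D
        if Y == 0:
            a_total = 0.0
        else:
            y = x_C / Y
            E_K = 1.0 - Y / K
            NC = (1.0 + (nC - 1.0) * y) / nC
            ND = (nD - 1.0) * y / nD
            r_C = aC * one_plus_es / (1.0 + exp_fn(sigma - beta * NC)) - kappa
            r_D = aD * one_plus_es / (1.0 + exp_fn(sigma - beta * ND))
            bC = r_C * E_K
            bD = r_D * E_K
            a1 = bC * x_C if bC > 0.0 else 0.0
            a2 = bD * x_D if bD > 0.0 else 0.0
            a3 = dC * x_C
            a4 = dD * x_D
            a_total = a1 + a2 + a3 + a4
        if a_total <= 0.0:
            break
        if ui >= BATCH - 1:
            u = rng.random(BATCH)
            ui = 0
        t_next = t - log_fn(1.0 - u[ui]) / a_total
        ui += 1
        if t_next > t_max:
            break
        while ri < record.size and record[ri] < t_next:
            rec_C[ri] = x_C
            rec_D[ri] = x_D
            ri += 1
        t = t_next
        r = u[ui] * a_total
        ui += 1
        if r < a1:
            x_C += 1
        elif r < a1 + a2:
            x_D += 1
        elif r < a1 + a2 + a3:
            x_C -= 1
        else:
            x_D -= 1
    while ri < record.size:
        rec_C[ri] = x_C
        rec_D[ri] = x_D
        ri += 1
    return x_C, x_D, rec_C, rec_D


def _gillespie_sampled(
    x_C: int,
    x_D: int,
    t_max: float,
    params: ModelParams,
    rng: np.random.Generator,
    record: np.ndarray,
):
    """Event loop with per-event hypergeometric neighborhood sampling."""
    dC, dD = params.delta_C, params.delta_D
    K = params.K
    rec_C = np.empty(record.size, dtype=float)
    rec_D = np.empty(record.size, dtype=float)
    ri = 0
    t = 0.0
    while True:
        Y = x_C + x_D
        if Y == 0:
            break
        r_C, r_D = sampled_neighborhood_rates(x_C, x_D, params, rng)
        E_K = 1.0 - Y / K
        a1 = max(r_C * E_K, 0.0) * x_C
        a2 = max(r_D * E_K, 0.0) * x_D
        a3 = dC * x_C
        a4 = dD * x_D
        a_total = a1 + a2 + a3 + a4
        if a_total <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a_total)
        if t_next > t_max:
            break
        while ri < record.size and record[ri] < t_next:
            rec_C[ri] = x_C
            rec_D[ri] = x_D
            ri += 1
        t = t_next
        r = rng.random() * a_total
        if r < a1:
            x_C += 1
        elif r < a1 + a2:
            x_D += 1
        elif r < a1 + a2 + a3:
            x_C -= 1
        else:
            x_D -= 1
    while ri < record.size:
        rec_C[ri] = x_C
        rec_D[ri] = x_D
        ri += 1
    return x_C, x_D, rec_C, rec_D


def gillespie_run(config: IBMConfig) -> Trajectory:
    """One exact sample path; reproducible given the seed.

    The returned trajectory holds the state on ``record_grid`` (by default
    50 evenly spaced times plus the endpoint), sampled zero-order-hold: the
    recorded state at time ``s`` is the state just before the first event
    after ``s``.
    """
    rng = np.random.default_rng(config.seed)
    if config.record_grid is None:
        record = np.linspace(0.0, config.t_max, 51)
    else:
        record = np.asarray(config.record_grid, dtype=float)
    core = _gillespie_mean_field if config.rate_mode == "mean_field" else _gillespie_sampled
    x_C, x_D, rec_C, rec_D = core(
        int(config.init[0]), int(config.init[1]), float(config.t_max), config.params, rng, record
    )
    # ensure the recorded path ends with the true final state
    rec_C[-1] = x_C if record[-1] >= config.t_max else rec_C[-1]
    rec_D[-1] = x_D if record[-1] >= config.t_max else rec_D[-1]
    return Trajectory(times=record, x_C=rec_C, x_D=rec_D, params=config.params)


def classify_outcome(
    final_state: tuple[int, int], coexistence_min: int = 1
) -> Literal["all_C", "all_D", "coexistence", "extinct"]:
    """Label a final integer state."""
    x_C, x_D = int(final_state[0]), int(final_state[1])
    if x_C == 0 and x_D == 0:
        return "extinct"
    if x_C == 0:
        return "all_D"
    if x_D == 0:
        return "all_C"
    if x_C >= coexistence_min and x_D >= coexistence_min:
        return "coexistence"
    # mixed state below the coexistence floor: call it for the majority type
    return "all_C" if x_C >= x_D else "all_D"


def run_ensemble(
    config: IBMConfig, n_runs: int, coexistence_min: int = 1
) -> EnsembleOutcome:
    """Independent seeded replicates with outcome frequencies and mean path.

    Child RNG streams are spawned from the root seed by run index, so the
    ensemble is reproducible and each replicate is statistically
    independent.  Label frequencies carry binomial standard errors.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    children = root.spawn(n_runs)
    record = (
        np.linspace(0.0, config.t_max, 51)
        if config.record_grid is None
        else np.asarray(config.record_grid, dtype=float)
    )
    labels: list[str] = []
    finals: list[tuple[int, int]] = []
    paths_C = np.empty((n_runs, record.size))
    paths_D = np.empty((n_runs, record.size))
    for i, child in enumerate(children):
        cfg = IBMConfig(
            params=config.params,
            init=config.init,
            t_max=config.t_max,
            seed=child,
            record_grid=record,
            rate_mode=config.rate_mode,
        )
        traj = gillespie_run(cfg)
        paths_C[i] = traj.x_C
        paths_D[i] = traj.x_D
        final = (int(traj.x_C[-1]), int(traj.x_D[-1]))
        finals.append(final)
        labels.append(classify_outcome(final, coexistence_min))

    freqs: dict[str, float] = {}
    ses: dict[str, float] = {}
    for lab in ("all_C", "all_D", "coexistence", "extinct"):
        p = labels.count(lab) / n_runs
        freqs[lab] = p
        ses[lab] = math.sqrt(p * (1 - p) / n_runs)
    return EnsembleOutcome(
        n_runs=n_runs,
        labels=labels,
        final_states=finals,
        frequencies=freqs,
        frequency_se=ses,
        record_grid=record,
        mean_x_C=paths_C.mean(axis=0),
        mean_x_D=paths_D.mean(axis=0),
        se_x_C=paths_C.std(axis=0, ddof=1) / math.sqrt(n_runs) if n_runs > 1 else np.zeros(record.size),
        se_x_D=paths_D.std(axis=0, ddof=1) / math.sqrt(n_runs) if n_runs > 1 else np.zeros(record.size),
        config=config,
    )
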