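"""Quasi-spatial compartment model with fluctuating neighborhood sizes.

Instead of fixing the neighborhood size exogenously, the population is
split into ``N`` compartments: all individuals are pooled and multinomially
redistributed (uniformly at random) every ``T_s`` days, and between mixes
each compartment evolves under the coupled logistic dynamics with its own
local cooperator fraction and a neighborhood size equal to its occupancy.
The number of compartments thus acts as the inverse of an emergent,
fluctuating effective neighborhood size with mean ``Y/N``.  Above a
critical compartment number ``N_crit`` the producer-only state takes over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelParams, intrinsic_growth_rate

__all__ = [
    "CompartmentState",
    "MixingProtocol",
    "mix",
    "select_within",
    "run_mixing_cycles",
    "sweep_N",
    "ncrit_numeric",
    "ncrit_meanfield",
]

CapacityMode = Literal["global", "per_compartment"]


@dataclass
class CompartmentState:
    """Integer counts of cooperators and defectors in each of N compartments."""

    c: np.ndarray
    d: np.ndarray
    cycle: int = 0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        if self.c.shape != self.d.shape:
            raise ValueError("c and d must have the same length")
        if np.any(self.c < 0) or np.any(self.d < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def N(self) -> int:
        return self.c.size

    @property
    def totals(self) -> tuple[int, int]:
        return int(self.c.sum()), int(self.d.sum())

    @property
    def fraction_C(self) -> float:
        C, D = self.totals
        return np.nan if C + D == 0 else C / (C + D)


@dataclass(frozen=True)
class MixingProtocol:
    """Mix-select loop settings; selection lasts ``T_s`` days per cycle."""

    N: int
    T_s: float = 10.0
    n_cycles: int = 200
    seed: int | np.random.SeedSequence = 0
    capacity_mode: CapacityMode = "global"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.T_s <= 0:
            raise ValueError("T_s must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def mix(state: CompartmentState, rng: np.random.Generator) -> CompartmentState:
    """Redistribute every individual into a uniformly random compartment.

    Equivalent to multinomial sampling of each type's total over the N
    compartments; both type totals are conserved exactly.
    """
    N = state.N
    C, D = state.totals
    p = np.full(N, 1.0 / N)
    return CompartmentState(
        c=rng.multinomial(C, p), d=rng.multinomial(D, p), cycle=state.cycle
    )


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expectation-preserving rounding of nonnegative masses to integers."""
    x = np.clip(x, 0.0, None)
    lo = np.floor(x)
    frac = x - lo
    return (lo + (rng.random(x.shape) < frac)).astype(np.int64)


def select_within(
    state: CompartmentState,
    params: ModelParams,
    T_s: float,
    rng: np.random.Generator,
    capacity_mode: CapacityMode = "global",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> CompartmentState:
    """Evolve each compartment for ``T_s`` days, then round back to integers.

    Within compartment *i* the dynamics are the coupled logistic equations
    with local fraction ``y_i`` and neighborhood size ``n_i`` fixed at the
    compartment's occupancy at the start of the step (minimum 1); the
    density factor couples all compartments through the shared carrying
    capacity (``capacity_mode='global'``) or acts per compartment on
    ``K/N`` (``'per_compartment'``).  The continuous end-of-step masses are
    stochastically rounded so the next mix operates on discrete
    individuals.
    """
    occ = state.c + state.d
    n_i = np.maximum(occ.astype(float), 1.0)
    K = params.K
    N = state.N

    def rhs(t, z):
        m = z.size // 2
        xc = np.clip(z[:m], 0.0, None)
        xd = np.clip(z[m:], 0.0, None)
        Y_i = xc + xd
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(Y_i > 0, xc / np.where(Y_i > 0, Y_i, 1.0), 0.0)
        y = np.where((xd == 0) & (xc > 0), 1.0, y)
        if capacity_mode == "global":
            E = 1.0 - Y_i.sum() / K
            E = np.full(m, E)
        else:
            E = 1.0 - Y_i / (K / N)
        NC = (1.0 + (n_i - 1.0) * y) / n_i
        ND = (n_i - 1.0) * y / n_i
        r_C = params.alpha_C * _benefit(NC, params) - params.kappa
        r_D = params.alpha_D * _benefit(ND, params)
        dxc = (r_C * E - params.delta_C) * xc
        dxd = (r_D * E - params.delta_D) * xd
        return np.concatenate([dxc, dxd])

    z0 = np.concatenate([state.c.astype(float), state.d.astype(float)])
    sol = solve_ivp(rhs, (0.0, float(T_s)), z0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"within-compartment integration failed: {sol.message}")
    m = state.N
    c_new = _stochastic_round(sol.y[:m, -1], rng)
    d_new = _stochastic_round(sol.y[m:, -1], rng)
    return CompartmentState(c=c_new, d=d_new, cycle=state.cycle + 1)


def _benefit(N_arr: np.ndarray, params: ModelParams) -> np.ndarray:
    return (1.0 + np.exp(params.sigma)) / (1.0 + np.exp(params.sigma - params.beta * N_arr))


def run_mixing_cycles(
    params: ModelParams,
    protocol: MixingProtocol,
    init_totals: tuple[int, int],
    init_state: CompartmentState | None = None,
    steady_window: float = 0.2,
) -> dict:
    """Alternate mixing and within-compartment selection for ``n_cycles``.

    Returns the per-cycle global totals, the long-run cooperator fraction
    (mean over the trailing ``steady_window`` share of cycles), and the
    final compartment state (reusable to continue a sweep without
    re-initialization).
    """
    rng = np.random.default_rng(protocol.seed)
    N = protocol.N
    if init_state is not None:
        if init_state.N != N:
            # re-bin an inherited population into the new compartment count
            C, D = init_state.totals
            state = CompartmentState(c=np.zeros(N, dtype=np.int64), d=np.zeros(N, dtype=np.int64))
            state.c[0], state.d[0] = C, D
        else:
            state = init_state
    else:
        state = CompartmentState(c=np.zeros(N, dtype=np.int64), d=np.zeros(N, dtype=np.int64))
        state.c[0], state.d[0] = int(init_totals[0]), int(init_totals[1])

    totals_C = np.empty(protocol.n_cycles, dtype=np.int64)
    totals_D = np.empty(protocol.n_cycles, dtype=np.int64)
    for k in range(protocol.n_cycles):
        state = mix(state, rng)
        state = select_within(state, params, protocol.T_s, rng, protocol.capacity_mode)
        totals_C[k], totals_D[k] = state.totals
    tail = max(1, int(round(steady_window * protocol.n_cycles)))
    C_tail = totals_C[-tail:].astype(float)
    D_tail = totals_D[-tail:].astype(float)
    Y_tail = C_tail + D_tail
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(Y_tail > 0, C_tail / np.where(Y_tail > 0, Y_tail, 1.0), np.nan)
    steady = float(np.nanmean(frac)) if np.any(Y_tail > 0) else np.nan
    return {
        "totals_C": totals_C,
        "totals_D": totals_D,
        "steady_fraction_C": steady,
        "final_state": state,
    }


def _label(frac: float, lo: float = 0.01, hi: float = 0.99) -> str:
    if np.isnan(frac):
        return "extinct"
    if frac >= hi:
        return "all_C"
    if frac <= lo:
        return "all_D"
    return "coexistence"


def sweep_N(
    params: ModelParams,
    N_values: Sequence[int],
    protocol: MixingProtocol,
    init_totals: tuple[int, int],
    reinitialize: bool = True,
    n_replicates: int = 1,
    directions: tuple[str, ...] = ("forward", "backward"),
) -> pd.DataFrame:
    """Steady-state cooperator fraction versus compartment number N.

    With ``reinitialize=True`` every N starts fresh from ``init_totals``;
    with ``False`` each N inherits the previous N's final population
    (quasi-static sweep), which exposes hysteresis between the forward and
    backward directions.  Returns a long-format frame with columns
    ``direction, N, replicate, final_fraction_C, label``.
    """
    N_values = sorted(int(v) for v in N_values)
    root = (
        protocol.seed
        if isinstance(protocol.seed, np.random.SeedSequence)
        else np.random.SeedSequence(protocol.seed)
    )
    rows = []
    for direction in directions:
        seq = N_values if direction == "forward" else N_values[::-1]
        for rep in range(n_replicates):
            child_iter = iter(root.spawn(len(seq)))
            inherited: CompartmentState | None = None
            for N in seq:
                proto = MixingProtocol(
                    N=N,
                    T_s=protocol.T_s,
                    n_cycles=protocol.n_cycles,
                    seed=next(child_iter),
                    capacity_mode=protocol.capacity_mode,
                )
                res = run_mixing_cycles(
                    params,
                    proto,
                    init_totals,
                    init_state=None if reinitialize else inherited,
                )
                inherited = res["final_state"]
                frac = res["steady_fraction_C"]
                rows.append(
                    {
                        "direction": direction,
                        "N": N,
                        "replicate": rep,
                        "final_fraction_C": frac,
                        "label": _label(frac),
                    }
                )
    return pd.DataFrame(rows)


def ncrit_numeric(
    params: ModelParams,
    protocol: MixingProtocol,
    N_search_range: tuple[int, int],
    n_replicates: int = 10,
    init_totals: tuple[int, int] = (50, 50),
) -> int | None:
    """Smallest N above which the long-run state is all-C (majority rule).

    Bisection over the (assumed monotone) all-C indicator: each probe runs
    ``n_replicates`` independent mixing experiments and takes the majority
    label.  Returns ``None`` if no transition lies in the range.
    """
    lo, hi = int(N_search_range[0]), int(N_search_range[1])
    if lo > hi:
        raise ValueError("invalid search range")
    root = (
        protocol.seed
        if isinstance(protocol.seed, np.random.SeedSequence)
        else np.random.SeedSequence(protocol.seed)
    )
    seed_iter = iter(root.spawn(4096))

    def all_C_at(N: int) -> bool:
        wins = 0
        for _ in range(n_replicates):
            proto = MixingProtocol(
                N=N,
                T_s=protocol.T_s,
                n_cycles=protocol.n_cycles,
                seed=next(seed_iter),
                capacity_mode=protocol.capacity_mode,
            )
            res = run_mixing_cycles(params, proto, init_totals)
            if _label(res["steady_fraction_C"]) == "all_C":
                wins += 1
        return wins * 2 > n_replicates

    if all_C_at(lo):
        return lo
    if not all_C_at(hi):
        return None
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if all_C_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def ncrit_meanfield(
    params: ModelParams,
    criterion: Literal["all_C_stable", "all_D_unstable"] = "all_C_stable",
    N_max: int | None = None,
) -> int | None:
    """Mean-field prediction of the critical compartment number.

    Each compartment is assigned its expected occupancy ``Y/N``, which
    plays the role of the effective neighborhood size.  Two readings of
    "critical" are supported:

    ``all_C_stable`` (default)
        Smallest N above which the producer-only state is uninvadable by a
        rare defector, i.e. ``r_D(1; n) delta_C / r_C(1; n) <= delta_D`` at
        ``n = Y*_C/N`` (solved self-consistently, since the all-C
        population size itself depends on the neighborhood).  This is the
        reading under which N_crit is non-monotone in beta: for weak
        benefits cooperation needs small patches to pay for its cost, while
        for very strong benefits the sigmoid saturates for both types and
        the producer's self-benefit edge survives only in nearly private
        neighborhoods, pushing N_crit up toward Y*.

    ``all_D_unstable``
        Smallest N at which a rare cooperator invades the defector-only
        state: ``r_C(0; n) delta_D / alpha_D > delta_C`` at ``n = Y*_D/N``.

    Returns ``None`` when the criterion holds for no N (e.g. beta = 0).
    """
    if params.alpha_D <= params.delta_D:
        raise ValueError("all-D is not viable (alpha_D <= delta_D)")
    Y_star_D = params.K * (1.0 - params.delta_D / params.alpha_D)
    if N_max is None:
        N_max = int(np.ceil(Y_star_D))

    if criterion == "all_D_unstable":
        E = params.delta_D / params.alpha_D
        for N in range(1, N_max + 1):
            n_eff = max(Y_star_D / N, 1.0)
            r_C0 = intrinsic_growth_rate(0.0, params.with_(n=n_eff), "C")
            if r_C0 * E > params.delta_C:
                return N
        return None

    if criterion != "all_C_stable":
        raise ValueError(f"unknown criterion {criterion!r}")
    for N in range(1, N_max + 1):
        # self-consistent occupancy of the all-C state: n = Y*_C(n) / N
        n_eff = max(params.K / N, 1.0)
        for _ in range(50):
            r_C1 = intrinsic_growth_rate(1.0, params.with_(n=n_eff), "C")
            if r_C1 <= params.delta_C:
                n_eff = np.nan
                break
            n_new = max(params.K * (1.0 - params.delta_C / r_C1) / N, 1.0)
            if abs(n_new - n_eff) < 1e-10:
                n_eff = n_new
                break
            n_eff = n_new
        if not np.isfinite(n_eff):
            continue  # all-C not even viable at this patch size
        p = params.with_(n=n_eff)
        r_C1 = intrinsic_growth_rate(1.0, p, "C")
        r_D1 = intrinsic_growth_rate(1.0, p, "D")
        if r_D1 * params.delta_C / r_C1 <= params.delta_D:
            return N
    return None
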