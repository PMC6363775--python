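"""Equilibria, stability, phase diagrams, bifurcations, and hysteresis.

Interior (polymorphic) equilibria of the coupled logistic system satisfy
``delta_D r_C(y) = delta_C r_D(y)`` together with
``Y* = K (1 - delta_C / r_C(y*))``.  For the sigmoidal benefit family there
are at most two interior roots; boundary (monomorphic) states are always
present when viable.  Dynamical classes follow from the invasibility of the
two monomorphic states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import VERDICT_HORIZON, integrate_ode, ode_rhs, single_species_equilibrium
from .model import ModelParams, PopulationState, intrinsic_growth_rate

__all__ = [
    "Equilibrium",
    "PhaseReport",
    "BifurcationDiagram",
    "find_interior_equilibria",
    "boundary_states",
    "classify_dynamics",
    "phase_diagram",
    "bifurcation_sweep",
    "hysteresis_sweep",
]

DynClass = Literal["C_dominance", "D_dominance", "bistability", "coexistence", "extinction"]

_GRID_SIZE = 4096
_ROOT_TOL = 1e-10
_DEDUP_TOL = 1e-6
_MARGINAL_TOL = 1e-8


@dataclass
class Equilibrium:
    """A fixed point of the coupled logistic system with its stability."""

    y_star: float
    Y_star: float
    kind: Literal["all_C", "all_D", "interior", "extinction"]
    stability: Literal["stable", "unstable", "saddle", "marginal", "degenerate"]
    eigenvalues: tuple[float, float]

    @property
    def is_stable(self) -> bool:
        """True only for an attracting fixed point.

        A frequency-unstable interior equilibrium of the planar system is a
        saddle (attracting in total size, repelling in composition), so
        "the unstable polymorphic state" corresponds to ``is_stable`` False.
        """
        return self.stability == "stable"

    @property
    def x_C(self) -> float:
        return self.y_star * self.Y_star

    @property
    def x_D(self) -> float:
        return (1.0 - self.y_star) * self.Y_star


@dataclass
class PhaseReport:
    """Dynamical class on a (beta, sigma) grid at fixed other parameters."""

    beta_values: np.ndarray
    sigma_values: np.ndarray
    classes: np.ndarray  # shape (len(sigma_values), len(beta_values)), dtype object
    base_params: ModelParams

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"beta": b, "sigma": s, "dyn_class": self.classes[i, j]}
            for i, s in enumerate(self.sigma_values)
            for j, b in enumerate(self.beta_values)
        ]
        return pd.DataFrame(rows)


@dataclass
class BifurcationEvent:
    kind: Literal["saddle_node", "transcritical"]
    control_value: float  # midpoint of the bracketing interval
    bracket: tuple[float, float]


@dataclass
class BifurcationDiagram:
    """Interior equilibrium branches vs a control parameter, with events."""

    control: str
    values: np.ndarray
    branches: list[list[Equilibrium]]  # interior equilibria per control value
    boundary: list[dict]  # stability labels of all_C / all_D per value
    events: list[BifurcationEvent] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, eqs in zip(self.values, self.branches):
            for eq in eqs:
                rows.append(
                    {
                        "control": self.control,
                        "value": v,
                        "y_star": eq.y_star,
                        "Y_star": eq.Y_star,
                        "stability": eq.stability,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# root finding on the interior-equilibrium condition


def _interior_condition(y, params: ModelParams):
    """delta_D r_C(y) - delta_C r_D(y); reduces to r_C - r_D for equal deaths."""
    r_C = intrinsic_growth_rate(y, params, "C")
    r_D = intrinsic_growth_rate(y, params, "D")
    if params.delta_C == 0.0 and params.delta_D == 0.0:
        return r_C - r_D
    return params.delta_D * r_C - params.delta_C * r_D


def _bisect(f, a, b, fa, fb, tol=_ROOT_TOL):
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if (fa < 0) != (fm < 0):
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def _jacobian(x_C: float, x_D: float, params: ModelParams, rel_step: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the 2D right-hand side.

    One-sided steps are used next to the nonnegativity boundary so the
    fraction convention at ``x = 0`` is respected.
    """
    J = np.empty((2, 2))
    x = np.array([x_C, x_D], dtype=float)
    scale = max(x.sum(), 1.0)
    h = rel_step * scale
    for j in range(2):
        lo = x.copy()
        hi = x.copy()
        hi[j] += h
        if x[j] - h >= 0:
            lo[j] -= h
            denom = 2 * h
        else:
            denom = h
        f_hi = ode_rhs((hi[0], hi[1]), params)
        f_lo = ode_rhs((lo[0], lo[1]), params)
        J[0, j] = (f_hi[0] - f_lo[0]) / denom
        J[1, j] = (f_hi[1] - f_lo[1]) / denom
    return J


def _stability_from_eigs(eigs: np.ndarray) -> str:
    re = np.sort(np.real(eigs))
    if np.any(np.abs(re) < _MARGINAL_TOL):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_interior_equilibria(
    params: ModelParams, grid_size: int = _GRID_SIZE, detect_tangency: bool = True
) -> list[Equilibrium]:
    """All interior roots of ``delta_D r_C = delta_C r_D`` on (0, 1).

    Sign changes on a uniform grid are refined by bisection; roots closer
    than 1e-6 are merged.  A local minimum of |f| below 1e-8 without a sign
    change (a saddle-node tangency) is reported with stability
    ``degenerate``.  Stability of regular roots comes from the eigenvalues
    of the finite-difference Jacobian of the full two-dimensional system;
    roots whose ``Y*`` would be nonpositive (growth below death at that
    composition) are discarded as dynamically infeasible.
    """
    ys = np.linspace(0.0, 1.0, grid_size + 1)[1:-1]
    f = np.asarray(_interior_condition(ys, params))
    roots: list[float] = []
    sign = np.sign(f)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    g = lambda y: float(_interior_condition(y, params))
    for i in idx:
        roots.append(_bisect(g, ys[i], ys[i + 1], f[i], f[i + 1]))
    exact = np.nonzero(f == 0.0)[0]
    roots.extend(ys[exact].tolist())

    degenerate: list[float] = []
    if detect_tangency:
        interior = np.arange(1, len(ys) - 1)
        is_min = (np.abs(f[interior]) <= np.abs(f[interior - 1])) & (
            np.abs(f[interior]) <= np.abs(f[interior + 1])
        )
        for i in interior[is_min]:
            if abs(f[i]) < _MARGINAL_TOL and not any(abs(ys[i] - r) < 1e-3 for r in roots):
                degenerate.append(float(ys[i]))

    # dedupe
    roots = sorted(roots)
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > _DEDUP_TOL:
            merged.append(r)

    out: list[Equilibrium] = []
    for y_star in merged:
        r_C = intrinsic_growth_rate(y_star, params, "C")
        if r_C <= params.delta_C:
            continue  # would need E_K >= 1, i.e. Y* <= 0: not an interior state
        Y_star = params.K * (1.0 - params.delta_C / r_C)
        eigs = np.linalg.eigvals(_jacobian(y_star * Y_star, (1 - y_star) * Y_star, params))
        out.append(
            Equilibrium(
                y_star=y_star,
                Y_star=Y_star,
                kind="interior",
                stability=_stability_from_eigs(eigs),
                eigenvalues=(float(np.real(eigs[0])), float(np.real(eigs[1]))),
            )
        )
    for y_star in degenerate:
        r_C = intrinsic_growth_rate(y_star, params, "C")
        if r_C <= params.delta_C:
            continue
        Y_star = params.K * (1.0 - params.delta_C / r_C)
        out.append(
            Equilibrium(
                y_star=y_star,
                Y_star=Y_star,
                kind="interior",
                stability="degenerate",
                eigenvalues=(np.nan, np.nan),
            )
        )
    out.sort(key=lambda e: e.y_star)
    return out


# ---------------------------------------------------------------------------
# boundary states and classification


def boundary_states(params: ModelParams) -> dict[str, Equilibrium]:
    """The all-C, all-D, and extinction equilibria with their stability.

    At the all-D state the transverse eigenvalue is the invasion fitness of
    a rare cooperator, ``r_C(0) delta_D / alpha_D - delta_C``; the radial
    eigenvalue is the logistic relaxation rate ``delta_D - alpha_D``.
    Symmetric formulas hold at all-C.  The extinction state at the origin is
    judged by the growth of a rare pure colony of each type.
    """
    out: dict[str, Equilibrium] = {}

    # extinction at the origin
    lam_C = intrinsic_growth_rate(1.0, params, "C") - params.delta_C
    lam_D = params.alpha_D - params.delta_D
    out["extinction"] = Equilibrium(
        y_star=np.nan,
        Y_star=0.0,
        kind="extinction",
        stability=_stability_from_eigs(np.array([lam_C, lam_D])),
        eigenvalues=(lam_C, lam_D),
    )

    if params.alpha_D > params.delta_D:
        Y_D = single_species_equilibrium(params, "D")
        E = params.delta_D / params.alpha_D
        lam_trans = intrinsic_growth_rate(0.0, params, "C") * E - params.delta_C
        lam_rad = params.delta_D - params.alpha_D
        out["all_D"] = Equilibrium(
            y_star=0.0,
            Y_star=Y_D,
            kind="all_D",
            stability=_stability_from_eigs(np.array([lam_trans, lam_rad])),
            eigenvalues=(lam_trans, lam_rad),
        )

    r_C1 = intrinsic_growth_rate(1.0, params, "C")
    if r_C1 > params.delta_C:
        Y_C = single_species_equilibrium(params, "C")
        E = params.delta_C / r_C1
        lam_trans = intrinsic_growth_rate(1.0, params, "D") * E - params.delta_D
        lam_rad = params.delta_C - r_C1
        out["all_C"] = Equilibrium(
            y_star=1.0,
            Y_star=Y_C,
            kind="all_C",
            stability=_stability_from_eigs(np.array([lam_trans, lam_rad])),
            eigenvalues=(lam_trans, lam_rad),
        )
    return out


def _invasibility(params: ModelParams) -> tuple[bool, bool]:
    """(C invades all-D, D invades all-C) from the rare-type growth at each boundary.

    C invades all-D iff ``r_C(0) E_K > delta_C`` with ``E_K = delta_D/alpha_D``
    at the resident equilibrium (equivalently ``r_C(0)/delta_C > r_D(0)/delta_D``
    for positive deaths); a missing boundary state counts as non-invadable.
    """
    d_viable = params.alpha_D > params.delta_D
    c_viable = intrinsic_growth_rate(1.0, params, "C") > params.delta_C
    c_inv = False
    d_inv = False
    if d_viable:
        E = params.delta_D / params.alpha_D
        c_inv = intrinsic_growth_rate(0.0, params, "C") * E > params.delta_C
    if c_viable:
        r_C1 = intrinsic_growth_rate(1.0, params, "C")
        d_inv = intrinsic_growth_rate(1.0, params, "D") * (params.delta_C / r_C1) > params.delta_D
    return c_inv, d_inv


def classify_dynamics(params: ModelParams, check_consistency: bool = True) -> DynClass:
    """Dynamical class from boundary invasibility.

    ``(C invades, D invades)`` maps to: (yes, yes) coexistence,
    (yes, no) C_dominance, (no, yes) D_dominance, (no, no) bistability;
    if neither monomorphic state is viable the class is extinction.  When
    requested, the interior-equilibrium structure is cross-checked and a
    diagnostic raised on disagreement.

    The labels describe rare-mutant invasion only.  In the fold regime of
    the sigmoidal family (beta > sigma) a stable interior equilibrium can
    coexist with a stable all-D state; the class is then ``D_dominance``
    (a rare producer cannot invade) even though an established mixture
    above the threshold fraction persists — inspect
    :func:`find_interior_equilibria` for the full picture.
    """
    d_viable = params.alpha_D > params.delta_D
    c_viable = intrinsic_growth_rate(1.0, params, "C") > params.delta_C
    if not d_viable and not c_viable:
        return "extinction"
    c_inv, d_inv = _invasibility(params)
    if not d_viable or not c_viable:
        # one monomorphic state missing: the viable type wins unless invaded
        if not c_viable:
            return "coexistence" if c_inv else "D_dominance"
        return "coexistence" if d_inv else "C_dominance"
    label: DynClass
    if c_inv and d_inv:
        label = "coexistence"
    elif c_inv:
        label = "C_dominance"
    elif d_inv:
        label = "D_dominance"
    else:
        label = "bistability"

    if check_consistency:
        interior = [e for e in find_interior_equilibria(params) if e.stability != "degenerate"]
        n_stable = sum(e.stability == "stable" for e in interior)
        if label == "coexistence" and len(interior) > 0 and n_stable == 0:
            raise RuntimeError(
                "classification diagnostic: mutual invasibility without a stable "
                f"interior equilibrium ({params})"
            )
        if label == "bistability" and n_stable > 1:
            raise RuntimeError(
                "classification diagnostic: bistability label with multiple stable "
                f"interior equilibria ({params})"
            )
    return label


def phase_diagram(
    beta_grid: Sequence[float], sigma_grid: Sequence[float], params_base: ModelParams
) -> PhaseReport:
    """Classify the dynamics on a (beta, sigma) grid."""
    beta_grid = np.asarray(beta_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if beta_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    classes = np.empty((sigma_grid.size, beta_grid.size), dtype=object)
    for i, s in enumerate(sigma_grid):
        for j, b in enumerate(beta_grid):
            classes[i, j] = classify_dynamics(
                params_base.with_(beta=float(b), sigma=float(s)), check_consistency=False
            )
    return PhaseReport(
        beta_values=beta_grid, sigma_values=sigma_grid, classes=classes, base_params=params_base
    )


# ---------------------------------------------------------------------------
# bifurcation and hysteresis sweeps


def _apply_control(params: ModelParams, control: str, value: float) -> ModelParams:
    if control == "n":
        return params.with_(n=value)
    if control == "beta":
        return params.with_(beta=value)
    if control == "n_C":
        return params.with_(n_C=value)
    if control == "n_D":
        return params.with_(n_D=value)
    raise ValueError(f"unsupported control parameter {control!r}")


def bifurcation_sweep(
    params: ModelParams, control: str, values: Sequence[float]
) -> BifurcationDiagram:
    """Interior branches and bifurcation events along a control parameter.

    A saddle-node event is recorded where the regular interior root count
    drops from 2 to 0 (or rises 0 to 2) while both monomorphic stabilities
    are unchanged; a transcritical event where a boundary state's stability
    flips between adjacent control values (the interior branch passes
    through the boundary exchanging stability with it).
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("control values must be sorted ascending")
    branches: list[list[Equilibrium]] = []
    boundary: list[dict] = []
    for v in values:
        p = _apply_control(params, control, float(v))
        branches.append(find_interior_equilibria(p))
        bs = boundary_states(p)
        boundary.append({k: e.stability for k, e in bs.items()})

    events: list[BifurcationEvent] = []
    for k in range(len(values) - 1):
        n0 = sum(e.stability != "degenerate" for e in branches[k])
        n1 = sum(e.stability != "degenerate" for e in branches[k + 1])
        same_boundary = boundary[k] == boundary[k + 1]
        mid = 0.5 * (values[k] + values[k + 1])
        bracket = (float(values[k]), float(values[k + 1]))
        if same_boundary and {n0, n1} == {2, 0}:
            events.append(BifurcationEvent("saddle_node", mid, bracket))
        elif not same_boundary:
            events.append(BifurcationEvent("transcritical", mid, bracket))
    return BifurcationDiagram(
        control=control, values=values, branches=branches, boundary=boundary, events=events
    )


def hysteresis_sweep(
    params: ModelParams,
    control: str,
    values: Sequence[float],
    perturbation: float = 1.0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Forward/backward quasi-static sweeps of the long-time cooperator fraction.

    The final state at each control value seeds the next one, after adding
    ``perturbation`` individual-equivalents of any missing type (mirroring
    stochastic reseeding); branches that disagree inside a window of the
    control parameter reveal hysteresis.  Returns a long-format frame with
    columns ``direction, value, y_final, Y_final``.
    """
    values = np.asarray(values, dtype=float)
    if t_end is None:
        t_end = VERDICT_HORIZON / max(params.alpha_C, params.alpha_D)
    rows = []
    for direction, seq in (("forward", values), ("backward", values[::-1])):
        p0 = _apply_control(params, control, float(seq[0]))
        Y0 = single_species_equilibrium(p0, "D")
        if Y0 <= 0:
            Y0 = 0.5 * p0.K
        state = PopulationState(x_C=perturbation, x_D=max(Y0, perturbation))
        for v in seq:
            p = _apply_control(params, control, float(v))
            x_C = state.x_C if state.x_C > 0 else perturbation
            x_D = state.x_D if state.x_D > 0 else perturbation
            # zero perturbation keeps absorbing monomorphic states absorbing
            if perturbation == 0.0:
                x_C, x_D = state.x_C, state.x_D
            traj = integrate_ode(p, (x_C, x_D), t_end, rtol=1e-8, atol=1e-10)
            state = traj.final_state
            Y = state.total
            y = np.nan if Y == 0 else state.x_C / Y
            rows.append({"direction": direction, "value": float(v), "y_final": y, "Y_final": Y})
    return pd.DataFrame(rows)
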