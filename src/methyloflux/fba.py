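"""Flux balance analysis on top of scipy's HiGHS LP solver.

Solves max/min c.v subject to S.v = 0 and bound constraints.  Optima of
such LPs are typically degenerate in the flux vector; for reproducibility
every optimal solve is followed by a second LP that minimizes the total
absolute flux at the fixed optimal objective (parsimonious FBA), so the
reported flux distribution is a deterministic representative.  Yields are
never affected by this choice, only the flux vectors themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import FluxSolution, MetabolicModel, build_stoichiometric_matrix
from .network import (
    BIOMASS_REACTION,
    METHANOL_EXCHANGE,
    PRODUCTS,
    ProductTarget,
)

#: numerical tolerances (feasibility, steady-state residual, yield equality)
FEASIBILITY_TOL = 1e-9
STEADY_STATE_TOL = 1e-6
YIELD_TOL = 1e-4


class InfeasibleModelError(RuntimeError):
    pass


class UndefinedYieldError(ZeroDivisionError):
    pass


def _linprog_status(status: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(status, "failed")


def _solve_raw(S: np.ndarray, c: np.ndarray, bounds: list[tuple[float, float]],
               A_ub: np.ndarray | None = None,
               b_ub: np.ndarray | None = None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                   b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")


def _minimize_total_flux(S: np.ndarray, c: np.ndarray,
                         bounds: list[tuple[float, float]],
                         opt_value: float) -> np.ndarray | None:
    """Among optima of max c.v, pick the vector minimizing sum |v|.

    Formulated with auxiliary variables t >= |v|; the optimal objective is
    held by the inequality c.v >= z* - eps (maximization convention).
    """
    n = S.shape[1]
    # variables x = [v, t]
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    rows = []
    rhs = []
    eye = np.eye(n)
    rows.append(np.hstack([eye, -eye]))        # v - t <= 0
    rhs.append(np.zeros(n))
    rows.append(np.hstack([-eye, -eye]))       # -v - t <= 0
    rhs.append(np.zeros(n))
    rows.append(np.concatenate([-c, np.zeros(n)])[None, :])  # c.v >= z* - eps
    rhs.append(np.array([-(opt_value - 1e-9 * max(1.0, abs(opt_value)))]))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    big = max(abs(b) for lo, hi in bounds for b in (lo, hi))
    bounds2 = list(bounds) + [(0.0, big)] * n
    res = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(A_eq.shape[0]), bounds=bounds2,
                  method="highs")
    if res.status != 0:
        return None
    return res.x[:n]


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str | None = None,
    minimize_total_flux: bool = True,
) -> FluxSolution:
    """Solve one FBA problem.

    ``objective``/``direction`` default to the model's own objective.  On
    an optimal outcome the returned fluxes satisfy S.v = 0 within 1e-6 and
    all bounds within 1e-9.
    """
    if objective is None:
        if model.objective is None:
            raise ValueError("model has no objective and none was given")
        objective, model_dir = model.objective
    else:
        model_dir = "maximize"
    direction = direction or model_dir
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"bad direction {direction!r}")
    model.reaction(objective)  # raises KeyError for unknown objective

    S, _met_index, rxn_index = build_stoichiometric_matrix(model)
    n = S.shape[1]
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    c = np.zeros(n)
    c[rxn_index[objective]] = 1.0
    sign = -1.0 if direction == "maximize" else 1.0
    res = _solve_raw(S, sign * c, bounds)
    status = _linprog_status(res.status)
    if status != "optimal":
        return FluxSolution(status=status)
    opt = float(c @ res.x)
    v = res.x
    if minimize_total_flux:
        cmax = c if direction == "maximize" else -c
        v2 = _minimize_total_flux(S, cmax, bounds,
                                  opt if direction == "maximize" else -opt)
        if v2 is not None:
            v = v2
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    return FluxSolution(status="optimal", objective_value=opt, fluxes=fluxes)


def compute_yield(solution: FluxSolution, product_exchange: str,
                  substrate_exchange: str) -> float:
    """Molar yield: product efflux divided by |substrate uptake|."""
    if not solution.optimal:
        raise ValueError(f"cannot compute a yield from a {solution.status} solution")
    uptake = abs(solution.flux(substrate_exchange))
    if uptake <= FEASIBILITY_TOL:
        raise UndefinedYieldError(
            f"substrate exchange {substrate_exchange} carries zero flux")
    return solution.flux(product_exchange) / uptake


def flux_variability(
    model: MetabolicModel,
    reaction: str,
    fix_objective_fraction: float | None = None,
) -> tuple[float, float]:
    """Feasible flux range of one reaction (two LP solves).

    With ``fix_objective_fraction`` the model objective is first optimized
    and then constrained to at least that fraction of its optimum.
    """
    work = model
    if fix_objective_fraction is not None:
        if model.objective is None:
            raise ValueError("fix_objective_fraction requires a model objective")
        base = solve_fba(model, minimize_total_flux=False)
        if not base.optimal:
            raise InfeasibleModelError(
                f"base model is {base.status}; cannot fix objective")
        rid, direction = model.objective
        target = fix_objective_fraction * base.objective_value
        work = model.copy()
        rxn = work.reaction(rid)
        if direction == "maximize":
            rxn.lower_bound = max(rxn.lower_bound,
                                  target - 1e-9 * max(1.0, abs(target)))
        else:
            rxn.upper_bound = min(rxn.upper_bound,
                                  target + 1e-9 * max(1.0, abs(target)))
    lo_sol = solve_fba(work, objective=reaction, direction="minimize",
                       minimize_total_flux=False)
    hi_sol = solve_fba(work, objective=reaction, direction="maximize",
                       minimize_total_flux=False)
    if not (lo_sol.optimal and hi_sol.optimal):
        raise InfeasibleModelError(
            f"FVA on {reaction}: model is {lo_sol.status}/{hi_sol.status}")
    return lo_sol.objective_value, hi_sol.objective_value


@dataclass(frozen=True)
class EnvelopePoint:
    """One point of a production envelope."""

    growth_fraction: float  # dimensionless, in [0, 1]
    growth_rate: float      # 1/h
    max_yield: float        # mol product / mol methanol


def production_envelope(
    model: MetabolicModel,
    product: ProductTarget | str,
    n_points: int = 21,
    substrate_exchange: str = METHANOL_EXCHANGE,
    biomass_reaction: str = BIOMASS_REACTION,
) -> list[EnvelopePoint]:
    """Maximum product yield as a function of imposed growth rate.

    For each of ``n_points`` growth fractions f in [0, 1] the biomass flux
    is fixed at f times its maximum and the product exchange is maximized.
    """
    if isinstance(product, str):
        product = PRODUCTS[product]
    model.reaction(biomass_reaction)
    model.reaction(product.exchange_reaction)
    growth = solve_fba(model, objective=biomass_reaction,
                       direction="maximize", minimize_total_flux=False)
    if not growth.optimal:
        raise InfeasibleModelError(f"growth optimization is {growth.status}")
    mu_max = growth.objective_value
    if mu_max <= FEASIBILITY_TOL:
        raise InfeasibleModelError(
            "maximum growth rate is zero; envelope undefined")
    points: list[EnvelopePoint] = []
    for f in np.linspace(0.0, 1.0, n_points):
        fixed = model.copy()
        rxn = fixed.reaction(biomass_reaction)
        target = f * mu_max
        rxn.lower_bound = max(0.0, target - 1e-8 * max(1.0, mu_max))
        rxn.upper_bound = target
        if f == 0.0:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        sol = solve_fba(fixed, objective=product.exchange_reaction,
                        direction="maximize", minimize_total_flux=False)
        if not sol.optimal:
            raise InfeasibleModelError(
                f"envelope point f={f:.3f} is {sol.status}")
        y = compute_yield(sol, product.exchange_reaction, substrate_exchange)
        points.append(EnvelopePoint(growth_fraction=float(f),
                                    growth_rate=float(target),
                                    max_yield=y))
    return points


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """max |S.v| of a solution against a model; sanity diagnostic."""
    S, _mi, rxn_index = build_stoichiometric_matrix(model)
    v = np.zeros(S.shape[1])
    for rid, j in rxn_index.items():
        v[j] = solution.flux(rid)
    return float(np.max(np.abs(S @ v)))
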