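"""Flux balance analysis and minimal-media determination.

Linear programs are solved with HiGHS through :mod:`scipy.optimize`
(single-threaded, deterministic given a fixed variable ordering, dual
feasibility tolerance 1e-9). Minimal media is a two-stage MILP: first
minimize the number of active import exchanges, then, at that cardinality,
minimize the total uptake flux — the tie-break pins down degenerate optima.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import InfeasibleError, UnboundedModelError, ValidationError
from .model import FLUX_BOUND, GROWTH_EPS, FluxSolution, MediaSpec, MetabolicModel

#: LP/MILP optimality tolerance.
OPT_TOL = 1e-9

#: Relative slack on the growth target when minimizing media.
MU_TOL = 1e-6

_LP_OPTIONS = {
    "presolve": True,
    "dual_feasibility_tolerance": OPT_TOL,
    "primal_feasibility_tolerance": OPT_TOL,
}


def _effective_bounds(model: MetabolicModel, media: MediaSpec) -> tuple[np.ndarray, np.ndarray]:
    """Reaction bounds with media uptake caps applied to exchanges."""
    lb, ub = model.bounds_arrays()
    for ex in model.exchange_ids:
        j = model._index[ex]
        lb[j] = max(lb[j], -media.cap(ex))
    return lb, ub


def optimize_growth(model: MetabolicModel, media: MediaSpec) -> FluxSolution:
    """Maximize biomass flux under steady-state mass balance and media caps.

    Solves ``max v_biomass  s.t.  S v = 0,  lb ≤ v ≤ ub`` where each
    exchange's lower bound is clipped at minus the media uptake cap.

    Raises
    ------
    UnboundedModelError
        If the biomass objective is unbounded (a thermodynamically impossible
        flux loop feeding biomass — a model construction bug).
    """
    S, _ = model.stoichiometric_matrix()
    lb, ub = _effective_bounds(model, media)
    c = np.zeros(len(model.reactions))
    c[model._index[model.biomass_id]] = -1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=np.column_stack([lb, ub]),
        method="highs", options=_LP_OPTIONS,
    )
    if res.status == 3:  # unbounded
        raise UnboundedModelError(
            f"biomass objective unbounded in model {model.id!r}; "
            "check for an unbalanced internal cycle", escape=None,
        )
    if res.status != 0 or res.x is None:
        return FluxSolution(status="infeasible", mu=0.0, fluxes={})
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxSolution(status="optimal", mu=float(-res.fun), fluxes=fluxes)


def replete_media(model: MetabolicModel, cap: float = FLUX_BOUND) -> MediaSpec:
    """Media with every exchange's uptake capped at the maximum flux bound."""
    return MediaSpec({ex: cap for ex in model.exchange_ids})


def minimal_media(
    model: MetabolicModel,
    mu_target: float,
    *,
    tol: float = MU_TOL,
) -> tuple[MediaSpec, FluxSolution]:
    """Smallest set of import exchanges sustaining ``mu_target``.

    Two-stage mixed-integer program. Stage 1 minimizes the number of active
    imports (binary indicator per exchange, big-M linking with M equal to the
    flux bound); stage 2 fixes that cardinality and minimizes total uptake
    flux. The returned media carries the stage-2 uptake magnitudes; the
    returned solution attains ``mu ≥ mu_target·(1 − tol)``.
    """
    if mu_target <= GROWTH_EPS:
        empty = MediaSpec({})
        return empty, optimize_growth(model, empty)

    S, _ = model.stoichiometric_matrix()
    n_rxn = len(model.reactions)
    ex_idx = np.array([model._index[ex] for ex in model.exchange_ids])
    n_ex = len(ex_idx)
    lb, ub = _effective_bounds(model, replete_media(model))
    mu_floor = mu_target * (1.0 - tol)
    j_bio = model._index[model.biomass_id]

    # Variables: [v (n_rxn), y (n_ex binary), u (n_ex uptake magnitudes)]
    n_var = n_rxn + 2 * n_ex
    integrality = np.zeros(n_var)
    integrality[n_rxn : n_rxn + n_ex] = 1

    var_lb = np.concatenate([lb, np.zeros(n_ex), np.zeros(n_ex)])
    var_ub = np.concatenate([ub, np.ones(n_ex), np.full(n_ex, FLUX_BOUND)])

    constraints = []
    A_mass = np.zeros((S.shape[0], n_var))
    A_mass[:, :n_rxn] = S
    constraints.append(LinearConstraint(A_mass, 0.0, 0.0))

    # v_ex + M·y ≥ 0  (uptake only through open imports)
    A_link = np.zeros((n_ex, n_var))
    for k, j in enumerate(ex_idx):
        A_link[k, j] = 1.0
        A_link[k, n_rxn + k] = FLUX_BOUND
    constraints.append(LinearConstraint(A_link, 0.0, np.inf))

    # u_ex ≥ −v_ex  (uptake magnitude)
    A_up = np.zeros((n_ex, n_var))
    for k, j in enumerate(ex_idx):
        A_up[k, j] = 1.0
        A_up[k, n_rxn + n_ex + k] = 1.0
    constraints.append(LinearConstraint(A_up, 0.0, np.inf))

    A_mu = np.zeros((1, n_var))
    A_mu[0, j_bio] = 1.0
    constraints.append(LinearConstraint(A_mu, mu_floor, np.inf))

    # Stage 1: minimize import count.
    c1 = np.zeros(n_var)
    c1[n_rxn : n_rxn + n_ex] = 1.0
    res1 = milp(
        c=c1, constraints=constraints, integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
    )
    if res1.status != 0 or res1.x is None:
        raise InfeasibleError(
            f"growth target {mu_target:g} unreachable for model {model.id!r}"
        )
    k_star = int(round(res1.fun))

    # Stage 2: at minimum cardinality, minimize total uptake flux.
    A_card = np.zeros((1, n_var))
    A_card[0, n_rxn : n_rxn + n_ex] = 1.0
    c2 = np.zeros(n_var)
    c2[n_rxn + n_ex :] = 1.0
    res2 = milp(
        c=c2,
        constraints=constraints + [LinearConstraint(A_card, -np.inf, k_star)],
        integrality=integrality, bounds=Bounds(var_lb, var_ub),
    )
    if res2.status != 0 or res2.x is None:  # pragma: no cover - stage 1 feasible
        raise InfeasibleError("minimal-media tie-break stage infeasible")

    v = res2.x[:n_rxn]
    uptake = {
        ex: float(max(0.0, -v[j]))
        for ex, j in zip(model.exchange_ids, ex_idx)
        if -v[j] > GROWTH_EPS
    }
    media = MediaSpec(uptake)
    solution = FluxSolution(
        status="optimal", mu=float(v[j_bio]), fluxes=dict(zip(model.reaction_ids, v))
    )
    return media, solution


def mass_balance_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """Largest absolute net production over all metabolites.

    Zero (within solver tolerance) for any steady-state solution.
    """
    if not solution.optimal:
        raise ValidationError("mass balance undefined for non-optimal solutions")
    S, _ = model.stoichiometric_matrix()
    v = np.array([solution.fluxes.get(r, 0.0) for r in model.reaction_ids])
    return float(np.abs(S @ v).max()) if len(v) else 0.0
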