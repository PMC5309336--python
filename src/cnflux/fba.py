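"""Linear-programming core: FBA, parsimonious FBA, FVA, blocked-reaction pruning.

All programs are solved with the HiGHS solver behind
:func:`scipy.optimize.linprog`; the solver call is isolated in
:func:`_solve_lp` so an alternative LP backend can be swapped in at a single
point.  Flux balance analysis maximizes the biomass objective flux subject to
steady state ``S v = 0`` and the reaction bounds; parsimonious FBA then
minimizes total absolute flux at the fixed optimum to pick a unique
representative among alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "FluxSolution",
    "FvaRange",
    "optimize",
    "parsimonious",
    "fva",
    "prune_blocked",
]

#: reactions with |flux range| below this are treated as blocked
BLOCKED_TOL = 1e-9


@dataclass
class FluxSolution:
    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FvaRange:
    reaction_id: str
    v_min: float
    v_max: float


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    return res, _STATUS.get(res.status, "numerical")


def _lp_parts(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S, list(zip(lb, ub))


def optimize(model: MetabolicModel) -> FluxSolution:
    """Maximize the biomass objective flux. Infeasibility is a status, not
    an exception."""
    if model.objective_id is None:
        raise ValueError("model has no objective reaction")
    S, bounds = _lp_parts(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective_id)] = -1.0
    res, status = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    if status != "optimal":
        return FluxSolution(None, {}, status)
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxSolution(float(-res.fun), fluxes, "optimal")


def parsimonious(model: MetabolicModel, opt_tol: float = 1e-9) -> FluxSolution:
    """pFBA: fix the objective at its optimum, minimize the total absolute flux.

    The flux vector is split ``v = p - q`` with ``p, q >= 0`` and
    ``sum(p + q)`` minimized, which equals ``sum |v|`` at the optimum.
    Returns the unique-total-flux representative solution.
    """
    base = optimize(model)
    if not base.ok:
        return base
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    j_obj = model.reaction_ids.index(model.objective_id)
    # pin the objective flux (tiny slack absorbs solver noise)
    lb = lb.copy()
    ub = ub.copy()
    lb[j_obj] = max(lb[j_obj], base.objective_value - opt_tol)
    ub[j_obj] = min(ub[j_obj], base.objective_value + opt_tol)
    # variables [p; q], v = p - q
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    # lb <= p - q <= ub  ->  -(p - q) <= -lb  and  (p - q) <= ub
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([-eye, eye]), np.hstack([eye, -eye])])
    b_ub = np.concatenate([-lb, ub])
    c = np.ones(2 * n)
    bounds = [(0, None)] * (2 * n)
    res, status = _solve_lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    if status != "optimal":
        return FluxSolution(None, {}, status)
    v = res.x[:n] - res.x[n:]
    lb0, ub0 = model.bounds_arrays()
    v = np.clip(v, lb0, ub0)  # shave sub-tolerance solver overshoot
    v[np.abs(v) < 1e-12] = 0.0
    return FluxSolution(base.objective_value, dict(zip(model.reaction_ids, v)), "optimal")


def fva(
    model: MetabolicModel,
    rxn_ids: list[str] | None = None,
    fix_objective_fraction: float = 0.0,
) -> list[FvaRange]:
    """Flux variability analysis: per-reaction achievable flux range.

    ``fix_objective_fraction=0`` is pure feasibility FVA; fraction 1 pins the
    objective at its optimum before ranging.
    """
    if not 0.0 <= fix_objective_fraction <= 1.0:
        raise ValueError("fix_objective_fraction must lie in [0, 1]")
    rxn_ids = model.reaction_ids if rxn_ids is None else rxn_ids
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if fix_objective_fraction > 0:
        base = optimize(model)
        if not base.ok:
            raise RuntimeError(f"FVA: model is {base.status}")
        j_obj = model.reaction_ids.index(model.objective_id)
        target = fix_objective_fraction * base.objective_value
        if base.objective_value >= 0:
            lb = lb.copy()
            lb[j_obj] = max(lb[j_obj], target)
        else:  # negative optimum: fixing a fraction bounds from above
            ub = ub.copy()
            ub[j_obj] = min(ub[j_obj], target)
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    n = len(model.reactions)
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    out = []
    for rid in rxn_ids:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo, status = _solve_lp(c, S, b_eq, bounds)
        if status != "optimal":
            raise RuntimeError(f"FVA minimization failed for {rid}: {status}")
        c[j] = -1.0
        hi, status = _solve_lp(c, S, b_eq, bounds)
        if status != "optimal":
            raise RuntimeError(f"FVA maximization failed for {rid}: {status}")
        vmin, vmax = float(lo.fun), float(-hi.fun)
        if vmin > vmax:  # solver noise on a fixed coordinate
            vmin = vmax = 0.5 * (vmin + vmax)
        out.append(FvaRange(rid, vmin, vmax))
    return out


def prune_blocked(
    model: MetabolicModel, tol: float = BLOCKED_TOL
) -> tuple[MetabolicModel, list[str], list[str]]:
    """Remove reactions that cannot carry flux under the applied constraints,
    then metabolites left orphaned.

    Blocked status is decided by feasibility FVA (objective unfixed): a
    reaction with ``|v_min| <= tol`` and ``|v_max| <= tol`` can never carry
    flux.  The reduced model preserves feasibility and the optimum.
    """
    base = optimize(model)
    if not base.ok:
        raise RuntimeError(f"cannot prune an {base.status} model")
    ranges = fva(model, fix_objective_fraction=0.0)
    blocked = [
        r.reaction_id
        for r in ranges
        if abs(r.v_min) <= tol and abs(r.v_max) <= tol
        and r.reaction_id != model.objective_id  # objective stays referenceable
    ]
    blocked_set = set(blocked)
    kept_rxns = [r for r in model.reactions if r.id not in blocked_set]
    used_mets: set[str] = set()
    for r in kept_rxns:
        used_mets |= set(r.stoichiometry)
    removed_mets = [m.id for m in model.metabolites if m.id not in used_mets]
    reduced = MetabolicModel(
        id=model.id,
        metabolites=[m for m in model.metabolites if m.id in used_mets],
        reactions=[
            Reaction(
                id=r.id,
                stoichiometry=dict(r.stoichiometry),
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gpr,
                subsystem=r.subsystem,
                name=r.name,
                reversible=r.reversible,
            )
            for r in kept_rxns
        ],
        objective_id=model.objective_id,
        extracellular_compartment=model.extracellular_compartment,
        currency=model.currency,
    )
    return reduced, blocked, removed_mets


def write_fluxes_tsv(sol: FluxSolution, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"reaction_id": list(sol.fluxes), "flux": list(sol.fluxes.values())}
    ).to_csv(path, sep="\t", index=False)


def write_fva_tsv(ranges: list[FvaRange], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.reaction_id, r.v_min, r.v_max) for r in ranges],
        columns=["reaction_id", "v_min", "v_max"],
    ).to_csv(path, sep="\t", index=False)
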