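"""Independent reference implementations used to check the library.

These deliberately avoid the code paths they verify: the LP oracle
enumerates basic feasible solutions instead of calling a simplex
solver through the library wrapper, the knockout oracle re-evaluates
GPR truth tables and builds its own matrices, and the flux-sum oracle
loops over reactions explicitly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from picogem.core import Model


def vertex_enumeration_max(model: Model, objective: str,
                           bounds_override: dict | None = None) -> float:
    """Maximum of the FBA LP by brute-force vertex enumeration.

    For S v = 0 with n variables and rank-m S, every vertex fixes
    (n - m) variables at a finite bound and solves the square system
    for the rest.  Only practical for tiny models (n <= ~12).
    """
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    met_ids = list(model.metabolites)
    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(mid), j] = coeff
    rank = np.linalg.matrix_rank(S)
    bounds = []
    for rid in rxn_ids:
        r = model.reactions[rid]
        lb, ub = r.lower_bound, r.upper_bound
        if bounds_override and rid in bounds_override:
            lb, ub = bounds_override[rid]
        bounds.append((lb, ub))
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = 1.0
    n_fixed = n - rank
    best = -math.inf
    for fixed_idx in itertools.combinations(range(n), n_fixed):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for choice in itertools.product(*[
            [b for b in bounds[j] if math.isfinite(b)] or [None]
            for j in fixed_idx
        ]):
            if any(v is None for v in choice):
                continue
            v = np.full(n, np.nan)
            for j, val in zip(fixed_idx, choice):
                v[j] = val
            A = S[:, free_idx]
            rhs = -S[:, fixed_idx] @ np.array(choice)
            sol, residual, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > 1e-8:
                continue
            v[free_idx] = sol
            ok = all(
                bounds[j][0] - 1e-9 <= v[j] <= bounds[j][1] + 1e-9
                for j in range(n)
            )
            if ok:
                best = max(best, float(c @ v))
    return best


def gpr_disabled(reaction, knocked_out: set[str]) -> bool:
    """Truth-table GPR evaluation: reaction is off iff no complex
    survives the knockout."""
    if reaction.gpr is None:
        return False
    for complex_genes in reaction.gpr.complexes:
        if not (set(complex_genes) & knocked_out):
            return False
    return True


def lp_max_growth(model: Model, medium, disabled: set[str]) -> float:
    """Direct scipy LP for maximum growth with a reaction set disabled;
    independent of the library's solve path."""
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(mid), j] = coeff
    bounds = []
    for rid in rxn_ids:
        r = model.reactions[rid]
        lb, ub = r.lower_bound, r.upper_bound
        if medium is not None and rid in medium.bounds:
            lb, ub = medium.bounds[rid]
        if rid in disabled:
            lb, ub = 0.0, 0.0
        bounds.append((
            None if math.isinf(lb) else lb,
            None if math.isinf(ub) else ub,
        ))
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(met_ids)), bounds=bounds,
                  method="highs")
    return -res.fun if res.status == 0 else 0.0


def knockout_oracle(model: Model, media: list, lethal_abs=1e-6, lethal_rel=1e-3):
    """Brute-force essentiality classification."""
    wild = {m.name: lp_max_growth(model, m, set()) for m in media}
    out = {}
    for gene in model.genes:
        disabled = {
            r.id for r in model.reactions.values() if gpr_disabled(r, {gene})
        }
        lethal = []
        for m in media:
            mu = lp_max_growth(model, m, disabled)
            lethal.append(mu < max(lethal_abs, lethal_rel * wild[m.name]))
        if all(lethal):
            out[gene] = "essential"
        elif any(lethal):
            out[gene] = "variable_essential"
        else:
            out[gene] = "nonessential"
    return out


def flux_sum_oracle(model: Model, fluxes: dict[str, float],
                    metabolite: str) -> float:
    """Explicit half-sum of absolute stoichiometry-weighted fluxes."""
    total = 0.0
    for rxn in model.reactions.values():
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        total += abs(coeff * fluxes[rxn.id])
    return 0.5 * total
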