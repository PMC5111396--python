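"""Biomass objective function (BOF) assembly and analytics.

The biomass reaction drains precursor compounds in measured mass
proportions (mass fraction / molecular weight, scaled to mmol per gram
dry weight) plus a growth-associated maintenance (GAM) ATP hydrolysis
term.  On top of the assembled reaction this module provides:

* elemental stoichiometry of 1 gDW of biomass (molar C:N:P and the full
  element vector);
* a Thornton-type enthalpy budget (heats of combustion from the degree
  of reduction, and the regression of enthalpy against cofactor cost);
* growth sensitivity Psi_k to small perturbations of composition pools;
* an exhaustive composition search constrained to molar C/P windows
  under phosphate- or carbon-limited growth;
* phosphorus partitioning among crude fractions and the quota-reduction
  arithmetic linking baseline and stress C/P ratios.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ELEMENTS, Model, ModelError, Reaction
from .fba import MediumSpec, solve_fba

__all__ = [
    "BiomassComposition",
    "assemble_bof",
    "install_bof",
    "bof_stoichiometry",
    "BofStoichiometry",
    "heat_of_combustion",
    "atp_energy_regression",
    "EnergyRegression",
    "biomass_sensitivity",
    "SensitivityReport",
    "cp_search",
    "CpSearchResult",
    "p_partitioning",
    "required_p_reduction",
    "PReduction",
]

#: Recognized crude fraction names, in reporting order.
CRUDE_FRACTIONS = (
    "DNA",
    "RNA",
    "protein",
    "lipid",
    "pigments",
    "cell_wall",
    "carbohydrate",
    "free_nucleic_acids",
    "free_amino_acids",
    "biopool",
    "minerals",
)


@dataclass
class BiomassComposition:
    """Crude fractions -> [(compound id, mass fraction of ash-free DW)].

    ``gam`` is the growth-associated ATP maintenance (mmol ATP/gDW) and
    ``ngam`` the non-growth-associated maintenance (mmol ATP/gDW/h).
    The defaults are documented placeholders used when no growth-rate /
    uptake pair is available to fit them.
    """

    fractions: dict[str, list[tuple[str, float]]]
    gam: float = 30.0
    ngam: float = 0.3

    def validate(self, tol: float = 1e-6) -> None:
        total = self.total_mass()
        if abs(total - 1.0) > tol:
            raise ModelError(f"mass fractions sum to {total:.8f}, not 1")
        for fraction, entries in self.fractions.items():
            for compound, mass in entries:
                if mass < 0:
                    raise ModelError(f"{fraction}/{compound}: negative mass fraction")

    def total_mass(self) -> float:
        return sum(m for entries in self.fractions.values() for _, m in entries)

    def scaled(
        self, scales: dict[str, float], renormalize: bool = False
    ) -> "BiomassComposition":
        """Multiply whole fractions (key = fraction name) or single
        compounds (key = ``fraction/compound``) by scale factors."""
        new = {}
        for fraction, entries in self.fractions.items():
            factor = scales.get(fraction, 1.0)
            new[fraction] = [
                (c, m * factor * scales.get(f"{fraction}/{c}", 1.0))
                for c, m in entries
            ]
        comp = BiomassComposition(new, self.gam, self.ngam)
        if renormalize:
            total = comp.total_mass()
            if total <= 0:
                raise ModelError("cannot renormalize an empty composition")
            comp = BiomassComposition(
                {
                    f: [(c, m / total) for c, m in entries]
                    for f, entries in comp.fractions.items()
                },
                self.gam,
                self.ngam,
            )
        return comp

    @classmethod
    def from_table(
        cls,
        rows: list[tuple[str, str, float]],
        gam: float = 30.0,
        ngam: float = 0.3,
    ) -> "BiomassComposition":
        fractions: dict[str, list[tuple[str, float]]] = {}
        for fraction, compound, mass in rows:
            fractions.setdefault(fraction, []).append((compound, mass))
        return cls(fractions, gam, ngam)

    def to_table(self) -> list[tuple[str, str, float]]:
        return [
            (f, c, m) for f, entries in self.fractions.items() for c, m in entries
        ]


def _formula_of(model: Model, compound: str) -> dict[str, int]:
    if compound not in model.metabolites:
        raise ModelError(f"biomass compound {compound!r} not in model")
    return model.metabolites[compound].formula


# ---------------------------------------------------------------------------
# Assembly

GAM_SPECIES = {
    "atp": "atp[c]",
    "h2o": "h2o[c]",
    "adp": "adp[c]",
    "pi": "pi[c]",
}


def assemble_bof(
    comp: BiomassComposition,
    model: Model,
    reaction_id: str = "BOF",
    gam_species: dict[str, str] | None = None,
    check_mass: bool = True,
) -> Reaction:
    """Build the biomass pseudo-reaction from a composition.

    Precursor coefficients are ``1000 * mass_fraction / MW`` (mmol/gDW);
    the GAM term consumes ATP and water and produces ADP and
    orthophosphate.
    """
    if check_mass:
        comp.validate()
    species = dict(GAM_SPECIES, **(gam_species or {}))
    stoich: dict[str, float] = {}
    for fraction, entries in comp.fractions.items():
        for compound, mass in entries:
            if mass == 0:
                continue
            met = model.metabolites.get(compound)
            if met is None or not met.molecular_weight:
                raise ModelError(
                    f"cannot resolve biomass compound {compound!r} (fraction"
                    f" {fraction})"
                )
            stoich[compound] = stoich.get(compound, 0.0) - 1000.0 * mass / met.molecular_weight
    if comp.gam:
        for sp in ("atp", "h2o"):
            stoich[species[sp]] = stoich.get(species[sp], 0.0) - comp.gam
        for sp in ("adp", "pi"):
            stoich[species[sp]] = stoich.get(species[sp], 0.0) + comp.gam
    return Reaction(
        id=reaction_id,
        name="biomass objective",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=math.inf,
        kind="internal",
        subsystem="biomass",
        pseudo=True,
    )


def install_bof(
    model: Model,
    comp: BiomassComposition,
    reaction_id: str = "BOF",
    ngam_id: str = "NGAM",
    gam_species: dict[str, str] | None = None,
    check_mass: bool = True,
) -> Model:
    """Return a copy of the model with BOF and NGAM installed and the
    objective set.  NGAM is a fixed-lower-bound ATP hydrolysis."""
    species = dict(GAM_SPECIES, **(gam_species or {}))
    out = model.copy()
    out.reactions[reaction_id] = assemble_bof(
        comp, model, reaction_id, gam_species, check_mass=check_mass
    )
    if comp.ngam:
        out.reactions[ngam_id] = Reaction(
            id=ngam_id,
            name="non-growth maintenance",
            stoichiometry={
                species["atp"]: -1.0,
                species["h2o"]: -1.0,
                species["adp"]: 1.0,
                species["pi"]: 1.0,
            },
            lower_bound=comp.ngam,
            upper_bound=math.inf,
            kind="internal",
            subsystem="maintenance",
            pseudo=True,
        )
    out.objective_id = reaction_id
    return out


# ---------------------------------------------------------------------------
# Elemental stoichiometry

@dataclass
class BofStoichiometry:
    element_totals: dict[str, float]  # mmol atoms per gDW

    @property
    def cp_ratio(self) -> float | None:
        p = self.element_totals.get("P", 0.0)
        if p <= 0:
            return None
        return self.element_totals.get("C", 0.0) / p

    @property
    def cnp(self) -> tuple[float, float, float] | None:
        p = self.element_totals.get("P", 0.0)
        if p <= 0:
            return None
        return (
            self.element_totals.get("C", 0.0) / p,
            self.element_totals.get("N", 0.0) / p,
            1.0,
        )


def bof_stoichiometry(comp: BiomassComposition, model: Model) -> BofStoichiometry:
    """Molar element content of 1 gDW of biomass.

    Element totals are sums over compounds of
    ``1000 * mass_fraction / MW * atoms`` (mmol atoms/gDW).  A zero
    phosphorus total leaves C/P undefined (None) rather than infinite.
    """
    totals = {e: 0.0 for e in ELEMENTS}
    for fraction, entries in comp.fractions.items():
        for compound, mass in entries:
            if mass == 0:
                continue
            met = model.metabolites.get(compound)
            if met is None or not met.molecular_weight:
                raise ModelError(f"cannot resolve biomass compound {compound!r}")
            mol = 1000.0 * mass / met.molecular_weight
            for e, n in met.formula.items():
                totals[e] = totals.get(e, 0.0) + mol * n
    return BofStoichiometry(totals)


# ---------------------------------------------------------------------------
# Enthalpy budget

#: Valence of each element relative to its combustion product.
_VALENCE = {"H": 1, "C": 4, "N": -3, "O": -2, "P": 5, "S": 6}
THORNTON_KJ_PER_ELECTRON = 115.0


def degree_of_reduction(formula: dict[str, int]) -> float:
    """Transferable electrons per mole relative to combustion products."""
    unknown = set(formula) - set(_VALENCE)
    if unknown:
        raise ModelError(f"no valence for elements {sorted(unknown)}")
    return float(sum(_VALENCE[e] * n for e, n in formula.items()))


def heat_of_combustion(
    formula: dict[str, int],
    kj_per_electron: float = THORNTON_KJ_PER_ELECTRON,
    method=None,
) -> float:
    """Thornton-type heat of combustion estimate in kJ/mol.

    The default estimator multiplies the degree of reduction (valences
    H:+1, C:+4, N:-3, O:-2, P:+5, S:+6) by ~115 kJ per mole of
    transferable electrons; a fully oxidized compound (CO2, O2) burns
    for nothing.  ``method`` may be a callable ``formula -> kJ/mol`` to
    substitute another estimator.
    """
    if method is not None:
        return float(method(formula))
    gamma = degree_of_reduction(formula)
    if gamma < 0:
        warnings.warn(
            f"negative degree of reduction ({gamma:g}); clamping heat of "
            "combustion to 0",
            stacklevel=2,
        )
        return 0.0
    return kj_per_electron * gamma


@dataclass
class EnergyRegression:
    slope_kj_per_mol_atp: float
    energy_density_kj_per_g: float
    n_compounds: int


def atp_energy_regression(
    comp: BiomassComposition,
    costs: dict[str, float],
    model: Model,
    kj_per_electron: float = THORNTON_KJ_PER_ELECTRON,
) -> EnergyRegression:
    """Regress heats of combustion on ATP-equivalent synthesis costs.

    ``costs`` maps compound ids to ATP equivalents (the summed NTP,
    nicotinamide and flavin cofactor demand of synthesis).  The slope is
    an ordinary least squares fit through the origin (kJ per mol ATP);
    the aggregate energy density is the mass-fraction-weighted heat of
    combustion per gram of biomass.
    """
    compounds: dict[str, float] = {}
    for entries in comp.fractions.values():
        for c, m in entries:
            if m > 0:
                compounds[c] = compounds.get(c, 0.0) + m
    shared = [c for c in compounds if c in costs]
    if len(shared) < 3:
        raise ModelError(f"need >= 3 costed compounds, have {len(shared)}")
    x = np.array([costs[c] for c in shared])
    if not np.any(x):
        raise ModelError("all ATP-equivalent costs are zero")
    y = np.array(
        [
            heat_of_combustion(_formula_of(model, c), kj_per_electron)
            for c in shared
        ]
    )
    slope = float(x @ y / (x @ x))
    density = 0.0
    for compound, mass in compounds.items():
        met = model.metabolites[compound]
        density += mass / met.molecular_weight * heat_of_combustion(
            met.formula, kj_per_electron
        )
    return EnergyRegression(slope, density, len(shared))


# ---------------------------------------------------------------------------
# Growth sensitivity

@dataclass
class SensitivityReport:
    psi: dict[str, float]  # target -> dZ per unit pool decrease
    share_percent: dict[str, float]  # |psi| share of the reported targets
    undefined: set[str] = field(default_factory=set)
    step: float = 1e-6


def biomass_sensitivity(
    model: Model,
    comp: BiomassComposition,
    targets: list[str] | None = None,
    medium: MediumSpec | None = None,
    step: float = 1e-6,
    renormalize: bool = False,
) -> SensitivityReport:
    """Growth sensitivity Psi of each composition target.

    Each target (a crude fraction name, or ``fraction/compound``) is
    perturbed multiplicatively by +-``step`` (default 1 ppm), the model
    is re-solved, and ``Psi = (Z(-step) - Z(+step)) / (2 step)``:
    positive Psi means growth rises when the pool shrinks.  The
    perturbation does not re-normalize total biomass mass unless
    ``renormalize`` is set.  Targets absent from the BOF have Psi = 0;
    infeasible perturbations are flagged as undefined.
    """
    targets = list(targets) if targets is not None else list(comp.fractions)
    base = install_bof(model, comp)
    base_sol = solve_fba(base, medium)
    if not base_sol.optimal:
        raise ModelError("baseline FBA not optimal; cannot compute sensitivity")
    psi: dict[str, float] = {}
    undefined: set[str] = set()
    present = {f for f, entries in comp.fractions.items() if any(m > 0 for _, m in entries)}
    present |= {
        f"{f}/{c}"
        for f, entries in comp.fractions.items()
        for c, m in entries
        if m > 0
    }
    for target in targets:
        if target not in present:
            psi[target] = 0.0
            continue
        z = {}
        failed = False
        for sgn in (+1, -1):
            scaled = comp.scaled({target: 1.0 + sgn * step}, renormalize=renormalize)
            # total mass moves off 1 by design when not renormalizing
            perturbed = install_bof(model, scaled, check_mass=False)
            sol = solve_fba(perturbed, medium)
            if not sol.optimal:
                failed = True
                break
            z[sgn] = sol.objective
        if failed:
            undefined.add(target)
            continue
        psi[target] = (z[-1] - z[+1]) / (2 * step)
    total = sum(abs(v) for v in psi.values())
    share = {
        t: (100.0 * abs(v) / total if total > 0 else 0.0) for t, v in psi.items()
    }
    return SensitivityReport(psi, share, undefined, step)


# ---------------------------------------------------------------------------
# C/P-constrained exhaustive composition search

DEFAULT_VARIABLE_FRACTIONS = ("DNA", "RNA", "lipid", "cell_wall", "biopool")


@dataclass
class CpBin:
    lo: float
    hi: float
    n: int
    mean_growth: float | None
    cv: float | None
    best_scales: dict[str, float] | None
    best_growth: float | None
    best_cp: float | None
    best_p_partition: dict[str, float] | None


@dataclass
class CpSearchResult:
    bins: list[CpBin]
    cp_range: tuple[float, float]  # allowable (10% beyond achievable) range
    mode: str
    constraint: tuple[str, float]  # (reaction id, imposed upper bound)

    @property
    def growth_span(self) -> tuple[float, float] | None:
        means = [b.mean_growth for b in self.bins if b.mean_growth is not None]
        if not means:
            return None
        return min(means), max(means)


def cp_search(
    model: Model,
    comp: BiomassComposition,
    medium: MediumSpec | None = None,
    variable_fractions: tuple[str, ...] = DEFAULT_VARIABLE_FRACTIONS,
    levels: int = 7,
    scale_range: tuple[float, float] = (0.1, 1.5),
    n_bins: int = 8,
    mode: str = "PLG",
    constraint_reaction: str | None = None,
    constraint_fraction: float = 0.5,
) -> CpSearchResult:
    """Exhaustively search compositions over a multiplicative grid and
    bin them by molar C/P under a suboptimal nutrient constraint.

    Each variable fraction is scaled by one of ``levels`` factors spread
    linearly over ``scale_range``; compositions are renormalized to unit
    mass, their molar C/P computed, and each is grown by FBA with either
    the orthophosphate transporter (mode ``PLG``) or the carbon-fixation
    reaction (mode ``CLG``) capped at ``constraint_fraction`` of its
    flux in the unconstrained optimum.  Bins span 10% below the minimum
    to 10% above the maximum achievable C/P; empty bins report n = 0.
    """
    if mode not in {"PLG", "CLG"}:
        raise ModelError(f"unknown search mode {mode!r}")
    variable_fractions = tuple(
        f for f in variable_fractions if f in comp.fractions
    )
    if not variable_fractions:
        raise ModelError("no variable fractions present in the composition")

    # constraint bound from the unconstrained optimum
    if constraint_reaction is None:
        constraint_reaction = _default_constraint_reaction(model, mode)
    base = install_bof(model, comp)
    base_sol = solve_fba(base, medium)
    if not base_sol.optimal:
        raise ModelError("unconstrained baseline is not optimal")
    cap = constraint_fraction * abs(base_sol.fluxes[constraint_reaction])
    constraint_bounds = {constraint_reaction: (0.0, cap)}

    grid = np.linspace(scale_range[0], scale_range[1], levels)
    combos = []
    for scales in itertools.product(grid, repeat=len(variable_fractions)):
        scale_map = dict(zip(variable_fractions, (float(s) for s in scales)))
        candidate = comp.scaled(scale_map, renormalize=True)
        cp = bof_stoichiometry(candidate, model).cp_ratio
        if cp is None:
            continue
        combos.append((scale_map, candidate, cp))
    if not combos:
        raise ModelError("no composition in the grid has defined C/P")

    cps = [cp for _, _, cp in combos]
    lo, hi = 0.9 * min(cps), 1.1 * max(cps)
    edges = np.linspace(lo, hi, n_bins + 1)

    bins: list[CpBin] = []
    for k in range(n_bins):
        b_lo, b_hi = float(edges[k]), float(edges[k + 1])
        members = [
            (scale_map, candidate, cp)
            for scale_map, candidate, cp in combos
            if (b_lo <= cp < b_hi) or (k == n_bins - 1 and cp == b_hi)
        ]
        growths = []
        best = None
        for scale_map, candidate, cp in members:
            grown = install_bof(model, candidate)
            sol = solve_fba(grown, medium, extra_bounds=constraint_bounds)
            mu = sol.objective if sol.optimal else 0.0
            growths.append(mu)
            if best is None or mu > best[1]:
                best = (scale_map, mu, cp, candidate)
        if growths:
            mean = float(np.mean(growths))
            cv = float(np.std(growths) / mean) if mean > 0 else None
            partition = (
                p_partitioning(best[3], model) if best is not None else None
            )
            bins.append(
                CpBin(
                    b_lo, b_hi, len(growths), mean, cv,
                    best[0], best[1], best[2], partition,
                )
            )
        else:
            bins.append(CpBin(b_lo, b_hi, 0, None, None, None, None, None, None))
    return CpSearchResult(
        bins=bins, cp_range=(lo, hi), mode=mode,
        constraint=(constraint_reaction, cap),
    )


def _default_constraint_reaction(model: Model, mode: str) -> str:
    """Guess the Pi transporter (PLG) or carboxylation (CLG) reaction."""
    hints = {"PLG": ("PIT", "pst"), "CLG": ("RBC", "rubisco")}[mode]
    for rid, rxn in model.reactions.items():
        if rid == hints[0] or hints[1] in rxn.name.lower() or hints[1] in rid.lower():
            return rid
    raise ModelError(
        f"cannot identify the {mode} constraint reaction; pass constraint_reaction"
    )


# ---------------------------------------------------------------------------
# Phosphorus partitioning and quota arithmetic

def p_partitioning(comp: BiomassComposition, model: Model) -> dict[str, float]:
    """Percent of total biomass phosphorus bound in each crude fraction."""
    p_by_fraction: dict[str, float] = {}
    for fraction, entries in comp.fractions.items():
        total = 0.0
        for compound, mass in entries:
            if mass == 0:
                continue
            met = model.metabolites.get(compound)
            if met is None or not met.molecular_weight:
                raise ModelError(f"cannot resolve biomass compound {compound!r}")
            total += mass / met.molecular_weight * met.formula.get("P", 0)
        p_by_fraction[fraction] = total
    grand = sum(p_by_fraction.values())
    if grand <= 0:
        raise ModelError("composition contains no phosphorus")
    return {f: 100.0 * p / grand for f, p in p_by_fraction.items()}


@dataclass
class PReduction:
    percent: float | None  # required reduction of non-static P pools, %
    feasible: bool
    target_p_quota: float  # P' with baseline P normalized to 1
    note: str = ""


def required_p_reduction(
    baseline_cp: float,
    c_increase: float,
    target_cp: float,
    static_p_share: float,
) -> PReduction:
    """Reduction of non-static P pools needed to reach a target C/P.

    With the baseline P quota normalized to 1 (so the C quota is
    ``baseline_cp``), the carbon quota grows by ``c_increase`` under
    limitation, the new P quota is ``P' = C'/target_cp``, and the static
    pool (e.g. the DNA share, fixed through G1) cannot shrink.  The
    remaining pools must then fall by
    ``1 - (P' - static) / (1 - static)``; if ``P' < static`` the target
    is infeasible because the static pool alone exceeds the allowed P.
    """
    if baseline_cp <= 0 or target_cp <= 0:
        raise ModelError("C/P ratios must be positive")
    if not 0 <= static_p_share < 1:
        raise ModelError("static P share must lie in [0, 1)")
    c_new = (1.0 + c_increase) * baseline_cp
    p_new = c_new / target_cp
    if p_new < static_p_share:
        return PReduction(
            None, False, p_new,
            "static pool alone exceeds the target P quota",
        )
    reduction = 1.0 - (p_new - static_p_share) / (1.0 - static_p_share)
    note = ""
    if reduction < 0 or reduction > 1:
        note = f"reduction {reduction:.3f} clamped into [0, 1]"
        warnings.warn(note, stacklevel=2)
        reduction = min(1.0, max(0.0, reduction))
    return PReduction(100.0 * reduction, True, p_new, note)
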