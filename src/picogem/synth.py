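"""Generators for a toy compartmentalized photoautotroph.

The toy model is a miniature oxygenic phototroph with three-plus
compartments (extracellular, cytoplasm, thylakoid membrane/lumen): a
full photosynthetic electron chain (PSII, cytochrome b6f, PSI, FdR,
FQR, NDH, COX, ATP synthase) wired through the plastoquinone,
plastocyanin, and ferredoxin redox pools with explicit thylakoid proton
translocation; a Rubisco-like carboxylation plus a three-step
Calvin-Benson-Bassham loop regenerating the acceptor from ATP and
NADPH; a branched TCA cycle (no 2-oxoglutarate -> succinate route
unless knocked in); lumped precursor syntheses; and a biomass objective
built from crude fractions whose compounds carry molecular formulas, so
elemental (C/P) manipulation is meaningful.  Every internal reaction is
elementally balanced by construction (lumped syntheses solve their
water/proton/CO2 coefficients from the element-balance linear system
and are asserted at generation time).

Redox chemistry is simplified electron bookkeeping: carriers differ by
whole H atoms (PQ/PQH2, NADP/NADPH) or by charge only (PC, Fd); the
model reproduces flux partitioning among linear, cyclic, and
pseudocyclic electron flow, not photochemical detail.

Generation is deterministic: the same configuration and seed yield a
bit-identical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biomass import BiomassComposition, bof_stoichiometry, install_bof
from .core import (
    Gene,
    GeneProteinRule,
    Metabolite,
    Model,
    ModelError,
    Reaction,
)
from .fba import MediumSpec
from .phenotypes import LightProfile

__all__ = [
    "ToyConfig",
    "make_toy_photoautotroph",
    "default_medium",
    "make_expression",
    "make_light_profile",
]


@dataclass
class ToyConfig:
    seed: int = 0
    n_filler_reactions: int = 0
    include_sdh: bool = False
    include_2ogdc_ssadh: bool = False
    baseline_cp: float = 121.0  # molar C/P of the biomass under balanced growth
    #: fixed crude-fraction masses (g/gDW); RNA and carbohydrate split the
    #: remainder to 1 so that the molar C/P hits ``baseline_cp``.
    protein_mass: float = 0.55
    lipid_mass: float = 0.12
    dna_mass: float = 0.015
    pigment_mass: float = 0.04
    cell_wall_mass: float = 0.05
    biopool_mass: float = 0.01
    gam: float = 30.0  # mmol ATP/gDW
    ngam: float = 0.3  # mmol ATP/gDW/h
    photon_ub: float = 100.0  # mmol photons/gDW/h
    pi_uptake: float = 10.0  # mmol/gDW/h
    nh3_uptake: float = 10.0
    co2_uptake: float = 1000.0
    storage_drawdown: float = 0.5  # night-time glycogen sink bound


_FORMULAS = {
    "photon[e]": {},
    "co2[c]": {"C": 1, "O": 2},
    "o2[c]": {"O": 2},
    "pi[e]": {"H": 3, "O": 4, "P": 1},
    "pi[c]": {"H": 3, "O": 4, "P": 1},
    "nh3[c]": {"H": 3, "N": 1},
    "h2o[c]": {"H": 2, "O": 1},
    "h[c]": {"H": 1},
    "h[l]": {"H": 1},
    "pq[m]": {"C": 13, "H": 18, "O": 2},
    "pqh2[m]": {"C": 13, "H": 20, "O": 2},
    "pcox[l]": {"Cu": 1},
    "pcred[l]": {"Cu": 1},
    "fdox[c]": {"Fe": 1},
    "fdred[c]": {"Fe": 1},
    "nadp[c]": {"C": 21, "H": 28, "N": 7, "O": 17, "P": 3},
    "nadph[c]": {"C": 21, "H": 29, "N": 7, "O": 17, "P": 3},
    "atp[c]": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp[c]": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "rubp[c]": {"C": 5, "H": 12, "O": 11, "P": 2},
    "pga[c]": {"C": 3, "H": 7, "O": 7, "P": 1},
    "gap[c]": {"C": 3, "H": 7, "O": 6, "P": 1},
    "pyr[c]": {"C": 3, "H": 4, "O": 3},
    "og[c]": {"C": 5, "H": 6, "O": 5},
    "fum[c]": {"C": 4, "H": 4, "O": 4},
    "succ[c]": {"C": 4, "H": 6, "O": 4},
    "glu[c]": {"C": 5, "H": 9, "N": 1, "O": 4},
    "glc[c]": {"C": 6, "H": 12, "O": 6},
    "amp[c]": {"C": 10, "H": 14, "N": 5, "O": 7, "P": 1},
    "damp[c]": {"C": 10, "H": 14, "N": 5, "O": 6, "P": 1},
    "lip[c]": {"C": 12, "H": 22, "O": 8},
    "cw[c]": {"C": 11, "H": 20, "N": 1, "O": 10, "P": 1},
    "pig[c]": {"C": 20, "H": 28, "O": 2},
}

_CHARGES = {
    "h[c]": 1,
    "h[l]": 1,
    "pcox[l]": 2,
    "pcred[l]": 1,
    "fdred[c]": -1,
    "nadph[c]": -1,
}

_NAMES = {
    "pi": "orthophosphate",
    "pq": "plastoquinone",
    "pqh2": "plastoquinol",
    "pcox": "plastocyanin (oxidized)",
    "pcred": "plastocyanin (reduced)",
    "fdox": "ferredoxin (oxidized)",
    "fdred": "ferredoxin (reduced)",
    "rubp": "ribulose 1,5-bisphosphate",
    "pga": "3-phosphoglycerate",
    "gap": "glyceraldehyde 3-phosphate",
    "og": "2-oxoglutarate",
    "amp": "AMP (RNA unit)",
    "damp": "dAMP (DNA unit)",
    "lip": "glycolipid unit",
    "cw": "cell wall unit",
    "pig": "pigment unit",
}

_COMPARTMENT_NAMES = {
    "e": "extracellular",
    "c": "cytoplasm",
    "m": "thylakoid membrane",
    "l": "thylakoid lumen",
}


def _lumped_synthesis(product: str, a_glc: float, e_atp: float, r_nadph: float
                      ) -> dict[str, float]:
    """Balanced lumped biosynthesis of *product* from glucose carbon,
    ammonia nitrogen, and orthophosphate, with chosen ATP and NADPH
    costs.  The CO2, water, and proton coefficients are solved from the
    C/O/H balance (negative solutions simply land the species on the
    product side)."""
    fx = _FORMULAS[product]
    c_x, h_x = fx.get("C", 0), fx.get("H", 0)
    n_x, o_x, p_x = fx.get("N", 0), fx.get("O", 0), fx.get("P", 0)
    n_nh3 = float(n_x)
    p_pi = float(p_x)
    q_co2 = c_x - 6.0 * a_glc
    w_h2o = o_x + e_atp - 6.0 * a_glc - 4.0 * p_pi - 2.0 * q_co2
    y_h = (
        h_x + 2.0 * e_atp - 12.0 * a_glc - 3.0 * n_nh3 - 3.0 * p_pi
        - 2.0 * w_h2o - r_nadph
    )
    stoich = {
        "glc[c]": -a_glc,
        "atp[c]": -e_atp,
        "adp[c]": e_atp,
        "pi[c]": e_atp,
        "nadph[c]": -r_nadph,
        "nadp[c]": r_nadph,
        product: 1.0,
        "co2[c]": -q_co2,
        "h2o[c]": -w_h2o,
        "h[c]": -y_h,
    }
    stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
    if n_nh3:
        stoich["nh3[c]"] = -n_nh3
    if p_pi:
        stoich["pi[c]"] = stoich.get("pi[c]", 0.0) - p_pi
    _assert_balanced(stoich)
    return stoich


def _assert_balanced(stoich: dict[str, float]) -> None:
    sums: dict[str, float] = {}
    for met, coeff in stoich.items():
        for e, k in _FORMULAS[met].items():
            sums[e] = sums.get(e, 0.0) + coeff * k
    bad = {e: v for e, v in sums.items() if abs(v) > 1e-9}
    if bad:
        raise ModelError(f"generated reaction is unbalanced: {bad}")


def _reaction(
    rid: str,
    name: str,
    stoich: dict[str, float],
    gpr: str | None,
    subsystem: str,
    lb: float = 0.0,
    ub: float = 1000.0,
    kind: str = "internal",
    check: bool = True,
) -> Reaction:
    if check and kind == "internal":
        _assert_balanced(stoich)
    return Reaction(
        id=rid,
        name=name,
        stoichiometry=dict(stoich),
        lower_bound=lb,
        upper_bound=ub,
        gpr=GeneProteinRule.from_string(gpr) if gpr else None,
        kind=kind,
        subsystem=subsystem,
    )


# gene id -> pangenome class
_GENES = {
    "psbA": "core", "psbD": "core", "petB": "core", "psaA": "core",
    "psaB": "core", "petH": "core", "fqr1": "flexible", "ndhA": "core",
    "cox1": "core", "atpA": "core", "atpB": "core", "rbcL": "core",
    "rbcS": "core", "pgk1": "core", "prk1": "core", "glgA": "flexible",
    "gapA": "core", "gapB": "flexible", "ppc1": "core", "gltA": "core",
    "gdhA": "core", "mdh1": "core", "frd1": "flexible", "zwf1": "core",
    "purA": "core", "nrdA": "core", "lipA": "core", "murA": "core",
    "pigA": "core", "pstS": "core", "adk1": "unknown",
}


def make_toy_photoautotroph(config: ToyConfig | None = None) -> Model:
    """Build the toy photoautotroph model (biomass objective installed).

    The returned model carries a ``toy_composition`` attribute (the
    :class:`BiomassComposition` used to assemble its biomass reaction)
    and a ``toy_config`` attribute.
    """
    config = config or ToyConfig()
    rng = np.random.default_rng(config.seed)
    model = Model(id="toy_photoautotroph")

    for met_id, formula in _FORMULAS.items():
        if met_id == "ssa[c]" and not config.include_2ogdc_ssadh:
            continue
        from .core import base_id, compartment_of

        code = compartment_of(met_id) or "c"
        model.metabolites[met_id] = Metabolite(
            id=met_id,
            name=_NAMES.get(base_id(met_id), base_id(met_id)),
            compartment=_COMPARTMENT_NAMES[code],
            formula=dict(formula),
            charge=_CHARGES.get(met_id, 0),
        )
    # photons are massless
    model.metabolites["photon[e]"].molecular_weight = None

    R = model.reactions

    # --- exchanges ---------------------------------------------------------
    def exchange(rid, met, lb, ub):
        R[rid] = _reaction(
            rid, f"{met} exchange", {met: -1.0}, None, "exchange",
            lb=lb, ub=ub, kind="exchange", check=False,
        )

    exchange("EX_photon", "photon[e]", -config.photon_ub, 0.0)
    exchange("EX_co2", "co2[c]", -config.co2_uptake, 1000.0)
    exchange("EX_o2", "o2[c]", -1000.0, 1000.0)
    exchange("EX_pi", "pi[e]", -config.pi_uptake, 1000.0)
    exchange("EX_nh3", "nh3[c]", -config.nh3_uptake, 1000.0)
    exchange("EX_h2o", "h2o[c]", -1000.0, 1000.0)
    exchange("EX_h", "h[c]", -1000.0, 1000.0)

    # --- transport ---------------------------------------------------------
    R["PIT"] = _reaction(
        "PIT", "phosphate ABC transporter (pst)",
        {"pi[e]": -1, "atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 2},
        "pstS", "transport", kind="transport",
    )
    # --- photosynthetic electron chain -------------------------------------
    R["PSII"] = _reaction(
        "PSII", "photosystem II",
        {
            "h2o[c]": -2, "pq[m]": -2, "photon[e]": -4, "h[c]": -4,
            "o2[c]": 1, "pqh2[m]": 2, "h[l]": 4,
        },
        "psbA and psbD", "photosynthesis",
    )
    R["CYTB6F"] = _reaction(
        "CYTB6F", "cytochrome b6f",
        {"pqh2[m]": -1, "pcox[l]": -2, "pq[m]": 1, "pcred[l]": 2, "h[l]": 2},
        "petB", "photosynthesis",
    )
    R["PSI"] = _reaction(
        "PSI", "photosystem I",
        {"photon[e]": -1, "pcred[l]": -1, "fdox[c]": -1,
         "pcox[l]": 1, "fdred[c]": 1},
        "psaA and psaB", "photosynthesis",
    )
    R["FDR"] = _reaction(
        "FDR", "ferredoxin-NADP+ reductase",
        {"fdred[c]": -2, "nadp[c]": -1, "h[c]": -1, "fdox[c]": 2, "nadph[c]": 1},
        "petH", "photosynthesis",
    )
    R["FQR"] = _reaction(
        "FQR", "ferredoxin:quinone oxidoreductase",
        {"fdred[c]": -2, "pq[m]": -1, "h[c]": -2, "fdox[c]": 2, "pqh2[m]": 1},
        "fqr1", "photosynthesis",
    )
    R["NDH"] = _reaction(
        "NDH", "NADPH dehydrogenase type 1",
        {"nadph[c]": -1, "pq[m]": -1, "h[c]": -3,
         "nadp[c]": 1, "pqh2[m]": 1, "h[l]": 2},
        "ndhA", "photosynthesis",
    )
    R["COX"] = _reaction(
        "COX", "cytochrome oxidase bd",
        {"pqh2[m]": -1, "o2[c]": -0.5, "h[c]": -2,
         "pq[m]": 1, "h2o[c]": 1, "h[l]": 2},
        "cox1", "photosynthesis",
    )
    R["ATPS"] = _reaction(
        "ATPS", "ATP synthase",
        {"adp[c]": -1, "pi[c]": -1, "h[l]": -3,
         "atp[c]": 1, "h2o[c]": 1, "h[c]": 3},
        "atpA and atpB", "photosynthesis",
    )

    # --- Calvin-Benson-Bassham loop ----------------------------------------
    R["RBC"] = _reaction(
        "RBC", "rubisco carboxylation",
        {"rubp[c]": -1, "co2[c]": -1, "h2o[c]": -1, "pga[c]": 2},
        "rbcL and rbcS", "carbon fixation",
    )
    R["PGR"] = _reaction(
        "PGR", "phosphoglycerate reduction",
        {"pga[c]": -1, "atp[c]": -1, "nadph[c]": -1, "h[c]": -1,
         "gap[c]": 1, "adp[c]": 1, "pi[c]": 1, "nadp[c]": 1},
        "pgk1", "carbon fixation",
    )
    R["CBBR"] = _reaction(
        "CBBR", "acceptor regeneration",
        {"gap[c]": -5, "atp[c]": -3, "h2o[c]": -2,
         "rubp[c]": 3, "adp[c]": 3, "pi[c]": 2},
        "prk1", "carbon fixation",
    )

    # --- central carbon ----------------------------------------------------
    R["GLCS"] = _reaction(
        "GLCS", "glucose/glycogen interconversion",
        {"gap[c]": -2, "h2o[c]": -2, "glc[c]": 1, "pi[c]": 2},
        "glgA", "central carbon", lb=-1000.0,
    )
    R["GLYC"] = _reaction(
        "GLYC", "lower glycolysis (GAP to pyruvate)",
        {"gap[c]": -1, "nadp[c]": -1, "adp[c]": -2, "pi[c]": -1,
         "pyr[c]": 1, "nadph[c]": 1, "h[c]": 1, "atp[c]": 2, "h2o[c]": 1},
        "(gapA) or (gapB)", "central carbon",
    )
    R["OPP"] = _reaction(
        "OPP", "oxidative pentose phosphate shunt (lumped)",
        {"glc[c]": -1, "nadp[c]": -12, "h2o[c]": -6,
         "co2[c]": 6, "nadph[c]": 12, "h[c]": 12},
        "zwf1", "central carbon",
    )
    R["SK_glc"] = _reaction(
        "SK_glc", "glycogen storage drawdown",
        {"glc[c]": 1.0}, None, "central carbon",
        lb=0.0, ub=0.0, kind="sink", check=False,
    )

    # --- branched TCA ------------------------------------------------------
    R["OXTCA"] = _reaction(
        "OXTCA", "oxidative TCA branch (lumped to 2-oxoglutarate)",
        {"pyr[c]": -2, "atp[c]": -1, "nadp[c]": -2, "h2o[c]": -2,
         "og[c]": 1, "co2[c]": 1, "adp[c]": 1, "pi[c]": 1,
         "nadph[c]": 2, "h[c]": 2},
        "gltA", "TCA cycle",
    )
    R["REDTCA"] = _reaction(
        "REDTCA", "reductive TCA branch (to fumarate)",
        {"pyr[c]": -1, "co2[c]": -1, "atp[c]": -1, "nadph[c]": -1,
         "h[c]": -1, "fum[c]": 1, "adp[c]": 1, "pi[c]": 1, "nadp[c]": 1},
        "ppc1 and mdh1", "TCA cycle",
    )
    R["GS"] = _reaction(
        "GS", "glutamate synthesis",
        {"og[c]": -1, "nh3[c]": -1, "nadph[c]": -1, "h[c]": -1,
         "glu[c]": 1, "h2o[c]": 1, "nadp[c]": 1},
        "gdhA", "protein synthesis",
    )
    R["FRD"] = _reaction(
        "FRD", "fumarate reductase (soluble)",
        {"fum[c]": -1, "nadph[c]": -1, "h[c]": -1, "succ[c]": 1, "nadp[c]": 1},
        "frd1", "TCA cycle",
    )

    # --- precursor syntheses (lumped, auto-balanced) ------------------------
    R["AMPS"] = _reaction(
        "AMPS", "nucleotide (AMP) synthesis",
        _lumped_synthesis("amp[c]", a_glc=2.0, e_atp=4.0, r_nadph=2.0),
        "purA", "nucleotide synthesis",
    )
    R["ADK"] = _reaction(
        "ADK", "adenylate kinase",
        {"amp[c]": -1, "atp[c]": -1, "adp[c]": 2},
        "adk1", "nucleotide synthesis", lb=-1000.0,
    )
    R["DAMPS"] = _reaction(
        "DAMPS", "deoxynucleotide synthesis",
        {"amp[c]": -1, "nadph[c]": -1, "h[c]": -1,
         "damp[c]": 1, "nadp[c]": 1, "h2o[c]": 1},
        "nrdA", "nucleotide synthesis",
    )
    R["LIPS"] = _reaction(
        "LIPS", "glycolipid synthesis",
        _lumped_synthesis("lip[c]", a_glc=2.0, e_atp=2.0, r_nadph=2.0),
        "lipA", "lipid synthesis",
    )
    R["CWS"] = _reaction(
        "CWS", "cell wall unit synthesis",
        _lumped_synthesis("cw[c]", a_glc=2.0, e_atp=3.0, r_nadph=2.0),
        "murA", "cell wall synthesis",
    )
    R["PIGS"] = _reaction(
        "PIGS", "pigment synthesis",
        _lumped_synthesis("pig[c]", a_glc=4.0, e_atp=2.0, r_nadph=6.0),
        "pigA", "pigment synthesis",
    )

    # --- genes --------------------------------------------------------------
    for gene_id, cls in _GENES.items():
        model.genes[gene_id] = Gene(
            id=gene_id,
            pangenome_class=cls,
            expression_level=float(np.round(rng.lognormal(3.0, 1.0), 3)),
        )

    # --- fillers: balanced isomerization chain off glucose ------------------
    for k in range(config.n_filler_reactions):
        fid = f"fil{k + 1}[c]"
        model.metabolites[fid] = Metabolite(
            id=fid, name=f"filler hexose {k + 1}", compartment="cytoplasm",
            formula={"C": 6, "H": 12, "O": 6},
        )
        prev = "glc[c]" if k == 0 else f"fil{k}[c]"
        # hexose isomerizations are balanced by construction; the
        # in-module assertion only knows the fixed species table
        R[f"FIL{k + 1}"] = _reaction(
            f"FIL{k + 1}", f"filler isomerase {k + 1}",
            {prev: -1, fid: 1}, None, "filler", lb=-1000.0, check=False,
        )

    # --- optional knock-ins at generation time ------------------------------
    if config.include_2ogdc_ssadh or config.include_sdh:
        from .phenotypes import apply_variant, variant_preset

        names = []
        if config.include_2ogdc_ssadh:
            names += ["2OGDC", "SSADH"]
        if config.include_sdh:
            names += ["SDH"]
        model = apply_variant(model, variant_preset(*names))

    # --- biomass ------------------------------------------------------------
    comp = _solve_composition(model, config)
    model = install_bof(model, comp)
    model.toy_composition = comp  # type: ignore[attr-defined]
    model.toy_config = config  # type: ignore[attr-defined]
    model.biomass_table = comp.to_table()  # type: ignore[attr-defined]
    model.validate()
    return model


def _solve_composition(model: Model, config: ToyConfig) -> BiomassComposition:
    """Fix the crude fractions and split the RNA/carbohydrate remainder
    so the molar C/P of the composition equals ``baseline_cp``."""
    fixed = {
        "protein": [("glu[c]", config.protein_mass)],
        "lipid": [("lip[c]", config.lipid_mass)],
        "DNA": [("damp[c]", config.dna_mass)],
        "pigments": [("pig[c]", config.pigment_mass)],
        "cell_wall": [("cw[c]", config.cell_wall_mass)],
        "biopool": [("atp[c]", config.biopool_mass)],
    }
    remainder = 1.0 - sum(m for entries in fixed.values() for _, m in entries)
    if remainder <= 0:
        raise ModelError("fixed crude fractions exceed unit mass")

    def per_gram(met_id, element):
        met = model.metabolites[met_id]
        return 1000.0 / met.molecular_weight * met.formula.get(element, 0)

    base = BiomassComposition(
        dict(fixed, RNA=[("amp[c]", 0.0)], carbohydrate=[("glc[c]", remainder)]),
        config.gam, config.ngam,
    )
    totals = bof_stoichiometry(base, model).element_totals
    c0, p0 = totals["C"], totals["P"]
    dc = per_gram("amp[c]", "C") - per_gram("glc[c]", "C")
    dp = per_gram("amp[c]", "P") - per_gram("glc[c]", "P")
    t = config.baseline_cp
    denom = t * dp - dc
    if abs(denom) < 1e-12:
        raise ModelError("C/P target is unreachable by the RNA/carb split")
    x = (c0 - t * p0) / denom
    if not 0.0 <= x <= remainder:
        raise ModelError(
            f"baseline C/P {t:g} outside the achievable range for this"
            " composition"
        )
    fractions = dict(fixed)
    fractions["RNA"] = [("amp[c]", x)]
    fractions["carbohydrate"] = [("glc[c]", remainder - x)]
    comp = BiomassComposition(fractions, config.gam, config.ngam)
    comp.validate()
    return comp


def default_medium(config: ToyConfig | None = None, name: str = "balanced"
                   ) -> MediumSpec:
    """The balanced photolithoautotrophic medium matching the generator
    defaults (photon-limited; Pi, NH3, CO2 replete)."""
    config = config or ToyConfig()
    return MediumSpec(
        {
            "EX_photon": (-config.photon_ub, 0.0),
            "EX_co2": (-config.co2_uptake, 1000.0),
            "EX_pi": (-config.pi_uptake, 1000.0),
            "EX_nh3": (-config.nh3_uptake, 1000.0),
        },
        name=name,
    )


# ---------------------------------------------------------------------------
# Expression tables with planted signal

def make_expression(
    model: Model,
    planted: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Differential-expression table (gene -> (log2 fold change, p)).

    Null genes draw p ~ Uniform(0, 1]; genes of reactions in a planted
    subsystem draw a one-sided normal test statistic centred at the
    stated effect size (in sigma units), so their p-values concentrate
    near zero.  Fold-change signs follow the sign of the effect.
    """
    from scipy import stats

    planted = planted or {}
    subsystems = {r.subsystem for r in model.reactions.values()}
    unknown = set(planted) - subsystems
    if unknown:
        raise ModelError(f"unknown subsystems {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    effect_by_gene: dict[str, float] = {}
    for rxn in model.reactions.values():
        if rxn.subsystem in planted:
            for g in rxn.genes:
                effect_by_gene[g] = max(
                    effect_by_gene.get(g, 0.0), planted[rxn.subsystem],
                    key=abs,
                )
    table: dict[str, tuple[float, float]] = {}
    for gene_id in model.genes:
        effect = effect_by_gene.get(gene_id, 0.0)
        if effect == 0.0:
            p = float(rng.uniform(np.nextafter(0.0, 1.0), 1.0))
            fc = float(rng.normal(0.0, 0.25))
        else:
            z = rng.normal(abs(effect), 1.0)
            p = float(np.clip(stats.norm.sf(z), 1e-300, 1.0))
            fc = float(np.sign(effect) * abs(rng.normal(effect, 0.25)))
        table[gene_id] = (fc, p)
    return table


# ---------------------------------------------------------------------------
# Light profiles

def make_light_profile(
    kind: str = "parabolic-14-10",
    peak: float = 45.0,
    conversion: float = 0.5,
    resolution: float = 0.1,
) -> LightProfile:
    """Named 24-h light profiles.

    * ``parabolic-14-10``: parabola over a 14-h photoperiod, dark 10 h;
    * ``ramp-hold-ramp``: linear rise (10 h), 4-h plateau, linear fall;
    * ``constant``: flat irradiance around the clock.
    """
    if peak < 0:
        raise ModelError("peak irradiance must be non-negative")
    t = np.arange(0.0, 24.0 + resolution / 2, resolution)
    if kind == "constant":
        irr = np.full_like(t, float(peak))
    elif kind == "parabolic-14-10":
        irr = np.where(
            t <= 14.0, peak * (1.0 - ((t - 7.0) / 7.0) ** 2), 0.0
        )
        irr = np.clip(irr, 0.0, None)
    elif kind == "ramp-hold-ramp":
        irr = np.interp(t, [0.0, 10.0, 14.0, 24.0], [0.0, peak, peak, 0.0])
    else:
        raise ModelError(f"unknown light profile kind {kind!r}")
    return LightProfile(times=t, irradiance=irr, conversion=conversion, kind=kind)
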