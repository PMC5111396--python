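"""Readers and writers for the tabular model dialect (and SBML import).

The canonical archive is either a directory of TSV files or an Excel
workbook with four sheets:

* ``REACTIONS``: id, name, equation, lb, ub, gpr, subsystem, kind
* ``METABOLITES``: id, name, compartment, formula, charge, mw
* ``GENES``: id, pangenome_class, expression
* ``BIOMASS``: crude_fraction, compound_id, mass_fraction

Reaction equations use bracketed compartment tags and arrows:
``2 h2o[c] + 2 pq[m] <=> o2[c] + 2 pqh2[m]`` (``<=>`` reversible,
``=>`` irreversible).  Writing then reading an archive is the identity
on the model.

SBML Level 3 (with the fbc package for bounds and GPRs) is read on a
best-effort basis when libsbml is importable; notes fields are mapped to
subsystem/pangenome class where present.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import pandas as pd

from .core import (
    Gene,
    GeneProteinRule,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    format_formula,
    parse_formula,
)

__all__ = [
    "parse_equation",
    "format_equation",
    "load_model",
    "write_model",
    "read_medium",
    "write_medium",
    "read_expression",
    "write_expression",
]

_ARROW_RE = re.compile(r"<=>|=>")
_SHEETS = ("REACTIONS", "METABOLITES", "GENES", "BIOMASS")
_INF = 1e6  # bound magnitude treated as unbounded in text form


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``a A[c] + b B[p] <=> c C[c]`` into (stoichiometry, reversible).

    A missing right- or left-hand side (e.g. ``pi[e] =>`` for an
    exchange) is allowed.
    """
    match = _ARROW_RE.search(text)
    if not match:
        raise ModelError(f"no arrow in equation {text!r}")
    reversible = match.group(0) == "<=>"
    lhs, rhs = text[: match.start()], text[match.end() :]
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and re.fullmatch(
                r"[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?", parts[0]
            ):
                coeff, met = float(parts[0]), parts[1].strip()
            else:
                coeff, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelError(f"empty equation {text!r}")
    return stoich, reversible


def _coeff_str(c: float) -> str:
    return repr(c) if c != int(c) else f"{c:g}"


def format_equation(stoichiometry: dict[str, float], reversible: bool) -> str:
    lhs = [
        (f"{_coeff_str(-c)} {m}" if -c != 1 else m)
        for m, c in stoichiometry.items()
        if c < 0
    ]
    rhs = [
        (f"{_coeff_str(c)} {m}" if c != 1 else m)
        for m, c in stoichiometry.items()
        if c > 0
    ]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# Tabular archive

def _read_tables(path: Path) -> dict[str, pd.DataFrame]:
    if path.is_dir():
        tables = {}
        for sheet in _SHEETS:
            f = path / f"{sheet}.tsv"
            if sheet in ("REACTIONS", "METABOLITES") and not f.exists():
                raise ModelError(f"missing sheet {sheet} in {path}")
            tables[sheet] = (
                pd.read_csv(f, sep="\t", dtype=str, keep_default_na=False)
                if f.exists()
                else pd.DataFrame()
            )
        return tables
    if path.suffix in {".xlsx", ".xls"}:
        book = pd.read_excel(path, sheet_name=None, dtype=str)
        return {
            sheet: book.get(sheet, pd.DataFrame()).fillna("") for sheet in _SHEETS
        }
    raise ModelError(f"unrecognized model archive {path}")


def _to_float(text: str, default: float) -> float:
    text = str(text).strip()
    if not text or text in {"-", "nan"}:
        return default
    value = float(text)
    if value >= _INF:
        return math.inf
    if value <= -_INF:
        return -math.inf
    return value


def load_model(path: str | Path, dialect: str = "tabular") -> Model:
    """Load a model archive.

    ``dialect`` is ``tabular`` (TSV directory or Excel workbook) or
    ``sbml``.
    """
    path = Path(path)
    if dialect == "sbml":
        return _load_sbml(path)
    if dialect != "tabular":
        raise ModelError(f"unknown dialect {dialect!r}")
    tables = _read_tables(path)
    model = Model(id=path.stem if path.suffix else path.name)

    mets = tables["METABOLITES"]
    for row in mets.itertuples(index=False):
        met = Metabolite(
            id=str(row.id),
            name=str(getattr(row, "name", "") or ""),
            compartment=str(getattr(row, "compartment", "cytoplasm")),
            formula=parse_formula(str(getattr(row, "formula", ""))),
            charge=int(_to_float(getattr(row, "charge", "0"), 0.0)),
            molecular_weight=_to_float(getattr(row, "mw", ""), 0.0) or None,
        )
        if met.id in model.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        model.metabolites[met.id] = met

    rxns = tables["REACTIONS"]
    if rxns.empty:
        raise ModelError("no reactions")
    for i, row in enumerate(rxns.itertuples(index=False)):
        try:
            stoich, reversible = parse_equation(str(row.equation))
            lb = _to_float(getattr(row, "lb", ""), -math.inf if reversible else 0.0)
            ub = _to_float(getattr(row, "ub", ""), math.inf)
            rxn = Reaction(
                id=str(row.id),
                name=str(getattr(row, "name", "") or ""),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=GeneProteinRule.from_string(str(getattr(row, "gpr", ""))),
                kind=str(getattr(row, "kind", "internal") or "internal"),
                subsystem=str(getattr(row, "subsystem", "") or ""),
                pseudo=str(getattr(row, "pseudo", "")).strip().lower()
                in {"1", "true", "yes"},
            )
        except ModelError as exc:
            raise ModelError(f"REACTIONS row {i + 2}: {exc}") from None
        if rxn.id in model.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        model.reactions[rxn.id] = rxn

    genes = tables["GENES"]
    if not genes.empty:
        for row in genes.itertuples(index=False):
            gene = Gene(
                id=str(row.id),
                pangenome_class=str(getattr(row, "pangenome_class", "core") or "core"),
                expression_level=(
                    None
                    if str(getattr(row, "expression", "")).strip() in {"", "-"}
                    else float(row.expression)
                ),
            )
            if gene.id in model.genes:
                raise ModelError(f"duplicate gene id {gene.id!r}")
            model.genes[gene.id] = gene

    bof = tables["BIOMASS"]
    if not bof.empty:
        model.biomass_table = [  # type: ignore[attr-defined]
            (str(r.crude_fraction), str(r.compound_id), float(r.mass_fraction))
            for r in bof.itertuples(index=False)
        ]
        for _, compound, _ in model.biomass_table:  # type: ignore[attr-defined]
            if compound not in model.metabolites:
                raise ModelError(f"BIOMASS references unknown compound {compound!r}")

    meta_path = path / "MODEL.tsv" if path.is_dir() else None
    if meta_path is not None and meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
        if not meta.empty:
            row = meta.iloc[0]
            model.id = str(row.get("id", model.id)) or model.id
            model.objective_id = str(row.get("objective", "")) or ""
    for rxn in model.reactions.values():
        if rxn.pseudo and not model.objective_id:
            model.objective_id = rxn.id
    if not model.objective_id:
        for rid in model.reactions:
            if "biomass" in rid.lower() or rid.upper().startswith("BOF"):
                model.objective_id = rid
                break
    model.validate()
    return model


def write_model(model: Model, path: str | Path) -> Path:
    """Write a model as a TSV directory archive (the canonical dialect)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def bound_str(b: float) -> str:
        if math.isinf(b):
            return str(_INF if b > 0 else -_INF)
        return repr(b) if b != int(b) else f"{b:g}"

    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lb": bound_str(r.lower_bound),
                "ub": bound_str(r.upper_bound),
                "gpr": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "kind": r.kind,
                "pseudo": "true" if r.pseudo else "",
            }
            for r in model.reactions.values()
        ]
    ).to_csv(path / "REACTIONS.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula),
                "charge": m.charge,
                "mw": repr(m.molecular_weight) if m.molecular_weight else "",
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(path / "METABOLITES.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "id": g.id,
                "pangenome_class": g.pangenome_class,
                "expression": (
                    repr(g.expression_level) if g.expression_level is not None else ""
                ),
            }
            for g in model.genes.values()
        ]
    ).to_csv(path / "GENES.tsv", sep="\t", index=False)

    biomass_rows = [
        {"crude_fraction": f, "compound_id": c, "mass_fraction": repr(x)}
        for f, c, x in getattr(model, "biomass_table", [])
    ]
    pd.DataFrame(
        biomass_rows, columns=["crude_fraction", "compound_id", "mass_fraction"]
    ).to_csv(path / "BIOMASS.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"id": model.id, "objective": model.objective_id}]
    ).to_csv(path / "MODEL.tsv", sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# SBML (best effort)

def _load_sbml(path: Path) -> Model:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ModelError("libsbml not available for SBML import") from exc
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelError(f"SBML parse error in {path}")
    sb = doc.getModel()
    model = Model(id=sb.getId() or path.stem)

    def unprefix(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid
    comp_names = {
        c.getId(): c.getName() or c.getId() for c in sb.getListOfCompartments()
    }
    for sp in sb.getListOfSpecies():
        fbc_sp = sp.getPlugin("fbc")
        formula = ""
        charge = 0
        if fbc_sp is not None:
            formula = fbc_sp.getChemicalFormula() or ""
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        sid = unprefix(sp.getId(), "M_")
        model.metabolites[sid] = Metabolite(
            id=sid,
            name=sp.getName() or sid,
            compartment=comp_names.get(sp.getCompartment(), sp.getCompartment()),
            formula=parse_formula(formula),
            charge=charge,
        )
    fbc = sb.getPlugin("fbc")
    params = {
        p.getId(): p.getValue() for p in sb.getListOfParameters()
    }
    for rx in sb.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            ref = rx.getReactant(i)
            key = unprefix(ref.getSpecies(), "M_")
            stoich[key] = stoich.get(key, 0.0) - (ref.getStoichiometry() or 1.0)
        for i in range(rx.getNumProducts()):
            ref = rx.getProduct(i)
            key = unprefix(ref.getSpecies(), "M_")
            stoich[key] = stoich.get(key, 0.0) + (ref.getStoichiometry() or 1.0)
        fbc_rx = rx.getPlugin("fbc")
        lb, ub = (-math.inf, math.inf)
        gpr = None
        if fbc_rx is not None:
            lb = params.get(fbc_rx.getLowerFluxBound(), -math.inf)
            ub = params.get(fbc_rx.getUpperFluxBound(), math.inf)
            assoc = fbc_rx.getGeneProductAssociation()
            if assoc is not None:
                complexes = _fbc_association_complexes(
                    assoc.getAssociation(), libsbml
                )
                complexes = [
                    frozenset(unprefix(g, "G_") for g in cx) for cx in complexes
                ]
                if complexes:
                    gpr = GeneProteinRule(tuple(complexes))
        elif not rx.getReversible():
            lb = 0.0
        kind = "exchange" if len(stoich) == 1 else "internal"
        rid = unprefix(rx.getId(), "R_")
        model.reactions[rid] = Reaction(
            id=rid,
            name=rx.getName() or rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            kind=kind,
        )
    if fbc is not None:
        for gp in fbc.getListOfGeneProducts():
            gid = unprefix(gp.getId(), "G_")
            model.genes[gid] = Gene(id=gid)
        objs = fbc.getListOfObjectives()
        if objs is not None and objs.size():
            obj = objs.get(0)
            if obj.getNumFluxObjectives():
                model.objective_id = unprefix(
                    obj.getFluxObjective(0).getReaction(), "R_"
                )
    # register genes referenced only via GPR strings
    for rxn in model.reactions.values():
        for g in rxn.genes:
            model.genes.setdefault(g, Gene(id=g))
    model.validate()
    return model


def _fbc_association_complexes(assoc, libsbml) -> list[frozenset[str]]:
    """Flatten an fbc gene-product association into disjunctive normal
    form: a list of complexes (gene-id conjunctions)."""
    if assoc is None:
        return []
    if isinstance(assoc, libsbml.GeneProductRef):
        return [frozenset({assoc.getGeneProduct()})]
    children = [
        _fbc_association_complexes(assoc.getAssociation(i), libsbml)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcOr):
        return [c for child in children for c in child]
    if isinstance(assoc, libsbml.FbcAnd):
        combos = [frozenset()]
        for child in children:
            combos = [a | b for a in combos for b in child]
        return combos
    return []


# ---------------------------------------------------------------------------
# Auxiliary tables

def read_medium(path: str | Path) -> dict[str, tuple[float, float]]:
    """Medium TSV with columns exchange_id, lb, ub."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        str(r.exchange_id): (_to_float(r.lb, -math.inf), _to_float(r.ub, math.inf))
        for r in df.itertuples(index=False)
    }


def write_medium(bounds: dict[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [{"exchange_id": k, "lb": lb, "ub": ub} for k, (lb, ub) in bounds.items()]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> dict[str, tuple[float, float]]:
    """Expression TSV with columns gene_id, log2fc, pvalue."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.gene_id): (float(r.log2fc), float(r.pvalue))
        for r in df.itertuples(index=False)
    }


def write_expression(table: dict[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g, "log2fc": fc, "pvalue": p}
            for g, (fc, p) in table.items()
        ]
    ).to_csv(path, sep="\t", index=False)
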