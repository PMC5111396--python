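"""Data model for compartmentalized genome-scale metabolic networks.

The central objects are :class:`Metabolite`, :class:`Reaction`,
:class:`Gene`, and :class:`Model`.  A model is the in-memory form of a
stoichiometric network: metabolite rows, reaction columns, flux bounds,
gene-protein-reaction (GPR) rules, and molecular formulas from which the
elemental (atom-count) matrix is derived.

Conventions
-----------
* Metabolite ids carry a compartment tag in square brackets
  (``pi[c]``, ``h[l]``); :func:`base_id` strips the tag so that the same
  chemical species in different compartments can be merged.
* Reversibility is encoded solely in the bounds: a reaction is
  reversible iff its lower bound is negative.  There is no independent
  boolean field.
* Reaction ``kind`` is one of ``internal``, ``transport``, ``exchange``
  or ``sink``.  Exchange reactions touch exactly one metabolite; sinks
  are bookkeeping reactions (e.g. storage drawdown) excluded from
  balance checks, as are pseudo-reactions such as the biomass objective.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ELEMENTS",
    "ATOMIC_WEIGHTS",
    "COMPARTMENTS",
    "parse_formula",
    "format_formula",
    "formula_weight",
    "base_id",
    "compartment_of",
    "Metabolite",
    "Gene",
    "GeneProteinRule",
    "Reaction",
    "Model",
    "ModelError",
    "BalanceEntry",
    "BalanceReport",
    "ClassificationReport",
    "build_matrices",
    "validate_balance",
    "classify_reactions",
]

#: Elements always present as rows of the elemental matrix, in order.
ELEMENTS = ("H", "C", "N", "O", "P", "S")

ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Mg": 24.305,
    "Fe": 55.845,
    "Cu": 63.546,
    "K": 39.098,
    "Na": 22.990,
    "Ca": 40.078,
    "Cl": 35.45,
    "Zn": 65.38,
    "Mn": 54.938,
}

#: Compartment code -> full name.  The codes appear in metabolite ids.
COMPARTMENTS = {
    "e": "extracellular",
    "p": "periplasm",
    "im": "cytoplasmic membrane",
    "c": "cytoplasm",
    "m": "thylakoid membrane",
    "l": "thylakoid lumen",
    "x": "carboxysome",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_TAG_RE = re.compile(r"^(.*)\[([a-z]{1,2})\]$")


class ModelError(ValueError):
    """Raised for structurally invalid models or unresolvable references."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula (``C6H12O6``) into an
    element -> atom-count map.  Empty or ``'-'`` formulas yield ``{}``."""
    if not text or text.strip() in {"-", "none", "None", "nan"}:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(text.strip()):
        if match.start() != pos:
            raise ModelError(f"cannot parse formula {text!r}")
        element, digits = match.groups()
        n = int(digits) if digits else 1
        if n < 0:
            raise ModelError(f"negative atom count in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(text.strip()):
        raise ModelError(f"cannot parse formula {text!r}")
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    """Render an atom-count map in Hill order (C, H, then alphabetical)."""
    if not formula:
        return ""
    keys = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{e}{formula[e] if formula[e] != 1 else ''}" for e in keys if formula[e]
    )


def formula_weight(formula: Mapping[str, int]) -> float:
    """Molecular weight in g/mol from an atom-count map."""
    try:
        return sum(ATOMIC_WEIGHTS[e] * n for e, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ModelError(f"no atomic weight for element {exc}") from None


def base_id(metabolite_id: str) -> str:
    """Strip the compartment tag: ``pi[c]`` -> ``pi``."""
    match = _TAG_RE.match(metabolite_id)
    return match.group(1) if match else metabolite_id


def compartment_of(metabolite_id: str) -> str | None:
    """Compartment code from the id tag, or None if untagged."""
    match = _TAG_RE.match(metabolite_id)
    return match.group(2) if match else None


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    formula: dict[str, int] = field(default_factory=dict)
    charge: int = 0
    molecular_weight: float | None = None

    def __post_init__(self) -> None:
        if any(n < 0 or int(n) != n for n in self.formula.values()):
            raise ModelError(f"{self.id}: atom counts must be non-negative integers")
        if self.molecular_weight is None and self.formula:
            self.molecular_weight = formula_weight(self.formula)
        if self.formula and not self.molecular_weight:
            raise ModelError(f"{self.id}: molecular weight must be positive")


@dataclass
class Gene:
    id: str
    pangenome_class: str = "core"  # core | flexible | unknown
    expression_level: float | None = None

    def __post_init__(self) -> None:
        if self.pangenome_class not in {"core", "flexible", "unknown"}:
            raise ModelError(
                f"{self.id}: pangenome_class {self.pangenome_class!r} invalid"
            )
        if self.expression_level is not None and self.expression_level < 0:
            raise ModelError(f"{self.id}: expression level must be non-negative")


@dataclass(frozen=True)
class GeneProteinRule:
    """Disjunction of enzyme complexes (conjunctions of gene ids).

    A reaction proceeds iff at least one complex has every one of its
    genes present.  This is the complex-complete rule used for in silico
    knockouts.
    """

    complexes: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.complexes):
            raise ModelError("GPR contains an empty complex")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return frozenset(out)

    def is_active(self, present: Iterable[str]) -> bool:
        present = set(present)
        return any(c <= present for c in self.complexes)

    def disabled_by(self, knocked_out: Iterable[str]) -> bool:
        """True if removing *knocked_out* genes kills every complex."""
        ko = set(knocked_out)
        return all(c & ko for c in self.complexes)

    @classmethod
    def from_string(cls, text: str) -> "GeneProteinRule | None":
        """Parse ``(g1 and g2) or g3`` style rules (one level of nesting)."""
        text = text.strip()
        if not text or text in {"-", "none"}:
            return None
        complexes = []
        for clause in re.split(r"\s+or\s+", text):
            clause = clause.strip()
            if clause.startswith("(") and clause.endswith(")"):
                clause = clause[1:-1]
            genes = frozenset(g.strip() for g in re.split(r"\s+and\s+", clause))
            if any(not g or "(" in g or ")" in g for g in genes):
                raise ModelError(f"cannot parse GPR {text!r}")
            complexes.append(genes)
        return cls(tuple(complexes))

    def to_string(self) -> str:
        parts = []
        for c in self.complexes:
            genes = sorted(c)
            parts.append(f"({' and '.join(genes)})" if len(genes) > 1 else genes[0])
        return " or ".join(parts)


REACTION_KINDS = ("internal", "transport", "exchange", "sink")


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GeneProteinRule | None = None
    kind: str = "internal"
    subsystem: str = ""
    pseudo: bool = False  # biomass/maintenance pseudo-reactions

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"{self.id}: unknown reaction kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelError(f"{self.id}: lower bound exceeds upper bound")
        if self.kind == "exchange" and len(self.stoichiometry) != 1:
            raise ModelError(f"{self.id}: exchange must touch exactly one metabolite")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr else frozenset()


@dataclass
class Model:
    """A genome-scale metabolic model: m metabolites x n reactions."""

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    objective_id: str = ""

    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def compartments(self) -> set[str]:
        return {met.compartment for met in self.metabolites.values()}

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Check cross-references and structural invariants; raise ModelError."""
        if not self.reactions:
            raise ModelError("no reactions")
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id}: unresolved metabolite {met_id!r}"
                    )
            for gene_id in rxn.genes:
                if gene_id not in self.genes:
                    raise ModelError(f"reaction {rxn.id}: unresolved gene {gene_id!r}")
        if self.objective_id and self.objective_id not in self.reactions:
            raise ModelError(f"objective {self.objective_id!r} not in model")

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def reactions_of(self, metabolite_id: str) -> list[Reaction]:
        return [
            r for r in self.reactions.values() if metabolite_id in r.stoichiometry
        ]


# ---------------------------------------------------------------------------
# Matrices

def build_matrices(model: Model) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Return ``(S, A, met_ids, rxn_ids)``.

    ``S`` is the m x n stoichiometric matrix (signed coefficients);
    ``A`` is the element x metabolite atom matrix over :data:`ELEMENTS`
    plus any extra elements found in formulas (rows ordered: the six
    CHNOPS rows first, extras alphabetically after).
    """
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[met_id], j] = coeff
    extras = sorted(
        {
            e
            for met in model.metabolites.values()
            for e in met.formula
            if e not in ELEMENTS
        }
    )
    elements = list(ELEMENTS) + extras
    A = np.zeros((len(elements), len(met_ids)))
    for i, met_id in enumerate(met_ids):
        for e, n in model.metabolites[met_id].formula.items():
            A[elements.index(e), i] = n
    return S, A, met_ids, rxn_ids


def element_rows(model: Model) -> list[str]:
    """Row labels matching the ``A`` matrix of :func:`build_matrices`."""
    extras = sorted(
        {
            e
            for met in model.metabolites.values()
            for e in met.formula
            if e not in ELEMENTS
        }
    )
    return list(ELEMENTS) + extras


# ---------------------------------------------------------------------------
# Balance checking

@dataclass(frozen=True)
class BalanceEntry:
    reaction_id: str
    element: str  # element symbol, or "charge"
    imbalance: float


@dataclass
class BalanceReport:
    element_imbalances: list[BalanceEntry]
    charge_imbalances: list[BalanceEntry]
    warnings: list[str]

    @property
    def balanced(self) -> bool:
        return not self.element_imbalances


def validate_balance(model: Model, tol: float = 1e-6) -> BalanceReport:
    """Per-element and charge balance of every internal/transport reaction.

    Exchanges, sinks, and pseudo-reactions (biomass, maintenance) are
    excluded.  Missing formulas produce warnings, never failures; charge
    imbalances are reported separately and are advisory.
    """
    element_entries: list[BalanceEntry] = []
    charge_entries: list[BalanceEntry] = []
    warnings: list[str] = []
    for rxn in model.reactions.values():
        if rxn.kind in {"exchange", "sink"} or rxn.pseudo:
            continue
        sums: dict[str, float] = {}
        charge = 0.0
        missing = False
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if not met.formula:
                # photons and similar massless species legitimately have
                # an empty formula; only warn for compounds that should
                # carry mass (nonzero MW declared).
                if met.molecular_weight:
                    warnings.append(
                        f"{rxn.id}: metabolite {met_id} has no formula"
                    )
                    missing = True
                continue
            for e, n in met.formula.items():
                sums[e] = sums.get(e, 0.0) + coeff * n
            charge += coeff * met.charge
        if missing:
            continue
        for e, total in sorted(sums.items()):
            if abs(total) > tol:
                element_entries.append(BalanceEntry(rxn.id, e, total))
        if abs(charge) > tol:
            charge_entries.append(BalanceEntry(rxn.id, "charge", charge))
    return BalanceReport(element_entries, charge_entries, warnings)


# ---------------------------------------------------------------------------
# Classification

@dataclass
class ClassificationReport:
    counts_by_kind: dict[str, int]
    blocked: set[str]
    orphaned: set[str]
    gap_filled: set[str]
    reversible: set[str]
    dead_end_metabolites: set[str]


def classify_reactions(model: Model) -> ClassificationReport:
    """Count reactions by kind and flag blocked/orphaned/gap-filled ones.

    * blocked: reactions containing a dead-end metabolite (one that no
      reaction can produce, or none can consume, taking reversibility
      into account);
    * orphaned: reactions sharing no metabolite with any other reaction;
    * gap_filled: internal reactions with no gene association.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            if (coeff > 0 and rxn.upper_bound > 0) or (
                coeff < 0 and rxn.lower_bound < 0
            ):
                producible.add(met_id)
            if (coeff < 0 and rxn.upper_bound > 0) or (
                coeff > 0 and rxn.lower_bound < 0
            ):
                consumable.add(met_id)
    dead_ends = {
        m for m in model.metabolites if m not in producible or m not in consumable
    }
    blocked = {
        r.id
        for r in model.reactions.values()
        if any(m in dead_ends for m in r.stoichiometry)
    }
    orphaned = set()
    for rxn in model.reactions.values():
        shared = False
        for met_id in rxn.stoichiometry:
            for other in model.reactions_of(met_id):
                if other.id != rxn.id:
                    shared = True
                    break
            if shared:
                break
        if not shared:
            orphaned.add(rxn.id)
    gap_filled = {
        r.id
        for r in model.reactions.values()
        if r.kind == "internal" and r.gpr is None and not r.pseudo
    }
    counts: dict[str, int] = {k: 0 for k in REACTION_KINDS}
    for rxn in model.reactions.values():
        counts[rxn.kind] += 1
    reversible = {r.id for r in model.reactions.values() if r.reversible}
    return ClassificationReport(
        counts_by_kind=counts,
        blocked=blocked,
        orphaned=orphaned,
        gap_filled=gap_filled,
        reversible=reversible,
        dead_end_metabolites=dead_ends,
    )
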