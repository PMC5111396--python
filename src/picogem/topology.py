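"""Topology analytics on the stoichiometric matrix.

Two views of network structure are provided: the metabolite
participation spectrum (a degree distribution normalized to the number
of internal reactions, so that networks of different size are
comparable) and the singular value decomposition ``S = U Sigma V^T``,
whose singular vector pairs ("systems reactions" or modes) are linearly
dependent sets of reactions weighted by their singular values.  The
fractional weight ``sigma_k / sum(sigma)`` of the mode dominated by a
compound measures how central that compound's transformations are to
the network as a whole.

Compartment-duplicated species (e.g. periplasmic and cytoplasmic
orthophosphate) are merged to their parent compound before counting or
mode attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Model, ModelError, base_id

__all__ = [
    "ParticipationSpectrum",
    "SvdSpectrum",
    "participation",
    "svd_modes",
    "transformation_mode",
]

#: Currency species excluded from participation by default (merged ids).
DEFAULT_EXCLUDE = frozenset({"h2o", "h"})


@dataclass
class ParticipationSpectrum:
    values: dict[str, float]  # merged compound -> fraction of internal reactions
    n_internal: int

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: (-kv[1], kv[0]))


def participation(
    model: Model,
    exclude: frozenset[str] | set[str] | None = DEFAULT_EXCLUDE,
) -> ParticipationSpectrum:
    """Fraction of internal reactions each (compartment-merged) compound
    participates in.

    Exchange, transport, and sink reactions are excluded from both the
    counts and the denominator, as are pseudo-reactions; transporters
    would otherwise inflate the degree of every medium compound.
    """
    exclude = frozenset(exclude or ())
    internal = [
        r
        for r in model.reactions.values()
        if r.kind == "internal" and not r.pseudo
    ]
    n = len(internal)
    counts: dict[str, int] = {}
    for rxn in internal:
        compounds = {base_id(m) for m in rxn.stoichiometry}
        for compound in compounds:
            counts[compound] = counts.get(compound, 0) + 1
    values = {
        c: (k / n if n else 0.0) for c, k in counts.items() if c not in exclude
    }
    # compounds appearing only outside internal reactions participate at 0
    for met_id in model.metabolites:
        c = base_id(met_id)
        if c not in values and c not in exclude:
            values[c] = 0.0
    return ParticipationSpectrum(values=values, n_internal=n)


@dataclass
class SvdSpectrum:
    singular_values: np.ndarray  # length r, descending
    U: np.ndarray  # m x r
    V: np.ndarray  # n x r
    met_ids: list[str]
    rxn_ids: list[str]

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    @property
    def fractional_weights(self) -> np.ndarray:
        return self.singular_values / self.singular_values.sum()

    def merged_loadings(self, k: int) -> dict[str, float]:
        """Root-sum-square |U| loadings of mode k per merged compound."""
        out: dict[str, float] = {}
        for i, met_id in enumerate(self.met_ids):
            c = base_id(met_id)
            out[c] = out.get(c, 0.0) + float(self.U[i, k]) ** 2
        return {c: v**0.5 for c, v in out.items()}

    def top_metabolites(self, k: int, n: int = 10) -> list[tuple[str, float]]:
        loadings = self.merged_loadings(k)
        return sorted(loadings.items(), key=lambda kv: -kv[1])[:n]


def svd_modes(
    model: Model,
    include_transport: bool = True,
    rank_tol: float = 1e-10,
) -> SvdSpectrum:
    """Full SVD of S restricted to internal (and by default transport)
    reaction columns; exchange and sink columns are removed.

    The rank is cut at singular values below ``rank_tol * sigma_1``.
    """
    from .core import build_matrices

    S, _, met_ids, rxn_ids = build_matrices(model)
    keep_kinds = {"internal"} | ({"transport"} if include_transport else set())
    cols = [
        j
        for j, rid in enumerate(rxn_ids)
        if model.reactions[rid].kind in keep_kinds
        and not model.reactions[rid].pseudo
    ]
    if not cols:
        raise ModelError("no reaction columns selected for SVD")
    Ssub = S[:, cols]
    U, sigma, Vt = np.linalg.svd(Ssub, full_matrices=False)
    r = int(np.sum(sigma > rank_tol * sigma[0])) if sigma.size else 0
    return SvdSpectrum(
        singular_values=sigma[:r],
        U=U[:, :r],
        V=Vt[:r].T,
        met_ids=met_ids,
        rxn_ids=[rxn_ids[j] for j in cols],
    )


def transformation_mode(
    spectrum: SvdSpectrum,
    metabolite: str,
    top: int = 5,
) -> tuple[int, float]:
    """Mode attributed to a compound's transformations.

    Returns ``(k, weight_percent)`` where *k* (1-based) is the smallest
    mode index at which the compartment-merged compound ranks among the
    ``top`` metabolites by |U| loading, and the weight is the fractional
    singular value of that mode in percent.  Raises if the compound
    never reaches the dominance threshold.
    """
    compound = base_id(metabolite)
    if compound not in {base_id(m) for m in spectrum.met_ids}:
        raise ModelError(f"metabolite {metabolite!r} not in spectrum")
    weights = spectrum.fractional_weights
    for k in range(spectrum.rank):
        leaders = [c for c, _ in spectrum.top_metabolites(k, n=top)]
        if compound in leaders:
            return k + 1, float(weights[k] * 100.0)
    raise ModelError(
        f"{compound!r} does not dominate any mode at top-{top} threshold"
    )
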