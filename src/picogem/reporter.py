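"""Reporter metabolites and reporter subnetworks.

Transcriptional responses are mapped onto the metabolic network through
GPR associations: each scored gene receives ``Z = Phi^-1(1 - p)`` from
its differential-expression p-value, each metabolite aggregates the Z
scores of the genes of its neighboring reactions as
``(1/sqrt(k)) * sum(Z)``, and the aggregate is corrected against a
background distribution estimated by randomly sampling k-gene sets.  A
high corrected Z marks a metabolite around which expression changes
coordinate.  Subnetworks extend the idea to connected metabolite sets
grown greedily from the top reporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Model, ModelError, base_id

__all__ = [
    "gene_z",
    "ReporterScores",
    "Subnetwork",
    "reporter_metabolites",
    "reporter_subnetworks",
    "compare_shadow",
    "ShadowComparison",
]

_P_FLOOR = 1e-15


def gene_z(expression: dict[str, tuple[float, float]],
           signed: bool = False) -> dict[str, float]:
    """Per-gene Z scores from p-values: ``Z = Phi^-1(1 - p)``.

    p-values are clamped to ``[1e-15, 1 - 1e-15]``.  With
    ``signed=True`` the Z score carries the fold-change sign (the
    one-tailed direction-blind form is the default).
    """
    out: dict[str, float] = {}
    for gene, (fc, p) in expression.items():
        if not 0.0 < p <= 1.0:
            raise ModelError(f"gene {gene}: p-value {p} outside (0, 1]")
        p = min(max(p, _P_FLOOR), 1.0 - _P_FLOOR)
        z = float(stats.norm.isf(p))
        if signed and fc < 0:
            z = -z
        out[gene] = z
    return out


def metabolite_gene_map(
    model: Model, scored_genes: set[str] | None = None
) -> dict[str, frozenset[str]]:
    """Metabolite -> genes of the reactions touching it (GPR neighbors).

    Genes absent from ``scored_genes`` (e.g. not measured) are dropped
    rather than imputed.
    """
    out: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        if not rxn.genes:
            continue
        genes = set(rxn.genes)
        if scored_genes is not None:
            genes &= scored_genes
        if not genes:
            continue
        for met_id in rxn.stoichiometry:
            out.setdefault(met_id, set()).update(genes)
    return {m: frozenset(g) for m, g in out.items()}


@dataclass
class Subnetwork:
    metabolites: frozenset[str]
    genes: frozenset[str]
    corrected_z: float


@dataclass
class ReporterScores:
    metabolite_z: dict[str, float]  # corrected Z per metabolite
    neighbor_counts: dict[str, int]  # k genes per metabolite
    unmatched_genes: int
    subnetworks: list[Subnetwork] = field(default_factory=list)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.metabolite_z.items(), key=lambda kv: -kv[1])


def _background(
    z_values: np.ndarray, sizes: set[int], n_background: int, rng
) -> dict[int, tuple[float, float]]:
    """Mean/SD of the raw aggregate for random k-gene samples."""
    out: dict[int, tuple[float, float]] = {}
    n_genes = len(z_values)
    for k in sorted(sizes):
        if k >= n_genes:
            samples = np.full(n_background, z_values.sum() / np.sqrt(n_genes))
        else:
            # k-subsets without replacement, vectorized over draws
            keys = rng.random((n_background, n_genes))
            idx = np.argpartition(keys, k, axis=1)[:, :k]
            samples = z_values[idx].sum(axis=1) / np.sqrt(k)
        sd = float(samples.std())
        out[k] = (float(samples.mean()), sd if sd > 1e-12 else 1.0)
    return out


def reporter_metabolites(
    model: Model,
    gene_scores: dict[str, float],
    n_background: int = 10_000,
    seed: int = 0,
) -> ReporterScores:
    """Background-corrected reporter Z score per metabolite.

    The raw score of a metabolite with k neighboring scored genes is
    ``sum(Z)/sqrt(k)``; the corrected score subtracts the mean and
    divides by the SD of that statistic over ``n_background`` random
    k-gene draws from all scored genes (seeded, deterministic).
    Metabolites with k = 0 are excluded.
    """
    scored = {g for g in gene_scores if g in model.genes}
    unmatched = len(gene_scores) - len(scored)
    if not scored:
        raise ModelError("no expression genes match the model")
    neighbor = metabolite_gene_map(model, scored)
    z_all = np.array([gene_scores[g] for g in sorted(scored)])
    rng = np.random.default_rng(seed)
    sizes = {len(genes) for genes in neighbor.values()}
    bg = _background(z_all, sizes, n_background, rng)
    met_z: dict[str, float] = {}
    counts: dict[str, int] = {}
    for met_id, genes in neighbor.items():
        k = len(genes)
        raw = sum(gene_scores[g] for g in genes) / np.sqrt(k)
        mu, sd = bg[k]
        met_z[met_id] = float((raw - mu) / sd)
        counts[met_id] = k
    return ReporterScores(met_z, counts, unmatched)


def reporter_subnetworks(
    model: Model,
    gene_scores: dict[str, float],
    scores: ReporterScores | None = None,
    size_limit: int = 6,
    n_seeds: int = 3,
    n_background: int = 10_000,
    seed: int = 0,
) -> list[Subnetwork]:
    """Greedy reporter-subnetwork search on the metabolite graph.

    Starting from the ``n_seeds`` top reporter metabolites (disjointly:
    metabolites used by an accepted subnetwork are not reused), the
    subnetwork grows by adding the neighboring metabolite (sharing a
    reaction) that most increases the background-corrected aggregate Z
    of the union of member genes, until no extension improves the score
    or ``size_limit`` is reached.  Deterministic for a fixed seed.
    """
    if scores is None:
        scores = reporter_metabolites(model, gene_scores, n_background, seed)
    scored = {g for g in gene_scores if g in model.genes}
    neighbor = metabolite_gene_map(model, scored)
    if not neighbor:
        return []
    z_all = np.array([gene_scores[g] for g in sorted(scored)])
    rng = np.random.default_rng(seed + 1)
    max_genes = len(
        frozenset().union(*neighbor.values())
    )
    bg = _background(z_all, set(range(1, max_genes + 1)), n_background, rng)

    # metabolite adjacency via shared reactions (GPR-bearing only)
    adjacency: dict[str, set[str]] = {m: set() for m in neighbor}
    for rxn in model.reactions.values():
        mets = [m for m in rxn.stoichiometry if m in neighbor]
        for a in mets:
            for b in mets:
                if a != b:
                    adjacency[a].add(b)

    def corrected(gene_set: frozenset[str]) -> float:
        k = len(gene_set)
        if k == 0:
            return -np.inf
        raw = sum(gene_scores[g] for g in gene_set) / np.sqrt(k)
        mu, sd = bg[k]
        return float((raw - mu) / sd)

    used: set[str] = set()
    results: list[Subnetwork] = []
    for met_id, _ in scores.ranked():
        if len(results) >= n_seeds:
            break
        if met_id in used:
            continue
        members = {met_id}
        genes = set(neighbor[met_id])
        score = corrected(frozenset(genes))
        improved = True
        while improved and len(members) < size_limit:
            improved = False
            frontier = sorted(
                {n for m in members for n in adjacency[m]} - members - used
            )
            best = None
            for cand in frontier:
                cand_genes = frozenset(genes | neighbor[cand])
                cand_score = corrected(cand_genes)
                if cand_score > score + 1e-12 and (
                    best is None or cand_score > best[1]
                ):
                    best = (cand, cand_score, cand_genes)
            if best is not None:
                members.add(best[0])
                score = best[1]
                genes = set(best[2])
                improved = True
        results.append(
            Subnetwork(frozenset(members), frozenset(genes), score)
        )
        used |= members
    results.sort(key=lambda s: -s.corrected_z)
    scores.subnetworks = results
    return results


# ---------------------------------------------------------------------------
# Comparison against shadow prices

@dataclass
class ShadowComparison:
    spearman_rho: float
    spearman_p: float
    top_k_overlap: int
    k: int
    n_shared: int


def compare_shadow(
    reporters: ReporterScores,
    lambdas: dict[str, float],
    k: int = 10,
) -> ShadowComparison:
    """Rank agreement between reporter Z scores and shadow-price
    magnitudes ``|-lambda|`` on compartment-merged metabolites.

    Species are merged to parent compounds taking the
    maximum-magnitude value in each; the comparison reports the
    Spearman correlation and the overlap of the two top-k lists.
    """
    merged_z: dict[str, float] = {}
    for met_id, z in reporters.metabolite_z.items():
        c = base_id(met_id)
        if c not in merged_z or z > merged_z[c]:
            merged_z[c] = z
    merged_l: dict[str, float] = {}
    for met_id, lam in lambdas.items():
        c = base_id(met_id)
        mag = abs(lam)
        if c not in merged_l or mag > merged_l[c]:
            merged_l[c] = mag
    shared = sorted(set(merged_z) & set(merged_l))
    if not shared:
        raise ModelError("no shared metabolites between reporters and duals")
    z = [merged_z[c] for c in shared]
    lam = [merged_l[c] for c in shared]
    if len(shared) > 1:
        rho, p = stats.spearmanr(z, lam)
    else:
        rho, p = float("nan"), float("nan")
    top_z = {c for c, _ in sorted(merged_z.items(), key=lambda kv: -kv[1])[:k]}
    top_l = {c for c, _ in sorted(merged_l.items(), key=lambda kv: -kv[1])[:k]}
    return ShadowComparison(
        float(rho), float(p), len(top_z & top_l), k, len(shared)
    )
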