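"""Weighted Kolmogorov-Smirnov (GSEA-style) gene-set enrichment.

Walking down a ranked gene list, the running sum rises by
``|score|^exponent / sum_set |score|^exponent`` at set members and falls by
``1 / (N - |set|)`` elsewhere; the enrichment score ES is the signed maximum
deviation from zero, so |ES| <= 1 and the sum returns to zero after the last
gene.  Exponent 0 recovers the classical (unweighted) Kolmogorov-Smirnov
statistic between the member and non-member rank distributions; exponent 1
is the standard weighting.  The default null permutes set membership over
the gene universe; a sample-mode null scores gene sets against rankings
recomputed from design permutations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "weighted_ks_es",
    "enrichment_p",
    "enrich_collection",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the four CSC pathways) from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] | None = None
    source: str | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        if self.descriptions is None:
            self.descriptions = {name: "" for name in self.sets}

    def restricted_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with the measured universe; empty sets error."""
        uni = set(universe)
        restricted = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if not inter:
                raise ValueError(f"gene set {name!r} has no member in the measured universe")
            restricted[name] = inter
        return GeneSetCollection(restricted, dict(self.descriptions), self.source)


def _validate(ranked_genes: Sequence[str], scores, gene_set: Sequence[str]):
    genes = list(ranked_genes)
    s = np.asarray(scores, dtype=float)
    if s.shape != (len(genes),):
        raise ValueError("scores must align one-to-one with ranked_genes")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    member = np.isin(np.asarray(genes, dtype=object), list(gene_set))
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranking universe")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole universe; miss decrement undefined")
    return genes, s, member


def _running_sum(s: np.ndarray, member: np.ndarray, exponent: float) -> np.ndarray:
    w = np.abs(s) ** exponent
    denom = w[member].sum()
    if denom == 0:
        raise ValueError("all set members have zero score; weighted increments undefined")
    steps = np.where(member, w / denom, -1.0 / (member.size - member.sum()))
    return np.cumsum(steps)


def weighted_ks_es(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and running-sum profile of a gene set.

    ``ranked_genes`` must cover the measured universe in ranking order with
    ``scores`` aligned; returns (ES, running sum over positions).
    """
    _, s, member = _validate(ranked_genes, scores, gene_set)
    run = _running_sum(s, member, weight_exponent)
    es = run[np.argmax(np.abs(run))]
    return float(es), run


def _es_matrix(s: np.ndarray, members: np.ndarray, exponent: float) -> np.ndarray:
    """ES per row of a boolean membership matrix (n x N), vectorised."""
    w = np.abs(s) ** exponent
    n_hit = members.sum(axis=1)
    denom = (members * w).sum(axis=1)
    miss = 1.0 / (members.shape[1] - n_hit)
    steps = np.where(members, w / denom[:, None], -miss[:, None])
    run = np.cumsum(steps, axis=1)
    flat = np.abs(run).argmax(axis=1)
    return run[np.arange(run.shape[0]), flat]


def enrichment_p(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    gene_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    weight_exponent: float = 1.0,
    mode: str = "gene_label",
    permuted_scores: np.ndarray | None = None,
    permuted_genes: Sequence[str] | None = None,
    chunk: int = 512,
) -> tuple[float, float]:
    """Empirical two-sided p-value for |ES| and the observed ES.

    ``gene_label`` mode permutes set membership over the universe.  ``sample``
    mode scores the set against rankings rebuilt from ``permuted_scores``
    (one row per design permutation, columns aligned to ``permuted_genes``),
    e.g. from ``TrendScreenResults.sample_permutation_scores``.  The p-value
    uses the add-one convention ``(b + 1) / (B + 1)``.
    """
    genes, s, member = _validate(ranked_genes, scores, gene_set)
    run = _running_sum(s, member, weight_exponent)
    es_obs = float(run[np.argmax(np.abs(run))])

    if mode == "gene_label":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        b = 0
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            mat = rng.permuted(np.tile(member, (k, 1)), axis=1)
            es = _es_matrix(s, mat, weight_exponent)
            b += int((np.abs(es) >= abs(es_obs) - 1e-12).sum())
            done += k
        return (b + 1) / (n_perm + 1), es_obs

    if mode == "sample":
        if permuted_scores is None or permuted_genes is None:
            raise ValueError("sample mode needs permuted_scores and permuted_genes")
        perm = np.asarray(permuted_scores, dtype=float)
        pg = list(permuted_genes)
        member_pg = np.isin(np.asarray(pg, dtype=object), list(gene_set))
        b = 0
        for row in perm:
            order = np.argsort(-row)
            es = _es_matrix(row[order][None, :], member_pg[order][None, :], weight_exponent)[0]
            if abs(es) >= abs(es_obs) - 1e-12:
                b += 1
        return (b + 1) / (perm.shape[0] + 1), es_obs

    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    empirical_p: float
    leading_edge: list[str]


def _leading_edge(ranked_genes, run: np.ndarray, member: np.ndarray) -> list[str]:
    peak = int(np.argmax(np.abs(run)))
    if run[peak] >= 0:
        sel = member[: peak + 1]
        return [g for g, m in zip(ranked_genes[: peak + 1], sel) if m]
    sel = member[peak:]
    return [g for g, m in zip(ranked_genes[peak:], sel) if m]


def enrich_collection(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Gene-label permutation enrichment of every set in a collection."""
    restricted = collection.restricted_to(ranked_genes)
    rng = np.random.default_rng(seed)
    results = []
    for name, members in restricted.sets.items():
        genes, s, member = _validate(ranked_genes, scores, members)
        run = _running_sum(s, member, weight_exponent)
        p, es = enrichment_p(
            ranked_genes, scores, members, n_perm=n_perm, seed=rng, weight_exponent=weight_exponent
        )
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es,
                empirical_p=p,
                leading_edge=_leading_edge(genes, run, member),
            )
        )
    return results
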