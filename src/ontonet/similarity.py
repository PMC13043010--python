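"""Gene-gene and term-term similarity scores.

The edge metric between two genes is the weighted Tanimoto (weighted
Jaccard) index over their ontology-term profiles: each term t carries the
weight w_t = -log(P_t) from the enrichment table, and

    Tw(G1, G2) = sum_{t in A∩B} w_t / sum_{t in A∪B} w_t,

where A and B are the term sets of G1 and G2 restricted to terms with
overlap >= 1 against the gene list (the only terms that have weights).
Term-term similarity is the plain Tanimoto index |A∩B| / |A∪B| over member
genes. Each shared term's contribution to an edge is its weight divided by
the summed weights of all shared terms, so contributions sum to 1 per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np

from .enrichment import EnrichmentTable
from .genesets import GeneTermProfile


@dataclass(frozen=True)
class EdgeRecord:
    """An unordered gene pair with its Tw score and per-term contributions.

    ``shared_terms`` maps each shared term to its contribution fraction;
    the fractions sum to 1 whenever the map is non-empty. ``gene_a`` sorts
    before ``gene_b``.
    """

    gene_a: str
    gene_b: str
    tw: float
    shared_terms: Mapping[str, float] = field(default_factory=dict)

    @property
    def edge_length(self) -> float:
        """1 / Tw — the target drawing length of the edge (Tw > 0 only)."""
        if self.tw <= 0:
            raise ValueError("edge_length undefined for tw <= 0")
        return 1.0 / self.tw

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def top_contributing_term(self) -> str | None:
        if not self.shared_terms:
            return None
        return max(self.shared_terms, key=lambda t: (self.shared_terms[t], t))


@dataclass(frozen=True)
class TermEdge:
    """An unordered term pair with its plain Tanimoto score."""

    term_a: str
    term_b: str
    t: float


def _check_weights(terms: Iterable[str], weights: Mapping[str, float]) -> None:
    for t in terms:
        w = weights[t]
        if w < 0:
            raise ValueError(f"negative weight {w} for term {t!r}")


def tw_score(
    terms_a: AbstractSet[str],
    terms_b: AbstractSet[str],
    weights: Mapping[str, float],
) -> float:
    """Weighted Tanimoto between two term sets: shared weight / union weight.

    Returns 0.0 when the union carries no weight. Weights must be
    non-negative and defined for every term in the union.
    """
    union = terms_a | terms_b
    _check_weights(union, weights)
    # summation in sorted term order keeps results bit-identical across runs
    denom = sum(weights[t] for t in sorted(union))
    if denom <= 0:
        return 0.0
    num = sum(weights[t] for t in sorted(terms_a & terms_b))
    return num / denom


def t_score(genes_a: AbstractSet[str], genes_b: AbstractSet[str]) -> float:
    """Plain Tanimoto index |A∩B| / |A∪B| between two non-empty gene sets."""
    if not genes_a or not genes_b:
        raise ValueError("t_score requires two non-empty sets")
    return len(genes_a & genes_b) / len(genes_a | genes_b)


def term_contributions(
    terms_a: AbstractSet[str],
    terms_b: AbstractSet[str],
    weights: Mapping[str, float],
) -> dict[str, float]:
    """Relative contribution of each shared term: w_t / sum of shared weights.

    Empty when the intersection is empty or carries no weight.
    """
    shared = terms_a & terms_b
    _check_weights(terms_a | terms_b, weights)
    total = sum(weights[t] for t in sorted(shared))
    if total <= 0:
        return {}
    return {t: weights[t] / total for t in sorted(shared)}


def pairwise_edges(
    genes: Sequence[str],
    profiles: Mapping[str, GeneTermProfile],
    table: EnrichmentTable,
) -> list[EdgeRecord]:
    """All positive-Tw edges among the genes, in lexicographic pair order.

    Profiles are restricted to terms present in the enrichment table before
    scoring (only those terms have weights). Genes with empty restricted
    profiles participate in no edge; self-edges are never created.
    """
    weights = table.weights()
    table_terms = set(weights)
    ordered = sorted(dict.fromkeys(genes))
    restricted = {
        g: frozenset(profiles[g].associated_terms & table_terms) if g in profiles else frozenset()
        for g in ordered
    }
    # sorted-order sums: bit-identical across processes regardless of hash seed
    totals = {g: sum(weights[t] for t in sorted(ts)) for g, ts in restricted.items()}
    edges: list[EdgeRecord] = []
    for i, ga in enumerate(ordered):
        ta = restricted[ga]
        if not ta:
            continue
        for gb in ordered[i + 1 :]:
            tb = restricted[gb]
            shared = ta & tb
            if not shared:
                continue
            num = sum(weights[t] for t in sorted(shared))
            denom = totals[ga] + totals[gb] - num
            if denom <= 0 or num <= 0:
                continue
            tw = num / denom
            contrib = {t: weights[t] / num for t in sorted(shared)}
            edges.append(EdgeRecord(gene_a=ga, gene_b=gb, tw=tw, shared_terms=contrib))
    return edges


def tw_matrix(
    genes: Sequence[str],
    profiles: Mapping[str, GeneTermProfile],
    weights: Mapping[str, float],
) -> np.ndarray:
    """Dense symmetric matrix of Tw scores (diagonal set to 0).

    Vectorised path used by cutoff calibration, where only the score
    distribution is needed and per-term contributions are not.
    """
    ordered = list(dict.fromkeys(genes))
    terms = sorted(weights)
    tindex = {t: j for j, t in enumerate(terms)}
    w = np.array([weights[t] for t in terms], dtype=float)
    a = np.zeros((len(ordered), len(terms)), dtype=float)
    for i, g in enumerate(ordered):
        if g in profiles:
            for t in profiles[g].associated_terms:
                j = tindex.get(t)
                if j is not None:
                    a[i, j] = 1.0
    inter = (a * w) @ a.T
    tot = a @ w
    union = tot[:, None] + tot[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tw = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(tw, 0.0)
    return tw


def write_edge_list(edges: Sequence[EdgeRecord], path: str | Path) -> None:
    """TSV edge writer: gene_a, gene_b, tw, n_shared_terms, top_contributing_term."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\ttw\tn_shared_terms\ttop_contributing_term\n")
        for e in sorted(edges, key=lambda e: e.key):
            top = e.top_contributing_term() or ""
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.tw!r}\t{len(e.shared_terms)}\t{top}\n")
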