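"""Functional interpretation of gene networks.

Covers: per-term cumulative edge weight ("total Tw"), representative-term
selection under enrichment / edge-contribution / redundancy criteria, the
dominant (largest-coverage) term of a subnetwork, the optimal-subnetwork
scan over ascending Tw thresholds, and ontology clustering by the plain
Tanimoto index between terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .enrichment import EnrichmentTable
from .genesets import GeneSetCollection
from .network import GeneNetwork, Subnetwork, decompose, subnetwork_view
from .similarity import TermEdge, t_score

logger = logging.getLogger(__name__)

#: Default representative-term criteria: -log10(P) > 2 (i.e. P < .01),
#: total Tw > 1, and pairwise term Tanimoto < 0.3 among selected terms.
DEFAULT_MIN_NEG_LOG_P = 2.0
DEFAULT_MIN_TOTAL_TW = 1.0
DEFAULT_MAX_PAIRWISE_T = 0.3


@dataclass(frozen=True)
class SelectedTerm:
    term_id: str
    neg_log_p: float
    total_tw: float
    n_genes_in_network: int


@dataclass(frozen=True)
class TermSelection:
    """Ordered representative terms with the criteria that produced them."""

    selected: tuple[SelectedTerm, ...]
    min_neg_log_p: float = DEFAULT_MIN_NEG_LOG_P
    min_total_tw: float = DEFAULT_MIN_TOTAL_TW
    max_pairwise_t: float = DEFAULT_MAX_PAIRWISE_T

    def __len__(self) -> int:
        return len(self.selected)

    def term_ids(self) -> list[str]:
        return [s.term_id for s in self.selected]


@dataclass(frozen=True)
class OptimalSubnet:
    """The largest subnetwork, over scanned thresholds, that is well labeled
    by more than one representative term."""

    subnetwork: Subnetwork
    threshold: float
    representative_terms: TermSelection
    labeled_ratio: float


@dataclass(frozen=True)
class OntologyCluster:
    """Term-term Tanimoto graph and its connected-component clustering."""

    term_ids: tuple[str, ...]
    edges: tuple[TermEdge, ...]
    t_threshold: float
    clusters: tuple[frozenset[str], ...]
    exemplars: tuple[str, ...]


def term_totals(network: GeneNetwork, mode: str = "edge_weighted") -> dict[str, float]:
    """Cumulative edge weight allocated to each term over the whole network.

    mode="edge_weighted" (default): each edge's Tw is split across its
    shared terms in proportion to their contribution fractions, so the term
    totals conserve the summed edge weight exactly:
    sum_t total(t) == sum_e tw(e).

    mode="fraction": raw contribution fractions are summed instead (each
    edge then distributes a total of 1 across its shared terms).
    """
    if mode not in ("edge_weighted", "fraction"):
        raise ValueError(f"unknown total-Tw mode {mode!r}")
    totals: dict[str, float] = {}
    for e in network.edges:
        scale = e.tw if mode == "edge_weighted" else 1.0
        for t, frac in e.shared_terms.items():
            totals[t] = totals.get(t, 0.0) + frac * scale
    return totals


def term_total_tw(network: GeneNetwork, term_id: str, mode: str = "edge_weighted") -> float:
    """Total Tw of one term; 0 with a warning for a term on no edge."""
    totals = term_totals(network, mode=mode)
    if term_id not in totals:
        logger.warning("term %r contributes to no edge in this network", term_id)
        return 0.0
    return totals[term_id]


def representative_terms(
    network: GeneNetwork,
    table: EnrichmentTable,
    collection: GeneSetCollection,
    min_neg_log_p: float = DEFAULT_MIN_NEG_LOG_P,
    min_total_tw: float = DEFAULT_MIN_TOTAL_TW,
    max_pairwise_t: float = DEFAULT_MAX_PAIRWISE_T,
    total_tw_mode: str = "edge_weighted",
) -> TermSelection:
    """Greedy selection of representative terms for a network.

    Candidates must pass (strictly) the enrichment and total-Tw thresholds;
    they are then visited in order of total Tw descending (ties: higher
    -log P, then term id) and accepted iff their gene-set Tanimoto with
    every previously accepted term is < max_pairwise_t. An empty selection
    is legal.
    """
    totals = term_totals(network, mode=total_tw_mode)
    weights = table.weights()
    net_genes = set(network.nodes)
    candidates = [
        tid
        for tid, total in totals.items()
        if total > min_total_tw and weights.get(tid, 0.0) > min_neg_log_p
    ]
    candidates.sort(key=lambda tid: (-totals[tid], -weights[tid], tid))
    accepted: list[SelectedTerm] = []
    accepted_genes: list[frozenset[str]] = []
    for tid in candidates:
        genes = collection.terms[tid].genes
        if all(t_score(genes, g) < max_pairwise_t for g in accepted_genes):
            accepted.append(
                SelectedTerm(
                    term_id=tid,
                    neg_log_p=weights[tid],
                    total_tw=totals[tid],
                    n_genes_in_network=len(genes & net_genes),
                )
            )
            accepted_genes.append(genes)
    return TermSelection(
        selected=tuple(accepted),
        min_neg_log_p=min_neg_log_p,
        min_total_tw=min_total_tw,
        max_pairwise_t=max_pairwise_t,
    )


def dominant_term(
    subnetwork: Subnetwork,
    collection: GeneSetCollection,
    table: EnrichmentTable,
) -> str:
    """The table term covering the most subnetwork genes.

    Ties break toward higher -log P, then lexicographic term id. The
    dominant term may differ from the most enriched (representative) term.
    """
    if not subnetwork.genes:
        raise ValueError("subnetwork is empty")
    weights = table.weights()
    best: tuple[int, float, str] | None = None
    best_tid: str | None = None
    for tid in table.rows:
        cover = len(collection.terms[tid].genes & subnetwork.genes)
        if cover == 0:
            continue
        # sort key: maximize coverage, then weight; minimize term id
        key = (-cover, -weights[tid], tid)
        if best is None or key < best:
            best = key
            best_tid = tid
    if best_tid is None:
        raise ValueError("no term covers any gene of the subnetwork")
    return best_tid


def optimal_subnet(
    network: GeneNetwork,
    table: EnrichmentTable,
    collection: GeneSetCollection,
    step: float = 0.05,
    labeled_ratio_min: float = 0.8,
    min_rep_terms: int = 2,
    min_nodes: int = 1,
    min_neg_log_p: float = DEFAULT_MIN_NEG_LOG_P,
    min_total_tw: float = DEFAULT_MIN_TOTAL_TW,
    max_pairwise_t: float = DEFAULT_MAX_PAIRWISE_T,
    total_tw_mode: str = "edge_weighted",
) -> OptimalSubnet | None:
    """Scan Tw thresholds 0, step, 2*step, ... for the optimal subnetwork.

    At each threshold the network is decomposed into connected components;
    each component gets its own representative-term selection, and its
    labeled ratio is the fraction of component genes covered by at least
    one selected term. A component qualifies iff labeled_ratio >
    labeled_ratio_min and it has >= min_rep_terms representative terms.
    The largest qualifying component wins; ties resolve toward the higher
    threshold, then more representative terms. Returns None when nothing
    qualifies.
    """
    if not network.nodes:
        raise ValueError("network is empty")
    max_tw = network.max_tw()
    best: OptimalSubnet | None = None
    best_key: tuple[int, float, int] | None = None
    k = 0
    threshold = 0.0
    while threshold <= max_tw:
        if threshold >= network.tw_cutoff:
            for sub in decompose(network, threshold, min_nodes=min_nodes):
                view = subnetwork_view(network, sub)
                sel = representative_terms(
                    view,
                    table,
                    collection,
                    min_neg_log_p=min_neg_log_p,
                    min_total_tw=min_total_tw,
                    max_pairwise_t=max_pairwise_t,
                    total_tw_mode=total_tw_mode,
                )
                if len(sel) < min_rep_terms:
                    continue
                covered = frozenset().union(
                    *(collection.terms[s.term_id].genes for s in sel.selected)
                )
                ratio = len(sub.genes & covered) / sub.size
                if ratio <= labeled_ratio_min:
                    continue
                key = (sub.size, threshold, len(sel))
                if best_key is None or key > best_key:
                    best_key = key
                    best = OptimalSubnet(
                        subnetwork=sub,
                        threshold=threshold,
                        representative_terms=sel,
                        labeled_ratio=ratio,
                    )
        k += 1
        threshold = k * step
    return best


def cluster_ontology(
    terms: Iterable[str],
    collection: GeneSetCollection,
    t_threshold: float,
    table: EnrichmentTable | None = None,
) -> OntologyCluster:
    """Cluster terms by plain Tanimoto over member genes.

    Edges connect pairs with t > threshold (strict); clusters are the
    connected components (singletons included). Each cluster's exemplar is
    its most enriched member when an enrichment table is supplied, else its
    largest term (ties: lexicographic term id).
    """
    term_ids = tuple(sorted(dict.fromkeys(terms)))
    for tid in term_ids:
        if tid not in collection.terms:
            raise KeyError(f"term {tid!r} not in collection")
    edges: list[TermEdge] = []
    for i, ta in enumerate(term_ids):
        for tb in term_ids[i + 1 :]:
            t = t_score(collection.terms[ta].genes, collection.terms[tb].genes)
            if t > t_threshold:
                edges.append(TermEdge(term_a=ta, term_b=tb, t=t))
    g = nx.Graph()
    g.add_nodes_from(term_ids)
    g.add_edges_from((e.term_a, e.term_b) for e in edges)
    weights = table.weights() if table is not None else {}
    clusters: list[frozenset[str]] = []
    exemplars: list[str] = []
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    for comp in comps:
        comp = frozenset(comp)
        if table is not None:
            ex = max(comp, key=lambda t: (weights.get(t, 0.0), t))
        else:
            ex = max(comp, key=lambda t: (len(collection.terms[t].genes), t))
        clusters.append(comp)
        exemplars.append(ex)
    return OntologyCluster(
        term_ids=term_ids,
        edges=tuple(edges),
        t_threshold=t_threshold,
        clusters=tuple(clusters),
        exemplars=tuple(exemplars),
    )


def write_term_selection(
    selection: TermSelection,
    path: str | Path,
    collection: GeneSetCollection | None = None,
) -> None:
    """TSV writer: term_id, description, neg_log_p, total_tw, n_genes_in_network."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("term_id\tdescription\tneg_log_p\ttotal_tw\tn_genes_in_network\n")
        for s in selection.selected:
            desc = ""
            if collection is not None and s.term_id in collection.terms:
                desc = collection.terms[s.term_id].description
            fh.write(
                f"{s.term_id}\t{desc}\t{s.neg_log_p!r}\t{s.total_tw!r}"
                f"\t{s.n_genes_in_network}\n"
            )


def write_ontology_cluster_graphml(cluster: OntologyCluster, path: str | Path) -> None:
    """Export the term-term Tanimoto graph with cluster labels as GraphML."""
    g = nx.Graph()
    g.graph["t_threshold"] = float(cluster.t_threshold)
    label = {}
    for ci, comp in enumerate(cluster.clusters):
        for tid in comp:
            label[tid] = ci
    for tid in cluster.term_ids:
        g.add_node(tid, cluster=label[tid], exemplar=tid in cluster.exemplars)
    for e in cluster.edges:
        g.add_edge(e.term_a, e.term_b, t=float(e.t))
    nx.write_graphml(g, Path(path))
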