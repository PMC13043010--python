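"""Gene networks: construction, thresholding, decomposition, node metrics,
consensus networks across gene lists, layout, and export/import.

Nodes are the input genes (isolated nodes are kept); edges are gene pairs
whose weighted Tanimoto score strictly exceeds the cutoff. By default every
edge with Tw > 0 is included; raising the cutoff decomposes the network
into more significantly connected subnetworks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    DEFAULT_LOG_BASE,
    DEFAULT_P_FLOOR,
    EnrichmentTable,
    combine_pvalues,
    fisher_enrichment,
)
from .genesets import GeneSetCollection, GeneTermProfile, build_profiles
from .similarity import EdgeRecord, pairwise_edges

logger = logging.getLogger(__name__)

VALID_NODE_TYPES = frozenset(range(1, 6))


@dataclass(frozen=True)
class NodeInfo:
    """Display/annotation attributes of a gene node.

    ``node_type`` (1-5) encodes which input list the gene came from (shape
    in a drawing); ``node_attr`` is an optional numeric attribute such as
    CRISPR knockout efficacy; ``list_ids`` records every input list that
    contains the gene.
    """

    node_type: int = 1
    node_attr: float | None = None
    list_ids: frozenset[str] = frozenset()


@dataclass
class GeneNetwork:
    """A weighted gene network.

    Invariants: every edge endpoint is a node; every edge has tw strictly
    greater than ``tw_cutoff``.
    """

    nodes: dict[str, NodeInfo]
    edges: list[EdgeRecord]
    tw_cutoff: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def max_tw(self) -> float:
        return max((e.tw for e in self.edges), default=0.0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene in sorted(self.nodes):
            g.add_node(gene)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, weight=e.tw)
        return g


@dataclass(frozen=True)
class Subnetwork:
    """A connected component of the thresholded network."""

    genes: frozenset[str]
    edges: tuple[EdgeRecord, ...]
    threshold: float

    @property
    def size(self) -> int:
        return len(self.genes)


def build_network(
    genes: Sequence[str],
    edges: Sequence[EdgeRecord],
    tw_cutoff: float = 0.0,
    node_types: Mapping[str, int] | None = None,
    node_attrs: Mapping[str, float] | None = None,
    list_ids: Mapping[str, Iterable[str]] | None = None,
    provenance: dict | None = None,
) -> GeneNetwork:
    """Assemble a network keeping edges with tw > cutoff (strict).

    All input genes remain as nodes, possibly isolated; node_type defaults
    to 1 and must lie in 1-5.
    """
    if tw_cutoff < 0:
        raise ValueError(f"tw_cutoff must be >= 0, got {tw_cutoff}")
    node_types = node_types or {}
    node_attrs = node_attrs or {}
    list_ids = list_ids or {}
    nodes: dict[str, NodeInfo] = {}
    for g in dict.fromkeys(genes):
        nt = int(node_types.get(g, 1))
        if nt not in VALID_NODE_TYPES:
            raise ValueError(f"node_type for {g!r} must be in 1..5, got {nt}")
        attr = node_attrs.get(g)
        nodes[g] = NodeInfo(
            node_type=nt,
            node_attr=None if attr is None else float(attr),
            list_ids=frozenset(list_ids.get(g, ())),
        )
    kept = [
        e
        for e in edges
        if e.tw > tw_cutoff and e.gene_a in nodes and e.gene_b in nodes
    ]
    return GeneNetwork(
        nodes=nodes, edges=kept, tw_cutoff=tw_cutoff, provenance=provenance or {}
    )


def decompose(
    network: GeneNetwork, tw_threshold: float, min_nodes: int = 0
) -> list[Subnetwork]:
    """Connected components of the graph with edges tw > threshold.

    Components with node count > min_nodes (strict) are returned, sorted by
    size descending, then by lexicographically smallest member gene.
    """
    if tw_threshold < network.tw_cutoff:
        raise ValueError(
            f"threshold {tw_threshold} below network cutoff {network.tw_cutoff}"
        )
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    surviving = [e for e in network.edges if e.tw > tw_threshold]
    for e in surviving:
        g.add_edge(e.gene_a, e.gene_b)
    subs: list[Subnetwork] = []
    for comp in nx.connected_components(g):
        if len(comp) > min_nodes:
            comp = frozenset(comp)
            comp_edges = tuple(
                e for e in surviving if e.gene_a in comp and e.gene_b in comp
            )
            subs.append(Subnetwork(genes=comp, edges=comp_edges, threshold=tw_threshold))
    subs.sort(key=lambda s: (-s.size, min(s.genes)))
    return subs


def subnetwork_view(network: GeneNetwork, sub: Subnetwork) -> GeneNetwork:
    """The network restricted to one subnetwork (nodes, edges, threshold)."""
    nodes = {g: network.nodes[g] for g in sorted(sub.genes)}
    return GeneNetwork(
        nodes=nodes,
        edges=list(sub.edges),
        tw_cutoff=sub.threshold,
        provenance=dict(network.provenance),
    )


def node_metrics(
    network: GeneNetwork,
    table: EnrichmentTable,
    profiles: Mapping[str, GeneTermProfile],
) -> pd.DataFrame:
    """Per-node degree, sum of incident Tw, sum of term weights, node_attr.

    ``sum_weight`` is the summed -log(P) of the terms associated with the
    gene (restricted to the enrichment table); isolated nodes get degree 0
    and sum_tw 0. Returned as a DataFrame indexed by gene.
    """
    weights = table.weights()
    degree = {g: 0 for g in network.nodes}
    sum_tw = {g: 0.0 for g in network.nodes}
    for e in network.edges:
        degree[e.gene_a] += 1
        degree[e.gene_b] += 1
        sum_tw[e.gene_a] += e.tw
        sum_tw[e.gene_b] += e.tw
    rows = []
    for g in sorted(network.nodes):
        terms = profiles[g].associated_terms if g in profiles else frozenset()
        sw = sum(weights[t] for t in sorted(terms) if t in weights)
        rows.append(
            {
                "gene": g,
                "degree": degree[g],
                "sum_tw": sum_tw[g],
                "sum_weight": sw,
                "node_attr": network.nodes[g].node_attr,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def attribute_correlation(
    metrics: pd.DataFrame,
    metric_name: str = "sum_tw",
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between a node metric and the numeric node attribute.

    Nodes with missing attributes are excluded pairwise; requires at least
    3 complete observations and non-constant vectors.
    """
    if metric_name not in metrics.columns:
        raise ValueError(f"unknown metric {metric_name!r}")
    sub = metrics[[metric_name, "node_attr"]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >=3 nodes with attributes, have {len(sub)}")
    x = sub[metric_name].to_numpy(dtype=float)
    y = sub["node_attr"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("metric or attribute is constant; correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def _combined_weight_map(
    tables: Sequence[EnrichmentTable],
    method: str,
    log_base: float,
    p_floor: float,
) -> dict[str, float]:
    """Combined -log(P) weight per term over the union of the tables' terms;
    a term absent from a table contributes P = 1 for that list."""
    term_ids: set[str] = set()
    for t in tables:
        term_ids |= t.term_ids()
    out: dict[str, float] = {}
    for tid in term_ids:
        per = [t.rows[tid].p_value if tid in t.rows else 1.0 for t in tables]
        _, w = combine_pvalues(per, method, log_base=log_base, p_floor=p_floor)
        out[tid] = w
    return out


def build_consensus_network(
    gene_lists: Mapping[str, Sequence[str]],
    collection: GeneSetCollection,
    *,
    method: str = "chisq",
    cross_policy: str = "pairwise",
    universe_mode: str = "annotated",
    fixed_n: int | None = None,
    log_base: float = DEFAULT_LOG_BASE,
    p_floor: float = DEFAULT_P_FLOOR,
    tw_cutoff: float = 0.0,
    node_attrs: Mapping[str, float] | None = None,
    provenance: dict | None = None,
) -> GeneNetwork:
    """Build one network from 1-5 gene lists with per-list enrichment.

    Fisher P-values are computed separately for each list. An edge between
    two genes that share a list uses that list's weights (lowest-index
    shared list if several). Under ``cross_policy="pairwise"`` an edge
    between genes of different lists uses the combined weights of the two
    lists involved (absent P-values treated as 1); under
    ``cross_policy="global_consensus"`` every edge uses the all-list
    combined weights. A gene in several lists is a single node whose
    node_type is its lowest list index and whose list_ids records all.

    With a single list this reduces exactly to the single-list network.
    """
    list_ids = list(gene_lists)
    n = len(list_ids)
    if not (1 <= n <= 5):
        raise ValueError(f"need 1-5 gene lists, got {n}")
    if cross_policy not in ("pairwise", "global_consensus"):
        raise ValueError(f"unknown cross_policy {cross_policy!r}")

    tables: dict[str, EnrichmentTable] = {}
    members: dict[str, list[str]] = {}  # gene -> list ids containing it (ordered)
    for lid in list_ids:
        genes = list(dict.fromkeys(gene_lists[lid]))
        if not genes:
            raise ValueError(f"gene list {lid!r} is empty")
        tables[lid] = fisher_enrichment(
            genes,
            collection,
            universe_mode=universe_mode,
            fixed_n=fixed_n,
            log_base=log_base,
            p_floor=p_floor,
            list_id=lid,
        )
        for g in genes:
            members.setdefault(g, [])
            if lid not in members[g]:
                members[g].append(lid)

    all_genes = sorted(members)
    profiles = build_profiles(collection, all_genes)
    list_index = {lid: i + 1 for i, lid in enumerate(list_ids)}
    node_types = {g: min(list_index[lid] for lid in members[g]) for g in all_genes}
    node_lists = {g: set(members[g]) for g in all_genes}

    if n == 1:
        only = list_ids[0]
        edges = pairwise_edges(all_genes, profiles, tables[only])
    else:
        # Weight maps: per single list, plus combined maps as required by policy.
        single_w = {lid: tables[lid].weights() for lid in list_ids}
        pair_w: dict[tuple[str, str], dict[str, float]] = {}
        global_w: dict[str, float] | None = None
        if cross_policy == "global_consensus":
            global_w = _combined_weight_map(
                [tables[lid] for lid in list_ids], method, log_base, p_floor
            )
        edges = []
        for i, ga in enumerate(all_genes):
            for gb in all_genes[i + 1 :]:
                if global_w is not None:
                    weights = global_w
                else:
                    shared_lists = [
                        lid for lid in list_ids if lid in node_lists[ga] and lid in node_lists[gb]
                    ]
                    if shared_lists:
                        weights = single_w[shared_lists[0]]
                    else:
                        la = min(members[ga], key=lambda l: list_index[l])
                        lb = min(members[gb], key=lambda l: list_index[l])
                        pair = tuple(sorted((la, lb), key=lambda l: list_index[l]))
                        if pair not in pair_w:
                            pair_w[pair] = _combined_weight_map(
                                [tables[pair[0]], tables[pair[1]]],
                                method, log_base, p_floor,
                            )
                        weights = pair_w[pair]
                ta = profiles[ga].associated_terms & weights.keys()
                tb = profiles[gb].associated_terms & weights.keys()
                shared = ta & tb
                if not shared:
                    continue
                # same summation form and order as pairwise_edges, so an edge
                # whose two genes share a list reproduces that list's Tw bit
                # for bit
                num = sum(weights[t] for t in sorted(shared))
                denom = (
                    sum(weights[t] for t in sorted(ta))
                    + sum(weights[t] for t in sorted(tb))
                    - num
                )
                if num <= 0 or denom <= 0:
                    continue
                edges.append(
                    EdgeRecord(
                        gene_a=ga,
                        gene_b=gb,
                        tw=num / denom,
                        shared_terms={t: weights[t] / num for t in sorted(shared)},
                    )
                )

    prov = dict(provenance or {})
    prov.setdefault("collection", collection.source_label)
    prov.setdefault("list_ids", list_ids)
    prov.setdefault("method", method)
    prov.setdefault("cross_policy", cross_policy)
    return build_network(
        all_genes,
        edges,
        tw_cutoff=tw_cutoff,
        node_types=node_types,
        node_attrs=node_attrs,
        list_ids=node_lists,
        provenance=prov,
    )


def layout(network: GeneNetwork, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Force-directed 2-D coordinates, deterministic under a fixed seed.

    Edge attraction is proportional to Tw, so high-Tw pairs are drawn
    closer (target length ~ 1/Tw). Coordinates are presentation only.
    """
    g = network.to_networkx()
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    return {gene: (float(xy[0]), float(xy[1])) for gene, xy in pos.items()}


def _network_to_dict(network: GeneNetwork) -> dict:
    return {
        "tw_cutoff": network.tw_cutoff,
        "provenance": network.provenance,
        "nodes": {
            g: {
                "node_type": info.node_type,
                "node_attr": info.node_attr,
                "list_ids": sorted(info.list_ids),
            }
            for g, info in sorted(network.nodes.items())
        },
        "edges": [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "tw": e.tw,
                "shared_terms": {t: e.shared_terms[t] for t in sorted(e.shared_terms)},
            }
            for e in sorted(network.edges, key=lambda e: e.key)
        ],
    }


def _network_from_dict(data: dict) -> GeneNetwork:
    nodes = {
        g: NodeInfo(
            node_type=int(nd["node_type"]),
            node_attr=None if nd["node_attr"] is None else float(nd["node_attr"]),
            list_ids=frozenset(nd["list_ids"]),
        )
        for g, nd in data["nodes"].items()
    }
    edges = [
        EdgeRecord(
            gene_a=ed["gene_a"],
            gene_b=ed["gene_b"],
            tw=float(ed["tw"]),
            shared_terms={t: float(c) for t, c in ed["shared_terms"].items()},
        )
        for ed in data["edges"]
    ]
    return GeneNetwork(
        nodes=nodes,
        edges=edges,
        tw_cutoff=float(data["tw_cutoff"]),
        provenance=dict(data.get("provenance", {})),
    )


def export_network(network: GeneNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network to GraphML, JSON, or a TSV edge list.

    GraphML and JSON are lossless for nodes (type, attr, list_ids) and
    edges (tw, contributions) and round-trip through
    :func:`import_network`; the TSV edge list is export-only.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.graph["tw_cutoff"] = float(network.tw_cutoff)
        g.graph["provenance"] = json.dumps(network.provenance, sort_keys=True)
        for gene, info in sorted(network.nodes.items()):
            attrs: dict = {
                "node_type": int(info.node_type),
                "list_ids": ",".join(sorted(info.list_ids)),
            }
            if info.node_attr is not None:
                attrs["node_attr"] = float(info.node_attr)
            g.add_node(gene, **attrs)
        for e in sorted(network.edges, key=lambda e: e.key):
            g.add_edge(
                e.gene_a,
                e.gene_b,
                tw=float(e.tw),
                n_shared_terms=len(e.shared_terms),
                contributions=json.dumps(
                    {t: e.shared_terms[t] for t in sorted(e.shared_terms)}, sort_keys=True
                ),
            )
        nx.write_graphml(g, path)
    elif format == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(_network_to_dict(network), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "edge_tsv":
        from .similarity import write_edge_list

        write_edge_list(network.edges, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_network(path: str | Path, format: str = "graphml") -> GeneNetwork:
    """Read a network written by :func:`export_network` (graphml or json)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = {}
        for gene, nd in g.nodes(data=True):
            lids = nd.get("list_ids", "")
            nodes[str(gene)] = NodeInfo(
                node_type=int(nd.get("node_type", 1)),
                node_attr=float(nd["node_attr"]) if "node_attr" in nd else None,
                list_ids=frozenset(x for x in lids.split(",") if x),
            )
        edges = []
        for ga, gb, ed in g.edges(data=True):
            ga, gb = sorted((str(ga), str(gb)))
            edges.append(
                EdgeRecord(
                    gene_a=ga,
                    gene_b=gb,
                    tw=float(ed["tw"]),
                    shared_terms={
                        t: float(c) for t, c in json.loads(ed.get("contributions", "{}")).items()
                    },
                )
            )
        edges.sort(key=lambda e: e.key)
        return GeneNetwork(
            nodes=nodes,
            edges=edges,
            tw_cutoff=float(g.graph.get("tw_cutoff", 0.0)),
            provenance=json.loads(g.graph.get("provenance", "{}")),
        )
    if format == "json":
        with Path(path).open("r", encoding="utf-8") as fh:
            return _network_from_dict(json.load(fh))
    raise ValueError(f"unknown import format {format!r}")
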