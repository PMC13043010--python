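"""Shared fixtures: hand-built and random gene-set collections."""

from __future__ import annotations

import numpy as np
import pytest

from ontonet.genesets import GeneSet, GeneSetCollection, build_profiles
from ontonet.enrichment import fisher_enrichment


def make_collection(term_map: dict[str, set[str]], extra_universe: set[str] = frozenset()):
    """Build a collection from a plain dict term -> gene set."""
    terms = {
        tid: GeneSet(description=f"term {tid}", genes=frozenset(genes))
        for tid, genes in term_map.items()
    }
    universe = frozenset().union(*(g.genes for g in terms.values())) | frozenset(extra_universe)
    return GeneSetCollection(terms=terms, universe=universe, source_label="test")


def random_collection(rng: np.random.Generator, n_genes=25, n_terms=30, term_size=(3, 10)):
    """A random collection over genes g000..g{n}; every term within size bounds."""
    genes = np.array([f"g{i:03d}" for i in range(n_genes)])
    term_map = {}
    for t in range(n_terms):
        size = min(int(rng.integers(term_size[0], term_size[1] + 1)), n_genes)
        term_map[f"t{t:03d}"] = set(rng.choice(genes, size=size, replace=False))
    return make_collection(term_map)


def random_case(rng: np.random.Generator, n_genes=25, n_terms=30, list_size=12):
    """(collection, gene list, enrichment table, profiles) on a random fixture."""
    coll = random_collection(rng, n_genes=n_genes, n_terms=n_terms)
    universe = sorted(coll.universe)
    size = min(list_size, len(universe))
    gene_list = list(rng.choice(np.array(universe), size=size, replace=False))
    table = fisher_enrichment(gene_list, coll)
    profiles = build_profiles(coll, gene_list)
    return coll, gene_list, table, profiles


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_collection():
    """A small deterministic collection used across modules."""
    return make_collection(
        {
            "T1": {"RPL7", "RPS3", "NOP56"},
            "T2": {"RPL7", "RPS3", "NOP56", "RRP9"},
            "T3": {"TP53", "MDM2", "CDKN1A"},
            "T4": {"TP53", "BRCA1", "ATM", "CHEK2"},
            "T5": {"CENPE", "BUB1B", "TTK", "TPX2", "PRC1"},
        },
        extra_universe={"LSM10", "MBLAC1"},
    )
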