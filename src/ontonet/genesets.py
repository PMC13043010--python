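"""Gene-set collections: GMT reading/writing, size filtering, gene->term profiles.

A collection is a flat map of term id -> member gene set, together with a
background universe of gene symbols. Terms are treated as unordered gene
sets; no ontology graph structure is used. Gene-symbol matching is exact,
case-sensitive string equality throughout — identifier mapping belongs
upstream of this package.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import GmtParseError

logger = logging.getLogger(__name__)

#: Default term-size bounds: terms with fewer than 3 or more than 300 member
#: genes are excluded before enrichment and network construction.
DEFAULT_MIN_TERM_SIZE = 3
DEFAULT_MAX_TERM_SIZE = 300


@dataclass(frozen=True)
class GeneSet:
    """One ontology term / curated signature: a description and its member genes."""

    description: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """A collection of gene sets plus the background universe.

    Parameters
    ----------
    terms
        Map of term id -> :class:`GeneSet`.
    universe
        Background gene symbols. Under the default "annotated" background
        mode this is the union of all member genes.
    source_label
        Free-text label for provenance (e.g. a file stem).
    """

    terms: Mapping[str, GeneSet]
    universe: frozenset[str]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id].genes


@dataclass(frozen=True)
class GeneTermProfile:
    """The set of (filtered) terms that contain a given gene.

    A gene absent from every term has an empty profile and will be an
    isolated node in any network built from it.
    """

    gene: str
    associated_terms: frozenset[str]

    def __len__(self) -> int:
        return len(self.associated_terms)


def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, gene, gene, ...).

    Gene symbols on each line are deduplicated with case preserved. The
    universe is initialised to the union of all member genes.

    Raises
    ------
    GmtParseError
        If the file is empty, a line has fewer than 3 fields, or a term id
        occurs twice.
    """
    path = Path(path)
    terms: dict[str, GeneSet] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            term_id, description = fields[0].strip(), fields[1].strip()
            if not term_id:
                raise GmtParseError(f"{path}: line {lineno}: empty term id")
            if term_id in terms:
                raise GmtParseError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: term {term_id!r} has no genes")
            terms[term_id] = GeneSet(description=description, genes=genes)
    if not terms:
        raise GmtParseError(f"{path}: no gene sets found (empty file)")
    universe = frozenset().union(*(gs.genes for gs in terms.values()))
    label = source_label if source_label is not None else path.stem
    return GeneSetCollection(terms=terms, universe=universe, source_label=label)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT. Terms and genes are written sorted, so the
    output is deterministic; read_gmt(write_gmt(c)) preserves (id, gene set)
    pairs exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term_id in sorted(collection.terms):
            gs = collection.terms[term_id]
            fh.write("\t".join([term_id, gs.description, *sorted(gs.genes)]) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_TERM_SIZE,
    max_size: int = DEFAULT_MAX_TERM_SIZE,
) -> GeneSetCollection:
    """Keep exactly the terms with min_size <= |genes| <= max_size (inclusive).

    The universe is left unchanged, so enrichment background does not shift
    when borderline terms are dropped. Idempotent.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got ({min_size}, {max_size})")
    kept = {
        tid: gs for tid, gs in collection.terms.items() if min_size <= len(gs.genes) <= max_size
    }
    return dataclasses.replace(collection, terms=kept)


def build_profiles(
    collection: GeneSetCollection, genes: Iterable[str]
) -> dict[str, GeneTermProfile]:
    """Map each input gene to the set of collection terms containing it.

    Genes not annotated in any term get empty profiles.
    """
    genes = list(dict.fromkeys(genes))
    index: dict[str, set[str]] = {g: set() for g in genes}
    wanted = set(genes)
    for tid, gs in collection.terms.items():
        for g in gs.genes & wanted:
            index[g].add(tid)
    return {
        g: GeneTermProfile(gene=g, associated_terms=frozenset(ts)) for g, ts in index.items()
    }
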