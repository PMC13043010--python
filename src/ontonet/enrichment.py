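"""Fisher's exact enrichment of ontology terms against a gene list.

Each term containing at least one list gene gets a one-sided (enrichment)
Fisher P-value from the 2x2 table (overlap, list-overlap, term-overlap,
rest of universe), equivalently the upper tail of a hypergeometric
distribution. The -log(P) of each term is the weight w_t that enters the
weighted Tanimoto similarity between genes. P-values here act as weighting
factors, not standalone hypothesis tests, so no multiple-testing correction
is applied.

Also implements Fisher's combined probability method across gene lists:
t = -2 * sum(ln P_i) referred to a chi-square distribution with 2n degrees
of freedom, plus the two-list "mean_log" shortcut where the combined weight
is the arithmetic mean of the two input weights (equivalently, the combined
P is the geometric mean of P1 and P2 — note this is not the chi-square
tail; both conventions are provided and documented).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

#: P-values are clamped below at this floor before taking -log, keeping
#: weights finite when a P-value underflows; the ranking of terms is
#: unaffected at any realistic scale.
DEFAULT_P_FLOOR = 1e-300

#: Default logarithm base for -log(P) weights (enrichment-tool convention).
DEFAULT_LOG_BASE = 10.0


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    overlap: int
    list_size: int
    term_size: int
    universe_size: int
    p_value: float
    weight: float


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-term Fisher P-values and -log weights for one gene list.

    Only terms with overlap >= 1 appear; terms never touched by the list
    carry no weight and contribute to no edge.
    """

    list_id: str
    rows: Mapping[str, EnrichmentRow]
    log_base: float = DEFAULT_LOG_BASE
    p_floor: float = DEFAULT_P_FLOOR

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.rows

    def term_ids(self) -> set[str]:
        return set(self.rows)

    def weights(self) -> dict[str, float]:
        """term id -> -log(P) weight."""
        return {tid: row.weight for tid, row in self.rows.items()}

    def p_values(self) -> dict[str, float]:
        return {tid: row.p_value for tid, row in self.rows.items()}


@dataclass(frozen=True)
class ConsensusWeights:
    """Combined per-term P-values and weights across n gene lists.

    Terms absent from a list's enrichment table contribute P = 1 for that
    list.
    """

    list_ids: tuple[str, ...]
    rows: Mapping[str, tuple[tuple[float, ...], float, float]]  # per_list_p, p_comb, weight
    method: str
    log_base: float = DEFAULT_LOG_BASE

    def weights(self) -> dict[str, float]:
        return {tid: row[2] for tid, row in self.rows.items()}


def hypergeom_tail_p(
    overlap: int | np.ndarray,
    list_size: int | np.ndarray,
    term_size: int | np.ndarray,
    universe_size: int | np.ndarray,
) -> np.ndarray | float:
    """P(X >= overlap) for X ~ Hypergeom(universe_size, term_size, list_size).

    This is the one-sided "greater" Fisher exact P-value of the 2x2
    enrichment table. Accepts scalars or broadcastable arrays.
    """
    k = np.asarray(overlap)
    return stats.hypergeom.sf(k - 1, M=universe_size, n=term_size, N=list_size)


def _weight(p: float, log_base: float, p_floor: float) -> float:
    p = max(p, p_floor)
    if log_base == 10.0:
        return -math.log10(p)  # dedicated log10 keeps e.g. p=0.01 -> exactly 2
    if log_base == math.e:
        return -math.log(p)
    return -math.log(p) / math.log(log_base)


def fisher_enrichment(
    genes: Sequence[str],
    collection: GeneSetCollection,
    *,
    universe_mode: str = "annotated",
    fixed_n: int | None = None,
    log_base: float = DEFAULT_LOG_BASE,
    p_floor: float = DEFAULT_P_FLOOR,
    list_id: str = "list",
) -> EnrichmentTable:
    """Fisher's exact enrichment of every collection term against a gene list.

    Parameters
    ----------
    genes
        The input gene list; duplicates are collapsed. Under
        ``universe_mode="annotated"`` genes outside the collection universe
        are dropped with a logged warning before testing.
    universe_mode
        "annotated": background = the collection universe (union of member
        genes). "fixed_n": background size = ``fixed_n`` (the list is used
        as given).
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("gene list is empty")
    if universe_mode == "annotated":
        kept = [g for g in genes if g in collection.universe]
        dropped = len(genes) - len(kept)
        if dropped:
            logger.warning(
                "%s: dropped %d/%d genes outside the %s universe",
                list_id, dropped, len(genes), collection.source_label or "collection",
            )
        genes = kept
        universe_size = len(collection.universe)
    elif universe_mode == "fixed_n":
        if fixed_n is None or fixed_n < 1:
            raise ConfigError("universe_mode='fixed_n' requires a positive fixed_n")
        universe_size = int(fixed_n)
    else:
        raise ConfigError(f"unknown universe_mode {universe_mode!r}")
    if not genes:
        raise ValueError(f"{list_id}: gene list empty after universe intersection")
    list_size = len(genes)
    if universe_size < list_size:
        raise ValueError(
            f"universe size {universe_size} smaller than list size {list_size}"
        )
    gene_set = set(genes)

    tids: list[str] = []
    overlaps: list[int] = []
    term_sizes: list[int] = []
    for tid in sorted(collection.terms):
        term_genes = collection.terms[tid].genes
        ov = len(term_genes & gene_set)
        if ov >= 1:
            tids.append(tid)
            overlaps.append(ov)
            term_sizes.append(len(term_genes))

    rows: dict[str, EnrichmentRow] = {}
    if tids:
        ps = hypergeom_tail_p(
            np.array(overlaps), list_size, np.array(term_sizes), universe_size
        )
        ps = np.clip(ps, 0.0, 1.0)
        for tid, ov, ts, p in zip(tids, overlaps, term_sizes, ps):
            p = float(p)
            rows[tid] = EnrichmentRow(
                term_id=tid,
                overlap=int(ov),
                list_size=list_size,
                term_size=int(ts),
                universe_size=universe_size,
                p_value=p,
                weight=_weight(p, log_base, p_floor),
            )
    return EnrichmentTable(list_id=list_id, rows=rows, log_base=log_base, p_floor=p_floor)


def weights_from_pvalues(
    table: EnrichmentTable,
    log_base: float = DEFAULT_LOG_BASE,
    p_floor: float = DEFAULT_P_FLOOR,
) -> EnrichmentTable:
    """Recompute weights as -log_base(max(p, p_floor)) for every row."""
    if not (0.0 < p_floor < 1.0):
        raise ValueError(f"p_floor must lie in (0, 1), got {p_floor}")
    rows = {
        tid: replace(row, weight=_weight(row.p_value, log_base, p_floor))
        for tid, row in table.rows.items()
    }
    return replace(table, rows=rows, log_base=log_base, p_floor=p_floor)


def combine_pvalues(
    per_list_p: Sequence[float],
    method: str = "chisq",
    *,
    log_base: float = DEFAULT_LOG_BASE,
    p_floor: float = DEFAULT_P_FLOOR,
) -> tuple[float, float]:
    """Combine n per-list P-values into (combined_p, combined_weight).

    method="chisq"
        Fisher's combined probability test: t = -2 * sum(ln P_i) referred
        to the chi-square upper tail with 2n degrees of freedom. For n = 1
        this is the identity.
    method="mean_log"
        Defined only for n = 2: the combined weight is the arithmetic mean
        of the two -log P weights, i.e. the combined P is the geometric
        mean sqrt(P1 * P2).
    """
    ps = [float(p) for p in per_list_p]
    if len(ps) < 1:
        raise ValueError("need at least one P-value")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"P-values must lie in (0, 1], got {p}")
    if method == "chisq":
        t = -2.0 * sum(math.log(p) for p in ps)
        p_comb = float(stats.chi2.sf(t, df=2 * len(ps)))
        p_comb = min(max(p_comb, 0.0), 1.0)
        return p_comb, _weight(p_comb, log_base, p_floor)
    if method == "mean_log":
        if len(ps) != 2:
            raise ValueError("method='mean_log' is defined only for exactly 2 lists")
        # combined weight is the arithmetic mean of the two input weights
        # exactly; the combined P is then the geometric mean of P1 and P2
        w = 0.5 * (_weight(ps[0], log_base, p_floor) + _weight(ps[1], log_base, p_floor))
        p_comb = min(max(math.sqrt(ps[0] * ps[1]), 0.0), 1.0)
        return p_comb, w
    raise ValueError(f"unknown combination method {method!r}")


def consensus_weights(
    tables: Sequence[EnrichmentTable],
    method: str = "chisq",
    *,
    log_base: float = DEFAULT_LOG_BASE,
    p_floor: float = DEFAULT_P_FLOOR,
    term_ids: set[str] | None = None,
) -> ConsensusWeights:
    """Combined P-value and weight per term across several enrichment tables.

    The term set is the union of the tables' terms (or ``term_ids`` if
    given); a term missing from a table contributes P = 1 for that list.
    """
    if not (1 <= len(tables) <= 5):
        raise ValueError(f"need 1-5 enrichment tables, got {len(tables)}")
    ids = tuple(t.list_id for t in tables)
    if term_ids is None:
        term_ids = set()
        for t in tables:
            term_ids |= t.term_ids()
    rows: dict[str, tuple[tuple[float, ...], float, float]] = {}
    for tid in sorted(term_ids):
        per = tuple(
            t.rows[tid].p_value if tid in t.rows else 1.0 for t in tables
        )
        p_comb, w = combine_pvalues(per, method, log_base=log_base, p_floor=p_floor)
        rows[tid] = (per, p_comb, w)
    return ConsensusWeights(list_ids=ids, rows=rows, method=method, log_base=log_base)


def write_enrichment_table(
    table: EnrichmentTable,
    path: str | Path,
    collection: GeneSetCollection | None = None,
) -> None:
    """Write a TSV (term_id, description, overlap, term_size, p_value, weight),
    sorted by ascending P then term id. Floats at full double precision."""
    path = Path(path)
    order = sorted(table.rows.values(), key=lambda r: (r.p_value, r.term_id))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("term_id\tdescription\toverlap\tterm_size\tp_value\tweight\n")
        for row in order:
            desc = ""
            if collection is not None and row.term_id in collection.terms:
                desc = collection.terms[row.term_id].description
            fh.write(
                f"{row.term_id}\t{desc}\t{row.overlap}\t{row.term_size}"
                f"\t{row.p_value!r}\t{row.weight!r}\n"
            )
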