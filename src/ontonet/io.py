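"""Gene-list CSV parsing and end-to-end run orchestration.

The gene-list dialect is a CSV whose first row is a header (content
ignored) followed by data rows of 1-3 columns:

    gene symbol, optional node type (1-5, default 1), optional numeric
    node attribute (e.g. CRISPR knockout efficacy).

Up to 1000 entries are analysed; longer lists are truncated to the first
1000 rows with a warning (or rejected under strict mode). Duplicate gene
symbols collapse to their first occurrence with a warning — silent gene
loss would corrupt enrichment.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import interpret, network, simulate
from .enrichment import (
    DEFAULT_LOG_BASE,
    DEFAULT_P_FLOOR,
    consensus_weights,
    fisher_enrichment,
    write_enrichment_table,
)
from .exceptions import ConfigError, GeneListError
from .genesets import (
    DEFAULT_MAX_TERM_SIZE,
    DEFAULT_MIN_TERM_SIZE,
    GeneSetCollection,
    build_profiles,
    filter_by_size,
    read_gmt,
)
from .similarity import pairwise_edges, write_edge_list

logger = logging.getLogger(__name__)

MAX_GENE_LIST_ENTRIES = 1000


@dataclass(frozen=True)
class GeneListEntry:
    gene: str
    node_type: int = 1
    node_attr: float | None = None


@dataclass(frozen=True)
class GeneListInput:
    """A parsed gene list with optional node types and attributes."""

    list_id: str
    entries: tuple[GeneListEntry, ...]

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def node_types(self) -> dict[str, int]:
        return {e.gene: e.node_type for e in self.entries}

    def node_attrs(self) -> dict[str, float]:
        return {e.gene: e.node_attr for e in self.entries if e.node_attr is not None}


def read_gene_list_csv(
    path: str | Path,
    list_id: str | None = None,
    max_entries: int = MAX_GENE_LIST_ENTRIES,
    strict: bool = False,
) -> GeneListInput:
    """Parse the 3-column gene-list CSV dialect (RFC-4180 quoting).

    The header row is skipped; missing node types default to 1 and missing
    attributes stay absent. Over-limit lists are truncated (or rejected
    with ``strict=True``); duplicates collapse to the first occurrence.
    """
    path = Path(path)
    lid = list_id if list_id is not None else path.stem
    rows: list[tuple[int, list[str]]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        for rowno, row in enumerate(reader, start=1):
            if rowno == 1:
                continue  # header content is unspecified and ignored
            if not row or not any(cell.strip() for cell in row):
                continue
            rows.append((rowno, row))
    if not rows:
        raise GeneListError(f"{path}: no data rows after the header")
    if len(rows) > max_entries:
        if strict:
            raise GeneListError(
                f"{path}: {len(rows)} data rows exceed the {max_entries}-entry limit"
            )
        logger.warning(
            "%s: %d data rows; analysing the first %d", path, len(rows), max_entries
        )
        rows = rows[:max_entries]

    entries: list[GeneListEntry] = []
    seen: set[str] = set()
    for rowno, row in rows:
        gene = row[0].strip()
        if not gene:
            raise GeneListError(f"{path}: row {rowno}: empty gene symbol")
        node_type = 1
        if len(row) > 1 and row[1].strip():
            try:
                node_type = int(row[1].strip())
            except ValueError as exc:
                raise GeneListError(
                    f"{path}: row {rowno}: node type {row[1]!r} is not an integer"
                ) from exc
            if node_type not in range(1, 6):
                raise GeneListError(
                    f"{path}: row {rowno}: node type must be 1-5, got {node_type}"
                )
        node_attr = None
        if len(row) > 2 and row[2].strip():
            try:
                node_attr = float(row[2].strip())
            except ValueError as exc:
                raise GeneListError(
                    f"{path}: row {rowno}: node attribute {row[2]!r} is not numeric"
                ) from exc
        if gene in seen:
            logger.warning("%s: row %d: duplicate gene %s collapsed", path, rowno, gene)
            continue
        seen.add(gene)
        entries.append(GeneListEntry(gene=gene, node_type=node_type, node_attr=node_attr))
    return GeneListInput(list_id=lid, entries=tuple(entries))


def write_gene_list_csv(gene_list: GeneListInput, path: str | Path) -> None:
    """Write a gene list back to the 3-column CSV dialect."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene", "node_type", "node_attr"])
        for e in gene_list.entries:
            writer.writerow(
                [e.gene, e.node_type, "" if e.node_attr is None else repr(e.node_attr)]
            )


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; defaults are the package defaults."""

    universe_mode: str = "annotated"
    fixed_n: int | None = None
    log_base: float = DEFAULT_LOG_BASE
    p_floor: float = DEFAULT_P_FLOOR
    min_term_size: int = DEFAULT_MIN_TERM_SIZE
    max_term_size: int = DEFAULT_MAX_TERM_SIZE
    tw_cutoff: float | None = None  # explicit cutoff overrides confidence
    confidence: float | None = None  # 0.01 / 0.05 / 0.10 / 0.15
    cutoff_profile: str | None = None  # "gobp", "hpo", or a cutoffs JSON path
    min_neg_log_p: float = interpret.DEFAULT_MIN_NEG_LOG_P
    min_total_tw: float = interpret.DEFAULT_MIN_TOTAL_TW
    max_pairwise_t: float = interpret.DEFAULT_MAX_PAIRWISE_T
    subnet_step: float = 0.05
    labeled_ratio_min: float = 0.8
    min_rep_terms: int = 2
    consensus_method: str = "chisq"
    cross_policy: str = "pairwise"
    seed: int = 0
    strict: bool = False

    def resolve_tw_cutoff(self) -> float:
        """Explicit cutoff wins; else confidence level via the cutoff
        profile; else the default 0 (all Tw > 0 edges)."""
        if self.tw_cutoff is not None:
            if self.tw_cutoff < 0:
                raise ConfigError("tw_cutoff must be >= 0")
            return float(self.tw_cutoff)
        if self.confidence is not None:
            if self.confidence not in (0.01, 0.05, 0.10, 0.15):
                raise ConfigError(
                    f"confidence must be one of 0.01/0.05/0.10/0.15, got {self.confidence}"
                )
            if self.cutoff_profile is None:
                raise ConfigError("confidence requires a cutoff profile (gobp/hpo/JSON)")
            if self.cutoff_profile in simulate.BUILTIN_TW_CUTOFFS:
                table = simulate.builtin_cutoff_table(self.cutoff_profile, "Tw")
            else:
                table = simulate.CutoffTable.from_json(self.cutoff_profile)
            return table.cutoff_for(self.confidence)
        return 0.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_collection(gmt: str | Path, config: RunConfig) -> GeneSetCollection:
    return filter_by_size(read_gmt(gmt), config.min_term_size, config.max_term_size)


def _write_manifest(
    outdir: Path, config: RunConfig, inputs: dict[str, Path], outputs: Sequence[str]
) -> Path:
    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
        "outputs": sorted(outputs),
    }
    path = outdir / "manifest.json"
    with path.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def run_single(
    config: RunConfig, list_csv: str | Path, gmt: str | Path, outdir: str | Path
) -> dict[str, Path]:
    """End-to-end single-list pipeline; returns the output-file map.

    Writes enrichment table, edge list, network exports (GraphML + JSON),
    node metrics, representative terms, optimal-subnet report, and a run
    manifest. Deterministic given (inputs, config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection = _load_collection(gmt, config)
    gene_list = read_gene_list_csv(list_csv, strict=config.strict)
    cutoff = config.resolve_tw_cutoff()

    table = fisher_enrichment(
        gene_list.genes,
        collection,
        universe_mode=config.universe_mode,
        fixed_n=config.fixed_n,
        log_base=config.log_base,
        p_floor=config.p_floor,
        list_id=gene_list.list_id,
    )
    profiles = build_profiles(collection, gene_list.genes)
    edges = pairwise_edges(gene_list.genes, profiles, table)
    net = network.build_network(
        gene_list.genes,
        edges,
        tw_cutoff=cutoff,
        node_types=gene_list.node_types(),
        node_attrs=gene_list.node_attrs(),
        list_ids={g: {gene_list.list_id} for g in gene_list.genes},
        provenance={
            "collection": collection.source_label,
            "list_ids": [gene_list.list_id],
            "tw_cutoff": cutoff,
            "seed": config.seed,
        },
    )
    metrics = network.node_metrics(net, table, profiles)
    selection = interpret.representative_terms(
        net,
        table,
        collection,
        min_neg_log_p=config.min_neg_log_p,
        min_total_tw=config.min_total_tw,
        max_pairwise_t=config.max_pairwise_t,
    )
    optimal = interpret.optimal_subnet(
        net,
        table,
        collection,
        step=config.subnet_step,
        labeled_ratio_min=config.labeled_ratio_min,
        min_rep_terms=config.min_rep_terms,
        min_neg_log_p=config.min_neg_log_p,
        min_total_tw=config.min_total_tw,
        max_pairwise_t=config.max_pairwise_t,
    )

    paths: dict[str, Path] = {
        "enrichment": outdir / "enrichment.tsv",
        "edges": outdir / "edges.tsv",
        "network_graphml": outdir / "network.graphml",
        "network_json": outdir / "network.json",
        "node_metrics": outdir / "node_metrics.tsv",
        "representative_terms": outdir / "representative_terms.tsv",
        "optimal_subnet": outdir / "optimal_subnet.json",
    }
    write_enrichment_table(table, paths["enrichment"], collection)
    write_edge_list(net.edges, paths["edges"])
    network.export_network(net, paths["network_graphml"], "graphml")
    network.export_network(net, paths["network_json"], "json")
    metrics.to_csv(paths["node_metrics"], sep="\t", float_format="%.17g")
    interpret.write_term_selection(selection, paths["representative_terms"], collection)
    with paths["optimal_subnet"].open("w", encoding="utf-8") as fh:
        if optimal is None:
            json.dump({"found": False}, fh, indent=1, sort_keys=True)
        else:
            json.dump(
                {
                    "found": True,
                    "threshold": optimal.threshold,
                    "size": optimal.subnetwork.size,
                    "labeled_ratio": optimal.labeled_ratio,
                    "genes": sorted(optimal.subnetwork.genes),
                    "representative_terms": [
                        {
                            "term_id": s.term_id,
                            "neg_log_p": s.neg_log_p,
                            "total_tw": s.total_tw,
                            "n_genes_in_network": s.n_genes_in_network,
                        }
                        for s in optimal.representative_terms.selected
                    ],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        fh.write("\n")
    paths["manifest"] = _write_manifest(
        outdir,
        config,
        {"gene_list": Path(list_csv), "gmt": Path(gmt)},
        [p.name for p in paths.values()],
    )
    return paths


def run_consensus(
    config: RunConfig,
    list_csvs: Sequence[str | Path],
    gmt: str | Path,
    outdir: str | Path,
) -> dict[str, Path]:
    """End-to-end consensus pipeline over 2-5 gene lists."""
    if not (2 <= len(list_csvs) <= 5):
        raise ConfigError(f"consensus needs 2-5 gene lists, got {len(list_csvs)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection = _load_collection(gmt, config)
    cutoff = config.resolve_tw_cutoff()

    gene_lists = [read_gene_list_csv(p, strict=config.strict) for p in list_csvs]
    ids = [gl.list_id for gl in gene_lists]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"gene-list ids are not unique: {ids}")

    node_attrs: dict[str, float] = {}
    for gl in gene_lists:
        for g, a in gl.node_attrs().items():
            node_attrs.setdefault(g, a)

    tables = {
        gl.list_id: fisher_enrichment(
            gl.genes,
            collection,
            universe_mode=config.universe_mode,
            fixed_n=config.fixed_n,
            log_base=config.log_base,
            p_floor=config.p_floor,
            list_id=gl.list_id,
        )
        for gl in gene_lists
    }
    net = network.build_consensus_network(
        {gl.list_id: gl.genes for gl in gene_lists},
        collection,
        method=config.consensus_method,
        cross_policy=config.cross_policy,
        universe_mode=config.universe_mode,
        fixed_n=config.fixed_n,
        log_base=config.log_base,
        p_floor=config.p_floor,
        tw_cutoff=cutoff,
        node_attrs=node_attrs,
        provenance={"seed": config.seed},
    )
    consensus = consensus_weights(
        [tables[i] for i in ids],
        config.consensus_method,
        log_base=config.log_base,
        p_floor=config.p_floor,
    )
    all_genes = sorted(net.nodes)
    profiles = build_profiles(collection, all_genes)
    # node metrics use the all-list consensus weights for sum_weight
    metrics = network.node_metrics(net, consensus, profiles)

    paths: dict[str, Path] = {}
    for lid in ids:
        p = outdir / f"enrichment_{lid}.tsv"
        write_enrichment_table(tables[lid], p, collection)
        paths[f"enrichment_{lid}"] = p
    paths["consensus_weights"] = outdir / "consensus_weights.tsv"
    with paths["consensus_weights"].open("w", encoding="utf-8") as fh:
        fh.write("term_id\t" + "\t".join(f"p_{i}" for i in ids) + "\tcombined_p\tcombined_weight\n")
        for tid in sorted(consensus.rows):
            per, p_comb, w = consensus.rows[tid]
            fh.write(
                tid + "\t" + "\t".join(repr(p) for p in per) + f"\t{p_comb!r}\t{w!r}\n"
            )
    paths["edges"] = outdir / "edges.tsv"
    write_edge_list(net.edges, paths["edges"])
    paths["network_graphml"] = outdir / "network.graphml"
    network.export_network(net, paths["network_graphml"], "graphml")
    paths["network_json"] = outdir / "network.json"
    network.export_network(net, paths["network_json"], "json")
    paths["node_metrics"] = outdir / "node_metrics.tsv"
    metrics.to_csv(paths["node_metrics"], sep="\t", float_format="%.17g")
    paths["manifest"] = _write_manifest(
        outdir,
        config,
        {f"gene_list_{i}": Path(p) for i, p in zip(ids, list_csvs)} | {"gmt": Path(gmt)},
        [p.name for p in paths.values()],
    )
    return paths


def run_calibrate(
    config: RunConfig,
    gmt: str | Path,
    outdir: str | Path,
    sizes: Sequence[int] = (10, 50, 100, 500, 1000),
    n_reps: int = 10,
    metric: str = "both",
) -> dict[str, Path]:
    """Calibrate Tw and/or T percentile cutoffs on a collection; write JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection = _load_collection(gmt, config)
    paths: dict[str, Path] = {}
    if metric in ("tw", "both"):
        table = simulate.calibrate_cutoffs(collection, sizes, n_reps, seed=config.seed)
        paths["cutoffs_tw"] = outdir / "cutoffs_tw.json"
        table.to_json(paths["cutoffs_tw"])
    if metric in ("t", "both"):
        table = simulate.calibrate_t_cutoffs(collection, sizes, n_reps, seed=config.seed)
        paths["cutoffs_t"] = outdir / "cutoffs_t.json"
        table.to_json(paths["cutoffs_t"])
    if not paths:
        raise ConfigError(f"metric must be 'tw', 't', or 'both', got {metric!r}")
    return paths
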