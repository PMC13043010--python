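"""Cutoff calibration from random gene lists, and synthetic benchmarks.

Random-list calibration: for gene lists sampled uniformly from the
collection universe, the distribution of positive pairwise Tw scores is
simulated and the top-1/5/10/15% quantiles recorded; averaging these over
list sizes and replicates yields confidence-level -> Tw-cutoff tables.
Built-in tables calibrated on large GO Biological Process and Human
Phenotype Ontology collections are shipped for convenience; users should
recalibrate on their own collections with :func:`calibrate_cutoffs`.

Synthetic benchmarks: :func:`make_synthetic` plants k disjoint gene
modules, each sharing several dedicated terms, inside a noisy collection,
and reports the ground-truth partition so that module-recovery can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import fisher_enrichment
from .genesets import GeneSet, GeneSetCollection, build_profiles, filter_by_size
from .similarity import t_score, tw_matrix

#: Confidence level -> average Tw cutoff for gene networks, calibrated on
#: full-size GO Biological Process / Human Phenotype Ontology collections
#: (terms of 3-300 genes, random lists of 10-1000 genes).
BUILTIN_TW_CUTOFFS: dict[str, dict[float, float]] = {
    "gobp": {0.01: 0.58, 0.05: 0.30, 0.10: 0.23, 0.15: 0.19},
    "hpo": {0.01: 0.26, 0.05: 0.16, 0.10: 0.12, 0.15: 0.10},
}

#: Confidence level -> average T cutoff for ontology clustering, same
#: calibration conditions over random term lists.
BUILTIN_T_CUTOFFS: dict[str, dict[float, float]] = {
    "gobp": {0.01: 0.146, 0.05: 0.086, 0.10: 0.068, 0.15: 0.057},
    "hpo": {0.01: 0.204, 0.05: 0.116, 0.10: 0.090, 0.15: 0.076},
}

DEFAULT_PERCENTILES = (1, 5, 10, 15)
#: confidence level shorthand: top-k% -> k/100
PERCENTILE_TO_CONFIDENCE = {1: 0.01, 5: 0.05, 10: 0.10, 15: 0.15}


@dataclass(frozen=True)
class CutoffTable:
    """Confidence level -> average similarity cutoff for one collection."""

    metric: str  # "Tw" (gene networks) or "T" (ontology clustering)
    collection_label: str
    cutoffs: Mapping[float, float]
    sizes: tuple[int, ...] = ()
    n_reps: int = 0
    seed: int | None = None

    def cutoff_for(self, confidence: float) -> float:
        if confidence not in self.cutoffs:
            raise KeyError(
                f"confidence {confidence} not calibrated; have {sorted(self.cutoffs)}"
            )
        return self.cutoffs[confidence]

    def to_json(self, path: str | Path) -> None:
        data = {
            "metric": self.metric,
            "collection_label": self.collection_label,
            "cutoffs": {repr(k): v for k, v in sorted(self.cutoffs.items())},
            "sizes": list(self.sizes),
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutoffTable":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(
            metric=data["metric"],
            collection_label=data["collection_label"],
            cutoffs={float(k): float(v) for k, v in data["cutoffs"].items()},
            sizes=tuple(data.get("sizes", ())),
            n_reps=int(data.get("n_reps", 0)),
            seed=data.get("seed"),
        )


def builtin_cutoff_table(label: str, metric: str = "Tw") -> CutoffTable:
    """The shipped confidence map for 'gobp' or 'hpo'."""
    maps = BUILTIN_TW_CUTOFFS if metric == "Tw" else BUILTIN_T_CUTOFFS
    if label not in maps:
        raise KeyError(f"no built-in cutoff table {label!r}; have {sorted(maps)}")
    return CutoffTable(metric=metric, collection_label=label, cutoffs=dict(maps[label]))


def _validate_sizes(sizes: Sequence[int], limit: int, what: str) -> list[int]:
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if not (10 <= s <= 1000):
            raise ValueError(f"{what} sizes must lie in [10, 1000], got {s}")
        if s > limit:
            raise ValueError(f"{what} size {s} exceeds available pool of {limit}")
    if not sizes:
        raise ValueError(f"no {what} sizes given")
    return sizes


def _quantile_cutoffs(values: np.ndarray, percentiles: Sequence[int]) -> dict[int, float]:
    """Empirical (1 - k/100) quantile of the positive-score distribution,
    linear interpolation."""
    return {
        k: float(np.quantile(values, 1.0 - k / 100.0, method="linear"))
        for k in percentiles
    }


def calibrate_cutoffs(
    collection: GeneSetCollection,
    sizes: Sequence[int] = (10, 50, 100, 500, 1000),
    n_reps: int = 10,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    seed: int = 0,
) -> CutoffTable:
    """Average top-k% Tw cutoffs over random gene lists of the given sizes.

    For each size and replicate a gene list is drawn uniformly without
    replacement from the collection universe, enrichment weights are
    computed, and the (1 - k/100) quantile of the positive pairwise Tw
    scores is recorded; cutoffs are averaged over all samples. Deterministic
    under a fixed seed.
    """
    sizes = _validate_sizes(sizes, len(collection.universe), "gene list")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(collection.universe))
    per_percentile: dict[int, list[float]] = {k: [] for k in percentiles}
    for size in sizes:
        for _ in range(n_reps):
            genes = list(rng.choice(universe, size=size, replace=False))
            table = fisher_enrichment(genes, collection)
            profiles = build_profiles(collection, genes)
            tw = tw_matrix(genes, profiles, table.weights())
            iu = np.triu_indices(len(genes), k=1)
            vals = tw[iu]
            vals = vals[vals > 0]
            if vals.size == 0:
                continue
            for k, c in _quantile_cutoffs(vals, percentiles).items():
                per_percentile[k].append(c)
    cutoffs = {
        PERCENTILE_TO_CONFIDENCE.get(k, k / 100.0): float(np.mean(v))
        for k, v in per_percentile.items()
        if v
    }
    return CutoffTable(
        metric="Tw",
        collection_label=collection.source_label,
        cutoffs=cutoffs,
        sizes=tuple(sizes),
        n_reps=n_reps,
        seed=seed,
    )


def calibrate_t_cutoffs(
    collection: GeneSetCollection,
    sizes: Sequence[int] = (10, 50, 100, 500, 1000),
    n_reps: int = 10,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    seed: int = 0,
) -> CutoffTable:
    """Average top-k% plain-Tanimoto cutoffs over random term lists.

    Same procedure as :func:`calibrate_cutoffs` but sampling term lists
    from the collection and scoring pairwise term-term Tanimoto.
    """
    all_terms = sorted(collection.terms)
    sizes = _validate_sizes(sizes, len(all_terms), "term list")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    per_percentile: dict[int, list[float]] = {k: [] for k in percentiles}
    for size in sizes:
        for _ in range(n_reps):
            terms = list(rng.choice(np.array(all_terms), size=size, replace=False))
            gene_sets = [collection.terms[t].genes for t in terms]
            vals = []
            for i in range(len(terms)):
                for j in range(i + 1, len(terms)):
                    t = t_score(gene_sets[i], gene_sets[j])
                    if t > 0:
                        vals.append(t)
            if not vals:
                continue
            for k, c in _quantile_cutoffs(np.array(vals), percentiles).items():
                per_percentile[k].append(c)
    cutoffs = {
        PERCENTILE_TO_CONFIDENCE.get(k, k / 100.0): float(np.mean(v))
        for k, v in per_percentile.items()
        if v
    }
    return CutoffTable(
        metric="T",
        collection_label=collection.source_label,
        cutoffs=cutoffs,
        sizes=tuple(sizes),
        n_reps=n_reps,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """A synthetic collection and gene list with a known planted partition."""

    collection: GeneSetCollection
    gene_list: tuple[str, ...]
    planted_modules: Mapping[str, frozenset[str]]
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def module_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.planted_modules.values():
            out |= genes
        return frozenset(out)

    def truth_labels(self) -> dict[str, int]:
        """gene -> planted module index (module genes only)."""
        labels = {}
        for mi, name in enumerate(sorted(self.planted_modules)):
            for g in self.planted_modules[name]:
                labels[g] = mi
        return labels


def make_synthetic(
    k: int = 3,
    module_size: int = 10,
    n_background: int = 30,
    n_filler: int = 160,
    terms_per_module: int = 6,
    n_noise_terms: int = 40,
    noise_term_size: tuple[int, int] = (5, 30),
    within_rate: float = 0.9,
    noise_rate: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a collection with k planted gene modules plus background noise.

    Each module gets ``terms_per_module`` dedicated terms: the first
    contains the whole module; the rest include each module gene with
    probability ``within_rate`` and, when ``noise_rate > 0``, a
    Binomial(module_size, noise_rate) number of contaminant genes drawn
    from outside the module. When ``noise_rate > 0``, ``n_noise_terms``
    additional terms of uniform-random membership (sizes drawn from
    ``noise_term_size``) connect background and filler genes at random; at
    ``noise_rate = 0`` the collection contains only the dedicated terms, so
    cross-module Tw is exactly 0 and background genes are isolated.

    The emitted gene list is the module genes plus the background genes;
    filler genes pad the universe only. The true partition is returned for
    recovery scoring.
    """
    if min(k, module_size, n_background, terms_per_module) < 1:
        raise ValueError("k, module_size, n_background, terms_per_module must be >= 1")
    if module_size > 300:
        raise ValueError(f"module_size {module_size} exceeds the 300-gene term cap")
    if not (0.0 < within_rate <= 1.0) or not (0.0 <= noise_rate <= 1.0):
        raise ValueError("rates must satisfy 0 < within_rate <= 1, 0 <= noise_rate <= 1")
    lo, hi = noise_term_size
    if not (3 <= lo <= hi <= 300):
        raise ValueError(f"noise_term_size must lie within [3, 300], got {noise_term_size}")
    rng = np.random.default_rng(seed)

    modules = {
        f"module_{i + 1}": frozenset(
            f"M{i + 1:02d}_G{j:03d}" for j in range(module_size)
        )
        for i in range(k)
    }
    background = [f"BG{j:03d}" for j in range(n_background)]
    filler = [f"FX{j:03d}" for j in range(n_filler)]
    all_genes = sorted(set().union(*modules.values())) + background + filler

    terms: dict[str, GeneSet] = {}
    for i, name in enumerate(sorted(modules)):
        mod_genes = sorted(modules[name])
        outside = [g for g in all_genes if g not in modules[name]]
        for t in range(terms_per_module):
            tid = f"MOD{i + 1}_T{t:02d}"
            if t == 0:
                members = set(mod_genes)
            else:
                mask = rng.random(len(mod_genes)) < within_rate
                members = {g for g, m in zip(mod_genes, mask) if m}
                while len(members) < 3:
                    members.add(mod_genes[int(rng.integers(len(mod_genes)))])
            if noise_rate > 0:
                n_contam = int(rng.binomial(module_size, noise_rate))
                if n_contam:
                    members |= set(
                        rng.choice(np.array(outside), size=n_contam, replace=False)
                    )
            terms[tid] = GeneSet(description=f"dedicated term {t} of {name}", genes=frozenset(members))
    if noise_rate > 0:
        pool = np.array(all_genes)
        for t in range(n_noise_terms):
            size = int(rng.integers(lo, hi + 1))
            members = frozenset(rng.choice(pool, size=size, replace=False))
            terms[f"NOISE_T{t:02d}"] = GeneSet(description="random background term", genes=members)

    universe = frozenset().union(*(gs.genes for gs in terms.values())) | frozenset(all_genes)
    collection = filter_by_size(
        GeneSetCollection(terms=terms, universe=universe, source_label="synthetic")
    )
    gene_list = tuple(sorted(set().union(*modules.values()))) + tuple(background)
    params = {
        "k": k,
        "module_size": module_size,
        "n_background": n_background,
        "n_filler": n_filler,
        "terms_per_module": terms_per_module,
        "n_noise_terms": n_noise_terms,
        "noise_term_size": list(noise_term_size),
        "within_rate": within_rate,
        "noise_rate": noise_rate,
    }
    return SyntheticTruth(
        collection=collection,
        gene_list=gene_list,
        planted_modules=modules,
        params=params,
        seed=seed,
    )


def predicted_labels(
    subnetworks: Sequence, truth: SyntheticTruth
) -> tuple[list[int], list[int]]:
    """Align decomposed components with the planted partition for scoring.

    Returns (true_labels, predicted_labels) over the planted module genes;
    genes falling in no returned component get unique singleton labels.
    """
    truth_map = truth.truth_labels()
    genes = sorted(truth_map)
    comp_of: dict[str, int] = {}
    for ci, sub in enumerate(subnetworks):
        for g in sub.genes:
            comp_of[g] = ci
    next_label = len(subnetworks)
    pred = []
    for g in genes:
        if g in comp_of:
            pred.append(comp_of[g])
        else:
            pred.append(next_label)
            next_label += 1
    return [truth_map[g] for g in genes], pred


def save_synthetic(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Serialize a synthetic benchmark: collection.gmt, genes.csv, truth.json."""
    from .genesets import write_gmt
    from .io import GeneListEntry, GeneListInput, write_gene_list_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": outdir / "collection.gmt",
        "csv": outdir / "genes.csv",
        "truth": outdir / "truth.json",
    }
    write_gmt(truth.collection, paths["gmt"])
    entries = tuple(GeneListEntry(gene=g) for g in truth.gene_list)
    write_gene_list_csv(GeneListInput(list_id="synthetic", entries=entries), paths["csv"])
    data = {
        "seed": truth.seed,
        "params": dict(truth.params),
        "planted_modules": {
            name: sorted(genes) for name, genes in truth.planted_modules.items()
        },
        "gene_list": list(truth.gene_list),
    }
    with paths["truth"].open("w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
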