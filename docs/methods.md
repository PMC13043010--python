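# Methods

## Model

`ontonet` treats a gene-set collection as a flat statistical resource
that is re-weighted for every input gene list. Terms are plain gene sets
(3–300 members after size filtering; the ontology graph is deliberately
ignored). For a list *L* drawn from a background universe of size *N*,
each term *t* of size *K* with overlap *k* ≥ 1 receives the one-sided
Fisher exact P-value

P_t = P(X ≥ k),  X ~ Hypergeometric(N, K, |L|),

and the weight w_t = −log(P_t). P-values are used as weighting factors
rather than standalone tests, so no multiple-testing correction is
applied; terms with zero overlap carry no weight and therefore no edge.

The edge metric between genes G₁, G₂ with table-restricted term profiles
A, B is the weighted Tanimoto (weighted Jaccard)

Tw(G₁,G₂) = Σ_{t∈A∩B} w_t / Σ_{t∈A∪B} w_t,

which is symmetric, bounded in [0,1], invariant to rescaling all weights,
and reduces to the plain Jaccard index when all weights are equal. The
restriction of profiles to table terms loses nothing for list genes:
every term containing a list gene has overlap ≥ 1. Each shared term's
contribution to an edge is w_t normalised over the shared terms, and a
term's total Tw is Σ_edges contribution × Tw — chosen (over summing raw
contribution fractions, which is kept behind `mode="fraction"`) so that
term totals conserve the network's total edge weight exactly. 1/Tw serves
as the target edge length in drawings.

Term–term similarity is the plain Tanimoto T = |∩|/|∪| over member
genes; it drives both the redundancy filter in representative-term
selection and ontology clustering (connected components of the T-graph
above a threshold).

## Assumptions

- Gene identifiers match by exact, case-sensitive string equality;
  alias/ID mapping belongs upstream.
- The background universe defaults to the union of annotated genes
  ("annotated" mode); a user-supplied integer universe ("fixed_n") is
  available since enrichment conventions differ on this point and the
  choice shifts every P-value.
- Size filtering (3–300) happens before enrichment and profile
  construction, so excluded terms contribute neither weights nor edges;
  the universe is not shrunk by filtering.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| log base | 10 | scale of −log(P) weights; Tw is invariant to it per-table, but it must be consistent wherever weights from different tables mix |
| p_floor | 1e-300 | clamp before −log, keeps weights finite under underflow without affecting ranking |
| tw_cutoff | 0 | edges kept strictly above the cutoff; 0 keeps every positive edge |
| confidence levels | 0.01/0.05/0.10/0.15 | top-1/5/10/15% of the positive random-list Tw distribution |
| representative criteria | −log₁₀P > 2, total Tw > 1, pairwise T < 0.3 | strict bounds; candidates ordered by total Tw, then −logP, then term id |
| optimal-subnet scan | step 0.05, labeled ratio > 0.8, ≥ 2 terms | ties resolve toward the higher (more stringent) threshold, then more terms |
| consensus method | chisq | Fisher's combined probability, χ² with 2n d.f. |
| cross-edge policy | pairwise | see below |
| gene-list cap | 1000 entries | longer lists truncated with a warning (strict mode rejects) |

All thresholds are strict inequalities (Tw > cutoff, node count > min),
matching how the decomposition criteria are conventionally stated.

## P-value combination across lists

For n lists, t = −2 Σ ln Pᵢ is referred to the χ² upper tail with 2n
degrees of freedom ("chisq"). A two-list shortcut ("mean_log") defines
the combined weight as the arithmetic mean of the two −log P weights,
i.e. the combined P is the geometric mean √(P₁P₂). These are different
statistics: the χ²₄ tail of t is e^(−t/2)(1+t/2), not the geometric
mean. Both conventions appear in practice, so both are implemented and
the default is the chi-square form; "mean_log" is restricted to exactly
two lists. In a consensus network, an edge whose genes share a list uses
that list's own weights (lowest-index shared list); an edge between
genes of different lists uses the combined weights of the two lists
involved, with absent P-values treated as 1. Whether cross-list edges
should instead use the all-list combination is a genuinely open design
point, so the alternative ships as `cross_policy="global_consensus"`.

## Cutoff calibration

The Tw scale depends strongly on the collection's coverage and overlap
structure, so fixed cutoffs are meaningless across collections.
`calibrate_cutoffs` samples gene lists uniformly without replacement
from the universe (sizes in [10, 1000], default 10 replicates each),
computes the full positive pairwise-Tw distribution per list, records
its empirical (1 − k/100) quantiles (linear interpolation — the
estimator is a free choice), and averages each percentile over all
samples. `calibrate_t_cutoffs` does the same over random term lists with
plain T. Shipped built-in maps ("gobp", "hpo") carry cutoffs calibrated
on full-size GO-Biological-Process- and HPO-scale collections, e.g. Tw
0.58/0.30/0.23/0.19 at the 1/5/10/15% levels for GOBP-scale data;
recalibration on the user's own collection is always preferable and is
one CLI command. On structureless collections the cutoffs drift slightly
downward as list size grows (larger lists dilute shared-term structure);
collections with strong planted structure can show the opposite trend,
which is why the monotone-in-size check is asserted only as a weak trend
on random collections.

## Synthetic benchmark generator

`make_synthetic` emulates the one property of real list/collection pairs
that the method exploits: groups of genes that co-occur in several
dedicated terms, embedded in a background of weakly structured
annotation. Defaults: k = 3 disjoint modules of 10 genes, 6 dedicated
terms per module (membership rate 0.9, the first term complete), 30
background list genes, 160 filler genes padding the universe, 40
uniform-random noise terms of 5–30 genes, and a contamination rate of
0.1 (each dedicated term picks ~Binomial(10, 0.1) out-of-module genes).
These sizes keep a full pipeline run around a second while leaving the
module/background contrast realistic rather than trivial: background
genes do form noise-term edges, and contaminated terms create weak
cross-module edges that only a calibrated cutoff removes. At zero noise
the construction forces disjoint profiles, so cross-module Tw is exactly
0 and decomposition at any positive threshold returns exactly the
planted modules.

What the generator does **not** emulate: the heavy-tailed term-size
distribution and the hierarchical term nesting of real ontologies,
annotation bias toward well-studied genes, and correlated
(non-uniform) gene lists. Passing the planted-recovery checks therefore
demonstrates that the pipeline's statistics and graph machinery are
correct, not that any particular biological collection will decompose
cleanly.

## Numerical choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the test
  suite checks them against exact integer-arithmetic tail sums
  (`math.comb`) for every table up to a 60-gene universe at 1e−10
  relative tolerance.
- Base-10 weights use `math.log10` directly (so P = 0.01 gives exactly
  2.0); other bases divide natural logs.
- Every floating-point accumulation over a set (Tw numerators and
  denominators, per-gene weight sums) iterates in sorted term order, so
  outputs are bit-identical across processes regardless of Python's
  per-process string-hash randomisation. All randomness flows through
  `numpy.random.default_rng(seed)`.
- Ties: edges are generated in lexicographic gene-pair order; components
  sort by size then smallest member; representative candidates by total
  Tw, −logP, term id; dominant terms by coverage, −logP, term id; the
  optimal-subnet scan prefers larger, then more stringent, then
  better-labeled components.
- Degenerate inputs: a zero-weight union gives Tw = 0 (no edge); an
  empty representative selection and a "no optimal subnet" result
  (`None`) are legal outcomes, not errors; unknown terms in total-Tw
  queries return 0 with a warning.

## Limitations

- The optimal-subnet criteria (> 80% labeling, ≥ 2 non-redundant terms)
  are conservative: networks whose components are each dominated by one
  term family legitimately return no optimal subnetwork, as happens on
  some synthetic draws.
- Built-in confidence maps apply only to collections of roughly GOBP/HPO
  scale and overlap structure; for anything else they are a starting
  point and recalibration is required.
- Consensus networks treat a gene present in several lists as one node;
  list-specific attribute conflicts resolve to the first list's value.
- Layout coordinates are presentation-only and carry no analytic
  guarantee beyond seed determinism and Tw-proportional attraction.
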