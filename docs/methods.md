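# Methods

## The model

`herbnet` treats a plant's recorded efficacy as a probability distribution
over a phenotype concept hierarchy and asks which constituent compounds
explain shared efficacy across plants. The pipeline has four stages —
diffusion, clustering, enrichment, effect mapping — each with a small number
of interpretable parameters.

### Phenotype network and edge weights

The hierarchy is parsed from broader/narrower (RB/RN) relation rows. By
default an RB row `(c1, RB, c2)` states that `c2` is broader than `c1`; the
orientation is a config flag because relation tables in the wild disagree on
it. Cycles (which occur in real terminologies) are broken deterministically:
a depth-first traversal ordered by concept ID drops the first back-edge it
meets, so a given input always yields the same DAG. Multiple parentless
concepts are joined under a virtual root.

Depth counts nodes on the shortest root path with `depth(root) = 1`; paths
count edges. The node-counting convention keeps root-adjacent edges at
positive weight (with edge-counting depth the root's edges would weigh 0 and
diffusion could never cross them). Edge weights are the Wu–Palmer similarity
of the endpoints; for a parent at depth `d` and its child this is
`2d/(1+2d)`, strictly increasing in `d`, which encodes the intuition that an
edge between *diabetes mellitus* and *diabetic retinopathy* is a far smaller
semantic step than one between *disease* and *inflammation*.

Two conventions deserve note on multi-parent DAGs (trees are unaffected):

- `lcs` is the deepest common ancestor with a lexicographic tie-break.
- With shortest-path depths a *proper ancestor* can sit deeper than its
  descendant, and scoring through the deepest common ancestor would then
  violate `sim(c, c) = 1`. `wup_similarity` therefore scores through the
  common ancestor that maximizes the similarity, which coincides with the
  deepest common ancestor on trees and restores the identity axiom in
  general.

### Random walk with restart

Written as `p_{t+1} = (1−r)·W·p_t + r·p₀`, where `W` is the column-normalized
weighted adjacency (hierarchy edges traversable in both directions; isolated
concepts get a unit self-loop) and `p₀` spreads unit mass uniformly over the
plant's mapped efficacy concepts. The column-stochastic operator multiplies
the probability vector directly, so total mass is conserved and steady
states are probability distributions; applying the transpose instead would
leak mass on any network with unequal degrees. `r = 0.7` keeps ~70% of the
mass on and near the seeds — diffusion refines an annotation, it does not
replace it.

Convergence uses the L1 norm (scale-invariant for probability vectors) at
tolerance 1e-8, with a 10,000-iteration cap. For networks up to 2,000
concepts the fixed point is solved directly as
`p = r·(I − (1−r)·W)⁻¹·p₀`; larger networks use sparse iteration. Both
routes agree to well below the convergence tolerance and the iterative
solver is kept as an independently tested oracle.

The phenotype vector is the raw restriction of the steady state to the
ordered universe, with no renormalization: a plant whose efficacy lies
mostly outside the universe *should* have a flatter, smaller vector than one
annotated inside it, and renormalizing would erase that comparability.

The "no-hierarchy" control replaces diffusion with binary indicator vectors
of the direct annotations; everything downstream is unchanged.

### Clustering and cluster support

Average-linkage agglomeration on cosine distance (scipy's implementation)
follows the conventions of pvclust, whose multiscale bootstrap this module
re-implements: for scale factors s ∈ {0.5, 0.6, …, 1.4}, draw 1,000
resamples of `round(s·P)` phenotype columns with replacement, recluster, and
record for every original dendrogram node the fraction of resampled trees
containing its exact member set — the bootstrap probability bp(s). The AU
p-value extrapolates bp to infinite sample size by weighted least squares on
the probit scale, `z(s) = Φ⁻¹(1−bp(s)) = v·√s + c/√s`, with weights from the
binomial variance of bp propagated through the probit, and
`AU = 1 − Φ(v − c)`.

Scales where bp sits at 0 or 1 carry no quantile information (the cluster is
always or never found); they are excluded from the fit, and if fewer than
two informative scales remain the AU is the majority-side limit (1 for a
cluster present in essentially every resample, 0 otherwise). Fitting clamped
pseudo-counts instead would flatten the z-curve and drag a perfectly
reproducible cluster toward AU ≈ 0.5, which is both wrong and incompatible
with pvclust's handling. Degenerate fits are flagged with an infinite fit
error.

Selected clusters are the maximal non-root nodes with AU ≥ 0.95: nested
significant nodes are absorbed by their outermost significant ancestor, so
the reported clusters are disjoint.

A practical consequence, visible on clean synthetic data: when the themes
themselves are tight, the merge order *above* the theme level is also stable
under resampling, so the maximal rule can return a supported supercluster
that absorbs two or more themes. This is correct behavior of the maximal
rule, not a support artifact — each theme's own node typically remains
individually supported. The recovery analysis (`herbnet.recovery`) therefore
reads out planted-theme recovery at the node level (is the theme's exact
plant set AU-supported?) and performs theme-level enrichment in the
supported node with maximal Jaccard overlap to the theme, while the pipeline
proper keeps the maximal disjoint clusters.

### Enrichment and effect mapping

For each supported cluster, each compound present in at least one member is
tested with a one-sided Fisher's exact test (hypergeometric upper tail) on
(in-cluster vs out-of-cluster) × (has vs lacks compound). One-sided because
the question is enrichment; depletion is not evidence that a cluster's
efficacy belongs to a compound. Raw p-values are compared to α = 0.001 with
no multiplicity correction — the threshold itself is the tuned,
reported knob. Predicted effects are the arithmetic mean of the cluster
members' phenotype vectors; a compound enriched in several clusters takes
the element-wise maximum over its cluster means (configurable to mean), so
no cluster's signal is diluted by another's. Associations with score ≥ 0.20
are reported, sorted by score with deterministic tie-breaks.

### Evaluation

AUROC is the tie-corrected normalized Mann–Whitney statistic; AUPR is the
non-interpolated step rule (mean over positives of precision at that
positive's rank) over a deterministic ranking (score descending, item ID
ascending on ties). Metrics are averaged per compound (ranking phenotypes)
or per phenotype (ranking compounds); units lacking both a positive and a
negative are skipped and counted. Negatives are all universe items not
labelled positive for the unit — the standard are positive-only data, so
unlabelled pairs are treated as negative, which if anything understates
performance. The F1 threshold scan binarizes scored pairs at thresholds
0–0.95 in steps of 0.05 and returns the smallest arg-max threshold.
Spearman rank correlation and top-10% Tanimoto overlap compare two methods'
rankings. The network-proximity ("target-closeness") baseline scores a
compound–phenotype pair by the mean shortest-path distance from each
compound target gene to the nearest phenotype gene on the largest connected
component of a PPI graph, with a uniform-random permutation null
(degree-matched nulls are out of scope and noted as such).

## The synthetic generator

`herbnet.synthgen` emulates the statistical shape of a herbal knowledge
base, not its scale. Defaults, chosen once as the benchmark condition:

| parameter | default | meaning |
|---|---|---|
| tree_depth / branching | 4 / 3 | complete phenotype tree, 40 concepts, universe 39 |
| n_themes | 5 | disjoint subtrees two levels below the root (of 9 candidates) |
| plants_per_theme | 8 | 40 plants total |
| annotations_per_plant | 4 | distinct draws from the theme subtree |
| annotation_noise ε | 0.1 | per-annotation chance of a uniform universe draw |
| compounds_per_theme | 3 | truth: compound → its theme's phenotype set |
| p_in / p_out | 0.9 / 0.05 | compound presence in theme vs non-theme plants |
| background compounds | 30 at q = 0.3 | uniform presence, no planted effect |

Themes sit two levels below the root because that is the shallowest level
with enough disjoint subtrees for five themes. Annotations are distinct
concepts per plant (a plant's efficacy is a set of indications, which is
also how the pipeline consumes it); i.i.d. draws with replacement were
considered and rejected because at these sizes they generate within-theme
annotation outliers that contradict the generator's own contract of a
recoverable signal. All randomness flows from one seed through named
substreams (themes, plants, compounds), so stages regenerate independently.

What the generator does *not* emulate: the scale of a real terminology
(~786k concepts), multi-parent phenotype concepts (a DAG variant exists for
hierarchy stress tests only), realistic phytochemical co-occurrence, or
annotation biases of curated databases. Passing recovery tests therefore
demonstrates internal correctness of the machinery under the stated
generative model, not field performance on real pharmacopoeias.

## Numerical and procedural choices

- Transition columns are validated to sum to 1 within 1e-9; steady states
  are checked to be probability vectors.
- Bootstrap resamples that zero out a row treat the affected cosine
  distances as maximal (1.0) rather than aborting the resample.
- Round-half-even is accepted in `round(s·P)`; scales yielding fewer than
  two columns are skipped with a log entry.
- Fisher tests use the hypergeometric survival function; the test suite
  verifies it against exhaustive enumeration for every table with N ≤ 20.
- The ablation comparison averages per-compound AUROC over *all* planted
  theme compounds, imputing chance level (0.5) for compounds an arm fails
  to enrich — otherwise an arm that recovers fewer compounds would be
  evaluated only on its easiest cases.
- Pipeline determinism: one integer seed drives clustering resamples
  (per-scale substreams) and the generator; rerunning a configuration
  reproduces every artifact byte for byte.

## Problem sizes

The benchmark worlds are deliberately small (40 plants × 39 phenotypes,
1,000 bootstrap resamples at 10 scales): the full pipeline runs in a few
seconds and the complete verification suite in well under a minute, while
every statistical mechanism — diffusion, multiscale bootstrap, exact tests,
ranking metrics — operates exactly as it would at database scale.

## Known limitations

- AU p-values use the two-parameter probit fit without the standard-error
  estimate of the full asymptotic theory; support values very close to the
  threshold should be read with that in mind.
- The maximal-cluster rule intentionally reports coarse clusters when the
  data support them; users wanting theme-grained clusters on clean data
  should inspect `cluster_support.tsv` for supported sub-clusters.
- The enrichment stage inherits Fisher's conservatism on small tables; with
  40 plants the attainable p-values are granular.
- No multiple-testing correction is applied, by design; interpret raw
  p-values accordingly.
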