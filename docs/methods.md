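# Methods

## Overview

`ctxgsa` interprets a differentially-expressed-gene (DEG) list in the light
of the experiment that produced it. Classical over-representation analysis
returns hundreds of enriched pathways with no notion of which ones matter
for the study at hand; this package reduces that list to a handful of
context-relevant, per-module representatives. The pipeline has four stages:

1. **Gene cluster detection.** The DEG list is restricted to a
   protein-protein interaction (PPI) network G = (V, E) with per-edge
   confidence in [0, 1]; edges at or below `min_confidence` (default 0.05,
   strict) are discarded, and STRING-style 0–1000 integer scores are
   divided by 1000 at ingest. The network is partitioned into
   non-overlapping clusters by motif-aware community detection (below).
2. **Per-cluster enrichment.** Each cluster is tested against every pathway
   in a GMT library with the one-sided hypergeometric tail; pathways with
   raw p < `alpha` (default 0.001) survive.
3. **Context screening.** A language-model stage judges each enriched
   pathway against the free-text *experimental conditions* (C_E) and
   removes contextually irrelevant ones.
4. **Summarization and scoring.** A second stage selects the single most
   representative pathway per cluster given the *research objectives*
   (C_R) and assigns a 0–10 relevance score justified by three criteria:
   contextual relevance, pathway function analysis, and gene co-expression
   analysis. Scores are banded at 5.5 (moderate) and 7.0 (high); both
   cutoffs are inclusive, a convention this package fixes since only the
   cutoff values themselves are standard.

## Motif-aware clustering

Clustering follows the motif edge-enhancement scheme (EdMot family):

* build the **triangle-motif graph** — keep an edge (u, v) iff u and v
  have at least one common neighbor (the edge lies on a triangle);
* take the `n_components` largest connected components of the motif graph
  (default 2);
* partition each selected component with the base partitioner, and
  **clique-complete** each resulting motif community on a copy of the
  original graph (edge enhancement; original edges are never removed);
* run the base partitioner on the enhanced graph;
* clusters smaller than `min_cluster_size` (default 5, the practical floor
  for enrichment) and isolated genes go into `dropped`.

The base partitioner is greedy (Clauset–Newman–Moore) modularity
agglomeration on the unweighted topology, run on a canonical
lexicographically sorted copy of the graph so ties always break the same
way — identical input implies an identical partition, with no randomness
anywhere in the stage.

Partitioning the motif components *before* clique completion is essential,
not cosmetic: a single spurious low-confidence edge between two dense
modules can land on one triangle, fusing their motif components; clique-
completing the fused component would weld the modules together and no
downstream partitioner could separate them. Completing motif
*communities* confines enhancement to genuinely dense regions. Motif
order is fixed to triangles; higher-order motifs are out of scope.

Batched edge queries: remote PPI sources cap query size (2,000 genes for
the STRING API), so longer inputs are covered by windows of 1,000 genes
advancing by 800, i.e. 200 genes shared between consecutive windows; edges
returned by several windows collapse to their maximum confidence. Edges
between genes that are never co-queried can still be missed; the overlap
mitigates but does not eliminate this.

## Enrichment test

For a cluster of size n (counted within the background universe), a
pathway with K members, and a background of N genes, the p-value is
P(X ≥ k) with X ~ Hypergeom(N, K, n). The background defaults to the
library's gene union and is overridable. Raw p-values are thresholded at
`alpha` with no multiple-testing adjustment — the filtering rule is part
of the method — but Benjamini–Hochberg adjusted values are attached to
every result for transparency. Genes outside the background universe do
not count toward the cluster size, so the test conditions on the annotated
universe.

## Language-model stages

Prompts are rendered from fixed templates with machine-stable candidate
lines (`PATHWAY: … | P_VALUE: … | OVERLAP: k/n | GENES: …`) and demand a
parseable structured answer (`PATHWAY:` / `SCORE:` / `RATIONALE:` lines,
and `VERDICT: RETAIN|REMOVE` for screening). The response parser is
tolerant of surrounding prose, clamps out-of-range scores into [0, 10]
with a warning, and raises a parse error carrying the raw text otherwise;
a term with no verdict in a screening response is conservatively retained.
Remote chat backends must run at temperature 0.0; one retry is allowed on
transient failure (determinism makes more retries pointless). Screening
verdicts are binary; a numeric screening threshold is supported in the
mock but categorical verdicts are the default contract.

**Mock backend.** The shipped backend is a deterministic rule, not a
model. Screening scores a candidate 10× the fraction of its name tokens
present in the embedded context and retains scores strictly above a floor
of 0. Summarization scores each candidate
`10 · (0.6 · ctx_frac + 0.4 · gene_frac)`, where `ctx_frac` is the same
name–context token overlap and `gene_frac` is the fraction of cluster
genes the pathway explains (read from the `OVERLAP: k/n` field — the
mock's stand-in for gene co-expression analysis); the argmax wins, ties
breaking lexicographically. The weights 0.6/0.4 keep context dominant
while letting gene support separate otherwise equally-named candidates;
they are a fixed design choice, not fitted to anything. The mock
exercises every contract of a real backend (structured output, screening
semantics, determinism) but knows nothing about biology: passing tests
show the pipeline's plumbing and logic are correct, not that a real model
would judge real pathways correctly.

## Evaluation

Predictions and ground truths are embedded and compared by cosine
similarity; matching is many-to-many at a threshold t (comparison is
inclusive, ≥ t — strict vs inclusive is immaterial at float resolution
but must be fixed):

* HIT = fraction of ground truths with at least one prediction ≥ t;
* ACC = fraction of predictions with at least one ground truth ≥ t;
* harmonic mean = 2·HIT·ACC/(HIT+ACC), defined 0 when both are 0.

ACC with zero predictions is defined as 0 and flagged. The default sweep
is t ∈ {0.5, 0.6, 0.7, 0.8, 0.9}; top-K evaluation truncates a ranked
prediction list before scoring. Encoder outputs are re-normalized to unit
length, so identical strings always score 1.0.

**Stub encoder.** Offline evaluation uses a character-trigram hashing
encoder (stable MD5 bucketing into 512 dimensions, L2-normalized). It is
deterministic across processes, maps identical strings to identical
vectors, and ranks texts sharing more trigrams as more similar — the
property the metrics need. It is not a semantic encoder: near-synonyms
with disjoint wording score low, so absolute similarity values are not
comparable to a biomedical sentence encoder's. An adapter slot accepts a
real encoder where available.

## Synthetic scenarios

`make_scenario` defines the study conditions for offline validation:

| parameter | default | meaning |
|---|---|---|
| `n_universe` | 1500 | gene universe size |
| `n_pathways` | 20 | library size; pathways are disjoint two-word terms |
| `pathway_size` | (20, 40) | per-pathway membership range |
| `n_modules` | 3 | planted modules = ground-truth pathways |
| `module_size` | 20 | genes per planted module |
| `noise_frac` | 0.1 | module members drawn from outside the pathway |
| `p_in` / `p_out` | 0.6 / 0.01 | within-module / background edge probability |
| `n_deg_noise` | 15 | unrelated genes appended to the DEG list |

These are sized so a dense functional module is unambiguous (p_in ≫
p_out), enrichment is decisive (≈18 of ≈20 module genes inside one
pathway of a ≈600-gene annotated universe), and the whole 20-seed
end-to-end recovery run completes in seconds. Pathway names are built
from disjoint token pairs and the context strings embed the planted names
verbatim — a stated test convenience that makes the mock backend's argmax
provably the planted truth, not a claim about real contexts. Edge
confidences are drawn above the ingest cutoff so filtering does not erase
planted structure. The generator emulates set structure and modular
topology only; it does not mimic real PPI degree distributions, pathway
overlap, or the semantics of real term names, so recovery results bound
plumbing correctness, not real-data accuracy.

**Contamination benchmark.** Curated sets are degraded by replacing
round(f·n) members (round-half-up; the convention for odd sizes) with
background draws, f ∈ {0, 0.5, 1}. The background pool excludes the
curated set's own genes so the nominal fraction equals the realized
fraction exactly — a deliberate, documented deviation from drawing from
the full annotated pool, which could re-sample originals and blur the
composition arithmetic the tests assert. Each row's context derives from
its term. Scoring runs enrichment directly on the contaminated set and
then the two LLM stages; a set with no significant pathway, or none
surviving screening, scores 0. Mean relevance decreases in f because
both the enrichment overlap and the name–context coherence degrade; with
the mock backend the trend is enforced qualitatively (non-increasing),
with no claim about the absolute scores a hosted model would assign.

## Numerical and degenerate-input conventions

* Duplicate edges collapse to maximum confidence; self-loops are dropped.
* Modularity of an empty edge set is defined as 0.
* An edgeless network clusters to nothing: all genes dropped, the report
  carries zero clusters and a status note, exit is clean.
* A cluster disjoint from the library universe enriches to an empty list
  with a warning rather than an error.
* Gene symbols are trimmed, uppercased, optionally alias-mapped; an alias
  mapping to several official symbols should be dropped upstream rather
  than guessed at.
* All generator randomness flows through one integer seed
  (`numpy.random.default_rng`); regeneration is bit-identical, and a full
  mock-backend run is a pure function of (inputs, config).

## Limitations

* The mock backend and stub encoder validate contracts and plumbing, not
  biological judgment; real-data performance requires real backends.
* Only non-overlapping communities are produced; directed or signed
  interactions are not modeled.
* The enrichment background defaults to the library union, which is
  conservative when the true assay universe is much larger.
* Batch-boundary edge loss for very long gene lists is mitigated, not
  eliminated, by window overlap.
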