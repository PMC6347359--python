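# Methods

## Model and procedure

The pipeline treats synthetic lethality (SL) as a property of unordered
human gene pairs and builds the SL universe from two routes:

**Orthology transfer.** A yeast double-knockout screen reports, per gene
pair, a genetic-interaction score ε (negative = aggravating) and a
p-value. Pairs with ε < −0.08 **and** p < 0.05 are retained as yeast SL
pairs; both inequalities are strict and both thresholds are configurable
(`filter_negative_interactions`). Strictness matters only for records
exactly at a cutoff and is the convention used throughout. Ortholog
tables from several resources are unioned per yeast gene; a yeast pair
(y1, y2) becomes every human pair (h1, h2) with h1 ∈ image(y1),
h2 ∈ image(y2), h1 ≠ h2. One-to-many orthology therefore expands to the
full cross-product; a pair with an unmapped endpoint contributes nothing.
Reciprocal duplicates are collapsed both before and after mapping (the
order of deduplication cannot change the result, since mapping commutes
with canonicalization).

**Computational inference.** Each candidate pair is described by ten
features:

* Dice coefficients 2|A∩B|/(|A|+|B|) of the endpoints' term sets in five
  annotation namespaces (two pathway vocabularies, a GO slim, disease
  terms, drug associations). Dice of two empty sets is defined as 0 — no
  evidence of similarity — not 1.
* Endpoint means of four node statistics on the gene-interaction network:
  degree; betweenness (unnormalized Brandes pair count, endpoints
  excluded — the 3-node path's middle node scores exactly 1); closeness
  (component-restricted, scaled by component size, hence in [0, 1]);
  local clustering coefficient (0 for degree < 2).
* Shortest-path hop count, with disconnected pairs assigned the sentinel
  `n_nodes` — one more than any realizable path, keeping the feature
  finite and ordinal. Hop count is used rather than any weighted
  distance; the network is unweighted.

Only relative feature values feed the classifier, so the choice of
normalization conventions is documented and frozen rather than
fine-tuned; the feature order is versioned
(`synletcombo-features-v1`) in feature files and model artifacts, and a
version mismatch is a hard error rather than a silent misprediction.

The modeling universe is restricted to *fully annotated* genes (non-empty
term set in all five namespaces); a permissive mode treats missing
namespaces as empty sets. Negatives are sampled uniformly, without
replacement and seeded, among pairs of fully annotated genes that appear
in **no** known SL pair, one negative per positive (balanced design).
Training uses a 2/3–1/3 class-stratified split (per-class counts in each
half differ by at most one) and a random forest whose ensemble size is
chosen from {25, 50, 93, 150, 300} by mean 10-fold cross-validated
accuracy, ties to the smallest ensemble. Per-tree hyperparameters stay at
scikit-learn defaults and are recorded in the artifact; the tuning grid
is configurable. Test metrics come from the confusion matrix at a 0.5
score threshold; ratios with zero denominators are reported as a
`None` ("not applicable") sentinel, never as 0. AUC is the Mann–Whitney
rank statistic with midranks for ties. Prediction applies the fitted
forest to all candidate pairs (default: unordered pairs of fully
annotated genes not already known SL; the universe is configurable) at a
0.5 threshold. Merging the yeast-derived and predicted sets is a set
union in which a pair supported by both routes keeps both provenance
tags.

## Combination screening

Trials are retained when **all** of: phase ∈ {III, IV}; interventional
study type; at least one condition entry equal (case-insensitive, exact
string — not substring — match) to one of six controlled
ovarian-cancer condition terms; at least one arm with ≥ 2
drugs/biologicals. Exact matching deliberately rejects, e.g., a
hypertension study that merely enrolls ovarian-cancer patients. Arm drug
names resolve through a synonym table, case-insensitively; unresolvable
names warn and never abort, and an arm is skipped only when fewer than
two resolvable drugs remain. A combination studied in several arms of one
trial counts that trial once. Combinations of more than two drugs expand
to all C(n, 2) pairs.

A drug pair *addresses* an SL pair when each drug directly targets one
endpoint and **no** drug in the full tested-with-protein-targets universe
targets both endpoints (a single covering drug would address the pair
alone). The exclusion is scoped to the whole tested drug universe, not
just the pair under evaluation. Drugs without protein targets (DNA
crosslinkers and the like) are excluded up front, since SL pairs are
protein-coding by definition. Target mechanism (inhibition vs substrate)
is ignored. Novel proposals enumerate all unordered pairs of tested,
protein-targeted drugs absent from the tested pairs, under the same
matching rule. Matches are stored with gene endpoints in canonical
(lexicographic) order and the drugs assigned to follow the genes.

Ranking sorts matches by annotation degree — the sum of the two SL
partners' per-gene publication counts in the disease context — with a
deterministic tie-break on (gene_a, gene_b, drug_a, drug_b); missing
counts are 0 with a warning. Each drug-pair × SL-pair match is its own
output row.

## Synthetic worlds

The generators emulate the statistical structure the classifier assumes —
SL pairs share more annotation and sit closer in the network — without
reproducing any real corpus's marginals:

* **Network**: Erdős–Rényi at `edge_density` over `n_genes` genes; each
  planted SL pair is, with probability `topology_boost` (default 0.9),
  wired to a shared random neighbor, bounding its distance by two hops.
* **Annotations**: per namespace, 1 + Poisson(`terms_per_gene` − 1) terms
  from a vocabulary of `vocab_size`; each SL pair receives
  Poisson(`annotation_overlap_boost`) extra shared terms per namespace
  (default boost 2.0, the value at which the mean Dice gap between SL and
  random pairs clearly exceeds 0.1; boost 0 yields a null world with no
  gap). SL endpoints are always fully annotated; other genes at
  `full_annotation_rate` (default 0.9).
* **Yeast screen**: planted pairs draw ε < −0.08 and p < 0.05 by
  construction; fillers draw ε ~ N(0, 0.05), p ~ U(0, 1), so ~0.3 % pass
  by chance. The generator records its own pass-set by reapplying the
  cutoffs row by row, giving the filter an independent oracle.
* **Drug/trial corpus**: random drugs (some with no protein target, as
  DNA-only-agent analogues); `n_planted_combos` SL pairs whose endpoints
  no drug co-targets each get a dedicated single-target drug pair and one
  valid late-phase trial; distractor trials each violate exactly one
  filter rule; filler trials are valid with random arms. Recovery of
  every planting is guaranteed by construction and verified end to end.

Every generator draws from an independent, salted stream of the world
seed, so each world is byte-reproducible and individual generators are
independently deterministic.

**Default sizes.** The small world (200 genes, 40 SL pairs, 20 drugs,
30 trials, ~400 screen records) runs the complete pipeline in seconds and
is the default for examples and most tests. The classifier benchmark
world (700 genes, 1,000 planted SL pairs, density 0.01) supports a
2,000-instance balanced design — 1,000 positives and as many sampled
negatives — matching the scale of a balanced-training protocol with a
2/3–1/3 split and 10-fold CV; one benchmark run takes roughly 15 s.

**What passing on synthetic worlds shows — and does not.** The planted
worlds verify that the pipeline recovers signal it is pointed at, that a
matched null stays at chance, and that all bookkeeping (canonical pairs,
exclusion rules, provenance, determinism) is exact. They say nothing
about how strongly *real* annotation and topology separate real SL pairs:
the generators use independent random term sets and an Erdős–Rényi
backbone, not the heavy-tailed degree distributions, correlated
annotations and ascertainment biases of curated resources. Null-world
accuracy sits slightly above 0.5 (~0.54 at benchmark scale) because SL
endpoint genes recur across many positive pairs, so continuous node
statistics leak a little gene identity between train and test — a known
pitfall of pair-level splits that the matched-null design makes visible
instead of hiding.

## Numerical and design choices

* Canonical pair order is lexicographic on the gene symbol; gene symbols
  are opaque, case-sensitive strings (any normalization belongs at
  ingestion).
* Cross-validated accuracies are compared after rounding to 12 decimal
  places, so float noise cannot break the ties-to-smallest rule.
* Negative sampling enumerates the candidate universe only when the
  request exceeds half of it; otherwise rejection sampling, which is
  exact and faster for sparse draws. Both paths are seeded.
* TSV writers use `%.17g` floats and readers parse with round-trip
  precision, so feature files and screens survive write/read cycles
  bit-exactly; SL sets iterate in sorted order, making output files
  byte-deterministic.
* The trial filter treats condition matching as exact string equality by
  design; substring matching would readmit exactly the confounded trials
  the controlled vocabulary exists to exclude.

## Known limitations

* SL transfer assumes yeast SL relations survive orthology; the pipeline
  propagates, but cannot test, that biological assumption.
* Annotation-degree ranking favors well-studied genes; enrichment-style
  corrections are out of scope here.
* The classifier's candidate universe in the permissive setting can be
  quadratically large; callers should restrict it (the default fully
  annotated universe does).
* Live retrieval from trial registries, drug databases, orthology
  services or literature indexes is intentionally unsupported: all
  corpora enter as files in the documented formats.
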