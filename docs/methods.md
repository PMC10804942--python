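# Methods

This note documents the models, conventions and numerical choices behind
`sensorscape`, and what the synthetic benchmarks do and do not demonstrate
about real metagenome data.

## HK identification and sensor excision

A gene is called a histidine kinase when its domain-hit set contains at
least one hit of **each** conserved accession (defaults PF02518/HATPase and
PF00512/HisKA); co-occurrence, not either/or, is required, so lone HATPase
ATPase domains from other proteins are excluded. Sensory domains are every
hit whose accession is in the curated sensor set supplied by the caller
(synthetic corpora carry their generator's accession set; real runs supply
the curated list as a text file).

Conventions and edge cases:

* **Coordinates** are 1-based and inclusive on both ends, the Pfam/HMMER
  alignment-coordinate convention, so a hit (5, 64) excises 60 residues.
  When ingesting HMMER `--domtblout`, envelope coordinates (columns 20–21)
  are used: the envelope is the region the domain plausibly occupies, and it
  is the closer analogue of a curated domain span than the alignment
  columns.
* **Overlapping sensor hits** in one gene cannot both be excised as
  disjoint substrings; the shorter of an overlapping pair is dropped (ties
  keep the earlier one) and the event is logged. Excision therefore always
  yields non-overlapping exact substrings of the protein.
* An accession in neither the conserved nor the sensor set is ignored.
* Repeated hits of the same sensor accession each yield their own domain.

## Sequence identity and greedy clustering

The clustering unit is the excised sensor-domain amino-acid sequence, first
collapsed by exact string equality (deduplication), then clustered by a
greedy incremental centroid algorithm in the CD-HIT/linclust tradition:

1. sort unique sequences longest-first (ties: lexicographic id — fully
   deterministic, no seed dependence);
2. each sequence joins the **first** (oldest) existing centroid with
   identity ≥ `min_identity` and coverage ≥ `coverage_fraction`, else founds
   a new cluster.

Identity comes from a Needleman–Wunsch global alignment scored match=1,
mismatch=0, gap=−1. Among score-optimal alignments, the one with the most
matches and then the most aligned residue pairs is selected; this is
computed without traceback by a composite-integer dynamic programme
(lexicographic (score, matches, pairs) maximisation), so the value is
deterministic even when co-optimal alignments exist. Then

* `identity = matches / alignment_columns`, with
  `alignment_columns = |a| + |b| − pairs`;
* `coverage(bidirectional) = min(pairs/|a|, pairs/|b|)`; `target` and
  `query` modes divide by one length only.

Defaults are `min_identity = 0.5` with bidirectional coverage 0.8; planted
-family benchmarks use 0.8 identity against families generated to be < 50%
identical. Quadratic DP is acceptable at desk scale (≤ a few thousand unique
sequences); no k-mer prefilter is implemented. The external-tool adapter
(`cluster_external`) shells out to an MMseqs2-compatible binary and parses
its (representative, member) TSV into the same assignment type; a missing
binary is a hard error, never a silent fallback, so results are always
attributable to the right backend.

## Profile matrix

`value(m, c)` sums the copy numbers of metagenome *m*'s genes that
contribute ≥1 domain to cluster *c*, divided by *m*'s total gene copy
number. A gene whose domains fall in *k* distinct clusters contributes its
full copy number to each of the *k* clusters (per-cluster accounting); the
same gene contributing two domains to the *same* cluster counts once. The
alternative — splitting a gene's copies across clusters — was rejected
because a multi-sensor protein genuinely carries each of its sensors. A
consequence worth knowing: row sums are per-cluster totals and can exceed
the unique-gene sensor fraction when multi-domain HKs are common. The
planted ground truth uses the same accounting, so perfect clustering
reproduces it exactly (the conservation and recovery tests assert this at
1e-9 relative tolerance and to machine precision respectively).

Filters: cluster prevalence is presence-based (value > 0, no abundance
floor), with clusters kept at ≥ `min_prevalence` samples (default 100);
sample classes are kept at **strictly more than** `min_per_class` members
(default 30; condition labels use 14), after removing labels such as
"Unclassified". Cluster filtering precedes sample filtering. No
renormalisation after filtering, and no compositional transforms (CLR etc.)
— fractions are used as-is.

## Richness statistics

RER and ETSR are computed on the **unfiltered** matrix so rare clusters
count toward the diversity picture. ETSR of a class with zero clusters is
reported as missing (NaN), never 0/0; ETSR of a single-sample ecosystem is
1 by construction. Inter-ecosystem correlation is Spearman's rank
correlation between per-class **mean** abundance vectors over the
(filtered) cluster set; a per-sample pooled alternative was considered but
mean profiles are the stabler summary at small per-class sample counts. A
class with a constant mean profile has no rank order and its pairs are
reported missing. Rare-cluster enrichment counts, per ecosystem, the
clusters present there whose total ecosystem-presence count is ≤
`rarity_max_ecosystems` (default 1 = ecosystem-unique).

## Models

The boosting backend is LightGBM run fully deterministically (single
thread, `deterministic=True`, fixed seed); the contract used — fit, predict,
per-class raw scores, exact tree-path attributions — is narrow enough that
any gradient-boosted-tree library could stand behind it. Tuned knobs
mirror the usual boosted-tree grid: learning rate, per-tree depth (leaf
count capped at 2^depth, max 64) and L2 leaf regularisation;
`min_child_samples` defaults to 5 because desk-scale corpora are small.

Evaluation protocol: stratified 70/20/10 train/test/validation split
(every class needs ≥ 3 members), exhaustive Cartesian grid search scored on
the validation set with ties broken by first-in-grid order, and the
headline metric — accuracy for classification, R² for regression — reported
on the untouched test set. The confusion matrix always covers the full
label set including zero rows, so row sums equal per-class test counts and
trace/total equals accuracy exactly. No class reweighting and no feature
selection by default. The cluster-vs-Pfam comparison trains the identical
configuration on the cluster matrix and on its Pfam-collapsed version
(cluster columns summed within each cluster's majority accession), so any
gap is attributable to feature resolution alone.

## Attributions and unsupervised views

Feature attributions are exact TreeSHAP values from the backend
(`pred_contrib`); `attribute` verifies local accuracy — Σ attributions +
base value = raw per-class score — on **every** row at 1e-6 relative
tolerance and raises on violation, making additivity a hard gate rather
than an assumption. Positive values push the model toward the class.
Rankings sum |attribution| over samples (and classes for global scope;
a signed-sum option exists), descending, ties by feature id.

Heatmap ordering: average-linkage hierarchical clustering of Euclidean
distances on log2(value + pseudocount), pseudocount = half the smallest
nonzero matrix value. Embedding: t-SNE with perplexity min(30, (n−1)/3),
deterministic given its seed. Correlated-feature groups use Spearman
correlation against an anchor cluster, top-k by |ρ|.

## Synthetic corpus generator

The generator emulates the structure of real annotation exports: per-gene
domain tables with copy numbers, sensor FASTA, and GOLD-style metadata.
The generative model per ecosystem:

* a shared pool of sensor families; centroids are uniform-random 20-letter
  sequences, rejection-sampled to pairwise identity < 0.5 so families are
  separable at the clustering threshold; family members substitute at most
  `floor(mutation_rate × length)` positions, making the ≥ (1 −
  mutation_rate) identity guarantee exact rather than in expectation;
* per-sample family weights are Dirichlet-distributed around the
  ecosystem's weights (concentration 50 by default — moderate
  sample-to-sample variability; the Dirichlet is the generator's choice of
  the simplest exchangeable compositional noise model);
* HK architecture: sensors N-terminal, then HisKA (60 aa) and HATPase
  (100 aa) spans with 5-aa linkers; sensor counts per gene are 0/1/2/3 with
  probabilities 0.15/0.50/0.25/0.10, and `inject_multidomain_hk` rewrites
  selected genes up to the 32-domain extreme seen in nature;
* gene copy numbers are geometric with mean 2, standing in for
  read-mapping abundance estimates; sensor gene counts are Poisson-scaled
  so the expected copy-weighted sensor fraction matches
  `sensor_fraction_mean` (default 0.10, within the 0.05–0.5 range typical
  of real ecosystems);
* background (non-HK) genes carry junk hits, no hits, or — for 5% — a
  single lone conserved domain, exercising the co-occurrence filter.

What the generator does **not** emulate: real Pfam domain length and
composition distributions, within-family indels (mutations are
substitution-only), phylogenetic correlation between samples, taxonomic
structure, chimeric or fragmented gene calls, and annotation noise
(missed/spurious hits). Passing the planted-recovery tests therefore shows
the machinery is correct and self-consistent, not that real corpora are as
separable; the headline accuracies on planted corpora are upper bounds by
construction.

## Problem sizes and determinism

Test and acceptance corpora use 4–10 families of 60–120 residues, 2–4
ecosystems and 10–50 metagenomes per ecosystem with ~50–150 genes per
metagenome — sizes at which the quadratic aligner and exhaustive reference
implementations (brute-force alignment recursion, full-pairwise greedy
clustering) remain exact oracles. One `numpy` Generator seeded from the
global seed drives every draw in fixed order, so a corpus is byte-identical
across runs of the same seed, and the pipeline manifest's SHA-256 checksums
for the simulate/extract/cluster/profile/metrics stages are reproducible by
contract (model stages reproduce too under the deterministic backend
settings, but only the former is asserted).

## Known limitations

* The greedy clusterer is quadratic in unique sequences per centroid scan;
  corpora beyond ~10⁴ unique sequences should use the external backend.
* Identity is match-count based with a unit gap penalty; no substitution
  matrix (BLOSUM) weighting, which would change borderline cluster
  membership for distantly related sensors.
* The pipeline's train stage is classification-only; regression runs
  through the library or the `train` CLI subcommand with `--task regress`.
* Binary classification is handled as the backend's two-class special case
  (a single margin toward the second class) rather than two softmax blocks.
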