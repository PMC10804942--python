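# sensorscape

Profiling of bacterial environmental sensing across metagenomes via sensor
histidine kinases (HKs).

Two-component-system histidine kinases are the main way prokaryotes sense
their surroundings: each HK carries the two conserved signalling domains —
HATPase (Pfam PF02518) and HisKA (PF00512) — plus zero or more *sensory*
domains (PAS, Cache, GAF, ...) that actually detect the stimulus. Because a
single Pfam sensor family can hide thousands of functionally distinct
sensors, this package clusters the excised sensor-domain *sequences* into
finer-grained sensor families and asks what the resulting per-metagenome
sensor repertoire can say about the environment the community lives in.

The pipeline, starting from domain-annotated metagenome gene tables
(IMG-style exports with per-gene copy-number estimates and GOLD-style
three-level ecosystem labels such as `Host-associated:Human:Large Intestine`):

1. **extract** — keep genes carrying ≥1 hit of *each* conserved domain, and
   excise every annotated sensor-domain subsequence (1-based inclusive
   coordinates).
2. **cluster** — deduplicate exact sequences, then greedy incremental
   centroid clustering (longest-first; a sequence joins the first centroid
   with alignment identity ≥ `min_identity` and coverage ≥
   `coverage_fraction`, else founds a cluster). An adapter for an external
   MMseqs2-compatible tool exposes the same contract.
3. **profile** — the metagenome × cluster matrix whose value is

   `f(m, c) = Σ copy_number(g in m contributing a domain to c) / total gene copies of m`,

   with prevalence filtering of clusters (present in ≥ *P* metagenomes,
   default 100) and class-size filtering of samples (> *N* per label,
   default 30 for ecosystems, 14 for disease/condition labels;
   "Unclassified" dropped).
4. **metrics** — Relative Ecosystem Richness `RER(e) = |clusters in e| /
   |clusters anywhere|`, Ecosystem Typical Sample Richness `ETSR(e) = mean
   per-sample cluster count / |clusters in e|`, per-sample sensor fractions,
   and Spearman correlations between per-ecosystem mean profiles.
5. **models** — gradient-boosted tree classification (ecosystem, condition)
   and regression (physical parameters such as temperature or pH), with a
   stratified 70/20/10 train/test/validation split and grid search over
   learning rate, tree depth and L2 leaf regularisation selected on the
   validation set; accuracy/R², per-class F1 and the confusion matrix are
   reported on the held-out test set.
6. **explain** — exact additive (Shapley-style) attributions per sample and
   class, feature rankings by summed |attribution|, log2 clustered heatmaps
   and t-SNE embeddings.

A synthetic-corpus generator with planted sensor families, Dirichlet
per-sample abundances and known ground truth makes every stage testable
end-to-end without any external download; see `docs/methods.md` for the
generative model and its limits.

## Worked example

```python
import sensorscape as ss
from sensorscape.profile import build_matrix, gene_totals_from_records
from sensorscape.ecometrics import ecosystem_metrics
from sensorscape.models import ModelConfig, SplitSpec, split, train_classifier, evaluate
from sensorscape.explain import attribute, rank_features

pool = ss.make_family_pool(6, seq_len_range=(60, 90), mutation_rate=0.05, seed=1)
specs = [
    ss.EcosystemSpec("Host-associated:Human:Large Intestine", 40, [4, 3, 1, 0, 0, 0],
                     sensor_fraction_mean=0.10, background_genes_mean=120),
    ss.EcosystemSpec("Environmental:Aquatic:Marine", 40, [0, 0, 1, 1, 3, 4],
                     sensor_fraction_mean=0.10, background_genes_mean=120),
]
corpus = ss.generate_corpus(specs, pool, global_seed=7)

hks = ss.identify_hk(corpus.genes, corpus.hk_config)
domains = [d for hk in hks
           for d in ss.excise_sensors(hk, corpus.proteins[hk.gene_id], corpus.hk_config)]
unique, mult = ss.dedup(domains)
assignment = ss.cluster_greedy(unique, ss.ClusterParams(0.8, "bidirectional", 0.8),
                               multiplicity=mult)
matrix = build_matrix(domains, assignment, gene_totals_from_records(corpus.genes),
                      corpus.metadata)

labels = matrix.meta["ecosystem"]
train_ids, test_ids, val_ids = split(labels, SplitSpec(seed=0))
cfg = ModelConfig(grid={"learning_rate": [0.1], "depth": [4], "l2_leaf_reg": [3.0]},
                  n_estimators=100)
model = train_classifier(matrix.values.loc[train_ids], labels.loc[train_ids], cfg)
report = evaluate(model, matrix.values.loc[test_ids], labels.loc[test_ids])
print(ecosystem_metrics(matrix).round(3))
print(f"test accuracy: {report.accuracy:.3f}")
print("top features:", list(rank_features(attribute(model, matrix.values.loc[test_ids])).index[:3]))
```

prints

```
10745 genes -> 1037 HK proteins -> 1427 sensor domains
1402 unique sequences -> 6 clusters
                                         rer   etsr  mean_sensor_fraction  n_samples
ecosystem
Environmental:Aquatic:Marine           0.667  0.888                 0.111         40
Host-associated:Human:Large Intestine  0.500  0.992                 0.101         40
test accuracy: 1.000
top features: ['C000001', 'C000000', 'C000002']
```

(first two lines from the extraction/clustering stage logs). The six planted
sensor families are recovered as six clusters; the gut spec draws on three
of them and the marine spec on four (one family shared), hence RER of 3/6
and 4/6; ETSR near 1 because most samples contain most
of their ecosystem's families; mean sensor fractions sit at the simulated
10% of gene copies; and the two ecosystems are perfectly separable from
their sensor profiles, with the discriminating clusters ranked first by the
attributions.

The same stages are scriptable from the shell:

```bash
sensorscape simulate --config cfg.json --seed 7 --outdir corpus/
sensorscape extract --annotations corpus/annotations.tsv --proteins corpus/proteins.faa \
    --sensor-list corpus/sensor_accessions.txt --out sensors.faa
sensorscape cluster --in sensors.faa --out clusters.tsv --min-id 0.8
sensorscape run --config pipeline.json --outdir run/      # everything + manifest
```

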