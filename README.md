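# neurowalk

Graph-embedding classification of brain functional connectomes.

`neurowalk` is for researchers who want to test whether shallow graph
embeddings of functional-connectivity networks — rather than raw
correlation values — carry diagnostic signal, and whether that signal
survives the hard test of cross-site generalization.  It implements the
full chain from ROI time series to a trained classifier:

- **Connectivity**: Pearson correlation, partial correlation, and the
  tangent-space parametrization `log(G^{-1/2} Σ G^{-1/2})` at the
  Karcher mean `G` of the training covariances;
- **Node embeddings** of the weighted 39-node connectivity graph:
  DeepWalk / node2vec (second-order biased random walks + skip-gram
  with negative sampling), struc2vec (k-hop degree sequences compared
  by dynamic time warping, accumulated into layer distances
  `w_k = w_{k-1} + d(R_k(v_i), R_k(v_j))`), and anonymous walk
  embeddings (per-node distributions over anonymized walk patterns);
- **Graph2Img**: PCA of the embedding to four components and 2-D
  binning of (PC1, PC2) and (PC3, PC4) into two 10 × 10 image channels;
- **Classifier**: a LeNet-variant CNN (64 and 96 conv filters, dense
  120/84, dropout keep 0.8, ReLU, 2-way softmax) over three input
  scenarios — a single N × d embedding, three node2vec channels at
  (p, q) = (1, 1), (1, 4), (4, 1), or the two Graph2Img channels;
- **Evaluation**: stratified k-fold and leave-one-site-out (LOSO)
  cross-validation with accuracy, precision, recall and F-score
  (`TP / (TP + (FP + FN)/2) ≡ 2PR/(P+R)`), with per-fold refitting of
  every data-dependent statistic and a built-in leakage audit.

A bundled synthetic-cohort generator emulates a multi-site two-class
study whose class difference lives in the covariance structure
(δ added to designated between-module edges) with a per-site nuisance
perturbation, so the whole pipeline is testable at desk scale without
any external data.  Everything is plain text on disk (CSV/TSV, JSON,
GraphML) and deterministic under a fixed seed.

## Worked example

```python
import neurowalk as nw

# a 4-site cohort: 10 patients + 10 controls per site, 39 ROIs,
# covariance class effect 0.4 on 20 between-module edges
cohort = nw.simulate_cohort(nw.CohortConfig(
    n_sites=4, subjects_per_site_per_class=10,
    class_effect=0.4, site_effect=0.1, seed=1,
))

cache = {}   # per-subject embeddings are reused across folds
result = nw.leave_one_site_out(
    cohort.subjects,
    lambda: nw.GraphEmbeddingPipeline(
        scenario="s3", connectivity_kind="pearson", d=25,
        walks_per_node=5, walk_length=20, window=5, epochs_sg=3,
        cnn_epochs=100, cnn_patience=None, seed=7,
        embedding_cache=cache,
    ),
)
for fold in result.folds:
    print(fold.fold_id, fold.n_subjects, fold.n_positive,
          f"{fold.metrics.accuracy:.2f}", f"{fold.metrics.fscore:.2f}")
print(f"mean accuracy {result.mean_metrics.accuracy:.3f}")
```

Output:

```
site_01 20 10 0.70 0.73
site_02 20 10 0.60 0.60
site_03 20 10 0.70 0.70
site_04 20 10 0.60 0.64
mean accuracy 0.650
```

Each row is one held-out site (site id, subjects, patients, accuracy,
F-score): the classifier never saw that site during training, so these
numbers measure cross-site generalization of the embedding-image
representation.  The mean is the unweighted average over sites.  At
this small size (20 training subjects per class) the pipeline recovers
the effect only partially; with `class_effect=0.0` the same experiment
hovers around 0.5 — it finds nothing when there is nothing to find —
and accuracy rises with cohort size and walk budget (the 200-subject
benchmark in `neurowalk.benchmarks` reaches ≈ 0.85–0.90 on its fixed
seeds).

The same run is available from the shell:

```bash
neurowalk simulate --config cohort.yaml --out data/
neurowalk run --config pipeline.yaml
```

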