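# vaxstance

Multi-modal classification of vaccine stance (vax-skeptic vs other, and
pro-vaxxer vs other) for Twitter-style collections, built around the
observation that *who talks to whom* carries stance information beyond what
the tweet text says.

The package is aimed at computational social scientists studying opinion
dynamics on social platforms. Because real tweet collections cannot be
redistributed, it ships a first-class synthetic-data generator that emulates
the statistical structure of such a collection — an attitude-homophilous
reply network with heavy-tailed degrees, a sparsely labeled tweet subset
(11.45% by default), class-conditional text vectors and region-dependent
skeptic signal — so the entire pipeline is testable end to end offline.

## The model

1. **Reply network.** Users u, v are joined by an undirected edge whenever
   either replied to the other; users with fewer than three distinct
   neighbors are pruned in a single pass.
2. **Node embedding (Walklets / DeepWalk).** Truncated random walks
   (r = 10 walks of length ℓ = 80 per node) are treated as sentences.
   Walklets extracts (center, context) pairs at offset exactly k along each
   walk — the co-occurrence statistics then approximate the k-th adjacency
   power Aᵏ — and trains one skip-gram-with-negative-sampling (SGNS) model
   per scale k = 1..K, concatenating the sub-embeddings to a 128-dim user
   vector. DeepWalk instead uses all offsets 1..w in one model. SGNS is
   implemented from scratch in numpy (unigram^(3/4) negative sampling,
   linearly decaying learning rate, bit-reproducible from the seed).
3. **Four modality blocks per tweet:** the 768-dim text vector; min, max,
   mean and population sd of the user's strictly earlier binary labels;
   eight network statistics (followers, friends, posts, likes, indegree,
   outdegree, core number, PageRank); and the user's embedding row.
   Auxiliary blocks are standardized with training-row statistics only.
4. **Classifier.** Concatenated features → FC1 (256, ReLU, dropout 0.1) →
   FC2 (128, ReLU) → sigmoid, trained with Adam on binary cross-entropy.
5. **Evaluation.** Labeled tweets are ordered by time and split 70/30
   (training strictly precedes testing); reported AUC averages ten
   classifier seeds on the identical split. Additional protocols: 7-day
   sliding-window AUC/positive-ratio series, bootstrap t-tests between
   modality configurations, and the EU/US cross-region transfer matrix with
   its diff% column, diff = (AUC_same − AUC_out) / AUC_out × 100.
6. **Topic space.** Per-subset 2-D PCA of user embeddings, per-term mean
   coordinates and per-class kernel densities.

## Worked example

```python
import vaxstance.synthetic_data as sd
import vaxstance.reply_graph as rg
import vaxstance.node_embedding as ne
import vaxstance.evaluation as ev
from vaxstance.features import ModalityToggles

ds = sd.generate_dataset(sd.SimConfig(
    n_users=800, n_tweets=2000, n_replies=6000,
    homophily=0.9, text_dim=32, seed=3))
graph = rg.prune_min_degree(rg.build_reply_graph(ds.replies))
stats = rg.compute_node_stats(graph, ds.users)
emb = ne.walklets_embed(graph.undirected,
                        ne.WalkConfig(walks_per_node=6, walk_length=30, seed=0),
                        ne.EmbedConfig(total_dim=64, scales=4, epochs=2, seed=0))
view = ev.prepare_view(ds, ev.SKEPTIC_TASK, embedding=emb, node_stats=stats)
text = ev.run_config(view, ModalityToggles(use_text=True), n_runs=3, seed=0)
both = ev.run_config(view, ModalityToggles(use_text=True, use_raw_network=True),
                     n_runs=3, seed=0)
print(f"text-only AUC      {text.mean:.3f}")
print(f"text + network AUC {both.mean:.3f}")
```

prints

```
text-only AUC      0.542
text + network AUC 1.000
```

The jump is the network effect under strong homophily (h = 0.9): reply
partners share attitudes, so the embedding almost reveals the latent
stance, while the text vectors (separation s = 1, here in 32 dimensions
with only ~280 labeled training tweets) support just a weak text-only
classifier. The *gap*, not the absolute levels, is the point: both numbers
are set entirely by the planted separations.

The same pipeline is scriptable from the shell:

```bash
vaxstance simulate --out data/ --seed 1 --n-users 800 --n-tweets 2000
vaxstance build-graph --replies data/replies.tsv --users data/users.csv --out graph/
vaxstance embed --edges graph/edges.tsv --method walklets --dim 128 --out emb.tsv
vaxstance evaluate --data data/ --toggles text,raw-network --task skeptic
```

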