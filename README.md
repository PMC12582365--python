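# conceptdrift

Temporal-semantic link prediction on dynamic concept co-occurrence graphs,
for literature-based hypothesis generation.

Concept co-occurrences mined from annotated articles are organized as a
sequence of per-time-step graph snapshots ("graphlets"; step 0 is empty).
Each concept carries an evolving *semantic state*, initialized from a
pre-computed embedding matrix. Whenever a concept co-occurs, an update
message — the two endpoint states concatenated with a functional encoding of
the time since the concept's last update — is integrated into its state by a
gated recurrent cell. To score a candidate future co-occurrence, temporal
multi-head cross-attention summarizes each concept's neighborhood (keys/values
carry neighbors' current states plus encodings of their *first* co-occurrence
steps), an MLP fuses that summary with the concept state into a predictive
embedding, and a symmetric MLP head maps a pair of predictive embeddings to a
co-occurrence probability.

Training is chronological predict-then-update: co-occurrences at step *t* are
scored against 1:1 uniformly sampled negatives *before* the step's events
touch the memory, with binary cross-entropy loss. Evaluation removes test
pairs seen at earlier steps (leakage removal) and reports AUC and average
precision. The neural components (GRU cell, attention, MLPs, Adam) run on a
small numpy reverse-mode autodiff core (`conceptdrift._tensor`), so the
package has no deep-learning framework dependency.

## Modules

| module | contents |
| --- | --- |
| `conceptdrift.events` | annotation parsing/filtering, temporal graph construction, neighborhoods, leakage removal, negative sampling, edge-event file I/O |
| `conceptdrift.memory` | semantic state store, time encoding, context aggregation, gated recurrent integration, per-graphlet updates |
| `conceptdrift.predictor` | first-co-occurrence neighbor index, queries/keys/values, cross-attention, predictive embeddings, pair scoring |
| `conceptdrift.training` | training loop, temporal splits, evaluation, AUC/AP, seeding, model persistence |
| `conceptdrift.synthetic` | dynamic-graph generator with planted converging pairs and correlated embeddings |
| `conceptdrift.analysis` | neighborhood-overlap (Jaccard) drift statistics, PCA state-trajectory tracking |
| `conceptdrift.nn`, `conceptdrift._tensor` | numpy autodiff core and layers |

## CLI

```bash
# generate a synthetic drifting graph (edge events, vocabulary, embeddings,
# planted-pair manifest)
conceptdrift simulate --seed 1 --out data/synthetic

# or build a graph from tab-separated annotation records
# (article_id, year, concept_id, concept_type, concept_name)
conceptdrift build-graph --annotations annotations.tsv \
    --first-year 2000 --last-year 2024 --out data/corpus

# train (train/val/test = steps 1..T-2, T-1, T by default)
conceptdrift train --graph data/synthetic \
    --embeddings data/synthetic.embeddings.tsv \
    --config train.yaml --out runs/model

# evaluate a saved model at a step
conceptdrift evaluate --model runs/model --graph data/synthetic --step 12

# drift diagnostics
conceptdrift analyze-drift --graph data/synthetic --step 12
conceptdrift trajectories --model runs/model --graph data/synthetic \
    --concepts C00003,C00017 --out traj.csv --png traj.png
```

`train.yaml` may set any `TrainConfig` field (`epochs`, `lr`, `seed`,
`state_dim`, `time_dim`, `heads`, `attn_dim`, `neighbor_cap`, `dz`,
`score_hidden`, `negative_ratio`, `data_fraction`, ...).

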