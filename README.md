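# dxpred

Sequential diagnosis prediction from electronic health records, with
diagnosis-code embeddings learned from the codes' **textual descriptions**.

Given a patient's visit history — each visit an unordered set of diagnosis
codes — the task is to predict the diagnosis *categories* of the next visit
(the second level of the code hierarchy, e.g. ICD-9's "Diseases of the
circulatory system (390–459)"). The catch in real EHR data is rare codes:
a model that only ever sees a code's identity cannot learn anything useful
about a code it has rarely observed. But codes have descriptions —
"Chronic diastolic heart failure" (428.32) and "Rheumatic heart failure
(congestive)" (398.91) obviously describe related conditions — and an
encoder over those descriptions places related codes near each other
regardless of how often they appear.

`dxpred` implements that idea end to end:

* a **convolutional description encoder**: word vectors are stacked per
  description and scanned by m filters for each of q window sizes; each
  ReLU feature map is max-pooled, and the concatenated features form the
  code embedding e_i ∈ R^d with d = m·q;
* **six sequence predictors**, each in a *base* form (random embedding
  matrix) and an *enhanced* form (description-derived matrix, trained end
  to end): a history-free MLP, a GRU, a GRU with location-based attention,
  a causal bidirectional GRU with attention (Dipole-style), a two-level
  reverse-time attention model (RETAIN-style), and an ontology
  graph-attention model (GRAM-style) in which each code's embedding is a
  learned convex combination of its own and its ancestors' basic
  embeddings;
* visit embedding v_t = tanh(E x_t + b_v), multi-label cross-entropy
  training with Adadelta and best-validation-epoch selection;
* the field's standard **top-k metrics**: visit-level precision@k and
  code-level accuracy@k, plus the data-sufficiency breakdown that bins
  category labels into frequency quartiles and scores each bin separately;
* a **synthetic cohort generator** (ICD-like ontology, descriptions with
  category-correlated word overlap, Zipf-skewed code and label
  frequencies, Markov visit dynamics with a determinism knob) so the whole
  pipeline is testable without access-restricted clinical data.

All differentiable computation runs on a compact reverse-mode autodiff
engine over numpy (`dxpred.autograd`); every layer is verified against
independent scalar-loop oracles and central finite differences.
See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a synthetic cohort, train the enhanced GRU model, and evaluate:

```bash
dxpred simulate --outdir fixtures --seed 1 --n-patients 200
dxpred train --visits fixtures/visits.jsonl \
  --descriptions fixtures/descriptions.tsv --ontology fixtures/ontology.tsv \
  --word-vectors fixtures/word_vectors.txt \
  --arch rnn --embedding description_cnn --epochs 10 --batch-size 50 \
  --seed 1 --checkpoint model.npz --history history.csv --manifest manifest.json
dxpred evaluate --checkpoint model.npz --visits fixtures/visits.jsonl \
  --descriptions fixtures/descriptions.tsv --ontology fixtures/ontology.tsv \
  --word-vectors fixtures/word_vectors.txt --seed 1 --ks 5,10 --report report.csv
```

The train step prints its model selection:

```
best epoch 9 valid loss 0.8623
```

and `report.csv` holds the metrics (here the cohort's transition rule is
fully deterministic and 10 epochs suffice to learn it, so the top-5 and
top-10 scores saturate):

```
model,embedding_source,k,metric,group,value
rnn,description_cnn,5,visit_precision,,1.0
rnn,description_cnn,10,visit_precision,,1.0
rnn,description_cnn,5,code_accuracy,,1.0
rnn,description_cnn,10,code_accuracy,,1.0
rnn,description_cnn,5,code_accuracy,0-25,1.0
...
```

`visit_precision` at k is |top-k ∩ true labels| / min(k, #true labels)
per predicted visit; `code_accuracy` at k is the fraction of
(visit, true-label) pairs whose label lands in the visit's top-k; rows
with a `group` entry restrict accuracy to one training-frequency quartile
of the labels ("0-25" = rarest). Checkpoints are single-file `.npz`
archives of named parameter arrays plus the JSON model config; a flat
key-value YAML can supply option defaults via `--config` (explicit flags
win). `dxpred export-embeddings` writes the
learned embedding matrix (CNN-derived E or graph-attention G) as a TSV of
code, category, and d floats, ready for an external t-SNE/UMAP projection.

The same workflow is available as a library — `dxpred.synthetic.generate`,
`dxpred.models.build_model`, `dxpred.training.train`,
`dxpred.evaluation.evaluate` — which is what the tests and the
reproduction script use.

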