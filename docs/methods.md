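# Methods

## Problem

Given a patient's longitudinal record — a time-ordered sequence of visits
V_1..V_T, each an unordered set of diagnosis codes — predict the
diagnosis *categories* of visit t+1 from visits 1..t, for every t. The
target space is not the raw codes but the second level of the code
hierarchy (e.g. ICD-9's "Diseases of the circulatory system (390–459)"),
which keeps the label space tractable while remaining clinically
meaningful. Each visit is represented as a multi-hot vector
x_t ∈ {0,1}^|C| over the code universe C; patients with fewer than two
visits carry no prediction target and are excluded.

## Code embeddings from descriptions

Every diagnosis code has a short textual description ("Chronic diastolic
heart failure"). The package learns a code-embedding matrix E ∈ R^{d×|C|}
from these descriptions with a convolutional sentence encoder:

1. tokens are mapped to pre-trained k-dimensional word vectors and stacked
   into an n×k matrix (zero-padded; n is the description length, padded at
   least up to the largest filter window);
2. for each window size h ∈ {2,3,4} (q = 3 sizes), m filters of shape h×k
   are slid over the rows; each position yields
   f_i = ReLU(⟨W_f, l_{i:i+h−1}⟩ + b_f);
3. each filter's feature map is max-pooled to one scalar, and the m·q
   pooled features, ordered by (window size, filter index), form the code
   embedding e_i ∈ R^d with d = m·q.

Codes with overlapping descriptions therefore get nearby embeddings even
if one of them is rare in the training data — this is the mechanism the
whole framework rests on. Word vectors are held fixed by default (they are
pre-trained inputs); a flag unfreezes them. The embedding matrix is
recomputed inside the computation graph on every forward pass, so the
filters train end-to-end with the predictor.

A batching subtlety: each code's windows are slid only over its own padded
description, never over the extra padding introduced by longer
descriptions in the same batch, so an embedding never depends on batch
composition and the batched matrix equals the per-code computation column
for column.

## Predictive models

A visit is embedded as v_t = tanh(E x_t + b_v) (so a visit is the
tanh-squashed sum of its codes' embeddings). Six predictors consume the
v_t sequence; every one exists in a *base* form (E drawn at random and
trained freely) and an *enhanced* form (E from the description CNN):

* **MLP** — softmax(W_c v_t + b_c); no history.
* **RNN** — a GRU over v_1..v_t; softmax head on h_t. The GRU is the
  standard update/reset-gate recurrence with logistic-sigmoid gates,
  h_t = z_t ∘ h_{t−1} + (1−z_t) ∘ h̃_t, started from h_0 = 0. (In one
  published statement of this recurrence the reset-gate and candidate
  lines carry a different input symbol than the update-gate line; we read
  that as a typesetting slip and feed the same input vector to all three
  lines.)
* **RNN_a** — location-based attention over GRU states 1..t: scalar
  scores α_i = W_α·h_i + b_α, softmax-normalised, context
  c_t = Σ α_i h_i, softmax head on c_t.
* **Dipole-style bidirectional** — a forward GRU over v_1..v_t and a
  backward GRU over the *same prefix* reversed; states concatenated to 2g
  dimensions, then location attention and softmax. Running the backward
  pass per prediction point over the observed prefix only (O(T²) GRU
  steps) keeps the model causal — a bidirectional net must not peek at
  visits after t. T is small in this domain, so the quadratic cost is
  immaterial.
* **RETAIN-style two-level attention** — two GRUs consume the reversed
  prefix v_t..v_1; one yields visit-level scalar weights α_i (scores as in
  location attention, softmaxed), the other code-level gate vectors
  β_i = tanh(W_β h_i + b_β); the context is c_t = Σ_i α_i β_i ∘ v_i over
  the *visit embeddings*, and the softmax head operates on R^d.
* **GRAM-style graph attention** — each ontology node (leaf code or
  internal grouping node) has a basic embedding; a leaf's final embedding
  is a learned convex combination g_i = Σ_{j∈A(i)} α_ij e_j over its
  ancestor set A(i) (which includes the leaf itself), with
  α_ij = softmax_j u_a^T tanh(W_a [e_i; e_j] + b_a). G replaces E in the
  visit embedding; then as RNN. In the enhanced form the *leaf* basic
  embeddings come from the description CNN while internal nodes remain
  randomly initialised.

All weights initialise from a seeded uniform ±√(1/fan-in); biases start at
zero. Every softmax is stabilised by max-subtraction. The masked-softmax
used for padded ancestor slots adds −1e30 before normalisation, which in
float64 yields exact zeros for the padding.

## Training

The paper lineage never states its objective in closed form; we use the
multi-label cross-entropy on the softmax output,

    loss = mean_t,p −[ y^T log ŷ + (1−y)^T log(1−ŷ) ],

with y the multi-hot of the next visit's labels and logs clamped at
1e-10. This is the one genuinely open design choice of the framework and
is worth flagging: a softmax output with a multi-label binary
cross-entropy is unusual but is what the cited model family uses.

Optimisation is Adadelta (ρ = 0.95, ε = 1e-6, no learning rate) on
minibatches of 100 patients, shuffled each epoch, padded per batch to the
longest record with masks; a padded timestep contributes exactly zero to
loss and gradients (tested against the unpadded per-patient computation).
"Training iterations" are read as epochs: up to 100 epochs with the
parameter snapshot of the best validation loss returned — no other early
stopping. Patients are split 0.75/0.10/0.15 (train/validation/test) by a
seeded shuffle, train taking floor(0.75·N) and validation floor(0.10·N).
An l2 penalty with coefficient 0.001 applies to all weight matrices,
biases excluded.

All differentiable computation runs on a compact reverse-mode autodiff
engine over float64 numpy arrays (`dxpred.autograd`). At the model sizes
this domain uses (d, g in the tens to low hundreds, T ≈ 10) this is fast —
an epoch over 375 patients takes well under a second on one CPU — and
every primitive is pinned by central-finite-difference tests at 1e-4
relative tolerance, with layer forwards additionally checked against
independent scalar-loop implementations at 1e-6.

## Evaluation

Micro-averaged over all predicted timesteps of all test patients, for
k ∈ {5, 10, 15, 20, 25, 30} (capped at the label-space size):

* visit-level precision@k = |top-k ∩ true labels| / min(k, #true labels);
* code-level accuracy@k = fraction of (visit, true-label) pairs whose
  label appears in the visit's top-k.

Top-k ties break toward the lower label index, which makes accuracy@k
exactly monotone in k (precision@k is not monotone, and is not asserted
to be). For the data-sufficiency analysis, labels are ranked by their
(visit, label) occurrence count in the training set — occurrences, not
patient counts — and cut into four equal-cardinality rank bins; "0-25" is
the rarest quarter, and per-group accuracy restricts the pair set to that
group's labels. A group with no test occurrences is reported as missing,
not zero. The per-cell aggregation (global micro-average rather than
per-patient averaging) is a documented choice; the source material does
not specify it.

## Synthetic cohorts

Real EHR corpora in this area are access-restricted, so the package ships
a generator that reproduces the statistical structure the framework
exploits, at toy scale:

* a three-level ontology: root → categories → codes;
* descriptions built from a private per-category word pool (words drawn
  from it with probability 0.7) plus a shared pool (25% of the
  vocabulary), so same-category codes overlap in words;
* patient dynamics: a first-order Markov chain over categories. At
  `transition_determinism = 1.0` the next category is a fixed function
  (successor mod K) of the current one — the Bayes-optimal accuracy@1 for
  the next category is then 1.0, giving training a known ceiling. Below
  1.0 the chain defects to a uniformly random category;
* start categories follow a Zipf law (exponent 1.2), so with more
  categories than visits per patient the label frequencies are skewed —
  the regime the rare-label analysis needs;
* within a category, codes are drawn Zipf(1.0) by rank, with the tail
  `rare_fraction` of ranks down-weighted 10×; visit sizes are
  Poisson(4) clipped to ≥1 (4 sits between the per-visit code counts of
  typical ICU and claims corpora); T is uniform on [2, max_T = 10].

What the generator deliberately does *not* emulate: real ICD code lists,
comorbidity structure, visit-gap timing, coding noise, or cross-category
visits (each synthetic visit draws from one category). Passing tests on
these cohorts therefore demonstrate that the machinery learns the
structure it claims to learn, not clinical-grade performance.

Two study cohorts are fixed for the headline checks:

* **standard** — 50 codes, 10 categories, 500 patients, determinism 1.0:
  the enhanced GRU model must reach code-level accuracy@5 ≥ 0.9 on the
  test split within 30 epochs (we train 20), over three seeds;
* **rare-label** — 144 codes, 48 categories, 300 patients, rare_fraction
  0.3, determinism 1.0. The label space is made wider than the deepest
  evaluated k (20) so accuracy@20 and the rarest quartile are informative;
  with 48 categories and at most 10 visits per patient the Zipf start
  distribution leaves the tail categories genuinely data-poor. On this
  cohort the enhanced GRU's rarest-quartile accuracy@20 exceeds the base
  GRU's on average over three seeds — the qualitative rare-label benefit
  of description-derived embeddings.

Training runs in the tests and the acceptance script use d = 24
(m = 8 filters × 3 window sizes), g = 32, 16-dimensional synthetic word
vectors and 20 epochs; these sizes are chosen as the smallest at which the
behaviour of interest is stable across seeds.

## Numerical and degenerate-input choices

* σ in the GRU gates is the logistic sigmoid; h_0 = 0.
* OOV words (or a missing vector file) get seeded uniform vectors in
  [−0.05, 0.05]^k.
* Descriptions shorter than a filter window are zero-padded up to it.
* Empty visits, patients with T < 2, empty descriptions, cyclic or
  multi-rooted ontologies, and leaves with an ambiguous level-2 ancestor
  are rejected with specific errors rather than silently handled.
* Ties: top-k prefers the lower label index; frequency-rank ties break by
  label index; max-pool gradient routes to the first argmax.

## Known limitations

* Multi-label cross-entropy over a softmax (see above) is a convention
  inherited from the model family, not a derived likelihood.
* The backward pass of the bidirectional model and both RETAIN GRUs are
  recomputed per prediction point (O(T²)); fine for T ≈ 10, wasteful for
  long sequences.
* The autodiff engine is minimal by design: no GPU, no fused kernels, and
  float64 only.
* Checkpoints store parameters and config but not the data files; the run
  manifest records input checksums so a run can be re-paired with its
  inputs.
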