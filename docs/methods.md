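# Methods

## The federated protocol

The simulator implements the standard synchronous federated loop. Per
communication round *t*: the server samples `clients_per_round` of the *K*
clients uniformly without replacement; broadcasts the global parameters
θ<sub>t</sub>; each sampled client initializes its local model at θ<sub>t</sub>
and runs a fixed budget of minibatch steps on its own data; the server
aggregates the returned models; every `eval_every` rounds the global model is
evaluated on **all** clients' test sets. Everything runs in one process —
there is no transport, encryption, straggler or dropout modeling; the object
of study is the optimization behavior under statistical heterogeneity, not
systems behavior.

Two aggregation rules are implemented:

* **Weighted averaging**: θ<sub>t+1</sub> = Σ n<sub>k</sub> θ<sup>k</sup> / Σ n<sub>k</sub>
  over the sampled clients, with n<sub>k</sub> the client training-set size.
* **Attention**: distances s<sub>k</sub> = ‖θ<sub>t</sub> − θ<sup>k</sup>‖₂ are
  softmax-normalized into weights α<sub>k</sub>, and
  θ<sub>t+1</sub> = θ<sub>t</sub> − λ Σ α<sub>k</sub>(θ<sub>t</sub> − θ<sup>k</sup>).
  At λ = 1 with uniform weights this is exactly the unweighted mean, which is
  one of the equivalences the test suite pins down.

Four local optimizers share one stepping interface: SGD; PGD (SGD on the
proximally augmented objective H(θ, θ<sub>t</sub>) = F<sub>k</sub>(θ) +
(μ/2)‖θ − θ<sub>t</sub>‖², i.e. gradient g + μ(θ − θ<sub>t</sub>)); Adam
(bias-corrected moments, update η·m̂/(√v̂ + ε)); and PAdam (Adam on the
perturbed gradient). The anchor θ<sub>t</sub> is the round-start global model
and is frozen for the whole round.

### Assumptions and deliberate conventions

* **Softmax sign.** The attention weights are a softmax of the *raw*
  distances, so more distant clients get more weight. The "similarity"
  reading of the construction suggests the opposite sign; both conventions
  circulate, and this package follows the raw-distance form as its default
  while exposing `negate_scores=True`. The choice is surfaced (the
  per-round `AttentionReport` is logged) rather than hidden.
* **Softmax scope.** Default is one softmax per layer (`scope="per_layer"`),
  the convention of the attentive-aggregation lineage; `whole_model` is
  available and tested.
* **Attention replaces size weighting.** The attention step carries no
  n<sub>k</sub>/m factors; sample sizes influence it only through where the
  client models end up.
* **Optimizer state is per round.** Moments reset at the start of every
  `client_update`: the broadcast overwrites local parameters, which
  invalidates stale moment estimates. Nothing leaks across rounds, which is
  also what makes runs exactly reproducible from the config seed.
* **Local budget.** `num_epochs` and `num_iters` multiply: a client takes
  `num_epochs × num_iters` minibatch steps, drawing batches by shuffled
  cycling (reshuffled each epoch, wrap-around within one). The alternative
  reading — `num_epochs` full passes over the data — is available as
  `iter_mode="epoch_pass"`.
* **Evaluation.** Acc is pooled correct/total over all clients' test sets
  (identical to the test-size-weighted mean of per-client accuracies).
  The reported loss is the test-sample-weighted cross-entropy by default;
  whether published loss curves are train or test loss is generally
  ambiguous, so `loss_on="train"` exposes the alternative.
* **fedavgt is an alias of fedavgs.** The pair originates as a
  library-Adam vs hand-written-Adam validation; the mathematics is
  identical, so this package implements one Adam and validates it with
  closed-form property tests (constant-gradient telescoping: m̂<sub>t</sub> = g
  and v̂<sub>t</sub> = g² exactly for all t). Under shared seeds the two
  algorithm labels produce bit-identical trajectories.

### Hyperparameters

| name | meaning | default | notes |
|---|---|---|---|
| `learning_rate` | local optimizer step η | 0.01 | 0.001 for Adam-family presets |
| `num_rounds` | communication rounds | 100 | |
| `clients_per_round` | sampled clients per round | 10 | of 30 |
| `num_epochs` × `num_iters` | local minibatch steps | 10 × 20 | see local budget above |
| `batch_size` | minibatch size | 10 | full-batch (with a warning) if a client is smaller |
| `mu` | proximal strength μ | 1 | presets use 0.03 for the attention+proximal algorithms |
| `stepsize` | attention step λ | 1.2 | presets: 4 (synthetic), 9 (text) |
| `eval_every` | evaluation cadence | 1 | |
| `seed` | training seed | 0 | independent of the data seed |

PGD/PAdam stability requires η(μ + L) < 2 (L the loss smoothness constant);
at η = 0.01 the proximal term is stable for μ up to ~100, and the 1-D
quadratic closed form (PGD converges to μ·θ<sub>global</sub>/(1+μ)) is a
test oracle.

## Client models

* **Multinomial logistic regression** (layers `W`: d×C, `b`: C), zero-
  initialized — the problem is convex, so a deterministic start costs
  nothing and removes one seed. Closed-form gradients.
* **LSTM sentence classifier**: embedding → single LSTM layer → last
  unmasked hidden state → dense softmax, written in numpy with hand-coded
  backpropagation-through-time. Token index 0 is padding and is masked out
  of the recurrence (state carries through unchanged), so appending padding
  never changes the output — a contract the tests exercise both for
  trailing and internal padding. Weights initialize uniform(−0.08, 0.08)
  from the init seed; gate layout is [input, forget, cell, output]. Default
  dims (embed 100, hidden 128, max_len 50) are ordinary small-LSTM choices;
  the text presets use reduced dims (embed 16, hidden 32, max_len 20)
  because the fixture corpus is small and high-signal. Both models are
  validated against central finite differences (h = 1e−5, 1e−4 relative).

Pretrained embeddings can be loaded from word2vec text format and installed
into the embedding layer; out-of-vocabulary tokens get seeded random
vectors. The default is a seeded random embedding.

## The synthetic(α, β) generator

Per client k: sample size n<sub>k</sub> = 50 + ⌊LogNormal(4, 2)⌋; latent mean
u<sub>k</sub> ~ N(0, α); client model W<sub>k</sub>, b<sub>k</sub> ~ N(u<sub>k</sub>, 1);
feature-mean offset B<sub>k</sub> ~ N(0, β); feature means v<sub>k,j</sub> ~ N(B<sub>k</sub>, 1);
samples x ~ N(v<sub>k</sub>, Σ) with Σ<sub>jj</sub> = j<sup>−1.2</sup>; labels
y = argmax softmax(W<sub>k</sub>ᵀx + b<sub>k</sub>). α therefore skews the
per-client label distributions (clients have different labeling functions)
and β skews the feature clouds. The IID variant shares one (W, b) and one
feature mean across clients. Every constant (offset 50, lognormal 4/2,
covariance exponent 1.2, 90/10 split) is a `SyntheticSpec` field.

**Seeding convention.** Client k is a pure function of `(seed, k)`: its
size, latent model and samples come from the child stream
`default_rng((seed, k))`. Consequences: adding clients never reshuffles
existing ones; datasets differing only in α/β share their size draws; and
dataset totals are properties of one pinned realization of a *heavy-tailed*
law (the lognormal has mean e⁶ ≈ 403 but median e⁴ ≈ 55, so totals across
seeds span several-fold). At data seed 0 the defaults yield 4208 training /
482 test samples over 30 clients, largest client 932, smallest 45. The
smallest-client value is essentially structural (the smallest of 30
lognormal draws almost always floors to near 0, leaving 50 raw / 45 train
samples); the other statistics move substantially from seed to seed, which
is exactly the imbalance the generator is meant to produce.

**What it does and does not emulate.** It produces controllable label/
feature skew and realistic client-size imbalance, with a known-linear
ground-truth labeling per client. It does not emulate label noise,
covariate shift over time, feature correlation structure, or any linguistic
property; passing benchmarks here shows optimizer behavior under skew, not
clinical-text performance.

## The dialogue-text path and its fixture

Real corpora in the IMCS-V2 JSON layout (per-dialogue sentence lists with
per-sentence symptom labels) are read directly; sentences without a label
are dropped and counted. Whole dialogues are dealt round-robin (after a
seeded shuffle) onto clients, so conversational heterogeneity lands intact
on single clients. The default tokenizer is greedy longest-match over a
lexicon with single-character fallback — the language-neutral analogue of
dictionary-based Chinese segmentation; any `text -> tokens` callable can be
plugged in instead.

The fixture generator emits the same JSON layout: Poisson sentence counts,
alternating speakers, sentences built by concatenating fixed-width
synthetic tokens drawn from class-conditional categorical distributions
(so the label is recoverable from the text), and per-dialogue label priors
drawn from a Dirichlet whose concentration is controlled by `label_skew`
(0 = one shared prior; larger = more dialogue-specific). Fixed-width tokens
make greedy segmentation an exact inverse of generation, which the tests
verify. The fixture is deliberately *synthetic*: it validates the pipeline
and the algorithms' relative behavior, not absolute clinical accuracy.

## Numerical choices

* Softmaxes (labels, attention) subtract the maximum before exponentiation.
* Cross-entropy guards log(0) with an additive 1e−300 (only reachable with
  adversarially saturated logits).
* Adam's ε = 1e−8 sits outside the square root, first-step magnitude ≈ η.
* Argmax prediction ties break toward the lowest class index (numpy
  convention, pinned by a test).
* All parameter algebra is float64 and pure (no operand mutation), which is
  what makes the μ = 0 reduction identities bit-exact rather than merely
  close.
* Train/test splits use ⌊fraction·n⌋ training samples, clamped so both
  splits are nonempty.

## Problem sizes used by the shipped checks

The test suite runs the Adam-family comparison at 50 of the 100 rounds over
five data seeds and the text comparison at 20 rounds over five fixture
seeds; the acceptance script runs the full 100-round configuration once per
algorithm. These sizes keep a full check of the package in the
minutes range on one CPU while leaving the per-round configuration (10 of
30 clients, 200 local steps) at its benchmark values.

## Known limitations

* Absolute accuracy/loss levels on the synthetic benchmark depend on the
  pinned data realization; cross-seed orderings of the algorithms are the
  robust quantity, and those are what the property-based checks assert.
* The LSTM is single-layer and unidirectional by design; no transformer or
  pretrained-LM clients.
* No privacy mechanisms (secure aggregation, differential privacy) and no
  system heterogeneity; timing columns in the metrics are wall-clock
  curiosities, not a communication-cost model.
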