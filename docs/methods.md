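# Methods

## Problem and model

The classifier maps a peptide of 11–25 amino-acid residues to the
probability that it is a linear B-cell epitope. Input sequences are
validated against the 20-letter alphabet `ACDEFGHIKLMNPQRSTVWY`
(lower-case input is upper-cased first; `B, J, O, U, Z` and the padding
symbol `X` are rejected), integer-coded alphabetically (`A=1 … Y=20`,
`X=0`), padded at the tail with code 0 to the standardized length L, and
truncated to their first L residues when longer. Truncation is a package
extension for arbitrary input — curated benchmark peptides never exceed 25
residues, so padding alone suffices there — and is always logged.

The network is two-branched. An embedding layer (vocabulary 21, width
`embed_dim`) feeds (a) a bidirectional LSTM whose per-step hidden states
h_t (width 2·`lstm_units`) are pooled by feed-forward attention, and (b)
one 1-D convolution per kernel width in `active_scales`, each with ReLU,
'same' zero padding, stride 1, and global max pooling. The concatenated
branch outputs pass through dropout and dense layers 64 → 9 → 1 with ReLU
between and a sigmoid at the end. Padding code 0 is embedded like any
other token (no masking): length standardization to L=25 is itself part of
the representation.

**Attention.** The scorer a(·) is a single learnable affine map to a
scalar with a tanh nonlinearity, e_t = tanh(w·h_t + b); weights are
α = softmax(e) and the branch output is the context c = Σ_t α_t h_t, which
always lies in the convex hull of the hidden states. When attention is
ablated the Bi-LSTM branch instead contributes the concatenation of its
final forward and final backward hidden states — a fixed-width summary is
required once softmax pooling is removed, and this is the conventional
choice.

## Hyperparameters

| parameter | default | notes |
|---|---|---|
| L (standardized length) | 25 | maximum benchmark peptide length; longer of the three candidates (11/16/25) performs best |
| embed_dim | 64 | embedding width |
| lstm_units | 64 | per direction; hidden states are 128 wide |
| cnn_scales | 11, 13, 15 | winning triple of the kernel grid search |
| cnn_filters | 64 | per scale |
| dense_sizes | 64, 9, 1 | fixed head |
| dropout_rate | 0.3 | after branch concatenation, training only |
| loss / optimizer | BCE-with-logits / Adam, lr 1e-3 | |
| batch_size / epochs | 32 / 50 | early stopping (patience 10) when a validation set is supplied |

The published architecture fixes L, the scale triple and the dense head;
the widths, pooling, activation, dropout rate and the entire training
recipe are package choices, held in `ModelConfig` so every one is
overridable and recorded with each run.

## Implementation

No deep-learning framework is used. `epitopenet.autograd` is a ~300-line
reverse-mode autodiff engine over float64 NumPy arrays providing exactly
the ops the model needs (broadcast arithmetic, matmul, sigmoid/tanh/ReLU,
softmax, reductions, slicing/stacking/concatenation, embedding gather,
'same' 1-D convolution via shifted matmuls, max pooling, inverted dropout,
stable BCE on logits) plus Adam. Gradients of every op and of the whole
network are verified against central finite differences in the test suite.
Weight initialization is Glorot-uniform (embedding: N(0, 0.05); LSTM
forget-gate bias 1), all drawn from `config.seed`; batch order and dropout
use independent streams spawned from the same seed, so two runs with equal
config are bit-identical.

## Evaluation protocol

Metrics are Sn, Sp, ACC and MCC from the confusion matrix; predicted
probability ≥ threshold (default 0.5, ties positive) calls a peptide
positive. A metric whose denominator vanishes (e.g. no negatives in a
fold) is reported as 0 and flagged `degenerate` rather than raising, so
fold aggregation stays total.

- **Holdout**: stratified 80/20 split, seeded.
- **k-fold CV** (default k=10): label-stratified near-equal folds, one
  fresh model per fold (no weight reuse), every sample tested exactly
  once; the Mean row is the arithmetic fold average. Stratification is the
  natural reading of "equal or approximately equal parts" for balanced
  data; whether to stratify and whether to stop early are protocol
  defaults, not published facts.
- **Scale grid**: every unordered triple of distinct kernel widths from
  {7, 9, 11, 13, 15} (C(5,3)=10 combinations) scored by holdout; the best
  row maximizes ACC with ties broken by MCC, then by smaller kernels.
- **Ablations**: delete Bi-LSTM (attention goes with it), delete the
  smallest scale, the two smallest scales, the whole CNN branch, or the
  attention pooling. "Scale 1" is read as the smallest kernel
  (smallest-first ordering). Deleting both branches is a config error.
  Every variant has strictly fewer trainable parameters than the full
  model (248,596 at defaults).
- **Activation taps**: per-sample activations at the embedding, Bi-LSTM,
  attention, CNN or combined stage, flattened one row per peptide, with
  optional seeded 2-D t-SNE (scikit-learn, PCA init, perplexity capped at
  (n−1)/3).

## Synthetic benchmark generator

The generator emulates the *shape* of curated linear-epitope benchmarks:
balanced classes, lengths uniform on {11…25} (mean 18), uniform residue
background. Class signal is a fixed 5-mer motif (default `CWKHY`) written
over a window at a uniform random offset in exactly
round-half-up(penetrance·n_pos) positives and
round-half-up(contamination·n_neg) negatives; overwriting rather than
inserting keeps the length distribution exact, and non-carrier sequences
are redrawn in the (astronomically rare) event a motif appears by chance,
so substring counts are exact for every seed. It is **not** a biophysical
epitope simulator: no antigen context, no structural constraints, no
realistic residue composition. Passing the learnability tests therefore
shows the pipeline can extract a planted sequence signal end to end — not
that it attains any particular accuracy on real epitope data, whose signal
is weaker and noisier (real-benchmark cross-validation accuracies are
typically far below the near-perfect synthetic ones).

## Problem sizes used in tests and the acceptance script

Synthetic learnability uses 800 training / 200 test peptides with a fully
penetrant motif and 12 training epochs (the planted signal saturates well
before that; the label-shuffled control uses the same budget). The 10-fold
CV demonstration uses 200 peptides at 5 epochs per fold; the kernel grid
uses 120 peptides at 5 epochs per triple; the ablation harness trains each
variant for one epoch. Partition properties are checked exactly at
n = 20, 55 and 1110.

## Known limitations

- CPU-only float64 training: fine for peptide-scale data (seconds per
  epoch for ~1,000 peptides), not for corpus-scale pretraining.
- No masking of padding tokens; very short peptides at large L lean on
  the embedding of code 0 carrying "absence" information.
- Probabilities are uncalibrated sigmoid outputs.
- Sequences longer than L lose their tail silently except for a log
  warning.
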