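# Methods

## Problem setting and data model

A candidate 5mC site is represented by the 41-bp fragment centred on it:
flank length δ = 20 on each side, fragment length 2δ + 1, candidate
cytosine at 0-based index δ. Fragments are processed single-strand; no
reverse-complement scanning is performed. Windows containing `N` are
dropped at extraction (with a logged count) because the k-mer vocabulary is
defined over A/C/G/T only. Coordinates are 0-based throughout; windows
include both flank endpoints.

## Tokenization and vocabulary

Fragments are read into overlapping k-mers with stride 1 (k default 3,
configurable to 5 and 7). k ≥ 3 is enforced so every base appears with both
a left and a right neighbour inside some token. The vocabulary is built
from the training corpus only, in deterministic first-occurrence order;
unknown tokens at prediction time raise by default (an opt-in policy maps
them to the zero vector with a logged count, since silent substitution
corrupts evaluation). Positive and negative training fragments are pooled
into one embedding corpus.

## Co-occurrence and GloVe

The co-occurrence matrix accumulates directed counts for every ordered
token pair at distance ≤ w inside one fragment (w default 1 — immediate
neighbours; optional 1/distance weighting, off by default) and is then
symmetrised by mirroring, X = D + Dᵀ. The embedding minimises

J = Σ over nonzero X_ij of f(X_ij)(V_iᵀṼ_j + b_i + b_j − log X_ij)²,
with f(x) = (x/T_X)^α below the truncation T_X and 1 above it.

Numerical choices:

* the sum is restricted to nonzero cells (f(0) = 0 and log 0 is undefined);
* α = 0.75; T_X = 100 (the conventional truncation, as no value is implied
  by the data);
* optimisation is per-pair SGD with AdaGrad per-parameter step sizes
  (initial step 0.05, accumulators initialised to 1), pairs reshuffled each
  epoch with a seeded generator — two runs with the same seed are
  bit-identical;
* initialisation is uniform in (−0.5/d, 0.5/d);
* the exported per-token vector is the main vector V_i (the context vector
  exists to solve for V_i); the common V + Ṽ variant is a config switch;
* a non-finite loss raises immediately, naming the epoch.

The full energy J is recorded after every epoch. On an exactly-fittable
instance (two tokens, one off-diagonal count) the fit drives J below 1e−4,
but needs on the order of 800 epochs because AdaGrad's step sizes decay as
gradients accumulate; the default epoch budget (50) targets realistic
corpora, where the loss curve flattens long before that.

Embedding dimension d defaults to 300 at full scale. Training-heavy tests
and the acceptance script use d = 32–64: performance on the synthetic task
saturates well below d = 300, and the smaller dimension keeps CPU runs
short.

## Encoders

GloVe encoding stacks the embedding vectors of a fragment's tokens into an
(L−k+1) × d matrix. The one-hot ablation encoder is defined at the *k-mer*
level (39 × 4^k), not the base level, so both encodings present the same
sequence length to the classifier and differ only in how a token is
represented. This is a deliberate interpretation: a base-level one-hot
(41 × 4) would change the downstream geometry and confound the comparison.

## Classifier

Input (B, L−k+1, d) flows through:

1. per-channel standardisation using mean/std computed on the training
   fold (stored with the model; default on). Without it, encodings with
   large correlated offsets can destabilise early training;
2. three parallel dilated 1-D convolutions along the token axis (dilation
   rates 1, 2, 3; kernel 3; same-length padding; ReLU), concatenated to
   width 3 × conv_filters;
3. additive fixed sinusoidal positional encoding — self-attention is
   permutation-equivariant, and base order is meaningful in DNA;
4. one or more Transformer encoder blocks: multi-head self-attention →
   residual Add & LayerNorm → position-wise feed-forward (ReLU, width
   4 × model width by default) → Add & LayerNorm;
5. mean pooling over positions (flattening available);
6. dense head 128 → 64 → 32, dropout (rate 0.2) after each layer, 2-unit
   softmax.

Training minimises categorical cross-entropy with Adam (lr 1e−3, batch 32
by default), early-stops on validation loss, and restores the best-epoch
weights. Optional balanced class weighting is off by default — the natural
imbalance is part of the task. Calls use prob ≥ threshold (default 0.5;
ties map to the positive class). Everything is pure NumPy float64: fixed
seeds give bit-identical trajectories, and every layer's backward pass is
verified against central finite differences in the test suite (parameters
are jittered before differencing so no ReLU sits exactly at its kink, where
the subgradient and a central difference legitimately disagree).

The two-unit softmax with categorical cross-entropy is mathematically
equivalent to a single sigmoid logit for two classes; the softmax form is
implemented.

Default hyperparameters not dictated by the architecture (64 filters per
branch, 4 heads, 1 encoder block, dropout 0.2, Adam at 1e−3) are ordinary
first choices for a model of this size and are all exposed in
configuration.

## Synthetic data

The generator emulates the *structure* of real 5mC benchmark sets — fixed
41-bp fragments, centre base forced, heavy negative:positive imbalance —
with a controllable signal: positives carry a planted 8-mer motif
(`ACGTACGT` by default) at a uniformly drawn offset in the right flank,
with probability `planting_prob`, optionally corrupted by per-position
mutation noise; negatives are i.i.d. uniform background. Ratio presets
1:10, 1:12, 1:15 mirror the common benchmark imbalances (1:12 being the
usual benchmark ratio).

What this does and does not show: a planted literal motif guarantees the
positive class is learnable (a substring detector alone reaches AUC ≥ 0.99
at full planting, which is asserted as a test), so classifier tests have a
fair, known target. Real methylation signal is distributed, context
dependent and correlated with CpG-island structure and base composition —
none of which the generator models. Passing tests demonstrate that the
pipeline can extract a genuine sequence signal at realistic fragment sizes
and imbalances, not that it attains any particular accuracy on real CCLE
or EMDLP data.

Stratified splitting sends round(count × fraction) of each class to the
test fold (so an 80/20 split of 69,750 positives yields exactly 13,950
test positives), shuffling per class with a seeded generator.

## Desk-scale study conditions

CPU-friendly problem sizes used by the acceptance checks, chosen once:

* end-to-end learning: 2,000+2,000 training and 500+500 validation
  fragments, full planting, embedding d = 50, 16 filters per branch,
  ≤ 10 epochs — validation AUC ≥ 0.95 is expected within this budget;
* permutation null: labels shuffled across the *whole* dataset before
  splitting. Shuffling only the training fold would leave true validation
  labels in place, and best-epoch selection can then cherry-pick chance
  correlations between random projections of the (separable) inputs and
  the true labels — inflating the null;
* imbalance sweep: 120 positives against 1:10/1:12/1:15 negatives, d = 32,
  8 filters, 6 epochs; validation accuracy is expected to vary by < 0.05
  across ratios;
* encoding ablation: 800+800 fragments, planting probability 0.8, motif
  mutation rate 0.15 (high enough that exact k-mer memorisation is
  penalised and generalisation across motif variants matters), embedding
  d = 64 against one-hot's 4³ = 64, identical model and 16-epoch budget.
  Sensitivity and Mcc are compared as means over three replicate seeds:
  the replicate mean is reported because single-run sensitivity at a fixed
  0.5 threshold is dominated by calibration noise, while the ranking
  quality (AUC, Mcc) difference between encodings is stable.

## Known limitations

* Single-strand processing; no deduplication of overlapping genomic
  windows (how real pipelines handle duplicate candidate sites is dataset
  specific and deliberately not guessed here).
* The NumPy network is CPU-bound and desk-scale; it is not intended for
  full-genome training runs.
* The generator's i.i.d. background makes the co-occurrence structure of
  the corpus much simpler than real genomic sequence; GloVe embeddings fit
  on it mostly encode token-overlap and motif-context structure.
* Metrics with vanishing denominators (reachable under extreme imbalance)
  are reported as NaN with an explicit flag, never silently as 0.
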