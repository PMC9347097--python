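# Methods

## Problem setting

Drug–target binding affinity prediction is posed as regression: given a
drug's SMILES string and a target protein's amino-acid sequence, predict a
real-valued affinity (pKd for dissociation-constant panels such as Davis,
or a composite bioactivity score such as KIBA).  `msadta` implements the
two ingredients of the approach — a multi-granularity subword encoding of
both sequence types, and a multi-scaled self-attention regressor — plus the
evaluation statistics standard in this literature, and a seeded synthetic
benchmark so the whole pipeline is exercisable without downloads.

## Multi-granularity encoding (BPE)

Character-level dictionaries cannot represent two-letter atoms (`Cl`,
`Br`), stereocentres (`[C@@H]`) or functional groups (`C(=O)`) as single
symbols.  Byte-pair encoding recovers such units from an unlabelled corpus:
starting from single characters, each iteration counts all adjacent token
pairs across the corpus and merges the most frequent pair into one new
token, until the number of merge operations reaches a threshold `T`.  The
vocabulary is the character alphabet plus one token per merge, so `T`
directly controls vocabulary size; ids are assigned deterministically
(sorted alphabet first, then merges in learned order, starting at 1).

Choices where the procedure is underdetermined:

* **Tie-breaking.** Equal-frequency pairs are resolved by the
  lexicographically smallest `(left, right)` pair, making training
  deterministic and serialized vocabularies byte-identical across runs.
* **No word boundaries.** Each corpus line is a single unbroken token
  stream; merges may span any adjacent positions within a line but never
  cross lines.  SMILES and protein sequences have no word structure, so no
  end-of-word marker is used.
* **Early stop.** Merging halts when the best pair occurs fewer than twice:
  a frequency-1 merge compresses nothing and wastes a vocabulary slot.
* **Unknowns and padding.** Id 0 is reserved for padding; tokens unseen at
  encode time map to a reserved `unk` id (largest id + 1).  Characters
  outside the training alphabet pass through segmentation as
  single-character tokens, so `join(segment(s)) == s` holds for every
  string — an invariant the tests enforce by property.
* **Length cap.** Encoded sequences are truncated on the right at the
  configured maximum length `l` and zero-padded below it.
* **No normalisation.** Sequences are used verbatim (isomeric SMILES kept);
  no lowercasing, canonicalisation or validity filtering.

Segmentation of a new string replays the learned merges in order on the
character sequence.  Token counts are therefore non-increasing in the merge
list: applying more merges can only coarsen a segmentation.

## The multi-scaled self-attention model

Both encoders share one architecture.  An encoded sequence of ids is mapped
to `E = tok[ids] + pos`, the sum of a trainable token table (rows =
vocabulary id range, width `e`) and a trainable position table (`l × e`).
Each of `L` blocks then computes, for heads `h = 1..N` with per-head width
`d_h = e / N`:

    Q, K, V  = E W_Q^h, E W_K^h, E W_V^h
    head^h   = softmax(Q Kᵀ / √d_h + M^h) V
    M^h[i,j] = 0      if  i − m^h ≤ j ≤ i + m^h
             = −∞     otherwise

`m^h` is the head's *window size*: the banded additive mask confines each
query's attention to a neighbourhood of half-width `m^h`, so different
heads see patterns at different scales (defaults `m^h ∈ {0, 1, 2, 3}`; with
more heads than windows the list cycles).  `m = 0` makes a head copy its
value vectors; `m ≥ l − 1` is ordinary global attention, and the block then
reduces exactly to a vanilla Transformer encoder block (verified against an
independent reference implementation to 1e−6).  Head outputs are
concatenated — widths are chosen so the concatenation restores `e` and no
output projection is applied — followed by a residual connection and
LayerNorm, one fully connected ReLU layer of width `e`, and a second
residual + LayerNorm.

The two deep representations are flattened (`l·e` each), concatenated and
passed through a 4-layer feed-forward stack (hidden widths 1024, 1024, 512
with ReLU, then a linear scalar output).  Mean- and max-pooling are
available as alternative aggregations via `ModelConfig.aggregation`.

Further design points:

* **Padding.** Key positions holding pad id 0 receive the −∞ mask in every
  head so padded tokens never receive attention; query rows whose mask
  blocks every key output exactly zero.
* **−∞ realisation.** The masks use the finite constant −1e9, large enough
  to zero the softmax weight at float64 yet safe from NaN propagation.
* **Dropout** (rate 0.1 by default) is applied to the embedding sum, the
  attention weights after softmax, and each hidden interaction layer.
* **Initialisation.** Glorot-uniform projections and interaction weights,
  N(0, 0.1) embedding tables, zero biases, unit LayerNorm gains.
* **Target standardisation.** `fit` standardises training targets to zero
  mean / unit variance and `predict` undoes the transform.  Affinities sit
  around 5–11 on the pKd scale; standardising keeps Adam's step sizes at
  the shipped learning rate (1e−4) commensurate with the output scale so
  short training budgets converge.  Loss traces are reported on the
  original scale.
* **Optimisation.** Adam (β = 0.9/0.999) on mean squared error, seeded
  shuffling, mini-batches (default 32; the tiny preset uses 8, sized for
  training splits of a few hundred pairs).  A non-finite batch loss aborts
  with a diagnostic rather than silently training on NaNs.

The whole model runs on a small float64 reverse-mode autodiff tape written
for this package (`msadta._autograd`); analytic gradients are checked
end-to-end against central finite differences in the test suite.

## Evaluation statistics

* **MSE** — the training criterion.
* **Concordance index** — the probability that two pairs with different
  true affinities are predicted in the correct order; summed over ordered
  pairs with strictly greater true affinity, tied predictions scoring 0.5.
  Ties in the *true* values are excluded from the normalisation.
* **r²m** — Roy's modified r²: `r²·(1 − √(r² − r²₀))`, where `r²` is the
  squared Pearson correlation between observed and predicted values and
  `r²₀` the through-origin coefficient of determination with slope
  `k = Σ(y·y*)/Σ(y*²)`.  The radicand is clamped at zero when `r²₀ > r²`
  (numerically possible) to keep the metric real-valued.  A held-out
  r²m above 0.5 is the conventional bar for an acceptable model.
* **pKd transform** — `pKd = −log₁₀(Kd / 1e9)` for Kd in nM.

## Cross-validation protocol

`split_folds` reserves a seeded test fraction (default 1/6) and deals the
remaining triples round-robin into k folds (default 5).  `run_cv` trains
one model per fold on the other k − 1 folds, evaluates every model on the
shared test split, and reports per-fold {MSE, CI, r²m} with their mean and
standard deviation; all aggregates are recomputable from the per-fold raw
values stored in the manifest.

## The synthetic benchmark

The generator plants a recoverable signal connecting sequence content to
affinity.  Drugs are SMILES-like strings assembled from filler characters
and 0–2 copies of each of five chemical motifs; proteins carry a non-empty
subset of five 4-mer tag blocks (letters disjoint from the filler alphabet)
at the front of the sequence, ahead of random amino-acid filler, so the
model's length cap never truncates the informative part.  The affinity of a
pair is

    y(d, p) = 5.0 + 0.6 · Σ_k counts_k(d) · tag_k(p) + N(0, noise_sd²)

spanning roughly 5–11 like a pKd panel.  An oracle that recovers the
planted function exactly is left with MSE ≈ noise_sd², which bounds any
model's achievable error; the tests verify this bound and that BPE on the
drug corpus rediscovers the planted motifs as single tokens.

What the generator does *not* emulate: chemically valid molecules, realistic
protein families, sparse affinity matrices, assay noise structure, or the
scale of real benchmarks (hundreds of thousands of corpus sequences,
tens of thousands of interactions).  Passing tests on this benchmark show
the pipeline learns a planted sequence→affinity mapping end to end; they do
not certify accuracy on real kinase panels.

## Problem sizes and numerical choices

Desk-scale runs use the `tiny` preset (l = 16, e = 16, 4 heads with windows
0–3, one block per encoder, 50 epochs, batch 8) on the 40-drug × 10-protein
dataset: about 330 training pairs, ~1–2 minutes on one CPU at float64.  The
shipped `kiba`/`davis` presets mirror the published hyper-parameter tables
(l_d = 80/36, l_p = 800/900, e_d = 128/64, L_d = 2, L_p = 2/1, 300 epochs)
and are intended for real benchmark data, which this package deliberately
does not download.  BPE thresholds for the synthetic pipeline default to
~60–100 merges, enough to cover all planted motifs with headroom.

## Known limitations

* Training is CPU-bound pure NumPy; the published-scale configurations are
  represented but not trained here.
* The attention mask materialises an `l × l` matrix per head and batch
  element; fine at desk scale, memory-hungry at l = 800+ with large batches.
* `r²₀`'s through-origin convention follows the common benchmark practice
  (observed regressed on predicted); other conventions exist in the QSAR
  literature and give slightly different values.
* The DeepDTA-release reader ignores the release's own fold-index files;
  folds are always re-derived with the seeded splitter.
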