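# Methods

This note documents the models, defaults, and numerical choices behind
`simpep`, and what the synthetic benchmark does and does not establish.

## Problem setting and model

Osteogenic peptide detection is a binary classification problem with an
extreme data regime: on the order of 100 experimentally confirmed positives
and a few hundred presumed negatives. Training a per-peptide deep classifier
directly would overfit, so the package trains on *pairs*: a pair is positive
when both peptides share a class (OP–OP or non-OP–non-OP) and negative when
they differ. With `|O|` positives and `|N|` negatives this yields
`C(|O|,2) + C(|N|,2)` same-class and `|O|·|N|` cross-class pairs — a far
larger training signal than the peptide count suggests, at the cost of
non-independent examples.

The pair scorer is a siamese network: one dense ReLU encoder (512, 128, 64,
32 units; dropout 0.2 after every hidden layer during training) applied to
both embeddings with literally shared parameters, an elementwise absolute
difference of the two latents, one 16-unit ReLU layer, and a single sigmoid
output. The absolute difference makes the score exactly symmetric under
operand swap (bit-level, since `|a−b| = |b−a|` in IEEE arithmetic) and makes
the score of any identical pair a constant independent of the input. Loss is
binary cross-entropy with predictions clamped to `(1e-7, 1−1e-7)`; the
optimizer is Adam at learning rate 1e-3 with default moments (0.9/0.999),
batch size 32, shuffled per epoch. The network is implemented directly in
NumPy (forward, backpropagation through the shared encoder — both channels'
gradients accumulate into one parameter set — and Adam); weights initialize
with He fan-in scaling under the run's seed.

### Balanced pair construction

Same-class pairs are *unordered* and exclude self-pairs: the scorer is
symmetric, so ordered duplicates add no information, and a self-pair would
leak a trivial zero-difference signal. Because non-OP–non-OP pairs vastly
outnumber OP–OP pairs, the NN block is subsampled without replacement to the
OO block's size (`|T_pos| = 2·C(|O|,2)`); the cross-class block is then
sampled to the same size — without replacement when it is large enough,
with replacement otherwise. Evaluation pairs over a labeled test set are all
*ordered* distinct pairs. One explicitly seeded PRNG stream drives each
construction call, and seeds are recorded in provenance.

### Iterative re-pairing

Each training round draws a fresh balanced pair dataset (new subsample of NN
and ON blocks) and trains 5 epochs, continuing from the current weights.
"Stable" is defined as: the range of the last 5 per-epoch training
accuracies falls below `stability_tol` (default 0.005); training stops then
or after `max_rounds` (default 20) rounds. This criterion is bounded,
monotone-checkable, and reproducible; the re-pairing de-correlates the model
from any one subsample of the heavily re-used peptides.

### Aggregated detection and screening

A test peptide is paired with every training peptide; with summed
similarities `C_O` and `C_N`, the detection score is
`ρ = ((1 − C_N/|N|) + C_O/|O|) / 2 ∈ [0,1]`, monotone increasing in
similarity to the positive pool and decreasing in similarity to the negative
pool. The detection threshold is 0.5, boundary inclusive — consistent with
reading ρ as a probability; it is configurable. Screening repeats the whole
train+predict cycle `R = 10` times with seeds derived from one root seed;
candidates qualify when `ρ ≥ τ = 0.8` in at least `min_runs = 2` runs
(a single-run hit is treated as sampling noise). The reported mean ρ
averages qualifying runs only; `avg_all_runs` switches to an all-runs mean.
External annotations (docking scores, bioactivity, toxicity) are pass-through
columns, never computed.

## Peptide representations

* **PLM backends.** ProtBERT (Rostlab `prot_bert`, 1024-d) and ESM-2
  (650M-parameter variant, the one with hidden size 1280). Sequences are
  uppercased; for ProtBERT rare residues map to X and residues are
  space-separated before tokenization. Token embeddings from the last hidden
  layer are mean-pooled per sequence, excluding special tokens; pooling
  accumulates in float64. Inference is per-sequence, so padding never enters
  the pool. These backends require the optional `plm` extra and explicit
  download opt-in; absent that, they raise a capability error pointing at
  the offline backends.
* **Descriptor backends.** Sandberg z-scales and Tian topological T-scales,
  5 components per residue, shipped as JSON package data with citations;
  a peptide's representation is the residue-wise mean. These tables cover
  only the 20 canonical residues, hence the strict alphabet mode.
* **Mock backend.** Hash-seeded Gaussian vectors, deterministic per
  sequence; carries no biology, used to exercise pipelines.

Alphabet policy: curated peptide tables contain nonstandard one-letter codes
(B, J, O, U, X, Z). The default policy maps them deterministically to X,
keeping such peptides usable by every backend; `strict` mode rejects them,
protecting descriptor lookups; `pass_through` preserves them for round-trip
I/O.

## Digestion

Cleavage rules follow the PeptideCutter/Keil presentation: a set of P1
residues, per-P1 sets of blocking P1′ residues, and longer-context exception
patterns (e.g. tryptic K–P bonds resist cleavage unless preceded by W).
Rules ship as an auditable JSON file: trypsin (after K/R, blocked by P, with
the documented exception triplets), chymotrypsin at high specificity (after
F/Y/W; F and Y blocked by P, W by M or P) and low specificity (additionally
after L and M, with M also blocked by Y). Enzymes are applied separately and
results unioned, duplicates retained — the separate-digest presentation;
sequential double digestion is available via the union of each enzyme's
fragments of prior fragments if needed. Coordinates are 0-based, site `i`
cutting after residue `i`; concatenating fragments always reconstructs the
protein, and this invariant is asserted in the digest routine itself. No
default length filter is applied; filters are opt-in. The exact rule dialect
(specificity level, joint vs separate digestion, duplicate handling) that
produced the original curated negative sets is not fully determined, so
fragment counts from named source proteins are reconciliation targets, not
guaranteed reproductions.

## Physicochemistry

Molecular mass is the sum of average (isotope-abundance-weighted) residue
masses plus one water (18.01528 Da); a monoisotopic mode is available.
Net charge at pH uses Henderson–Hasselbalch sums over ionizable side chains
(K/R/H positive; D/E/C/Y negative) plus free termini, with EMBOSS-style pKa
defaults shipped in the same JSON data file. Integer-rounded charges are
robust to the standard choice of pKa set; fractional charges are
dialect-dependent and reported to 4 decimals without further claims.

## Evaluation protocol

Folds are split per class: each pool is permuted under the seed and cut into
k near-equal parts (sizes differ by at most one; e.g. 108 → 22/22/22/21/21),
so every fold preserves the class ratio. Per fold, the model trains on the
out-of-fold pools and is evaluated twice: on all ordered distinct pairs of
the held-out fold (pair task, threshold 0.5) and on the aggregated ρ of each
held-out peptide (detection task). ACC/SPC/SEN come from the standard
confusion-count formulas, with undefined ratios reported as NaN rather than
zero; AUC-ROC is the rank-based (Mann–Whitney, ties count half)
implementation from scikit-learn, cross-checked in the test suite against an
O(n²) pairwise count. Summary rows are the arithmetic mean and the *sample*
(n−1) standard deviation of the fold values; the 95% confidence half-width
is `1.96 · STD / √k` over the k folds.

## Synthetic benchmark

`gen_embedding_clusters` draws the two classes from isotropic Gaussians in
`dim` dimensions whose means are `delta·sigma` apart along a random unit
direction. Defaults are the package's reference study conditions: dim 32,
40 positives, 160 negatives (1:4 imbalance mirroring the ~108:488 regime of
curated data), sigma 1. `delta = 6` gives a task a linear threshold solves
at ≥ 99% accuracy (Gaussian overlap ≈ Φ(3)), so any competent pipeline must
recover it; `delta = 0` is an exact null. `gen_peptides` adds random
sequences with class-biased residue frequencies for sequence-facing code.
Dimension 32 (not 1024) keeps the full suite fast; the spec of the clouds is
otherwise unchanged by dimension.

The end-to-end recovery harness trains on 40+160 and evaluates on held-out
draws from the same distributions. The separable check uses 10+40 held-out
peptides; the null check uses 50+200 held-out peptides and averages the AUC
over three seeds, because a single-seed AUC over 50 test points has a
standard error (~0.07–0.14) comparable to the acceptance band around chance.

What passing these benchmarks shows: the pairing, training, aggregation and
evaluation machinery is correct and recovers separable structure without
inventing structure in noise. What it does not show: anything about real
peptide biology — Gaussian clouds have none of the anisotropy, manifold
structure, or label noise of PLM embeddings of curated peptides, and
sequence redundancy between pools is absent by construction.

## Known limitations

* The PLM backends are consumers of external encoders; their outputs are
  cached but the models themselves are neither shipped nor fine-tuned.
* ρ aggregates over *all* training peptides with equal weight; a few
  mislabeled pool members shift every score.
* Pair examples are non-independent (each peptide occurs in many pairs), so
  pair-task metrics overstate effective sample size; the detection-task
  metrics and fold-level dispersion are the more honest summary.
* The digestion rule tables encode one published dialect; other tools differ
  in exception handling and will produce different fragment counts.
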