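# Methods

## The model

`twinfuse` treats multimodal breast-image classification as three coupled
sub-problems: per-modality visual feature learning, binary feature-subset
selection, and late (probability-level) fusion. Nothing is fused at the
architecture or feature level; the two CNNs are trained independently and
only their class-probability outputs meet.

### Twin extractors

Each extractor is a conv-pool stack: per block, two valid 3×3 stride-1
convolutions with ReLU, then a 2×2 max-pool. Filter counts double per block
(32/64/128/256 in the reference layouts; 8/16 in the mini layout). The head
is flatten → dense (ReLU) → dropout 0.5 → dense + softmax. The penultimate
dense activation is the feature vector.

The reference layouts use pool stride 1, which shrinks feature maps very
slowly; that choice is kept available in `ExtractorSpec.pool_stride` but
the mini layout uses stride 2, the common choice, so desk-scale geometry
stays small. A second flatten before the dense layer would be a no-op and
is omitted.

The networks are implemented directly on numpy: im2col convolutions with
explicit backward passes, max-pool argmax scatter, softmax cross-entropy,
and Adam (β₁ = 0.5, β₂ = 0.999, ε = 1e−8) with L2 weight decay 2e−4 on the
weight matrices. Reference training hyper-parameters (learning rate 1e−6,
batch 32, stratified 0.75/0.15/0.10 train/eval/test splits) are the
`TrainConfig` defaults; the desk-scale pipeline raises the learning rate to
1e−3 because 1e−6 cannot move a small network in a dozen epochs. All
stochastic elements (init, shuffling, dropout, splits) derive from the
config seed, so training is bit-reproducible.

### BEOSA

The optimizer maintains a population of binary vectors with a continuous
"shadow" position. Each iteration an *infected* subset is selected — a
recruited core of `ceil(recruitment_rate·pop)` members plus any member
hit by one of four Bernoulli contact draws (p₁..p₄, default 0.1 each;
contacts of infected, host, dead, recovered individuals) — and updated;
the rest persist. The continuous move is

    shadow = Δ · e^rand · cos(2π·rand) · (pos − best),  rand ~ U[−1, 1]

with Δ = 1 − t/maxIter (linear decay). Re-binarization draws r ~ U[0, 1)
per bit and sets the bit by comparing r with the transfer value:
`bit = 1 iff r > T(shadow)` with T the S- or V-function. This direction is
the reverse of common binary-metaheuristic usage; it is implemented as
stated, with `printed_rule=False` flipping to the conventional `r < T`.

**Branch semantics.** With the rule above, a converged individual
(`pos == best`, shadow 0) binarizes to an unbiased coin per bit under the
S-function and to all-ones under the V-function — neither can intensify
around an incumbent. The S-branch is therefore used as stated (it is a
good explorer: agreeing bits randomize, disagreeing bits drift toward the
best), while the V-branch — the intensification step, whose mechanics are
otherwise open — is implemented as a stochastic local search: each bit
adopts the incumbent's value with probability `lrate + (1 − lrate)·V(shadow)`
and then mutates with probability 1/dim. `srate` routes an update to the
S-branch with that probability, `lrate` floors the pull toward the best.
This reading keeps every stated ingredient (transfer functions, srate/lrate,
the Δ-scaled move) and makes the optimizer actually converge: on structured
10-bit objectives it matches exhaustive search in ≈100% of trials within a
2^dim evaluation budget.

**Wrapper fitness.** A mask is scored
`0.99·(1 − acc) + 0.01·|F|/dim`, acc being stratified 3-fold
cross-validated accuracy of a 5-NN classifier on the selected columns (the
split protocol is seeded; 3 folds keep desk-scale evaluation cheap). An
all-zero mask is assigned the worst score 1.0 instead of raising, so the
optimizer can escape it. Note the sparsity term means that when single
columns are individually strong enough to saturate accuracy, the true
optimum may exclude a redundant informative column; the recovery tests use
effect sizes where informative columns are complementary (each one's
removal costs measurable accuracy), which is the regime where "recover the
informative subset" is well defined.

### Fusion layer

Fine labels remap onto the coarse {N, B, M} partition
(mammography: N→{N}, B→{BC, BM}, M→{CALC, M}; histology: N→{N},
B→{B, A, F, PT, TA}, M→{IS, IV, DC, LC, MC, PC}); coarse probabilities are
sums over member fine classes, conserving mass exactly.

The per-modality fused probability is the mean of the actual-label and
predicted-label probabilities. The multimodal rule is
`hist_pred/2 + mammo_pred/4` — histology weighted twice mammography; the ¼
may arise from averaging over a two-member coarse class. Both rules are
plain functions passed as strategies, so alternative weightings can be
swapped in. Disagreeing coarse decisions concatenate with an en dash
(`M–N`, histology first); agreeing pairs collapse to the single label (the
tables only ever show disagreement, so the collapse is an extrapolation).

The fusion search space holds one item per (histology, mammography) record
pair — Cartesian by default, with class-matched and row-paired modes — each
carrying six coarse probabilities and a 6-bit selection initialized to all
ones. Its fitness `2 − Σ selected probabilities` is monotone non-increasing
in added bits, so full selection of normalized vectors is the optimum (0);
BEOSA over the 64-point space is verified against brute force. When a
record carries only scalar probabilities (as the packaged fixture does),
its coarse 3-vector is synthesized by placing the predicted probability on
the predicted coarse class and splitting the remainder uniformly.

### Statistics

`welch_t_test` implements the unequal-variance t with Welch–Satterthwaite
df; when one sample is constant the df expression degenerates to n−1 of the
varying sample, which the implementation reproduces. Sample variances are
computed with one guard: a column whose entries are all identical has
variance exactly 0 (naive accumulation leaves ~1e−33 of floating-point
dust, and dividing by it manufactures an astronomical variance ratio).
Consequently the F statistic against a constant column is reported as +inf
with a warning. Multiclass AUC is macro-averaged one-vs-rest.

## Synthetic data

The generators define the desk-scale study conditions:

* **Mammography-like** (32×32 grayscale by default): vertical background
  gradient 0.15–0.45 plus N(0, 0.05) noise; class motifs are soft Gaussian
  blobs (mass-like; 'M' brighter/more numerous than 'BM') and bright
  speckle (calcification-like 'BC'/'CALC'); 'N' is background only. Motif
  amplitudes guarantee the malignant/normal mean-intensity gap exceeds
  twice the noise sd, so classes are learnable by construction.
* **Histology-like** (RGB): sinusoidal textures with class-specific spatial
  frequency under a class-specific stain-like tint, plus noise — enough
  structure for Reinhard normalization and 3-channel training to be
  exercised.
* **Feature matrices**: two balanced classes; informative columns are
  Gaussians shifted ±effect/2 by class, all others N(0, 1); the oracle mask
  is returned. Default effect 3.0 gives near-separable single columns;
  recovery experiments use 1.5 (see above).
* **Probability-table fixture**: the packaged 20-row table (constant
  histology column, varying mammography column). The fine labels 'DC' and
  'N' attached to it are synthetic stand-ins — the source table prints only
  coarse labels, and any malignant histology fine class remaps identically.

What the generators do **not** emulate: anatomical structure, scanner and
staining physics, class overlap and label noise, dataset imbalance at
realistic scale. Passing tests therefore demonstrate that the machinery is
correct (geometry, gradients, selection, fusion arithmetic, statistics),
not that the pipeline reaches any particular accuracy on real mammograms or
slides.

## Problem sizes

The suite and the acceptance script run entirely on one CPU: 120 synthetic
32×32 images, a two-block (8/16-filter) extractor trained 12 epochs,
BEOSA populations of 20–24 for 30–40 iterations (with restarts up to a
2^10-evaluation budget for the oracle comparison), and 10-run recovery
experiments on 200×10 matrices. These sizes make the whole suite finish in
about a minute while leaving every code path identical to a full-scale run;
full-size extractor specs (299×299, 224×224, 4 blocks) are constructed and
geometry-checked but not trained.

## Known limitations

* The exact epidemic bookkeeping of the optimizer (who recovers, dies, or
  re-enters) is reduced to the infected-subset rule described above; the
  compartment dynamics beyond that are not modelled.
* The multimodal fusion weights are fixed by reproducing the reference
  probability tables, not learned; `run_multimodal` accepts alternative
  strategies but ships only the two defaults.
* The numpy extractors are desk-scale tools: no GPU, no augmentation-aware
  data loaders, float64 only. They are not a route to training on
  ~100k-image corpora.
* Reinhard normalization uses CIELAB as its perceptual space rather than
  the original log-LMS lαβ; for the stain-tint ranges generated here the
  difference is below the test tolerances.
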