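# Methods

This note records the model, the numerical choices made where the design was
open, what the synthetic benchmark does and does not emulate, and the known
limitations.  Notation: `Nc` circRNAs, `Nd` drugs, binary association matrix
`Y ∈ {0,1}^(Nc×Nd)`.

## Similarity construction

* **Sequence similarity** `SC(i,j) = 1 − lev/(len_i + len_j)` with unit-cost
  Levenshtein distance computed by `edlib` (C implementation); the
  normalisation by the *sum* of lengths keeps the value in [0,1] and makes
  the empty-sequence case ill-defined, so empty sequences are rejected.
  FASTA input is uppercased with U→T so RNA and DNA coordinates are
  interchangeable for edit distance.
* **Drug structure similarity**: Tanimoto coefficient on binary topological
  (path-based) fingerprints, 2048 bits by default (configurable).  Two
  all-zero fingerprints get similarity 0 by convention, but the diagonal of
  `SD` is forced to 1.
* **Interaction-profile kernels** `GC`, `GD`: Gaussian kernels on the rows /
  columns of the *training* association matrix with bandwidth equal to the
  reciprocal mean squared profile norm.  Computing them from the training
  matrix only (test entries zeroed) is a deliberate leakage-hygiene choice;
  an instrumented test verifies that no feature depends on held-out labels.
* **Integration** is the entrywise average where the biological similarity is
  nonzero, else the kernel value.  The exact-zero test identifies *missing*
  annotations: real Levenshtein/Tanimoto similarities are essentially never
  exactly zero.

## Random walk with restart

The transition matrix is the column-normalised similarity matrix and the
restart vector of node `l` is its similarity row normalised to sum one.  With
both normalisations every iterate — hence every output row — is a probability
distribution, matching the interpretation of the output as a visiting
distribution.  Defaults: restart probability `c = 0.3`, `tol = 1e-6`,
`max_iter = 100`.  The iterate agrees with the closed form
`(1−c)(I − cW̃)^{-1}e` to the tolerance (tested up to 50 nodes).

## Mixed-neighbourhood encoder

Order-`i` reachability `Āⁱ` binarizes the `i`-th adjacency power (entry 1
where any `i`-step walk exists).  Each is normalised as
`D̃^{-1/2}(Āⁱ + I)D̃^{-1/2}`.  A layer computes
`∥_{i∈1..n} ReLU(Ãⁱ H W_i)`; the embedding width is `n × per_order_dim`
(defaults n = 3, per_order_dim = 64, two layers, Xavier-uniform init).  In the
bipartite graph odd orders aggregate heterogeneous neighbours and even orders
homogeneous ones, so the concatenation mixes both relation types per layer.
Setting n = 1 reduces the encoder exactly to a plain GCN stack (verified
numerically), which is the "no mixed neighbourhood" ablation.

## Contrastive task

The corrupted view keeps the adjacency and row-shuffles the features (fresh
permutation each epoch).  Readout `s = σ(mean_i H_i)`; bilinear critic
`Γ(h,s) = σ(hᵀWs)`.  Both losses are binary cross-entropies over nodes; they
are evaluated in softplus form (`−log σ(x) = softplus(−x)`), which is exactly
the same function but keeps gradients alive when the critic saturates —
clamping probabilities into `[ε, 1−ε]` and taking logs zeroes the gradient
precisely where the critic is most wrong.

## Predictor

Embedding kernels use a fixed bandwidth γ = 2⁻⁵ on the raw embedding rows.
The Laplacians are the *symmetric* normalised form
`L = D^{-1/2}(D − K)D^{-1/2}`; an asymmetric normalisation would not yield a
valid quadratic penalty `tr(WᵀLW)`.  Orientation convention: `Wc` is Nc×Nd
and `Wd` is Nd×Nc, so that `KcWc` and `(KdWd)ᵀ` are both Nc×Nd and the
residual targets `2Y`.  The two coefficient blocks are solved exactly in
closed form:

    Wc = (KcKc + λc Lc + jitter·I)^{-1} Kc (2Y − (KdWd)ᵀ)
    Wd = (KdKd + λd Ld + jitter·I)^{-1} Kd (2Yᵀ − (KcWc)ᵀ)

with `jitter = 1e-6` for numerical safety (Gaussian kernel Grams can be
near-singular).  Alternating the two solves is exact coordinate descent on a
convex quadratic, so the objective is non-increasing per solve; two sweeps
per epoch are used (the subproblem converges fast; a fixed point is reached
to ~1e-9 within a few thousand sweeps and tests that need the joint optimum
iterate further).  Final scores `A* = (KcWc + (KdWd)ᵀ)/2` target the 0/1
association scale, which motivates the default 0.5 classification threshold
for the confusion-matrix metrics (the threshold is configurable; ranking
metrics do not depend on it).

## Training

Total objective `L = L1 + αL2 + βL3` with α = β = 0.5 (the balance weights
are otherwise unconstrained by the method; they are exposed in the config).
Per epoch: encoder forward → embedding kernels → closed-form coefficient
solves (kernels treated as constants) → evaluate `L1` with gradients flowing
through the kernels into the encoder, plus `L2`, `L3` on a fresh corruption →
one Adam step (lr 0.005, weight decay 1e-5, coupled L2-style decay) on the
encoder and critic weights.  Treating `Wc`, `Wd` as constants during
backpropagation is an envelope argument: they are exactly optimal given the
kernels, so their sensitivity contributes no first-order term, and it avoids
differentiating through a matrix inverse.  Gradients come from a small
reverse-mode autodiff engine written for this package (dense matmul,
broadcasted arithmetic, ReLU/sigmoid/softplus, reductions, concatenation, a
fused Gaussian-kernel op); every primitive is finite-difference tested.
All randomness (init, corruption, fold plans, negative sampling) derives
from one root seed via fixed per-stage CRC-derived seeds, so runs are
bit-reproducible on CPU.

Ablation variants, each a config flag: `no_rwr` replaces the random-walk
smoothing by a two-dimensional-PCA reconstruction of the similarity matrix
(projection onto the top-q column-covariance eigenvectors and back, q = 2 by
default — this keeps the Nc×Nc / Nd×Nd block shapes that the feature matrix
layout requires); `no_mn` forces n = 1; `no_cl` drops the contrastive terms;
`no_lr` replaces the predictor with an inner-product decoder
`σ(H^c H^dᵀ)` trained by logits-form binary cross-entropy.

## Synthetic benchmark

The generator plants one shared group structure across all three data
channels: circRNAs and drugs are assigned uniformly at random to `g` groups;
`Y(i,j) ~ Bernoulli(p_in)` for matched groups, `Bernoulli(p_out)` otherwise;
sequences are per-group random prototypes with i.i.d. substitutions;
fingerprints are per-group prototype bit vectors with i.i.d. flips.  Defaults:
Nc = 60, Nd = 40, g = 3, p_in = 0.3, p_out = 0.02, sequence length 120,
substitution rate 0.1, 64 fingerprint bits with flip rate 0.1 — sized so a
full cross-validation runs in seconds and noise levels keep the within-group
similarity clearly above the between-group level without making channels
deterministic.

What it does *not* emulate, and therefore what passing tests cannot show:
real host-gene sequences vary greatly in length (equal-length random
prototypes give a high Levenshtein-similarity baseline between unrelated
sequences); real fingerprints are sparse and correlated rather than
i.i.d.-flipped dense bits; real association matrices have heavy-tailed
degree distributions rather than homogeneous blocks; and conditional on the
planted groups the synthetic labels are exchangeable, so no method can rank
within a block better than chance.  Results on the planted benchmark
validate the machinery (leakage-free evaluation, determinism, direction of
ablation effects), not real-data performance.

## Behaviour on the planted benchmark, and limitations

Two properties of the objective are worth knowing when interpreting
held-out metrics on small dense benchmarks:

* The least-squares objective `L1` is globally minimised in the kernels by
  `K → I`, where the closed-form solves interpolate the training matrix
  exactly and held-out entries score near zero.  Joint training therefore
  tends to sharpen the kernels toward this interpolation regime; the
  contrastive terms and weight decay counteract it only weakly.  On the
  small planted benchmark this caps the transductive 2-fold CV AUC well
  below the group-information ceiling; the new-drug protocol, whose scores
  cannot use the held-out column at all, is the more discriminating
  validation of the learned drug-space geometry.
* The score class is additive — block-smoothed row effects plus column
  effects — so even ideal group-indicator kernels pool evidence per column
  rather than per block, which is noise-limited when half the positives are
  masked.

Other limitations: the embedding-kernel bandwidth γ is fixed, so the kernel
operating point depends on the embedding scale the encoder happens to reach;
training is full-batch and dense (fine for benchmark-scale data, not for
genome-scale matrices); and the model is transductive — scoring a drug absent
from the association matrix requires retraining with its column present but
empty (the `new_drug` protocol).
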