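# Methods

## Model

The package trains a single softmax classifier over a label space that
grows across an ordered sequence of increments (new classes and/or new
image domains). Three ingredients define the method:

**Joint-representation Gaussians.** For each sample the teacher's
(previous model instance, frozen) and student's temperature-softened
probability vectors are concatenated into a joint vector of width
d = w_old + w_new. Per class, the joint is modelled with one multivariate
normal fitted by the arithmetic mean and the unbiased (n−1) sample
covariance. For Gaussians the joint density equals both chain-rule
factorizations p(old|new,t)p(new|t) and p(new|old,t)p(old|t), so a single
fit per class serves both directions of the coupling. Class priors are
empirical counts; Bayes' rule in log space yields the class posterior of
each joint vector.

**The objective.** L_CL = L_N + L_MD + L_O. L_N is a KL divergence from
the (possibly soft) target label distribution to the student's softened
output, averaged over the batch; with one-hot targets it reduces to
cross-entropy. L_O is the categorical cross-entropy of the true labels
against the teacher's softened output. L_MD sums, over retained old
exemplars and over current samples, the negative log-posterior of the
true class at the joint vector, scaled by 1/τ². The scale reproduces the
published formula, which divides both the one-hot indicator and the
log-posterior by τ; because that reading makes the term a constant
rescaling of a cross-entropy, the unscaled variant is exposed as
`md_scale_mode="none"`.

**The protocol.** Per increment: expand the label space (existing indices
never move; the classifier head is widened with freshly initialized
columns), snapshot the previous model as the teacher, then run 20 epochs
of ADADELTA. At each epoch start the class priors and Gaussian
conditionals are refitted on the union of exemplars and new data; within
an epoch they are constants. After training, a uniform random subset of
the increment's data (default 20 per class) joins the exemplar memory.
The first increment has no teacher and trains with L_N alone.

## Gradient treatment

All gradients are analytic. Gradients flow through the student's
temperature softmax in L_N and through the student half of the joint
vector inside L_MD's posterior (d log p(c|v)/dv = s_c − Σ_k p(k|v) s_k
with s_k the Gaussian score); the fitted μ/Σ, the priors and all teacher
outputs are treated as constants — distillation practice, and nothing in
the source formulation differentiates through the fits. L_O carries no
student gradient under the adopted reading (see "Open choices");
retention pressure on the student comes from L_MD's exemplar sum.
Finite-difference checks confirm the analytic gradient to ~1e-7 relative
error.

Two numerical guards matter in practice:

* **Ridge.** Softened probability vectors live on the simplex, so the
  per-class covariance is rank-deficient by construction; a diagonal
  ridge (default 1e-4) is always added before the Cholesky
  factorization. Densities are evaluated via triangular solves, never an
  explicit inverse.
* **Point-gradient clipping.** The Gaussian precision scales like
  1/ridge, so in the first batches of an increment — before the
  per-epoch refits settle — the posterior point gradient can reach norms
  of a few thousand and erase the acquisition signal. Rows are clipped
  to norm 5.0 (`md_point_grad_clip`), the ~p90 of settled-gradient norms;
  `None` disables clipping and restores exact gradients (used by the
  gradient tests).
* **Probability floor.** Probabilities are floored at 1e-12 before any
  log, so early one-hot outputs keep every loss finite. Natural
  logarithms throughout.

## Training backend

The reference backbone is a small fully connected ReLU network
(flattened pixels → 64 hidden units → linear head) written directly in
numpy with manual backprop, so the whole pipeline is serial,
CPU-friendly and bit-deterministic given a seed. The optimizer is
ADADELTA in its original formulation (ρ = 0.95, ε = 1e-6, lr = 1.0);
only the optimizer name is fixed by the protocol, so these values are
recorded in every run's metadata. Convolutional backbones are out of
scope for the desk-scale benchmark; the model interface
(`forward`/`backward`/`widen_head`) is small enough to swap.

## Synthetic benchmark

The generator emulates the structural axes of the real corpora — not
their content: grayscale vs. color domains (modality shift), a
"multiple" class compositing ≥ 2 distinct contraband shapes under a
single label, a "normal" class whose count is exactly
`imbalance_ratio × positives` (the SIXray10/100/1000 design), and a
stratified 20/80 train/test split. Classes are geometric primitives
(disc, bar, cross, ring, wedge, blob) rendered at random scale and
rotation with additive Gaussian noise; position jitter is limited to
± size/8 because a pixel-space MLP has no translation invariance and the
20% split leaves roughly 12 training samples per class. Defaults
(`noise_sigma=0.2`, `items_per_class=60`, `image_size=24`) were frozen
after checking that an off-the-shelf linear probe reaches 0.80–0.98 per
domain and that nearest-centroid accuracy falls monotonically over
noise levels {0, 0.2, 0.5, 1.0}.

What a green test on this benchmark does establish: the loss kernels
match their formulas, the coupling term carries a real retention signal,
ablating it or the teacher reproduces catastrophic forgetting, and the
temperature has the expected interior optimum. What it does not: any
claim about X-ray or OCT photometric realism, detection of overlapping
objects, or the absolute accuracies reported for the real nine-dataset
corpora, which required a ResNet101 and GPU-scale training.

## Open choices (and how they were resolved)

* **Which layer is the "soft representation".** Temperature-softened
  class probabilities (the protocol converts logits to soft
  probabilities); raw logits or penultimate features are alternative
  readings not taken.
* **Rows entering L_O.** The teacher assigns zero probability to classes
  it never saw (its output is zero-padded to the current width), so
  samples of brand-new classes would contribute only a floor constant
  −log(1e-12) with no gradient. L_O is therefore evaluated on batch rows
  whose true class existed at snapshot time.
* **Exemplar participation.** Old exemplars feed L_MD's first sum only;
  L_N runs over current-increment samples. Mixing exemplars into L_N is
  a documented alternative that would blur the term's "acquisition"
  reading.
* **Baseline definitions.** `cross_entropy` is plain fine-tuning: no
  teacher, no exemplars, softmax at τ=1. `kl_distill` is classic
  soft-target distillation: one-hot cross-entropy on the new data plus
  KL(teacher-softened ‖ student-softened) over the teacher's classes at
  τ, no exemplars.
* **Degenerate inputs.** A one-hot target hitting a zero-probability
  posterior column yields +inf with a warning; a class present in the
  registry but absent from the current fit keeps prior count 0 and a
  −inf posterior column; a single-sample Gaussian requires a positive
  ridge.

## Limitations

* The backbone is a pixel-space MLP; absolute accuracies on the
  synthetic benchmark (≈ 0.36 cumulative after three domains at 20
  epochs) are far below the published large-scale numbers and are only
  meaningful relative to the baselines run under identical conditions.
* The temperature dependence is shallow at this scale: τ = 2 wins the
  sweep under the full 20-epoch protocol, but with heavy under-training
  (≤ 5 epochs) flatter softmaxes dominate trivially.
* Class-imbalance weighting is deliberately out of scope; the "normal"
  class dominates exactly as the emulated corpora's negatives do.
* Exemplar selection is uniform random; herding-style selection is left
  as a pluggable extension.
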