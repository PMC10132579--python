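# Methods

## Scope and data model

The package predicts quantitative phenotypes of inbred plant accessions
from genome-wide marker panels. Two input codings are supported, matching
how SV and TE/SNP panels are distributed in practice:

* **Phased VCF genotypes** — diploid call strings (`0|0`, `1|1`, `.|.`;
  unphased `/` separators are accepted everywhere) with the variant class
  taken from the `SVTYPE` INFO key or a symbolic ALT (`<INV>`, `<DUP>`,
  `<DEL>`). Only the GT subfield of FORMAT is consumed. Calls are stored
  verbatim; all interpretation happens in the encoders.
* **Integer-coded matrices** — cells in {1, 0, −1} meaning homozygous
  reference (1/1), heterozygous (0/1) and homozygous alternate (0/0);
  `NA`, `.` and empty cells are missing, any other value is cleaned to
  missing with a counted warning.

Marker order is file order throughout. No coordinate arithmetic is ever
performed (positions are metadata), and no re-sorting by (chrom, pos) is
applied: the convolutional model is order-sensitive, and file order is the
only ordering that is reproducible across both codings.

## One-hot encoding

Each (accession, marker) call becomes a fixed-width binary fiber: width 6
for SVs (a reference/alternate channel pair per SV type, ordered INV, DUP,
DEL), width 3 for integer-coded markers, width 2 for phased biallelic
SNPs/indels. Every fiber is one-hot or all-zero; all-zero is reserved for
missing and unmappable calls.

Two cases need a rule the encoding table does not print:

* **Heterozygous calls** in the phased schemes. The SV and biallelic
  schemes define channels only for the two homozygous states (the source
  panels come from naturally selfing species and contain only `0|0` and
  `1|1`). A heterozygous call therefore encodes as all-zero — the same as
  missing — and bumps a warning counter, rather than silently widening the
  printed channel layout.
* **Allele indices above 1** (multi-allelic records). No channel exists for
  a second alternate allele; such calls are treated as missing with a
  warning, both in the encoders and in dosage conversion.

Markers outside {INV, DUP, DEL} are dropped (with a logged count) before an
SV6 tensor is built.

## Network architecture and training

The regressor is a 1D CNN: four same-padded convolutional layers of 16, 32,
64 and 128 filters (kernels 5, 5, 3, 3), each a cross-correlation
`Y = F * X + B` (no kernel flip) followed by `ReLU`; one max-pooling layer
(window 2, stride 2) halving the sequence length; flatten; dropout 0.6; one
dense output neuron. Training minimises MAE with Adam at learning rate
3·10⁻⁴ for at most 150 epochs. The forward/backward passes, Adam and the
training loop are implemented in NumPy (`novgmdeep.nn`): convolutions are
evaluated as a single GEMM over sliding windows, and the backward pass is
checked against central finite differences in the test suite, with the
forward pass checked against a brute-force triple-loop cross-correlation.

Numerical and configuration choices (all exposed on `ModelSpec`):

* **Initialisation** — zero-mean normal with variance 1/fan-in
  (LeCun-style), seeded; biases start at 0. One integer seed drives
  initialisation, shuffling and dropout, so identical calls give identical
  loss histories.
* **Kernel regularisation** — an elementwise L1+L2 penalty on convolution
  and dense kernels, default `l1 = l2 = 1e-4`. The default is deliberately
  mild: with an MAE loss the data gradient of each weight is bounded by the
  mean activation it sees, while the L1 term contributes a constant
  gradient of `l1` per weight that Adam renormalises to a full-size step.
  At strengths around 10⁻² the penalty gradient dominates every weight's
  data gradient, the network collapses to predicting a constant and the
  validation loss never moves; at 10⁻⁴ the penalty is active but training
  curves show the steady joint decrease of training and validation loss
  that the architecture is designed for. (Diagnostics on the protocol
  conditions below: held-out mean PCC ≈ 0.41 at 10⁻⁴ and ≈ 0.00 at 10⁻².)
* **Batch size 32**, **early-stopping patience 30** epochs monitoring
  validation MAE, restoring the best epoch's weights. The patience is
  deliberately long relative to common defaults because an epoch on a
  panel of a few hundred accessions is only a handful of Adam steps: with
  the MAE loss at learning rate 3·10⁻⁴ the validation curve descends
  slowly and noisily, and a short patience (e.g. 10 epochs ≈ 50 steps)
  frequently halts training around epoch 30 while the curve is still
  drifting down. Thirty epochs ≈ 150 optimizer steps of no improvement
  before stopping matches the long steady descent this architecture
  exhibits.
* **Phenotype scaling** — off by default, so reported MAE/SD are in raw
  trait units. An optional z-scoring flag standardises y for training and
  inverse-transforms predictions and loss histories before any metric is
  computed.
* **Dropout placement** — after flatten, immediately before the dense
  layer. Inverted dropout is used, so inference is deterministic with no
  rescaling.
* **Degenerate inputs** — non-finite phenotypes, mismatched tensor shapes
  and non-finite losses raise immediately (training aborts with a
  diagnostic rather than returning a silently diverged model). An empty
  convolution stack is valid configuration: with pooling and dropout
  disabled the model reduces to a linear regression trained by MAE, which
  the tests use to verify the layer stack composes correctly.

## Evaluation protocol

Accessions are split 80/20 (train/test) by seeded permutation, the boundary
rounding half-up. The test rows are set aside before any model development.
The training portion is partitioned into 3 seeded, balanced folds; round f
trains on the other two folds and uses fold f itself as the early-stopping
validation set (no inner split is defined, and a separate one would shrink
the small training sets further). The three saved models are scored on the
test set; the headline number is the arithmetic mean of their three Pearson
correlations — correlations are averaged, predictions are never ensembled,
and no Fisher z-transform is applied. The test MAE and the population SD
(divisor N) of per-sample absolute errors come from the single model with
the lowest validation MAE. PCC raises on constant vectors rather than
returning 0, so a degenerate model is loud, not silently uncorrelated.

## Linear baselines

`rrblup_fit` fits y = 1μ + Zu + e (u i.i.d. normal) on alternate-allele
dosages (hom-ref 0, het 1, hom-alt 2; integer codes map 1→0, 0→1, −1→2;
missing cells are mean-imputed per marker). `gblup_fit` fits the equivalent
individual-level model on a relationship matrix; `grm` builds VanRaden's
method-1 matrix K = WW′ / (2Σpⱼ(1−pⱼ)) with columns centred by 2pⱼ.

Variance components are estimated by REML on the eigendecomposition of the
covariance kernel. The restricted likelihood is profiled down to a 1D
function of δ = σ²ₑ/σ²ᵤ and maximised by a 121-point log₁₀ grid scan
followed by bounded Brent refinement (xatol 10⁻¹²). The search range is
[10⁻⁶, 10⁶] × trace(K)/n: anchoring it to the kernel's scale makes the
estimate exactly invariant to K → K/c (with δ → δ/c), which is what lets
gBLUP on ZZ′/c reproduce rrBLUP predictions to ~10⁻¹⁴ — the package's
strongest cross-implementation oracle. Near-singular kernels get a 10⁻⁶
diagonal ridge before solving. The reported heritability estimate is
σ²ᵤ·v_g/(σ²ᵤ·v_g + σ²ₑ), where v_g is the genetic variance the kernel
implies for this sample (the sum of marker dosage variances for rrBLUP, the
mean diagonal of the double-centred kernel for gBLUP), so it is insensitive
to uncentred dosages or a constant shift of K.

Prediction for unobserved accessions uses the ridge solution Z*û (rrBLUP)
or the relationship cross-block K*,obs(K + δI)⁻¹(y − μ̂) (gBLUP); the
`GBLUPRegressor` estimator reuses the training-set allele frequencies and
denominator when building the cross-block.

## Synthetic data generator

The generator emulates the two panel types at configurable size. Phased SV
panels use an inbred-line model — each accession is homozygous alternate at
marker j with probability pⱼ ~ U(0.05, 0.5), otherwise homozygous
reference, with SV types drawn from a configurable INV/DUP/DEL mix — because
the species the SV panels describe are naturally selfing and carry only
homozygous calls. Coded panels draw genotypes at Hardy–Weinberg
frequencies, so heterozygotes occur there. Calls are masked to missing at
rate 0.02 by default.

Phenotypes are strictly additive: a sparse causal subset (default 30
markers) receives N(0, 1) effects, g = Zβ on dosages, and noise is scaled
so Var(g)/Var(y) equals the target heritability in expectation (default
0.8, matching a strongly heritable trait; the realised ratio converges to
the target as n grows and is verified within 0.05 at n = 2000). Non-causal
effects are exactly zero, which keeps effect-recovery tests sharp. One
global seed is split into per-stage substreams, so the same genotype panel
can be reused across phenotype replicates.

What the generator deliberately omits — linkage disequilibrium, population
structure, epistasis, genotype×environment interaction, allele-frequency
spectra estimated from real panels — bounds what passing tests show: they
demonstrate that the pipeline is correct and recovers known additive signal
under clean conditions, not that any architecture choice is optimal for
real SV/TE panels, where LD and structure can dominate.

## Problem sizes and expected behaviour

The end-to-end protocol checks run at 200 accessions × 300 SV markers
(h² = 0.8, 30 causal), the baseline benchmarks at 400 × 500 over several
replicate panels, and calibration checks at n = 2000 — sizes chosen so the
whole suite runs in minutes on one CPU while keeping the statistical checks
well-powered. At these sample sizes the linear mixed models outperform the
CNN on the generator's strictly additive data, and the CNN's cross-validated
mean test PCC sits well above zero on real signal while a
permuted-phenotype control stays near zero. That ordering is the expected
small-n behaviour — the network's advantage, when it has one, comes from
large panels and non-additive structure that the generator intentionally
does not produce.

## Known limitations

* The CNN engine is single-threaded NumPy; it is sized for panels of
  hundreds of accessions and up to a few thousand markers, not for
  genome-wide panels with 10⁵–10⁶ markers.
* Heterozygous calls carry no information in the phased SV/biallelic
  schemes (by construction of the channel layout); panels from outcrossing
  species should use the integer-coded scheme.
* REML uses a single 1D profile; models with additional fixed effects or
  multiple variance components are out of scope.
* BND records, indexed/compressed VCF access and INFO parsing beyond
  `SVTYPE` are not supported.
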