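# Methods

## Model and reconstruction conventions

The package reconstructs the RenalNet architecture from its published
description and its published ablation parameter budgets.  Several wiring
details are not stated anywhere and had to be fixed; wherever a choice was
open, the criterion was *exact integer agreement with the eight published
variant totals* (Proposed 213,174; CNN-1 182,886; GCNN-2 56,500; GCNN-3
208,582; GCNN-4 202,038; GCNN-5 219,964; GCNN-6 211,816; GCNN-7 207,742).
The conventions that follow are forced, or near-forced, by that arithmetic:

* **Two batch norms per MCRT path** (Conv3×3 with bias → BN → ReLU → SE → BN).
  One path at width `C` then carries `9C² + 5C` trainable parameters and the
  three MCRT stages at widths 16/32/64 with SE ratios (2,4,8) total exactly
  156,674.  A single-BN arrangement misses the budget by 672.  Whether ReLU
  precedes or follows the second BN is not decidable from counts; ReLU is
  placed before the SE gate.
* **SE units are two biased dense layers** `C → C/r → C` with ReLU inside and
  a logistic gate (`2C²/r + C/r + C` parameters).  Bias inclusion is forced
  by the uniform-ratio deltas (8,148 between ratios 2→4 and 4,074 between
  4→8 on the three-stage total).
* **Stem/transition/classifier closure (26,212).**  Conv3×3(3→16)+BN,
  Conv3×3(16→32)+BN, Conv3×3(32→64)+BN, then BN → Conv1×1(64→32) → BN →
  global average pool → FC(32→4).  Downsampling uses parameter-free 2×2 max
  pooling after each MCRT stage, with the transition convolutions applied at
  the pooled resolution.
* **Batch-norm "trainable parameters" are 2 per channel** (scale, shift);
  running statistics are buffers and excluded from all counts.

## Solving the head configuration

The GCDL head's internal widths are never published; only the variant totals
are.  Subtraction and inclusion–exclusion over those totals give exact
sub-budgets: shared strided fusion 14,560, ADSC-proper 11,136,
attention-proper 4,592 (head total 30,288).  `solve_reference_config`
searches integer widths under the package's fixed per-layer bias/BN policy
(strided convs biased + BN; separable merges depthwise-biased +
pointwise-unbiased + BN; ADSC branches unbiased + BN with a biased 1×1
projection; gate dense layers biased with BN on the output) and finds a
unique simultaneous solution: fusion widths (6, 9, 16), merge width 45, ADSC
branch width 21, gate bottleneck 40.  Two structural points deserve note:

* a **single** dense projection from the pooled descriptor to 64 factors has
  no integer solution for the 4,592 budget (`64·C_f + 192 = 4,592` gives
  `C_f = 68.75`), so the gate is a two-layer bottleneck, matching the SE
  idiom used everywhere else in the network;
* the attention projection output is **linear** (no squashing): the published
  formulation scales the stage-3 map by the pooled factors directly, and a
  linear projection also preserves the zero-weight-head ⇒ zero-output
  property;
* `X_AM` and the ADSC output are merged by **element-wise addition**, not
  concatenation: the classifier closure (26,212) requires a 64-channel input
  in *every* variant, and addition is the only merge under which the eight
  budgets decompose additively.

## FLOP accounting

`count_flops` charges 2 FLOPs per multiply-accumulate over convolutional and
fully connected layers only (depthwise convolutions divide by the group
count); batch norm, activations, pooling and element-wise work are excluded,
and totals are compared in units of 10⁹ at 3 significant figures.  Under this
convention one MCRT path convolution at 224² is 2·224²·9·16·16 =
231,211,008 FLOPs and the assembled reference model totals **2.53 G**.

The published complexity figure for the reference model is 2.71 G.  That
value is not reachable by *any* per-layer accounting consistent with the
published parameter totals: the MCRT convolutions are pinned at 2.08 G by
the 156,674-parameter closure and the 224/112/56 stage geometry, and the
remaining 56,500 parameters can contribute at most ≈0.19 G at the available
resolutions (placing a transition convolution before its pooling step
overshoots to ≥2.87 G).  The published ablation FLOP column is also
internally inconsistent: the attention-only variant (a few thousand dense
parameters, ~10⁻⁵ G) is quoted *above* the ADSC-only variant (eleven thousand
convolutional parameters at 56², ~0.07 G).  The package therefore reports
the honestly computed total and documents the discrepancy rather than tuning
the convention to hit the quoted number.

## Synthetic benchmark

`synthetic_data` emulates the *statistical structure* of the study dataset —
four balanced classes, 1,100 patches/class drawn from ~170 cases/class, a
per-case stain state shared by all patches of a case — with deterministic
per-patch rendering (a patch's image is a pure function of the global seed
and its (class, case, patch) key, so regeneration is byte-identical).

Class signatures are coarse morphological caricatures on an eosin-pink
stroma: tubule rings (Normal), clear vacuoles with rim nuclei (KIRC), densely
nucleated papillary fronds (KIRP), large pale cells with perinuclear halos
and prominent membranes (KICH), with hematoxylin-purple nuclei throughout,
per-case stain jitter (σ = 0.04 in RGB) and pixel noise (σ = 0.02).  Default
densities/radii were chosen once to be visually distinct at 224² and are the
fixed study conditions of the test suite.  The renderer does **not** emulate
real chromatin texture, stain deconvolution physics, scanner artefacts, or
pathologist ROI selection — so green tests demonstrate protocol and
implementation correctness, not clinical performance.

**Protocol.**  Splitting is case-wise ("slide-wise" with one slide per case):
a subset-sum packer selects whole cases so the test side hits the protocol's
printed per-class cardinality exactly (158 of 1,100 per class, i.e. 632 test
patches — marginally under a strict 15%); for non-reference sizes the target
defaults to round(0.15·n) with a nearest-achievable fallback when case sizes
cannot meet it.  The 5-fold partition is class-stratified and case-respecting
with rebalanced nearly-equal targets (exactly 880 per fold, 220 per class, at
the reference cardinalities).  The quoted protocol's "5 folds of 880 images
of each class" is internally inconsistent (880 = 4,400/5 is a per-fold total)
and is implemented as 880 per fold.

**Learnability floor.**  A small reference classifier (gradient-boosted trees
on translation-invariant color/texture summaries) must reach macro-F1 ≥ 0.90
on the case-disjoint test side at full scale.  This is a sanity floor on the
generator's class separability, not a claim about the CNN.

## Training and evaluation

Adam (initial learning rate 10⁻³), batch size 4, categorical cross-entropy,
65 epochs; learning rate halved when validation accuracy fails to improve by
10⁻⁴ for 5 epochs; early stopping after 30 stalled epochs with best-weight
restoration (checkpoints include batch-norm running statistics).  The
validation set is 10% of training patches, case-respecting (the size is a
documented choice; the reference protocol only states that validation patches
are drawn from the training set).  Per-image, per-channel normalisation to
zero mean/unit variance (variance floor 10⁻⁸) after bilinear, antialiased
resizing to 224².

Metrics: per-class precision/recall/F1 from the confusion matrix, per-class
one-vs-rest accuracy, macro (unweighted) overall precision/recall/F1, micro
overall accuracy, and per-class one-vs-rest ROC-AUC (trapezoidal, verified
against the Mann–Whitney pair statistic in tests).  A class absent from both
truth and predictions is reported as NaN and excluded from macro means with a
warning.  Activation maps are gradient-weighted CAMs over the pre-classifier
features, min-max normalised and banded at 0.7/0.4 into red/orange/light-blue.

## Problem sizes used by the test suite

The network is fully convolutional up to its global pool, so the same
parameter-exact model runs at any input size divisible by 4; the suite
exploits this.  Training demonstrations use reduced resolutions (16²–32²)
and small patch counts (a 200-patch, 5-epoch smoke run of the full reference
architecture at 32²); accounting, protocol-cardinality and learnability
checks run at the full reference scale (224² input spec; 4,400 patches).
The numpy training loop is single-threaded BLAS — a full 224² training run of
4,400 patches is possible but takes hours, which is why behavioural tests are
scaled down.

## Numerical notes

* Batch norm uses ε = 10⁻⁵; gradient checks run in eval mode (affine BN) in
  float64, comparing an analytic Jacobian-vector product against central
  finite differences (ε = 10⁻⁴, agreement < 10⁻³ required, typically ~10⁻¹⁰).
* Max pooling breaks ties by first-index argmax; gradients route to a single
  winner.
* The logistic is evaluated in its numerically stable split form.
* Dilated 3×3 convolutions pad by the dilation rate, so every ADSC branch is
  exactly shape-preserving; a dilation-d depthwise impulse response is the
  dilated 3×3 stencil (property-tested).

## Known limitations

* The renderer is a stand-in; none of its appearance parameters were fitted
  to real H&E statistics.
* Published real-data accuracies (and training wall-times) require the
  original WSI-derived patches and GPU-scale training and are out of scope;
  the property suite substitutes identity/gradient/oracle/learnability
  checks.
* The published FLOP total is not reproducible from the published parameter
  totals (see above); the package's FLOP ledger is self-consistent and
  auditable instead.
* Grouped convolutions other than dense (groups=1) and depthwise
  (groups=C_in) are implemented but not used by any variant.
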