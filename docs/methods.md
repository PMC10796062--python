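# Methods

## Scope and data model

The package segments 2D axial slices of multimodal brain MR volumes into
the three nested tumor regions (WT ⊇ TC ⊇ ET) used in brain-tumor
benchmarks. Volumes are (H, W, D) arrays; multimodal data is (4, H, W, D)
with the fixed channel order (t1, t2, t1ce, flair). Labels take values
{0, 1, 2, 4}; the region algebra is wt = {1,2,4}, tc = {1,4}, et = {4},
which forces et ⊆ tc ⊆ wt pointwise — this nesting is validated or
guaranteed by construction throughout.

## Preprocessing

Per modality, the full 3D volume is Z-scored (population SD, ddof=0) before
slicing; label volumes are never normalized. The default normalization
support is all voxels; `norm_support="nonzero"` restricts the statistics to
nonzero (brain) voxels for data where the background dominates. A constant
volume (SD 0) maps to zeros with a warning rather than an error, since empty
fixtures are common in tests.

Cropping uses a deterministic centered window (240 → 160 for BraTS-shaped
grids; generally `(n − c)//2 … (n − c)//2 + c − 1` per in-plane axis),
applied identically to intensities and labels. A centered window was chosen
over a brain-bounding-box crop because phantom and BraTS brains are
approximately centered and a fixed window keeps image/label alignment
trivial; phantoms are generated with the tumor inside the central crop
region.

Slicing runs along the third axis in ascending order. "Tumor-free" slices —
no voxel in {1, 2, 4} *after* cropping, since post-crop content is what the
model sees — are discarded for training; `keep_empty=True` retains them for
whole-volume evaluation and prediction.

## Phantom generator

Each case is a centered brain ellipsoid (85% of each half-extent) containing
three concentric spherical compartments: necrotic core (label 1) inside an
enhancing shell (label 4) inside edema (label 2), all clipped to the brain
mask. Outer radii default to (30, 18, 10) voxels on the 240×240×155 grid and
(10, 6, 3) on the small 64×64×24 grid. Intensities are piecewise-constant
tissue-class means per modality plus i.i.d. Gaussian noise (SD 0.03 in
intensity units where tissue means span ≈0.2–0.95); background mean is 0 in
every modality. Contrasts are chosen so each region is most conspicuous in a
different modality (edema brightest in flair, the enhancing shell in t1ce),
making multimodal fusion genuinely informative.

Per-case variation: the tumor center is jittered uniformly (±3 voxels
default, ±2 small) and all radii share a ±10% relative jitter, drawn from a
stream seeded by (seed, case_index) — so a fixed seed is byte-reproducible
and a case's content does not depend on how many cases are requested.

What the phantoms do **not** emulate: bias fields, MR physics, registration
error, anatomical texture, tumor-shape irregularity, or HGG/LGG grade
structure. Consequently a passing convergence test demonstrates that the
pipeline (normalization, fusion, network, loss, optimization, evaluation)
is wired correctly and can fit a separable segmentation problem; it says
nothing about accuracy on clinical data.

## Network

Classic U-Net scaffolding with dense blocks everywhere (encoder, bottleneck
and decoder stages are all dense blocks). A dense layer is BN → ReLU → 3×3
conv (padding preserves dims) emitting `growth_rate` channels; layer i
receives the concatenation of the block input and all previous outputs, so
a block maps c → c + L·growth. Transitions are BN → ReLU → 1×1 conv →
2×2 average pooling with channel compression ⌊θc⌋. The decoder upsamples
with 2×2 stride-2 transposed convolutions (a nearest-neighbour + 1×1 conv
alternative is available), compresses by θ, concatenates the same-scale
encoder skip, and applies a dense block. The head is a 1×1 convolution to 4
classes and a per-pixel softmax; class index i maps to label (0, 1, 2, 4)[i].

Defaults: 5 scales, block depth 4, growth 16, θ = 0.5, stem 32 — DenseNet-BC
style conventions at classic U-Net depth; the architecture literature the
model follows does not pin these, so they are configurable, and channel
bookkeeping (`plan_channels`) is derived rather than hard-coded. The small
test configuration is 3 scales / depth 2 / growth 8 / stem 16. No dropout
(dense connectivity is the overfitting control); He-normal init from a
seeded generator, so construction is reproducible.

Region probabilities for the loss come from the softmax head:
P(WT) = p1 + p2 + p3, P(TC) = p1 + p3, P(ET) = p3. This resolves the tension
between a 4-class softmax head and per-region binary losses without a
second head, and makes predicted-region nesting hold by construction in
both probability and argmax space.

## Losses

BCE is the pixel mean of −w[t log p + (1−t) log(1−p)] with p clamped to
(1e−7, 1−1e−7); w defaults to 1. The Tversky index uses soft set sizes
(|A∩B| = Σpt, |A−B| = Σp(1−t), |B−A| = Σ(1−p)t) plus a smoothing ε = 1e−6 in
numerator and denominator so empty-region slices are well-defined. The index
is maximal at perfect overlap, so the trained quantity is 1 − TI — the
standard Tversky-loss construction and the only reading under which the
BCE + Tversky sum is minimizable; the raw index is exposed separately.
Dice and Jaccard losses are implemented *as* the α=β=0.5 and α=β=1 special
cases, so those identities are structural, not numerical accidents. The
hybrid loss is computed per region channel and averaged over the three
regions with equal weights (per-label computation is available via
configuration). α = 0.3, β = 0.7 by default: β > α penalizes false negatives
harder, the appropriate asymmetry when the foreground is rare.

## Metrics

Dice, PPV and sensitivity come from exact integer confusion counts; Dice
equals the harmonic mean of PPV and sensitivity wherever both are defined,
and the suite checks this identity. Hausdorff distances are Euclidean in
pixel units on the cropped 2D grid (3D volume comparison uses voxel units);
directed distances are nearest-neighbour queries via a k-d tree, verified
in tests against an exhaustive all-pairs oracle. HD95 is the 95th percentile
(linear interpolation) of the two pooled directed distance lists; a literal
"0.95 × maximum" variant is available (`method="scaled_max"`) because the
definition is stated ambiguously in parts of the segmentation literature,
without asserting which reading any particular paper used.

Degenerate conventions, always flagged in reports: both masks empty →
overlap metrics 1 and distance 0; exactly one empty → overlap metrics 0 and
the image diagonal as the distance sentinel.

## Training

Adam (β₁ = 0.9, β₂ = 0.999) with L2 weight decay 1e−4 folded into the
gradient, constant learning rate 3e−4, batch size 32, 55 epochs, softmax
head — the reference hyperparameters for this architecture family. No
learning-rate schedule (only an initial rate is specified anywhere), no
augmentation. The split is by *case* (80/20, seeded) so adjacent slices of
one volume never straddle train/val. Per-epoch logging records train/val
mixed loss and whole-tumor IoU (train IoU is computed from the training
forward passes themselves; validation in eval mode with frozen BN
statistics). The best-validation-IoU checkpoint is kept; NaN loss aborts
with a diagnostic. Two runs with one seed on one device produce identical
curves (pure numpy arithmetic, seeded init/split/shuffling).

The `small` preset overrides epochs (10), batch size (8) and model size
(the small configuration) only; learning rate, weight decay and the loss
are unchanged.

### Problem sizes used by tests and the acceptance script

The desk-scale study set is 16 small-grid phantom cases (64×64×24, crop 48),
≈ 300 tumor-bearing slices, trained for 10 epochs per seed — about 100 s per
run on one CPU core. The convergence check requires final validation
IoU(WT) > 0.8 with a decreased final loss for ≥ 4 of 5 seeds (in practice
all seeds reach IoU ≈ 1.0 by mid-training). The loss-ablation harness runs
the three mixtures (BCE+Tversky, BCE+Dice, BCE+Jaccard) through an
identical pipeline; in the test suite it uses 2-epoch runs, since the check
is about pipeline structure, not asymptotic values. Unit tests use an even
smaller 4-case, 32×32×12 store.

## Numerical and engineering notes

The autograd core is a tape-based reverse-mode engine over numpy arrays
with the primitives this model family needs; convolution is im2col in a
channel-major layout so forward and both backward products are single
GEMMs. Large patch matrices are recycled through a refcount-based buffer
pool — repeated allocation of tens-of-MB workspaces otherwise dominates
single-core runtime through page-fault churn. Graphs are strictly acyclic
(a test asserts zero cyclic-GC collections across training steps), so memory
is reclaimed promptly by reference counting. Network parameters are float32;
loss computations promote to float64 where numpy broadcasting dictates.

Known limitations: 2D slices only (no inter-slice context); no bias-field
or physics realism in phantoms; constant learning rate; pixel-unit (not
mm) distances; single-device CPU-oriented implementation — sufficient for
the desk-scale studies here, not for full-resolution clinical training runs.
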