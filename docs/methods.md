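# Methods

## Problem and model

Digitized screen-film mammograms (DFM) and full-field digital mammograms
(FFDM) depict the same anatomy with different acquisition statistics: film
scans have compressed contrast, a faded breast boundary, heavier grain and
softer edges. Large annotated archives exist mostly in film form, while
modern screening models need digital-looking inputs. `mammogan` learns an
unpaired translation G: DFM → FFDM (and its inverse F) so that existing
film archives can pretrain digital-domain screening models.

The model is a cycle-consistent adversarial pair. Two generators G and F
are residual U-Nets; two critics D_X (film domain) and D_Y (digital
domain) judge realism. For a film patch x and an independently drawn
digital patch y:

* critics minimize, per pyramid level l ∈ {1,2,3},
  `L(D) = Σ_l [ mse(D^l(real^l) − m_1^l) + mse(D^l(fake^l) − m_0^l) ]`
* generators minimize
  `L(G) = Σ_l mse(D_Y^l(G(x)^l) − m_1^l) + λ ‖F(G(x)) − x‖₁` (and the
  mirrored `L(F)`), with λ = 10.

Each squared-error term is a mean over pixels and both output channels,
then summed over the three levels; the cycle term is a mean absolute
error. The mean-then-sum reduction keeps λ = 10 meaningful regardless of
patch size.

### Gradient-augmented multi-scale critics

A critic never sees a raw patch. Level l receives the patch downsampled by
2^(l−1) (2×2 average pooling) concatenated with the Sobel
gradient-magnitude map of that downsampled image. The gradient channel
emphasizes exactly the structures film degrades — the skin line and
micro-calcifications. Gradient maps are computed *after* downsampling, not
downsampled from the fine scale. Sobel responses are divided by 8 so a
unit-slope ramp has unit magnitude, keeping the gradient channel on the
intensity channel's scale. During the generator update, gradients
backpropagate through the pooling and the Sobel magnitude (with a zero
subgradient at zero magnitude).

Each critic level outputs a two-channel map: a real/fake prediction plane
(kept linear, least-squares GAN) and a sigmoid breast-region probability
plane. Its target m_i^l stacks a constant label plane (1 = real, 0 =
fake) and the patch's breast mask area-downsampled to the output
resolution — real-valued in [0,1] at coarse scales, i.e. soft targets. For
a synthesized patch the spatially aligned source patch's mask is used (it
is the only aligned mask that exists). Supervising the critics with the
mask forces the generators to respect the inside/outside distinction even
where the film boundary is barely visible.

### Category-constrained pairing (PWC)

Patches (default 256×256 at 0.1 mm; 32×32 in the tiny preset) are
categorized by the fraction of background in their mask crop: exactly 1 →
background, exactly 0 → breast, otherwise boundary. A training pair is
drawn film-first: a film patch uniformly from the whole pool, then a
digital patch uniformly from the *same category*. This never pairs, say,
empty background with dense tissue, which would feed the cycle and
adversarial losses meaningless pairs. When the digital pool lacks the
drawn category the film draw is repeated (counted and logged); a strict
error mode exists.

### Networks

Generators: residual U-Nets — stem convolution, then per level
`n_res` residual blocks and a stride-2 convolution (reflection padding
everywhere), mirrored on the way up with nearest-neighbour upsampling,
skip concatenation and a fusing convolution, ending in a tanh. Defaults:
depth 4, base width 64, 2 residual blocks per level; the tiny preset uses
depth 2, width 16, 1 block. Critics: per scale, `n_layers` stride-2
kernel-4 convolutions with leaky-ReLU and a 1×1 convolution to 2 channels
(defaults: 4 layers, width 64; tiny: 2 layers, width 16); the three scales
share no weights. All convolutions initialize from N(0, 0.02); biases at
zero.

**No normalization layers.** Instance or group normalization would make a
patch's output depend on image-global statistics, breaking the equality
between whole-image and tiled inference that the fully-convolutional
design guarantees (and that the test suite checks to 1e−4). At the scales
this package trains, adversarial optimization is stable without them; the
choice trades some large-model stability for an exact spatial-locality
contract.

### Training protocol

Alternating updates: per iteration the critics update first (generator
outputs detached), then the generators update against the refreshed
critics. Adam with (β1, β2) = (0.5, 0.999), batch 16, learning rate 5e−4
held for 80 epochs then decayed linearly to zero over 120 more. An epoch
is one pass of `max(|film pool|, |digital pool|)` sampled pairs — the
pools are unpaired, so epoch length is a convention. Desk-scale runs are
specified in iterations instead (`max_iters`). One seed fans out (via
`numpy.random.SeedSequence.spawn`) to the four network initializers and
the pair sampler; checkpoints store all four networks, both optimizers and
the sampler state, so a resumed run reproduces the uninterrupted loss
trace bit for bit.

As an implementation detail, the generator forward graph is built once per
iteration and shared by both phases: the critic update consumes detached
fakes, and the generator update backpropagates through the same cached
activations against the updated critics. This is exact, not an
approximation — the critic step does not touch generator weights.

Training runs in float32; the engine (a small reverse-mode autodiff over
numpy arrays, `mammogan.autodiff`) preserves the input dtype, so tests
that need float64 precision get it by passing float64 arrays.

## Preprocessing

Images resample bilinearly to an isotropic target spacing (default
0.1 mm); masks resample nearest-neighbour so they stay binary. Intensities
map linearly from a percentile window (default min–max; tighter
percentiles available for film scans with specular outliers) to [−1, 1].
The breast mask comes from OTSU thresholding over a 256-bin histogram of
the whole mammogram — computed before tiling, because background-only
patches have no stable threshold — keeping only the largest connected
component by default. Dark background is an asserted convention, not
auto-detected.

## Phantoms

The synthetic-data generator targets *statistical*, not anatomical,
realism: it must give the categorization, pairing, gradient and loss
machinery a measurable domain gap. Each anatomy is a half-elliptical
breast (chest wall at the left edge, small nipple bump) with a
low-frequency Gaussian random field as tissue texture, 1–3 Gaussian blobs
as masses and a few 1–3 px specks as micro-calcifications, rendered twice:

* film: intensities ×0.45, boundary faded by a blurred-mask profile,
  Gaussian blur, correlated grain, small fog offset;
* digital: full contrast, unsharp-mask sharpening, mild white noise.

The film contrast scale must stay below the digital one — the
domain gap's direction is a construction invariant, checked per sample.
Defaults: 256×512 canvas at a nominal 0.1 mm; the tiny preset is 64×128
with 32 px patches. Mass radii in the tiny preset (6–10 px) are chosen so
that lesions survive the 4× downsampling of the segmentation task with at
least a couple of pixels. Pools for training are split by anatomy (film
patches from one half, digital from the other), so the unpaired setting is
genuine and no anatomy leaks across domains. Patch categorization in the
pools uses the pipeline's own OTSU masks, exactly as real data would;
ground truth rides along for evaluation only. What phantoms do **not**
model: X-ray physics, scatter, compression-thickness gradients, vendor
post-processing, real parenchymal texture. Tests passing on phantoms show
the machinery is correct and the optimization behaves as designed — not
that clinical image quality is achieved.

## Inference

Generators are fully convolutional, so patch-trained weights apply to
whole mammograms: reflect-pad to the next multiple of 2^depth, one forward
pass, crop. An overlap-tiled mode exists for very large images: the canvas
is divisor-aligned once, tiles overlap by a margin, and only tile cores
are kept. With a margin at least the (empirically measured)
receptive-field radius, tiled and single-pass outputs agree to float
noise; `receptive_field_radius` measures the radius by single-pixel
perturbation.

## Downstream evaluation

Two screening tasks measure whether translated images are *useful*:

* **Mass segmentation** — images downsampled 4× (the 0.4 mm working
  resolution for this task), small sigmoid U-Net (depth 1, width 8),
  trained with BCE + soft-dice (plain BCE collapses to the empty
  prediction under the extreme foreground imbalance of small lesions),
  scored by the Dice coefficient 2|A∩B|/(|A|+|B|); empty-vs-empty is
  defined as 1.0.
* **Calcification detection** — non-overlapping tiles at full working
  resolution, tiles with more than 80 % background removed, label 1 iff a
  calcification coordinate falls inside; a small stride-2 convolutional
  classifier scored by ROC AUC (computed as the Mann–Whitney statistic via
  midranks, so ties count half).

Protocol: fivefold cross-validation grouped by anatomy (no subject
straddles a split). The *baseline* arm trains from scratch on the fold's
real training split (400 steps, lr 1e−4 segmentation / 5e−4 detection).
The *finetuned* arm starts from a model pretrained **once** on the
synthesized-digital set — the pretraining set does not depend on folds —
for 1200 steps (to convergence on that set) and then continues on the real
split at lr 5e−5. Both arms share the per-fold initialization seed and
training-step budget, so the comparison is paired. With an empty
pretraining set the finetuned arm collapses to the baseline by
construction. Results are reported as mean ± sd per arm plus per-fold
paired differences and a sign count; no significance test is attached —
at desk scale the comparison is directional.

## Numerical choices and degenerate inputs

* OTSU: 256 uniform bins over the image's own min–max; constant images are
  a degenerate-input error. Thresholding is strict (`> t` is foreground).
* Normalization of a constant image returns all zeros (lenient mode) or
  raises (strict).
* `sqrt` in gradient magnitudes uses a zero subgradient at zero; L1 uses
  `sign`, so exact ties contribute zero gradient.
* Area-downsampling of masks uses exact block means when shapes divide,
  bilinear zoom otherwise, clipped to [0, 1].
* Divergence (non-finite loss) raises immediately and dumps a checkpoint.
* AUC on a single-class fold is undefined and reported as NaN rather than
  fabricated.

## Problem sizes used by the shipped checks

Desk-scale runs use the tiny preset throughout: 12 anatomies (64×128) for
translator training at 500 iterations / batch 4, three training seeds; 20
real + 30 synthesized anatomies for the transfer protocol at 5 folds × 3
seeds. These sizes were chosen as the smallest at which the training
signal (falling cycle loss, contrast-gap closure, pretraining benefit) is
reproducible across seeds.

## Known limitations

* Phantom realism is statistical only; no claim transfers to clinical data
  without retraining on real mammograms.
* The reference-BLAS numpy backend makes large presets (depth 4 / width
  64 at 256×256 patches) impractically slow on one CPU; the architecture
  supports them, the wall clock does not.
* No identity/appearance loss and no fake-history buffer — both are common
  cycle-GAN extras deliberately excluded from this loss system.
* Whole-slide-scale images are handled by the tiled mode only; memory use
  of single-pass inference grows with the full activation pyramid.
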