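# Methods

## Problem and approach

Tracing neurites from 3D optical microscopy stacks fails most often where it
matters most: on segments whose intensity sits near the noise floor.
Supervised 3D CNN segmentation solves this but demands voxelwise manual
annotation. `neurimine` implements the weakly supervised alternative: the
training labels are manufactured from an automatic tracer's skeletons, and the
label set is then improved by the network itself, in a closed loop that
exploits two structural priors — neurites are *tubular* and *continuous*.

One round of the loop:

1. **Pseudo-labels (S1).** Traced skeletons are pruned of isolated short
   components and short terminal branches, resampled so consecutive centerline
   voxels are 26-adjacent, and dilated into radius-2 cylinders. Radius 2 is
   the low end of the typical neurite radius (2–4 voxels): labels deliberately
   under-fill the tube so that nearly every labeled voxel really is neurite.
2. **Training (S2).** A voxelwise 3D residual network is trained on randomly
   sampled cubic patches with a hybrid loss (below).
3. **Prediction (S3).** The foreground posterior is assembled over the full
   volume by 50 %-overlap sliding-window tiling with uniform averaging.
4. **Mining (S4).** Argmax foreground voxels form seed components (objects
   under 200 voxels dropped as noise). Each component is flood-grown over
   voxels whose probability exceeds a threshold fixed *before* growth: the
   mean posterior over the component's 5³−1 shell (124 offsets, seed
   excluded). The grown region is thinned to a medial-axis skeleton, short
   terminal branches are pruned, and radius-2 cylinders around the skeleton
   become the next label generation.

Rounds repeat until the Dice between successive label generations reaches
0.995 or an iteration cap (3 by default, 3–5 in practice) is hit. Finally the
posterior is blended back into the image, `F = δ·I + (1−δ)·I_M·P` (δ = 0.7,
`I_M` the maximum representable intensity), lifting weak neurites into the
working range of any downstream tracer.

## Network and loss

The architecture is a VoxResNet-style deeply supervised residual network:
two full-resolution 3×3×3 convolutions (base width 32), three stride-2
downsampling convolutions (width 64) interleaved with six residual modules
(BN → ReLU → conv, twice, plus identity shortcut), and four auxiliary
branches — one per resolution — each a transposed convolution back to full
resolution followed by a 1×1×1 classifier. Branch outputs are summed and
softmax-normalized per voxel. The census is exactly 21 convolutional and
4 deconvolutional layers.

The loss is `σ·loss_ce + loss_dice` with σ = 0.5 and

    loss_ce   = mean_i( −α g_i log p_i ),  α = Σg_i / m
    loss_dice = 1 − (2 Σ p_i g_i + ε) / (Σ p_i + Σ g_i + ε),  ε = 1

The cross-entropy form is implemented verbatim as the default
(`ce_variant="as_printed"`); note it carries no background term, so on its
own it cannot penalize false positives — the Dice term does that work. A
`balanced` variant (−(1−α) g log p − α (1−g) log(1−p)) is provided.
Probabilities are clamped to [1e−7, 1−1e−7] before logarithms. The sum in the
cross-entropy is averaged over the m voxels; the printed form leaves this
open, and the mean keeps σ meaningful across patch sizes.

Patches with fewer than α₁·V foreground voxels (α₁ = 0.001, V the patch
volume; strict `<`) are rejected as blank. Survivors are augmented —
in-plane 90° rotations, axis flips, contrast/brightness jitter, occasional
light Gaussian blur — and standardized to zero mean, unit variance.

The network, backprop and SGD are implemented directly in numpy (im2col
convolutions lowered to GEMM; transposed convolutions restricted to
kernel = stride). This keeps the package dependency-light and fully
CPU-reproducible; the backward pass is verified against finite differences in
the test suite.

## Optimization profiles

The **reference profile** uses the canonical schedule: SGD, initial learning
rate 0.01 halved every 4 epochs, momentum 0.9, weight decay 5e-4, batch
size 3, up to 100 epochs, patches of 120³ or 64³.

The **desk profile** (`PipelineConfig.desk()`) is the CPU-scale configuration
the test suite runs: 8 base channels, 32³ patches, 24 patches/epoch,
20 epochs per mining iteration. At this scale (~160 SGD steps) the reference
schedule decays the learning rate long before the Dice-loss plateau at
p ≈ 0.5 is escaped — the Dice gradient per voxel is O(1/Σp), tiny in flat
regions — so the desk profile uses lr 0.05 halved every 8 epochs, which
converges reliably on all pinned seeds. Auxiliary classifier heads are
zero-initialized (a standard deep-supervision choice) so every run starts
from exactly p = 0.5 with an unsaturated softmax.

## Mining: numerical choices

* **Growth neighbourhood.** Growth uses 26-connectivity by default
  (`grow_neighborhood ∈ {6, 18, 26}`): growth must be able to follow neurites
  out of plane, and the thinning stage assumes 26-connectivity. The
  threshold's shell neighbourhood is always the 5³−1 cube.
* **Threshold scope.** `thre` is computed per connected seed component
  (`thre_scope="component"`), not globally: a weak neurite near a bright one
  would otherwise inherit an unreachable threshold. A `global` switch
  preserves the alternative. When a component has no shell (it fills the
  volume), growth is a no-op for it.
* **Strict inequalities throughout:** growth admits `s(v) > thre`; objects
  with volume `< 200` voxels are removed; patches with foreground `< α₁V`
  are rejected; metric matches use `< n` and "different structure" uses
  `> threshold`.
* **Degenerate thinning inputs.** 3D medial-axis thinning (Lee) can delete a
  plate-like component entirely (a 2-voxel-thick bar has no interior voxel).
  Any component whose skeleton vanishes is kept whole instead, preserving the
  26-connected component count.
* **Convergence.** "Labels converge" is operationalized as Dice between
  successive generations ≥ 0.995. A mid-loop stage failure (e.g. a label
  generation too empty to sample patches from) aborts the loop with the last
  good state.
* **Re-training.** Each iteration trains a fresh network on the current
  labels rather than fine-tuning the previous one, so every generation's
  quality is attributable to its labels alone.

## Evaluation

Skeletons are resampled root-to-leaf at 1-voxel arc-length spacing before any
comparison. Precision is the fraction of traced points whose nearest gold
point lies strictly within n = 6 voxels (about one neurite diameter); recall
is the reverse direction. The distance criteria: ESA12/ESA21 are directional
mean nearest-point distances, ESA their average; PDS is the fraction of
pooled points (both directions, mirroring ESA's bidirectionality; a
`directional` switch restricts to gold→test) farther than 2 voxels from the
other skeleton, and DSA the mean distance over those points (0 when none).
PDS is reported as a fraction. An undefined metric (empty reference set) is
reported as missing, never as 0.

## Synthetic phantoms

The phantom generator emulates the targeted data regime: smooth
bounded-curvature random 3D paths (≥20 resampled points, reflecting off the
volume boundary) rendered as tubes of radius 2–4 voxels with Gaussian radial
intensity falloff (σ = radius/2) over a noisy background. Defaults, chosen as
a plausible dim 8-bit fluorescence stack: 64³ volume, 2 neurites, background
40, peak 160, Gaussian noise σ 10 (foreground–background contrast ≈ 12σ at
the core), optional Poisson noise. A contiguous 20 % stretch of each path is
rendered at intensity 50 — one noise standard deviation above background —
the "weak neurite" the mining loop must recover. The generator also emits the
sub-skeleton covering only the bright stretches (`Phantom.traced`),
emulating what a threshold-based tracer recovers; pipeline runs build their
initial pseudo-labels from it.

What the phantom does **not** model: optics PSF anisotropy, axial spacing
anisotropy, somata, dense axon bundles, branching beyond simple geometry, and
intensity autocorrelation of real backgrounds. Passing tests therefore
demonstrate the mechanics of the method — label construction, trainability,
mining recovery of near-noise-floor segments, metric correctness — not
performance on real brain volumes.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the desk profile end to end on
64³ phantoms with three mining iterations (a few minutes per phantom on one
CPU core); oracle-equivalence suites use 100 random 16³ instances (region
growing) and 20 random ≤32³ instances (cylinder rasterization). The
end-to-end check measures gold-skeleton recall (match radius 6) of each label
generation on three pinned-seed phantoms and requires the final generation to
be at least as good as the first, reaching ≥0.85 on at least two of three.

## Known limitations

* The numpy network is CPU-bound; the reference profile (32/64 channels,
  120³ patches) is impractical without re-implementing the layers on a GPU
  framework — the architecture and training logic are framework-agnostic by
  design.
* The baseline tracer is a deliberately simple global-threshold /
  thinning / spanning-tree exporter used to make the enhancement benefit
  measurable; it is not a production tracer.
* Somata are neither rendered nor detected.
* With a very inaccurate initial tracing the loop can converge to poor labels;
  the iteration audit trail (per-generation Dice and recall) is retained
  precisely so such runs are diagnosable.
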