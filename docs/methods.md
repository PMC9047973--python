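# Methods

This note records the models implemented in `sealface`, the parameters
that matter, the design choices made where the design was genuinely
open, and what the synthetic experiments do and do not demonstrate.

## Problem setting

Individual harbor seals carry stable pelage-spot patterns on the face.
Given shoreline photographs, the pipeline (i) finds seal faces,
(ii) normalizes each face into a canonical *chip* using the two eye
centers, (iii) maps each chip to a point on the unit sphere in R^512,
and (iv) identifies individuals by cosine similarity against a gallery
of enrolled animals, either closed-set (the probe is known to be
enrolled; report rank-k accuracy) or open-set (the probe may be a
stranger; a threshold rejects low-scoring probes as imposters).

## Face detector

A fully-convolutional score-map network. Input is a grayscale image
standardized to zero mean and unit variance (detection is therefore
invariant to global affine intensity changes). Three stride-2
convolutions (5x5 then two 3x3, channel widths C/4 -> C/2 -> C with
C = 32) downsample by 8; four stride-1 3x3 conv + batch-norm + ReLU
layers refine the 32-channel map; a 1x1 convolution emits a
single-channel score map of shape (ceil(H/8), ceil(W/8)). "SAME"
padding throughout gives the ceiling shape for any input size.

*Detection rule.* Score-map cell (i, j) corresponds to an anchor box of
the fixed detection window (default 64x64 px) centered at
((j+0.5)*8, (i+0.5)*8). Detections are 3x3-neighborhood local maxima
above a threshold (operating default 0), greedily NMS-filtered at IoU
0.25. An image pyramid (3 levels, factor sqrt 2) covers faces larger
than the window; boxes are mapped back to the original resolution.

*Training loss.* The original tool trains with a max-margin objective
from the object-detection literature whose exact optimizer is outside
this package's sources; here the max-margin character is kept at desk
scale as a per-anchor hinge loss: anchors whose window overlaps a valid
truth box at IoU >= 0.5 must score >= +1, hard-mined background anchors
(the top max(8, 3x positives) scoring negatives) must score <= -1, and
anchors with ambiguous overlap (0.2 <= IoU < 0.5) or any overlap with
an invalid-flagged face contribute nothing. One scene per SGD step
(momentum 0.9, lr 0.02, weight decay 1e-4), scene order shuffled per
epoch from the seed. This is an approximation and is documented as
such; it trains to precision = recall = 1.0 on the synthetic scenes.

*Evaluation.* A prediction matches a truth box at IoU >= 0.5, assigned
one-to-one greedily by descending score (the matching criterion is a
package choice; the source material does not state one). Precision at
zero predictions is defined as 1.0 (no false claims). The threshold
sweep defaults to 101 evenly spaced quantiles of the pooled candidate
scores. Stratified k-fold splitting cuts each stratum (one site+date)
into k near-equal sections after a seeded shuffle; strata smaller than
k are distributed round-robin with a warning.

## Alignment and chipping

With left/right eye centers l, r (left = smaller x, viewer's left), the
tilt is theta = atan2(ry - ly, rx - lx) and the alignment transform is
the rotation by theta about the eye midpoint,

    M = [[cos t, -sin t, x(1-cos t) + y sin t],
         [sin t,  cos t, y(1-cos t) - x sin t]],

for midpoint (x, y). atan2 replaces the printed-arctangent form, which
divides by rx - lx and is singular for vertical eye pairs; for all
non-degenerate pairs the two agree. In y-down pixel coordinates the
chip warp applies the inverse rotation composed with scaling — one
bilinear resampling pass via `scipy.ndimage.map_coordinates` — so that
the eyes come out horizontal with the right eye at larger x.

Chip geometry: each eye lies 0.5 x IPD from its nearest side edge and
0.6 x IPD below the top edge; with side margins of 0.5 the chip width
is 2 x IPD, so after resizing to 112 x 112 the chip-frame IPD is 56 px
and the eyes land at (28, 33.6) and (84, 33.6). Margins are fixed in
chip coordinates (IPD' = 56), the only self-consistent reading for a
square output with 0.5 x IPD side margins. Windows extending beyond
the source image are edge-replicated with a logged warning. Chips are
8-bit PNG; provenance (source image and box) is encoded in the
filename (`IMG_001_l10_t20_w100_h100.png`) and round-trips losslessly.

## Embedding network

Input 112x112x1, standardized per chip. Four blocks of grouped 3x3
convolution (stride 2) + batch norm + ReLU + channel shuffle, widths
(32, 64, 128, 256) with groups (2, 4, 4, 8); the first block is an
ordinary convolution because a 1-channel input cannot be grouped. The
channel shuffle is the reshape-transpose permutation c ->
g*(c mod C/g) + floor(c/(C/g)), which lets consecutive layers' groups
exchange information. Global average pooling and a linear bottleneck
produce the 512-d embedding, L2-normalized.

*Loss.* The original training recipe is not in this package's sources;
the implementation uses the standard choice for this architecture
family: additive-margin softmax (margin m = 0.35, logit scale s = 30)
over identity classes, on the normalized embeddings against
row-normalized class weights, with SGD + momentum 0.9 (lr 0.05, weight
decay 5e-4, batch 32). Horizontal flip is the only augmentation (a
mirrored face is the same animal). The classification head is
discarded after training. All of m, s, widths, groups, epochs and
optimizer settings are exposed in `EmbedderConfig`.

## Identification

Folder-to-folder similarity is the arithmetic mean of all pairwise
cosine similarities between the probe's and the gallery individual's
chips (every pair is compared; the aggregation rule is a package
choice, with `max` available as an alternative). Candidates are ranked
descending with ties broken by ascending gallery id. Open-set
confusion counts at threshold T and rank k: TP = genuine probe with
top score >= T and truth within the top k; FN = genuine otherwise;
FP = imposter with top score >= T; TN = imposter otherwise. Derived
rates as usual; baseline = (FP+TN)/N is the accuracy of rejecting
everything; F-score is the harmonic mean of precision and TPR. With no
genuine (or no imposter) probes the affected rates are NaN with a
logged warning rather than an exception.

Database growth: a probe folder whose best gallery score is >= the
enrollment threshold (default 0.5, chosen from the published score
ranges — matches 0.55-0.85, non-matches 0.2-0.5 — and config-exposed)
merges into that identity; otherwise it is enrolled under a new
zero-padded id (optionally `NNN_Nickname`). The boundary case (score
exactly at threshold) merges.

Cross-validation: identities with at least k photos are split
per-identity into k near-equal sections (the data description
accompanying the published protocol uses "at least 5 photos" with 5
folds, so the filter is >= k, exposed as `min_photos`); fold f enrolls
the other k-1 sections as the gallery and probes with section f. The
open protocol additionally pools each under-threshold identity as an
imposter probe folder. Means and sample (n-1) standard deviations are
reported across folds.

## Synthetic data generator

An identity is a template: 6-10 dark spots (position, radius, darkness
drawn once per identity), an elliptical face with a per-identity axis
ratio and base gray, and jittered eye positions, all in canonical
face coordinates measured in IPD units. Rendering places the template
at a chosen scale and in-plane rotation (+/-45 deg), adds brightness
jitter and Gaussian pixel noise, and reports the true rendered eye
centers. Distinctness between identities (some spot differing by
> 2 px at nominal render scale or > 10 gray levels from every spot of
the other) is enforced by rejection sampling. Chip-source renders use
150 px per IPD so downstream alignment only downsamples. Scenes
(default 1024x768, 8-bit) composite faces onto smoothed-noise
backgrounds without box overlap; a configurable fraction (default 0.1)
is blurred/occluded and flagged invalid, mirroring how unusable faces
are marked in real annotation practice. A `difficulty` knob in [0, 1]
fades spot contrast and raises noise, monotonically increasing
cross-identity similarity.

What this emulates: pose (in-plane rotation, scale), illumination
jitter, sensor noise, occlusion flags, many faces per scene, and a
spot-constellation biometric. What it does not: out-of-plane pose,
molting and seasonal pelage change, wet/dry coat contrast, background
clutter with face-like structure, and camera optics. Passing tests
therefore demonstrate that the pipeline's machinery is correct and can
recover identity when the biometric is present — not field accuracy on
real photographs, whose published reference numbers the package prints
for context only.

## Problem sizes and numerical choices

The test suite trains at desk scale: the end-to-end recovery check
uses 40 identities x 8 chips (6 train / 2 probe), 50 scenes of 320x320
px with 4 faces each (40 train / 10 held out), 10 detector epochs and
15 embedder epochs — sizes chosen so the full suite runs in a couple
of minutes on one CPU while leaving wide margins on its thresholds
(both stages reach ~1.0 on the synthetic regime). Weight init is He
normal from a seeded generator; all training shuffles derive from the
config seed, so runs are bit-reproducible. Bilinear warps tolerate a
mean absolute difference of 2 gray levels in scale-invariance checks
(one resampling pass vs. two). Degenerate inputs fail loudly:
coincident eyes, IPD <= 2 px, zero-area boxes, single-identity
training sets, empty galleries.

## Known limitations

- The detector training loss is a desk-scale stand-in for the cited
  max-margin objective, not a re-implementation of its solver.
- The embedder's published training details are unavailable; the
  additive-margin recipe is the package's own (standard) choice.
- Only square chips are supported.
- Nose/mouth landmarks, mentioned in the source material's annotation
  workflow, play no role in the math and are not stored.
- The published accuracy numbers were measured on private field
  photographs and are reported as reference context, not reproduced.
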