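# Methods

This note documents the models, operators and numerical choices behind
`fundusburst`, and what the synthetic-data experiments do and do not show.

## Synthetic fundus phantoms

`generate_phantom` renders a stylized macula-centered fundus: a textured
background with a gentle vertical illumination gradient, a bright slightly
elliptical optic disc (default radius 7.5% of the image side, centered at
(0.50, 0.70) in fractional coordinates), a darker macula, and branching
curvilinear vessels grown by bounded random walks from the disc rim (the
number of major trees scales with `vessel_density`; default 0.1 gives six).
The field of view is the inscribed circle; everything outside is zero.

The phantom is deliberately not photorealistic. Every downstream operator is
contrast- or geometry-based, so plausible structure at realistic contrasts is
sufficient to exercise them. Conventions throughout: 0-based row-major
coordinates, origin top-left; shifts are `(dy, dx)` with positive down/right;
every operation is bit-reproducible given its seed.

## Burst acquisition model

A burst is up to 30 frames; when the single-flash flag is set the total
duration `n_frames × frame_interval_ms` must stay below 200 ms (the default
20 frames × 6 ms = 120 ms). Each frame is the phantom translated by that
frame's integer gaze shift (fixed list, or a bounded-step random walk),
multiplied by a radial vignette whose center jitters frame to frame — an
abstraction of an illumination system sweeping configurations across the
pupil; the true annulus geometry is not modeled. Artifact layers are then
composited, with positions redrawn per frame, as specular reflections and
lash positions genuinely vary within a burst: dark lash arcs entering from
the top, a low-frequency haze veil pulling values toward a bright scatter
level, defocus blur on a chosen fraction of frames, a global darkness gain,
and saturated specular spots. Additive Gaussian noise and clipping to [0, 1]
come last. For every artifact class and frame the simulator records the
exact boolean mask of modified pixels, and the true shifts, as ground truth.

Integer gaze shifts are the default so registration recovery can be exact;
subpixel motion, optical point-spread, chromatic effects and pupil dynamics
are out of scope.

## Burst fusion

**Registration** is translation-only: over a sub-200 ms burst, gaze drift is
well approximated by small translations, and rotation/affine terms are
negligible at the simulated magnitudes. Each frame is registered to a
reference frame (default: middle of the burst, ties toward the earlier
index) by FFT cross-correlation of mean-subtracted, FOV-masked images,
searching displacements up to ±16 px. Confidence is the peak normalized
correlation clipped to [0, 1]: structured, well-aligned frames approach 1,
while pure-noise frames stay below ~0.05 (the peak of ~10⁵ near-independent
correlations of zero-mean noise). Note the estimated shifts are relative to
the reference frame; the composite inherits the reference frame's own
absolute displacement, which is unidentifiable from the burst alone —
ground-truth comparisons in the tests compensate for it explicitly.

**Score layer.** After alignment, the per-pixel temporal median of the valid
frames is the robust reference. A frame's weight at a pixel is the product
of two terms:

- a deviation term, exactly 1 while |frame − median| ≤ τ and falling
  smoothly to 0 at τ + s, with τ = s = max(3σ̂, 0.02) and σ̂ the
  MAD-based noise estimate of the stack. Positive deviations capture
  specular scatter and saturation, negative ones occlusion and darkness;
- a blur term: the ratio of the frame's windowed gradient energy to the
  median frame's, mapped through a smooth ramp (0 below ratio 0.2, 1 above
  0.8), so locally defocused frames lose weight where detail is missing.

Ramps are cubic smoothsteps rather than logistics: they saturate exactly, so
identical frames get weight exactly 1 and fully occluded frames exactly 0.
Pixels a shifted frame never observed get weight 0.

**Merge.** The composite is the weight-normalized sum of aligned frames — a
pointwise convex combination, so no value can leave the range of the aligned
inputs and spatially constant inputs yield constant output (up to one ulp of
the per-pixel normalization). No spatial filtering of any kind is applied:
no sharpening, no contrast enhancement, no feature segmentation. Pixels
whose total weight falls below 10⁻³ × n_frames are filled from the temporal
median and flagged unrecoverable. `n_frames_used` counts frames whose mean
in-FOV weight is at least 0.1. For 3-channel input, registration and scoring
run on the green channel (highest vessel contrast); the merge applies the
shared weights per channel.

## Image quality control feature

The production counterpart of this component is a trained model; this
implementation is a transparent heuristic honoring the same contract:
per-pixel impairment → per-pixel visibility probability → scalar score →
fixed cutoff. It makes no claim of reproducing any proprietary model's
weights — concordance behaviour is validated on synthetic data only.

Local statistics use a window of 1/16 of the image side (odd-rounded),
masked to the FOV. The four impairment maps are:

- **darkness**: smooth ramp as the local mean falls below 0.1 (width 0.05);
- **saturation**: smooth ramp as the local mean rises above 0.9 (width 0.05);
- **blur**: 1 − local gradient energy normalized by the image's robust
  maximum (0.995 quantile × 0.025), floored;
- **haze**: 1 − local standard deviation normalized by the image's robust
  contrast (0.9 quantile × 0.3), floored at 0.03.

The floors matter: a purely per-image normalizer is scale-invariant, so a
uniformly degraded image would renormalize itself back to apparent health.
The gradient-energy floor is 2.5 × 10⁻⁴ at a 192 px reference side and
scales as 1/side², since the per-pixel gradient energy of a fixed physical
structure falls quadratically with resolution. Ramps are smoothsteps, so an
all-black image reaches darkness exactly 1.

Visibility is `Π_c (1 − i_c)` under an independent-impairment assumption,
and the score is the mean visibility over the FOV — a monotone aggregate
matching "probability that each pixel carries retinal signal". Small dark
lesion-like blobs (≤1% of the FOV) move the score by well under 0.05: the
measure is pathology-independent by construction and does not predict
gradability.

**Operating point.** No published cutoff exists, so the default is
calibrated, not copied: the midpoint between the 5th percentile of scores on
50 clean phantoms and the 95th percentile on 50 heavy-artifact single frames
(fixed seeds, 192 px), giving 0.698 with the suites fully separated
(clean ≥ 0.77, heavy-artifact ≤ 0.62). The value is frozen in
`DEFAULT_CUTOFF`; `calibrate_cutoff()` regenerates it.

Known limitations: additive noise inflates apparent gradient energy and
local contrast, so a noisy frame can out-score its denoised composite; and
the haze map reads large genuinely smooth regions as impairment. Both are
inherent to no-reference local statistics and are absorbed by the calibrated
cutoff at matched conditions.

## Study evaluation statistics

One analysis unit is a graded eye image with its participant (cluster) id.
The two grader judgments — "sufficient quality for clinical interpretation"
(comparative endpoint) and "gradable" (QC-concordance endpoint) — are
distinct columns and never conflated. Selection for grading mirrors the
two-camera protocol: reference camera, last image acquired; investigational
camera, first QC-passing image, else the last acquired. Majority vote is the
mode of exactly three binary labels. φ is computed in closed form from the
2×2 table and is verified in tests, by brute force, to equal the Pearson
correlation of the 0/1 codings to 10⁻¹²; its sign is positive when QC pass
aligns with gradable. The packaged record-level fixtures expand the
published aggregate tables; which particular records carry minority outcomes
is an arbitrary fixed choice that no aggregate statistic depends on,
although the bootstrap CI width does depend on the (unpublished)
within-participant allocation — the CI is therefore characterized by a
coverage simulation, not by matching a printed interval.

## Paired cluster bootstrap

Each replicate draws J participants with replacement; a drawn cluster
contributes all its eyes, each with both cameras' paired rows, preserving
original cluster sizes and the paired design. The difference in proportions
is computed per replicate; the point estimate is the replicate median and
the CI the 2.5%/97.5% quantiles, interpolated linearly between order
statistics (recorded in output metadata; no continuity correction).
Replicates where a camera has no usable records are excluded and counted —
practically unreachable with ≥2 clusters. A resampled proportion depends on
the draw only through per-cluster counts, so the implementation aggregates
counts per cluster and resamples index blocks (one J-vector per replicate
from a single seeded generator); this is exactly equivalent to materializing
each resample and is what makes large simulation studies cheap.
`cluster_resample` provides the record-level resample for verification.

## Session simulator and its closed forms

Each simulated participant contributes two eyes with probability 98/108;
each eye is imaged on both cameras with per-camera capture-failure
probabilities (defaults 3/209 investigational, 42/248 reference, reflecting
the reference camera's difficulty with small pupils). A latent good/bad
state per eye-camera drives everything: QC pass per acquisition
(P = 0.95 good / 0.08 bad), up to three acquisitions (the investigational
camera stops at the first QC pass), and the six grader labels
(sufficient: 0.995 / 0.05; gradable: 0.997 / 0.45 — graders often salvage
images the QC dislikes). Within-participant correlation (default 0.3) is
induced by reusing a shared participant-level uniform when thresholding the
good-state draw; this leaves the marginal P(good) exact, so the expected
majority-vote proportion has the closed form
`p_good·m(p_hi) + (1 − p_good)·m(p_lo)` with `m(p) = 3p²(1−p) + p³`, and
`p_good` can be inverted from a target marginal. Defaults are set so the
marginal sufficient proportions equal 98.5% / 97.1%. The simulator captures
the declared statistical structure — pairing, clustering, correlated
grader noise — but not real grader behaviour or real image-quality
distributions; passing tests show the statistics are computed correctly
under this structure, not that the device performs as reported.

## Problem sizes in the checked experiments

Phantoms of 128–256 px; bursts of 4–30 frames; the null-coverage study uses
500 simulated 108-participant studies at B = 2000 replicates, and the
point-estimate check the full B = 10,000. These sizes give Monte-Carlo error
comfortably inside every asserted tolerance (e.g. binomial SD ≈ 0.01 at
500 studies for coverage in 0.93–0.97).
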