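# fundusburst

Computational core of a burst-imaging retinal screening camera, plus the
statistics used to evaluate one — exercisable end to end on synthetic fundus
phantoms with known ground truth.

Nonmydriatic fundus photography for diabetic retinopathy screening must cope
with small pupils, eye motion, eyelash occlusion and media opacity. One
design answer is to oversample: capture up to 30 short-exposure frames within
a single sub-200 ms perceived flash, then fuse them into one composite image,
and gate the result with an automated quality score so that poor captures are
retaken immediately instead of reaching a grader. This package implements
that pipeline with transparent, documented operators, together with the
paired-study statistics used to characterize such a device:

- **`synthetic`** — fundus phantoms (disc, macula, branching vessels inside a
  circular field of view), burst acquisition simulation with per-frame gaze
  shifts, illumination vignettes and artifact layers (lash, haze, blur,
  darkness, specular saturation), and a paired two-camera study session
  simulator with closed-form expected proportions.
- **`burst_reduce`** — translation registration by FFT normalized
  cross-correlation; a per-pixel score layer that downweights deviations from
  the aligned stack's temporal median and locally depressed gradient energy;
  and a convex, weight-normalized merge with no spatial filtering.
- **`iqcf`** — an image quality control feature: four impairment maps
  (darkness, saturation, blur, haze), composed into a per-pixel visibility
  probability `v = Π_c (1 − i_c)`; the score is the mean visibility over the
  FOV, compared against a fixed calibrated cutoff to decide PASS versus
  RECAPTURE_NEEDED. The score measures visibility, not gradability.
- **`study`** — grading-image selection (first QC-passing image for the
  investigational camera, last acquired for the reference camera), 3-grader
  majority vote, proportions of clinically interpretable images, the
  QC-versus-gradability 2×2 table and the φ coefficient
  `φ = (ad − bc) / √((a+b)(c+d)(a+c)(b+d))`.
- **`bootstrap`** — the paired cluster (block) bootstrap for the difference
  in correlated proportions: draw J participants with replacement, keep every
  eye of each drawn cluster and both cameras' paired rows, difference of
  proportions per replicate; point estimate = replicate median, 95% CI =
  2.5/97.5 percentiles (B = 10,000 by default).
- **`fixtures`** — the published aggregate study tables expanded into
  deterministic record-level datasets, so every summary is recomputed from
  records rather than asserted.

## Worked example

```python
from fundusburst import (ArtifactSpec, BurstConfig, LashSpec, SaturationSpec,
                         generate_phantom, simulate_burst, burst_reduce, iqcf_score)
from fundusburst.synthetic import IlluminationSchedule

phantom = generate_phantom(seed=1, side_px=256)
cfg = BurstConfig(n_frames=20, frame_interval_ms=6.0, noise_sd=0.02,
                  gaze_model={"kind": "random_walk", "step_px": 2}, seed=1,
                  illumination=IlluminationSchedule(0.25, 3.0))
spec = ArtifactSpec(lash_occlusion=LashSpec(count=2, thickness_px=7, opacity=0.9),
                    saturation=SaturationSpec(spot_count=2, radius_px=14))
stack = simulate_burst(phantom, cfg, spec)          # 20 frames in 120 ms
composite = burst_reduce(stack)
qc = iqcf_score(composite, stack.fov_mask)
print(f"frames used: {composite.n_frames_used}/20")
print(f"IQCF score: {qc.score:.3f}  cutoff: {qc.cutoff:.3f}  decision: {qc.decision.value}")
```

prints

```
frames used: 20/20
IQCF score: 0.737  cutoff: 0.698  decision: PASS
```

All 20 frames carry enough clean signal to contribute; the composite's mean
retina visibility (0.737) clears the calibrated operating point (0.698), so
no recapture is requested. The same evaluation statistics run on the packaged
study records:

```python
from fundusburst import BootstrapConfig, bootstrap_difference
from fundusburst.fixtures import comparative_records

res = bootstrap_difference(comparative_records(), BootstrapConfig(B=10_000, seed=17))
print(f"difference in proportions: {res.point_estimate:.4f} "
      f"(naive {res.naive_difference:.4f})")
```

prints `difference in proportions: 0.0145 (naive 0.0146)` — the
investigational camera's majority-sufficient proportion (203/206 = 98.5%)
minus the reference camera's (200/206 = 97.1%).

A `fundusburst` console command exposes the stages
(`simulate`, `reduce`, `qc`, `select`, `evaluate`, `run-all`, `fixtures`);
see `fundusburst --help`.

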