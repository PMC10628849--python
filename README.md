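# boxnoise

Tools for measuring, simulating and correcting **localization noise** in
object-detection annotation sets — the boundary-coordinate errors that
creep into bounding boxes when plant-disease surveys, wheat-head counts
and similar biological imaging datasets are labelled under time pressure
or without domain expertise.

Everything operates on box geometry alone: no images, detectors or GPUs
are needed. Annotation sets are read and written as Pascal VOC XML (plus
a JSON dialect for scored detections), and synthetic fixture generators
make every analysis reproducible without downloading any dataset.

## What it computes

Given a *clean* and a *noisy* version of the same label set, each clean
box is matched to the maximum-IoU noisy box of the same category, and
each of the four boundaries yields a signed absolute error
Δ = clean − noisy with scale S (the clean box width for left/right,
height for top/bottom). The scalar noise level is the root mean square
relative error

    γ = sqrt( (1/n) Σᵢ (Δᵢ / Sᵢ)² )

and the absolute-error dispersion σ = sqrt(mean Δ²) grows in proportion
to box size: the through-origin slope of the size-binned σ curve is
again γ. Relative errors are approximately Gaussian, centred at zero and
nearly independent across the four boundaries, which justifies the
synthesis rule used throughout the package:

    Δᵢ ~ N(0, (γ · Sᵢ)²)   independently per boundary.

On top of this noise model the package provides:

- **`LocalizationNoiseModel`** — statsmodels-style model/results pair:
  `fit()` matches the two sets and returns estimates of γ (overall, per
  boundary, per size class), σ, the size-binned dispersion curve with
  its fitted slope, the 4×4 boundary-correlation matrix, a `summary()`
  table, `simulate()` and plotting helpers.
- **`synthesize`** — perturb a clean set at a chosen γ (clipped to the
  image, degenerate boxes resampled), for stress-testing detectors or
  validating analyses.
- **`run_iterations`** — the iterative teacher–student correction loop:
  a pluggable corrector proposes one refined box per annotation and the
  proposal is merged with the current box as
  `B_correct = λ·B* + (1−λ)·B` (default λ = 0.5, three iterations). An
  *oracle corrector* with fidelity ρ simulates a teacher at desk scale;
  the resulting γ trajectory follows the closed-form recursion
  `Var_{k+1} = λ²(ργ₀)² + (1−λ)²·Var_k`.
- **`postprocess`** — pseudo-label curation: score threshold (0.5),
  IoU ≥ 0.3 overlap resolution (cross-class by confidence, same-class by
  size) and control-class stripping (background/unknown/healthy).
- **`evaluate`** — 11-point interpolated per-class AP and mAP@50 under
  the classic VOC greedy-matching protocol.

## Worked example

```python
from boxnoise import (FixtureConfig, generate_annotation_set, NoiseModel,
                      synthesize, LocalizationNoiseModel,
                      OracleCorrectorConfig, make_oracle_corrector,
                      run_iterations, fixed_point_gamma)

clean = generate_annotation_set(FixtureConfig(n_images=500, seed=1))
noisy = synthesize(clean, NoiseModel(gamma=0.15, seed=2))
res = LocalizationNoiseModel(clean, noisy).fit()
print(res.summary())
```

```
Localization noise analysis
==============================================
images matched               500
box pairs                   1590
unmatched clean boxes          0
boundary errors             6360
gamma (RMS relative)      0.1476
sigma (RMS px)             26.50
sigma-size slope          0.1374
----------------------------------------------
per boundary            gamma   mean rel.
  left                   0.1508    -0.0007
  top                    0.1461    -0.0052
  right                  0.1446     0.0048
  bottom                 0.1486     0.0060
```

The injected noise level γ = 0.15 is recovered as 0.1476 from 6,360
boundary errors, and the size-binned dispersion slope (0.137) agrees —
the small shortfall is border clipping, which truncates perturbations of
boxes lying near the image edge. Correcting the same noisy set with a
half-fidelity oracle teacher (ρ = 0.5, λ = 0.5):

```python
corrector = make_oracle_corrector(
    OracleCorrectorConfig(truth=clean, rho=0.5, seed=3), 0.15)
final, trace = run_iterations(noisy, corrector, n_iter=3, lam=0.5,
                              reference=clean)
print([round(g, 4) for g in trace.gammas])   # [0.1476, 0.0824, 0.0558, 0.0463]
print(round(fixed_point_gamma(0.15, 0.5, 0.5), 4))  # 0.0433
```

γ falls monotonically toward the analytic fixed point — the annotation
set gets cleaner each round even though the teacher itself is imperfect,
and extra iterations beyond the third buy almost nothing.

## Command line

```sh
boxnoise generate   --n-images 200 --seed 7 --out clean/
boxnoise synthesize --clean clean/ --gamma 0.15 --seed 7 --out noisy/
boxnoise analyze    --clean clean/ --noisy noisy/ --out report.json
boxnoise simulate   --gamma0 0.15 --rho 0.5 --lam 0.5 --iters 5 --seed 7 --out trace.json
boxnoise postprocess --in detections.json --score 0.5 --iou 0.3 --out labels/
boxnoise evaluate   --det detections.json --gt clean/ --iou 0.5 --out eval.json
```

Every run writes a JSON manifest (parameters, seed, input checksums,
version) beside its output.

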