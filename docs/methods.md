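# Methods

## The noise model

A bounding-box annotation error is decomposed into four signed boundary
errors Δ ∈ {Δ_left, Δ_top, Δ_right, Δ_bottom}, each measured between a
clean (reference) box and the maximum-IoU noisy box of the same category
in the same image, with the convention Δ = clean − noisy. Each error is
scaled by the clean box's extent along its axis (width S for left/right,
height S for top/bottom) to give a relative error δ = Δ/S. The scalar
noise level is the RMS relative error γ = sqrt(mean δ²); the absolute
dispersion is σ = sqrt(mean Δ²).

The generative model treats the four relative errors as independent,
zero-mean Gaussians with common standard deviation γ:
Δ ~ N(0, (γ·S)²) per boundary. Its empirical signatures — all of which
the test suite verifies on synthesized data — are:

- γ estimated from matched pairs recovers the synthesis parameter
  (sampling SE of the RMS estimator is γ/√(2n) for n boundary errors);
- the pooled relative-error mean is zero;
- binning absolute errors by box size and taking the per-bin σ gives a
  line through the origin with slope γ;
- the 4×4 boundary-correlation matrix is close to the identity.

A real-world noise level of γ ≈ 0.15 is used as the reference operating
point throughout (synthesis defaults, simulated correction loops, the
acceptance script).

### Matching

Matching iterates clean boxes independently: for each clean box the
same-label noisy box with the largest IoU (strictly positive) is chosen.
IoU rather than raw intersection area is used, since intersection alone
favours oversized noisy boxes. A noisy box may be matched by several
clean boxes — no bipartite uniqueness is imposed, because the traversal
is per clean box. Clean boxes with no positive-IoU same-label candidate
are counted as unmatched and excluded from all error statistics (they
carry no measurable boundary error).

### Size classes and binning

Box sides are classed relative to the image dimension: small when
S/image ≤ 0.1, large when S/image > 0.3, middle otherwise. For the
dispersion curve, sizes and errors are rescaled to a 640-px square
reference image, binned in 64-px size bins, and bins with fewer than 10
errors are dropped (all three knobs are arguments). The slope is fitted
through the origin by least squares, slope = Σ S̄σ / Σ S̄², because the
model forces σ(0) = 0.

Pearson correlations between boundary-error series are flagged
undefined (boolean mask, not NaN propagation) when a series has zero
variance — e.g. when analysing a set against itself.

## Noise synthesis

`synthesize` draws the four Δ independently, subtracts each from its
boundary (so the measured clean − noisy equals the drawn Δ), and clips
the result to the image rectangle. If clipping leaves a side below
`min_side` (default 1 px — essentially only when noise inverts the box),
the four draws are redone, up to 25 times, after which the clean box
itself (clamped to validity) is used. Silent clamping of inverted boxes
would create zero-area boxes and bias γ; resampling keeps the output
valid with a negligible distributional footprint at realistic γ.

Clipping at the border does attenuate the noise slightly: boundaries
within ~3γS of an image edge have their outward excursions truncated.
With the default fixture geometry (640-px images, log-uniform sides in
[16, 480] px, uniform placement) the attenuation is ~1–2 % on γ and up
to ~6 % on the fitted σ-slope (the through-origin fit weights the
largest — most clipped — size bins hardest). Moment-sensitive tests
therefore use *edge-safe* sets whose boxes keep a margin proportional
to their size from the border; pipeline-level checks use the unrestricted
geometry and correspondingly wider tolerances.

One seeded RNG stream drives a whole-set synthesis in a fixed traversal
order (sorted image id, then box index), so synthesis is reproducible
as a unit rather than per box.

## The iterative correction loop

One correction step merges a proposal box B* with the current box B by
the convex combination B_correct = λ·B* + (1−λ)·B applied to each of
the four coordinates. λ defaults to 0.5: the endpoints are degenerate
(λ = 0 ignores the teacher, λ = 1 ignores the annotation) and the
symmetric midpoint is the natural default absent a stated weighting;
every loop property holds for any λ ∈ (0, 1]. The loop runs for a fixed
number of iterations (default 3) and always re-merges against the
*previously corrected* set, modelling a continuously optimised label
set; correspondence between proposals and labels is pinned by per-image
box index, which the corrector contract must preserve.

A real corrector is a detection network trained on the current labels.
For desk-scale study the package ships an oracle corrector that knows a
hidden reference set and emits reference boxes perturbed at γ = ρ·γ₀,
with fidelity ρ ∈ [0, 1] and fresh draws every call (a re-trained
teacher makes fresh errors). Under that corrector the per-boundary
relative-error variance follows the exact linear recursion

    Var_{k+1} = λ²(ργ₀)² + (1−λ)²·Var_k,   Var_0 = γ₀²,

with fixed point γ∞ = γ₀·λρ / sqrt(1 − (1−λ)²) — e.g. 0.0433 for
γ₀ = 0.15, ρ = λ = 0.5. The simulated trace matches this recursion to
within Monte-Carlo error, decreases monotonically, and plateaus: late
iterations change γ by under 5 % relative, which is why the loop stops
at a fixed small iteration count rather than a convergence criterion.

What the oracle does *not* emulate: a trained teacher's errors are
correlated with image content and with the noise it was trained on, it
can hallucinate or drop objects, and its fidelity improves across
iterations. Passing the loop tests therefore validates the merge
arithmetic and the variance bookkeeping, not detector behaviour.

## Pseudo-label post-processing

Three rules curate scored pseudo-labels, applied per image in the order
score filter → overlap resolution → control stripping:

1. **Score filter**: keep boxes with score ≥ 0.5 (inclusive).
2. **Overlap resolution** at IoU ≥ 0.3: a single greedy sweep in
   descending score order (ties: larger area, then input order). A
   candidate overlapping an accepted box of a different category is
   dropped; against accepted boxes of the same category the *larger
   area* wins, so a big low-score box evicts a smaller accepted one —
   the size rule deliberately outranks the score rule within a class.
   In chains of three or more mutually overlapping boxes the sweep's
   outcome is taken as canonical.
3. **Control stripping**: remove auxiliary absorber categories
   (background, unknown, healthy by default).

The greedy sweep with explicit tie-breaks makes the output independent
of input box order, free of any surviving pair at or above the IoU
threshold, and the whole pipeline idempotent — all three are property
tests.

## Evaluation

AP follows the 11-point interpolated VOC protocol: detections of one
class ranked by descending score (ties by input order), each greedily
claiming the highest-IoU unclaimed ground-truth box in its image
(TP iff IoU ≥ 0.5), precision interpolated as P(r) = max precision at
recall ≥ r over r ∈ {0, 0.1, …, 1}, AP their mean, mAP the unweighted
mean over classes with at least one ground-truth box. Classes with
detections but no ground truth score AP 0 with a warning and are
excluded from the mean; a class empty on both sides is undefined. The
implementation is tested against an independent brute-force oracle that
recomputes a precision/recall point per score cutoff from scratch.

## Synthetic fixtures

The fixture generator emulates the geometric structure of curated
plant-disease / wheat-head detection sets: square images (640 px),
log-uniform box sides (default [16, 480] px, so all three size classes
are populated), uniform placement, Poisson box counts per image
(mean 3, clipped to ≥ 1), and uniform category assignment over five
disease-like classes (or a single class for the wheat-head-like case).
Detection sets derive from a truth set by false-negative dropping,
localization perturbation, TP scores uniform on [0.5, 1] and injected
false positives scored uniform on [0, 0.7] — chosen so the 0.5
confidence threshold is a meaningful filter in tests. Real data differ
in ways the generator ignores (object co-occurrence, aspect-ratio and
spatial clustering, class imbalance, correlated annotator behaviour),
so passing tests certify the algorithms, not field performance.

## Problem sizes and numerics

Monte-Carlo checks use ~5,000 boxes (~20,000 boundary errors), where
the γ-estimator SE is ≈ γ/200 — comfortably inside every stated
tolerance while keeping the full suite under half a minute. The
acceptance script generates ~5,000 single-box images (Poisson mean 1,
clipped) with sides log-uniform in [32, 480] px. VOC I/O treats files
as 1-based inclusive integer coordinates (left = xmin − 1, right = xmax
on read, inverse with rounding on write), which keeps width arithmetic
exact and round-trips within 0.5 px; the source convention is a
documented choice, as annotation tools disagree and the files
themselves do not say. Scored boxes serialize a `<score>` child element
in VOC XML so pseudo-labels and ground truth share one format.

## Known limitations

- Class noise and missing labels are out of scope: synthesis perturbs
  geometry only, and the noise report conditions on successful
  same-label matching.
- The correction loop's closed-form analysis assumes the oracle
  corrector; with a real detector the recursion is only a qualitative
  guide.
- Border clipping makes γ estimates on unrestricted geometry biased low
  by ~1–2 % (see above); analyses of datasets whose objects hug image
  edges should expect the same attenuation.
- mAP here is the 11-point VOC variant; COCO-style 101-point or
  averaged-IoU metrics are not provided.
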