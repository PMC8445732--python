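# Methods

## Problem and scope

Ultra-widefield fluorescein angiography (UWFA) captures ~200° of retina in
one frame. Two quantitative biomarkers summarize diabetic-retinopathy (DR)
burden: the **ischemic index** (nonperfusion area over the visible-retina
standard `d²`) and the **leakage index** (leakage area over `d²`). The
package grades eyes as normal / NPDR / PDR from these indices and compares
the full UWFA field against a simulated ETDRS 7-standard-field (7-SF) crop.
Clinical UWFA cohorts are private, so a synthetic phantom generator supplies
seeded scenes with planted, exactly known lesions; every quantitative claim
the tests make is therefore a claim about recovery of known ground truth,
not about clinical images.

## Synthetic phantom

A scene is an axis-aligned elliptical footprint (default semi-axes 0.45 and
0.38 of the image side, image side 128 px) on a near-black background
(0.02), with:

* smooth radial illumination falloff (default slope 0.35 of the dynamic
  range across the footprint);
* a recursive branching vessel tree rooted at the optic disc, drawn with
  anti-aliased segments at brightness 0.78×illumination;
* perfused background at 0.45×illumination;
* additive Gaussian noise, σ = 0.02 of the dynamic range.

Landmarks are fixed: macula at the footprint center, disc nasally on the
horizontal midline at 0.15×image-width from the macula (configurable;
the peripheral-lesion experiments use 0.12 so that a genuine region beyond
three disc–macula distances exists inside the footprint).

Lesions are planted with exact area control: a Gaussian-smoothed noise
field (correlation length 0.08×image side) is thresholded at the quantile
that yields the requested pixel count inside the allowed region, so planted
area fractions are accurate to rounding. Nonperfusion multiplies local
intensity by a smooth factor in [0.2, 0.5] in both phases; leakage adds a
soft-interior bright bump (late phase only); microaneurysms are 1–3 px
bright dots in both phases and are folded into the bright-biomarker
(leakage) truth channel. Grade-conditional default burdens are strictly
ordered — normal: 0/0, NPDR: 0.07/0.05, PDR: 0.20/0.14 (nonperfusion /
leakage fractions) with 0, 8, 16 microaneurysms — and per-eye multiplicative
jitter (σ = 0.3, clipped to [0.4, 1.6]) spreads each grade into a cluster.
These burdens are in the range reported for ischemic/leakage indices in DR
cohorts; they are package defaults, exposed in `SceneParams`.

Each eye carries a lesion-free twin rendered from the identical scene and
the identical per-phase noise field. Consequently the twin equals the
lesion frame bit-for-bit outside the planted masks, `late − late_clean` is
exactly the leakage rendering, and `early − early_clean` exactly the
nonperfusion darkening: a perfect "fake normal" oracle for testing the
downstream stages independently of the GAN.

What the phantom does **not** emulate: device distortion and brightness
inhomogeneity of real Optos imagery, eyelash/eyelid artifacts, dynamic dye
transit, hemorrhage. Passing recovery tests on the phantom demonstrates the
pipeline's internal consistency, not clinical performance.

## Retina geometry

`d²` is interpreted as the **area** (pixel count) of the visible-retina
footprint, making both indices area fractions in [0, 1]; the alternative
reading (square of a length) has no operational definition for index
ratios. Footprint detection thresholds the frame with a three-class
multi-Otsu split (lowest threshold: device background vs any tissue — plain
Otsu would cut through dark nonperfusion), keeps the largest connected
component and takes its convex hull (the footprint is elliptical; dark
lesions touching the rim otherwise cut bays into the mask).

The 7-SF mask uses seven circles of radius `r` = disc–macula distance:
field 1 on the disc, field 2 on the macula, field 3 temporal at `2r` from
the macula, fields 4–7 on the same `2r` ring at ±60° and ±120° from the
macula→temporal axis, all intersected with the footprint. This is a
deliberate, config-exposed stand-in for the clinical 7-SF construction;
exact ETDRS spherical geometry is out of scope. Masked (7-SF) analyses keep
the **full-field** `d²`, so index differences between the two variants
measure the lesion area lost outside the posterior pole.

## Joint CycleGAN + classifiers

Two residual generators translate between domains (`G_X`: any → normal,
`G_Y`: any → abnormal; abnormal = NPDR ∪ PDR) with patch discriminators,
least-squares adversarial loss (cross-entropy available), L1
cycle-consistency both ways (weight 10), identity terms on same-domain
inputs (weight 5), and classification terms (weight 1): a 3-grade
classifier `C_X` on the signed `real − G_X(real)` difference and a binary
classifier `C_Y` on the `G_Y(real) − real` difference (biomarker present =
non-normal label). Signed differences are used so dark-lesion polarity is
preserved. Both phases enter as independent samples; flips, ±15° rotation
and ≤10% translation augment training batches.

Architectures are desk-scale: generators with 7-px stem, two stride-2
stages, four 32-channel residual blocks and nearest-neighbour upsampling
(sigmoid output in [0, 1]); 3-layer patch discriminators; 4-conv classifiers
with global average pooling. Everything runs on `angiograde.nn`, a small
NumPy engine (im2col convolution, instance norm, manual backward passes,
Adam). Optimization alternates (generators + classifiers) with
discriminators; Adam uses β₁ = 0.5 for the adversarial parts and β₁ = 0.9
with a larger step (1e-2 vs 2e-3) for the classifier heads, which evolve on
a much cleaner objective than the generators. After the adversarial epochs
the classifier heads are refitted on the frozen generators' difference
images over the training set (no augmentation); this stabilizes the
end-to-end `G_X → C_X` grading path at tiny data scale. Training is fully
seeded; two runs with the same seed, data and thread configuration are
bit-identical (the test and acceptance entry points pin BLAS to one thread
so seeded results do not depend on the host's core count).

## Biomarker segmentation

**Nonperfusion** (early phase). The local low-brightness distribution is a
7×7 minimum filter. A 15×15 grey opening (erosion then dilation) suppresses
bright thin structures — vessels, focal leakage — but, being anti-extensive,
it cannot restore perfused brightness *inside* a dark lesion, so the
moderate-brightness reference is completed by fitting a quadratic
illumination surface to the opened image over the footprint and iteratively
discarding pixels more than 1.0 residual SD *below* the fit (six
iterations): dark lesions are trimmed out and the fit tracks perfused
tissue everywhere. A pixel is suspected nonperfusion when its local minimum
falls below `dark_ratio` (default α = 0.7, multiplicative and therefore
illumination-scale invariant) times this reference. Since thresholding a
minimum map dilates the true sub-threshold set by the filter window, the
raw mask is eroded with the same 7×7 window (the pair acts as a binary
closing). Outside-footprint pixels are nearest-filled before filtering so
the dark device background never leaks into the statistics.

The real∧fake agreement (`pseudo_nonperfusion`) forms pseudolabels; note
that with a *perfect* fake (the phantom's clean twin) the fake's suspected
mask is rightly empty and the agreement degenerates — the agreement step
earns its keep with imperfect generator fakes. The oracle-twin index
experiments therefore use the real-frame suspected mask directly.

A two-level U-net (base width 8) refines pseudolabels: per-pixel binary
cross-entropy on label-smoothed targets (ε = 0.1 → targets {0.1, 0.9}),
foreground reweighted by inverse frequency, random flips, batches of 4,
25 epochs with a ×0.3 step decay at 60%, a two-member seed ensemble and
flip test-time averaging; the refined mask is mean sigmoid > 0.5 within the
footprint. At this scale the refined masks typically reach IoU 0.85–0.90
against planted truth versus ~0.99 for their rule-based teacher — the
refinement is useful where the rule is noisy (imperfect fakes), not a way
to beat a near-perfect teacher.

**Leakage** (late phase). The real − fake difference image is thresholded
inside the footprint. Default mode `robust`: `t = median + 2·1.4826·MAD`
over the nonnegative in-footprint differences — insensitive to lesion
burden, unlike `mean + 2σ` (`zscore` mode, also available), whose threshold
grows with lesion mass and censors high-burden eyes; Otsu on positive
values is the third option.

Window sizes rescale with image resolution (`SegParams.scaled`), defaults
stated at 128 px.

## Indices and grading

Indices are mask areas over `d²`. Grading projects `(II, LI)` on the
leading Fisher canonical axis (orientation fixed so the PDR training mean
is largest; a least-squares regression on coded grades 0/1/2 is available
behind `method="lstsq"`), then exhaustively searches two thresholds over
midpoints of adjacent sorted training scores, maximizing training accuracy
with ties broken toward the lower thresholds. Boundary convention: a score
exactly at a threshold belongs to the lower class. With singular
within-class scatter the direction falls back to the regularized
PDR-minus-normal mean difference.

## Evaluation

Stratified k-fold (default 5) splits each grade independently
(seeded shuffle, round-robin), so per-grade fold counts differ by ≤ 1.
Confusion matrices use rows = true grade, columns = predicted. Cohen's
kappa uses the standard margin-expected agreement. Class-size-weighted
accuracy rounds per-class correct counts to integers before summing,
mirroring an integer confusion matrix. Aggregating the published per-class
accuracies over the published cohort sizes (119/171/109) this way
reproduces the published overall 7-SF accuracy exactly (294/399 = 73.68%);
the same aggregation for the full-field variant gives 353/399 = 88.47%
against a printed 88.50% — a 0.03-point rounding inconsistency in the
source figures that the implementation reports as computed rather than
adjusting for.

`run_experiment` runs the paired full-field / 7-SF experiment with shared
fold splits; the 7-SF variant restricts frames and segmentation to the
field mask while keeping the full-field `d²`. The deterministic
`skip_gan` path substitutes the clean twins for generator fakes; the GAN
path trains a joint model per fold and adds the end-to-end classifier
report.

## Problem sizes

Default experiment scales were chosen for desk-scale reproducibility:
phantom cohorts of 30–60 eyes at 128 px for the deterministic path, and
20 training eyes at 64 px with 10 epochs for the joint-GAN smoke (about a
minute on one CPU), with 60 held-out eyes for its evaluation. Larger scenes
and cohorts only change runtimes, not the contracts the tests assert.

## Known limitations

* The phantom's lesions are brightness-defined blobs; no real texture,
  vessel dropout patterns, or phase dynamics.
* The joint GAN at this scale demonstrates learning signal (decreasing
  losses, lesion-sensitive residuals, above-chance held-out grading), not
  image quality.
* The 7-SF construction is a geometric stand-in, not the clinical grid.
* Thresholds fitted on synthetic clusters transfer to nothing clinical;
  they demonstrate the estimator's correctness on separable data.
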