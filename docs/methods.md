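# Methods

This note documents the models, numerical conventions and design choices of
phytoseg, in the package's own words. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The task is pixel-level binary segmentation of vegetation canopies in 8-bit
RGB imagery: label 1 (positive) = pest/disease-affected plant, label 0 =
healthy. On disk, ground-truth maps follow the convention that affected
regions are drawn black (gray value 0) and healthy regions white (255);
in memory disease is always 1. Coordinates are 0-based, row-major, with
half-open rectangles.

## Vegetation-index stack

Twenty-four visible-band indices plus the raw R, G, B bands form a
27-plane feature stack. Two band conventions coexist in the literature and
are recorded per index in the code registry:

* word-form symbols (red/green/blue) are evaluated on bands scaled to
  [0, 1] (value/255);
* lower-case r, g, b denote chromatic coordinates R/(R+G+B) etc., which
  remove overall brightness. CIVE, GLI and VI use this form; for GLI the
  printed sources are ambiguous between the two conventions, so the
  registry default (chromatic) is an explicit, auditable choice.

Numerical conventions:

* every division uses a signed denominator floor `max(|den|, 1e-8)`;
* VEG's fractional-power denominator (`R^0.667 · B^0.333`) lifts zero band
  values to 1e-8 so the index stays finite and order-preserving;
* residual non-finite pixels are replaced by the plane's finite median —
  a handful of degenerate pixels (e.g. the near-zero `red−green`
  denominator of WI over healthy canopy) must not be allowed to stretch
  the min–max normalization of the whole plane;
* each index plane is min–max normalized to [0, 1] over the full processed
  image (constant planes map to 0.5); the R, G, B planes are simply
  divided by 255. Because normalization is global, training on a
  sub-region is done by cropping *after* stack computation.

A black pixel (R+G+B = 0) has chromatic coordinates defined as (0, 0, 0),
which makes CIVE evaluate exactly to its additive constant 18.78745 there —
one of the reference quantities the acceptance script recomputes.

## Threshold segmentation

All nine methods operate on the [0, 1] planes quantized to 256 levels
(`round(255·x)`). Global methods return a threshold `t` and classify
`level < t` as the low class; local methods return masks directly.

* **Otsu** — maximize between-class variance; exhaustive scan over 255
  candidate splits.
* **Block Otsu** — per-cell Otsu on 100×100 tiles (edge tiles smaller);
  near-constant cells (single level or between-class variance < 1e-12)
  fall back to the global threshold.
* **Local dynamic (Sauvola form)** — `T = m·(1 + k·(s/R − 1))` over an
  odd `r×r` window (default 15) with k = 0.2 and R = 128; borders are
  handled by symmetric reflection. k and the window size are not fixed by
  the method's definition; 0.2 is the common Sauvola-family default.
* **Wellner adaptive** — a running average of the preceding s pixels
  (default s = width/8) maintained with the exponential approximation
  `f(n) = f(n−1)·(1−1/s) + p_n`, seeded with `s·p₀`; a pixel is dark-class
  when it falls t% (default 15) below `f(n)/s`. Rows are scanned
  serpentine (alternating direction) to reduce the directional bias of a
  one-way scan; the comparison rule itself does not prescribe a scan
  order.
* **Maximum entropy (Kapur, single threshold)** — maximize the sum of
  foreground and background entropies with 0·log 0 := 0.
* **Double peak** — first peak at the histogram argmax p; second peak at
  argmax (x−p)²·hist(x); the threshold is the smallest-level minimizer of
  the histogram strictly between the peaks. (A literal "smallest gray
  value between the peaks" would always be min(peak)+1 and could not
  segment; the valley reading is the only workable one.) Adjacent peaks
  (no interior level) return the higher peak.
* **Minimum error** — by default the weighted within-class variance
  `E = w₀σ₀² + w₁σ₁²` is minimized, which is the criterion in its printed
  two-class form; the classical Kittler–Illingworth log criterion is
  available behind a `kittler=True` flag for users who want the full
  Gaussian-mixture treatment.
* **Iterative mean** — fixed point `Th ← (m_low + m_high)/2` started at
  the global mean, stopping when the move is below eps = 0.5 levels
  (cap 256 iterations with a warning).
* **Combined global/local** — same fixed point with the stricter stopping
  rule "quantized threshold unchanged".

Tie-breaking for every criterion scan is "smallest gray level", applied
with a 1e-10 relative tolerance: criterion plateaus across empty histogram
bins are exact ties mathematically, and the tolerance keeps the selected
level independent of floating-point summation order.

Degenerate (constant) inputs raise a typed error at method level; the
`segment` dispatcher downgrades this to an all-healthy mask plus a warning
so batch runs never crash. Polarity is resolved automatically by default:
the orientation whose positive class has the lower mean gray value is
chosen, encoding the prior that disease is dark in these index planes.

## Feature selection

**Permutation importance (MDA).** The forest is built as explicit
bootstrap-bagged `DecisionTreeClassifier`s (default 100 trees, sqrt(p)
features per split) rather than sklearn's `RandomForestClassifier`,
because the importance definition needs each tree's out-of-bag rows: a
feature's score is the mean over trees of (OOB error after permuting that
feature − baseline OOB error), one permutation pass per tree, all draws
from one seeded generator. Training pixels come from a labeled rectangle
(default sampling cap 20,000 rows) that must contain both classes.

**Correlation pruning (CCIA).** From the Pearson matrix, repeatedly find
the remaining pair with the largest |ρ| and drop the member with the
larger mean |ρ| to all other remaining features — a deterministic rule
that favors globally less redundant features; the dropped-feature trace is
returned for audit. Stopping is either at a target count k (mirroring the
5/10/15/20/27 subset sizes) or at a correlation ceiling (`rho_threshold`).
The max pairwise |ρ| of the surviving set is non-increasing over
iterations, which the test suite checks.

## Beluga Whale Optimization

Positions X (n whales × d dims) evolve for T iterations in a clamped box.
Per whale and iteration the balance factor `Bf = B0·(1 − t/(2T))`,
B0 ~ U(−5, 5), routes to exploration (Bf > 0.5) or exploitation:

* exploration: for each dimension j, with a random pivot dimension p and
  partner whale r drawn per whale, `x_j ← x_p + (x_{r,p} − x_p)(1 + r₁)·
  sin/cos(2πr₂)` (sine for even j, cosine for odd, 0-based);
* exploitation: `x ← r₃·x_best − r₄·x + C₁·LF·(x_r − x)` with jump
  intensity `C₁ = 2r₄(1 − t/T)` and Lévy step `LF = 0.05·μσ/|V|^{1/β}`,
  β = 1.5, σ the Mantegna scale;
* whale fall: after the main phase each whale is independently repositioned
  with probability `W_f = 0.1 − 0.05·t/T` by
  `x ← r₅·x − r₆·x_r + r₇·x_step`, `x_step = exp(−2·W_f·n·t/T)·(Ub−Lb)`.

Choices the phase definitions leave open, decided here: the random partner
whale is drawn per whale (not per dimension); updates are accepted
greedily (a whale keeps its old position when the new fitness is worse),
which makes the best-so-far history non-decreasing — a property the
ensemble training relies on; bound handling is clamping; non-finite
fitness values are treated as −∞ with a warning. Integer-domain problems
(the vote weights) evolve continuously and are rounded half-up only at
fitness evaluation, avoiding an ad-hoc discrete variant.

## Fused index and ensemble

The fused plane `Σ wᵢ·VIᵢ` is re-normalized to [0, 1] before thresholding
so the histogram methods always see a standard 8-bit-equivalent plane;
positive rescaling of the weights therefore leaves the result unchanged,
and the sign freedom is absorbed by automatic polarity.

Both learners seed the initial BWO population with known feasible
candidates: the one-hot weight vectors (each single index / single base
classifier alone) and, for the ensemble, the equal-weight vector (plain
majority voting). With greedy acceptance this makes the spec-level
dominance guarantees — fused index ≥ best single index, trained vote ≥
majority vote and ≥ every base mask, on the training region — structural
rather than probabilistic; the remaining population is random as usual.
The reported training CSI is always a re-evaluation of the returned
weights, never a cached incumbent.

The weighted vote labels a pixel positive iff `2·Σ wᵢ·mᵢ > Σ wᵢ` (strict),
which is provably identical to replicating mask i wᵢ times and taking a
majority; ties go to healthy, a conservative rule chosen because false
alarms are the headline failure mode. The nine base masks default to the
per-thresholder fused-index segmentations; a pipeline flag selects raw
single-index segmentations instead.

## Synthetic scenes

`generate_scene` emulates what matters to this pipeline: spatially
coherent elliptical disease blobs (like crowns, not salt-and-pepper noise)
placed until a target prevalence is reached (stopping at the first
crossing keeps the realized prevalence within a few percent relative of
the request), healthy/diseased colors drawn from Gaussian color
distributions (defaults: healthy mean RGB (60, 110, 55), diseased
(120, 95, 60), sd 12 — chosen so single indices separate the classes
usefully but imperfectly), a smooth multiplicative texture field, darkened
shadow ellipses (10% of the scene at multiplier 0.35) and additive
Gaussian noise (sd 5). These are documented package constants, not
measurements of any particular survey.

What the generator does **not** model: radiometric calibration errors,
atmospheric effects, mosaicking seams, mixed pixels at crown boundaries,
view-angle variation, and disease color continua. Passing tests on these
scenes therefore demonstrate correctness of the algorithms and the
claimed orderings (fusion ≥ singles, trained vote ≥ majority), not field
accuracy on real UAV surveys.

## Problem sizes used in the automated checks

The acceptance-level tests run on a 512×512 synthetic scene with a
128×128 training region, n = 5 RF-selected features, BWO at its standard
operating point (population 50, 50 iterations, bounds ±10), three fitting
seeds for the fusion dominance check; importance-recovery checks use
~1,200-row tables with 40-tree forests over 20 seeds. These sizes were
chosen as the smallest at which the properties under test are
well-conditioned.

## Known limitations

* The metrics' FAR is the false-positive rate FP/(FP+TN); users expecting
  the forecasting "false alarm ratio" FP/(TP+FP) should derive it from the
  confusion matrix directly.
* CSI-optimal weights need not be OA- or kappa-optimal; no multi-objective
  handling is attempted.
* GeoTIFF georeferencing is carried opaquely (tag passthrough), not
  interpreted; JPEG is read-only.
* Kappa is computed in its standard chance-corrected form
  (P0 − Pc)/(1 − Pc).
* The BWO fitness landscape is evaluated on the quantized 256-level plane,
  so weight vectors differing only below quantization resolution are
  indistinguishable to the optimizer.
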