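# Methods

This note documents the models, defaults and design choices behind
`pillarforce`, in the order the pipeline runs.

## Beam model

Each pillar is a cantilever of circular cross-section, fixed at its base,
loaded by a point force at the contact plane height `a` (the imaging plane),
with the deflection read at the same plane.  Timoshenko theory adds shear
compliance to bending:

```
C = a^3 / (3 E I)  +  a / (kappa G A)        [um per uN]
I = pi d^4 / 64,  A = pi d^2 / 4,  G = E / (2 (1 + nu))
kappa = 6 (1 + nu) / (7 + 6 nu)              (solid circular section)
```

Units are chosen so that no hidden constants appear: lengths in um, E in
kPa (converted internally to MPa = uN/um^2), forces in uN.  For the default
pillar (d = a = 40 um) the shear term contributes ~16% of the compliance;
at slenderness a/d = 20 it is 0.16% (the Euler-Bernoulli limit, used as a
limit check in the tests).  Assumptions: small deflections (linear
response), rigid substrate, no pillar-pillar mechanical coupling, no
dynamic (inertial) response.  `kappa` is config-overridable; deflection
vectors are converted on magnitude, direction retained for reporting only.

### Arena defaults

The source protocol does not pin pillar geometry, elastomer modulus or
pixel calibration, so these are config-exposed with one set of defaults
chosen as plausible PDMS-arena values: d = 40 um, pillar height L = 87 um,
contact plane a = 40 um, square lattice at 120 um spacing (gap 80 um, so a
60-um adult worm fits between pillars), E = 250 kPa, nu = 0.49 (nearly
incompressible elastomer), 1 um/px.  These give C = 1.10 um/uN, so the
2-13 uN forces a worm exerts map to 2-14 um deflections — comfortably
measurable at sub-pixel tracking precision while staying within the
small-deflection regime (about a tenth of the lattice gap).

## Synthetic episodes and the ground-truth ledger

The generator renders what the measurement must invert, nothing more:

* **Worm**: a constant-width tube (default diameter 60 um) around a
  serpenoid midline — a traveling lateral sine (amplitude 40 um,
  wavelength 250 um, 0.5 Hz) advancing at 7.5 um/s.  Rendered mid-gray on
  a bright background; pillars are dark disks with a 2-px anti-aliased
  edge, drawn on top (the deflected tip is what the camera sees in focus).
* **Contact**: a pillar is contacted when its rest center lies within one
  worm radius plus one pillar radius of the midline.  Contacted pillars
  receive an imposed force `F = f_max * U(0.2, 1)` (f_max default 12 uN)
  along the outward normal from the nearest midline point, and are drawn
  displaced by `C * F`.  An optional diameter coupling scales f_max by
  `(D/60 um)^3`, making imposed strength strictly increasing in body
  diameter across a simulated cohort.
* **Acquisition**: 45-s episodes at 5 frames/s (225 frames), additive
  Gaussian intensity noise (sigma = 2% of dynamic range) clipped to range,
  and a 5% linear illumination gradient, 16-bit grayscale.  One integer
  seed fans out to independent force and noise streams.

The ledger records, per (frame, pillar), the imposed force, deflection
vector and contact flag, and per frame the midline — so every downstream
stage can be scored against known truth.

What the generator deliberately omits: hydrodynamics, worm deformation
feedback from pillar stiffness, pillar-pillar coupling, texture inside the
worm body, focus drift, and debris.  Passing the end-to-end benchmark
therefore shows the inverse problem (images -> forces -> f95) is solved
correctly under realistic noise and occlusion geometry; it does not certify
performance on real micrographs with artefacts outside this model.

## Tracking

Pillars are localized by normalized cross-correlation (NCC) against a
rendered disk template, with separable quadratic sub-pixel refinement of
the correlation peak.  Full-frame detection (`detect_pillars`) additionally
requires a candidate's disk core to be markedly darker than its surround —
NCC is contrast-invariant, and the worm's rounded head cap otherwise
correlates with the template.  Per-episode tracking (`track_deflections`)
searches a window of radius spacing/4 around each rest center (batched FFT
correlation with a precomputed template transform), marks sub-threshold
peaks as missing (never interpolated), and reports displacements in um.
Measured localization error on noise-free renders is ~0.01 px median,
<= 0.43 px worst-case next to the worm boundary; the 0.5-px bound is the
documented contract.

Rest positions come from the arena config when available; otherwise each
pillar's detections are pooled across frames (nearest-neighbor matching
within spacing/2, transient spurious anchors dropped by a 50%-of-frames
support rule) and the rest center is found by a trimmed median whose window
shrinks from 8 px to 0.75 px — this isolates the tight sub-pixel rest
cluster even when a pillar is contacted in half the frames.  A pillar with
no such cluster (contacted throughout) raises an error naming it.

### Contact classification

With worm masks available, a pillar is in contact when any mask pixel lies
within one pillar radius of its rest center (the center inside the mask
dilated by d/2).  That criterion alone is blind to deep contacts: a pillar
pressed well into the worm occludes every worm pixel in its own
neighbourhood.  It is therefore OR-ed with a displacement criterion,
|deflection| > max(k * sigma_noise, 1 px), with sigma_noise estimated from
pillars never mask-contacted.  The 1-px floor keeps the rescue above the
~0.5 px localization bias that uncontacted pillars adjacent to the worm
carry.  Without masks, the displacement criterion is used alone
(k default 3), with the noise floor taken from pillars that never move
beyond 0.75 px; if every pillar moves, an explicit threshold is required.
Measured agreement with ledger contact flags at default noise: ~99.5%.

### Worm segmentation and QC

Worm masks come from a three-class Otsu threshold (darkest = pillars,
middle = worm, brightest = background) computed on the episode's middle
frame, followed by a small binary opening (removes the thin anti-aliased
pillar rims that land in the middle class) and keeping the largest
connected component.  Episode QC: the motion score is the mean per-frame
displacement of the mask centroid; episodes under 1.5 um/frame are flagged
stationary and excluded from strength aggregation.  The threshold sits
well above the ~0.7 um/frame jitter a stationary worm shows (deflected
pillars bite moving holes out of its mask) and well below the >4 um/frame
of a crawling worm.  Unreadable or corrupt stacks become
processing-failure QC records, never exceptions mid-cohort.

## Strength statistics

`f95` is the 95th percentile of per-frame maximal contacted-pillar forces,
computed by explicit linear interpolation between order statistics
(`h = (n-1) * 95/100`), switchable to nearest-rank.  Frames without
contact are omitted rather than zero-scored — zero-padding would make f95
measure contact frequency instead of strength.  A minimum of 20
contact-frames (configurable) is required; shorter series raise.  Worm
diameter is the median over sampled frames of the median cross-sectional
mask width, measured perpendicular to the local midline (skeleton) with
sub-pixel bisection of the mask boundary.

Group comparisons use Welch's unequal-variance two-sample t-test, each worm
one independent sample; effects are also reported as percent of the
reference-group mean.  alpha = 0.05 throughout.

## Thrashing

One body bend is a full cycle: a rightward then a leftward excursion of
the bend angle.  The counter smooths the series with a 1/6-s moving
average, sets a hysteresis band at 20% of the amplitude envelope, and
counts completed (+band, then -band) pairs; partial cycles score zero.
The band makes the count invariant to amplitude scaling and robust to the
generator's default noise (10% of amplitude): over 500 noisy series the
count is within one bend of truth in >95% of cases, and exact on clean
sinusoids.  The assay design is 10 worms x 5 repeated 10-s windows x 3
biological replicates = 150 records per condition; aggregation refuses
incomplete designs explicitly rather than dropping cells.  The
temperature-sensitivity contrast is a two-way ANOVA (strain x temperature,
type-II SS) with Tukey HSD over the four cells.  Note that record-level
ANOVA treats the 150 records as independent; the simulator's between-worm
variability (worm-level frequency jitter, default SD 0.2 Hz) makes that
anticonservative, so the null-calibration checks run with worm-level
variance off.

## Levamisole paralysis

Cohorts carry i.i.d. exponential(lambda) latent paralysis times; scoring
is every 10 min, truncated at the first grid time by which the reference
cohort is fully paralyzed (flagged open-ended if that never happens within
the horizon).  Curves are compared by a split-plot ANOVA — worm as
subject, strain between, time within, binary paralyzed status as the
response — coded directly because the standard repeated-measures helpers
lack a between-subject factor; the decomposition was verified against an
independent split-plot fit, frozen in the tests.  Power note: at a 2x
hazard ratio the full 20 °C design (two replicates of n=50, total n=100
per strain) detects the strain effect in ~99% of simulations; a single
n=50 cohort per strain yields ~90%.

## OCR

Phase plan 5/9/5 (basal, post-FCCP maximal, post-azide non-mitochondrial);
the final 3/7/2 cycles of each phase are retained (selection is
order-preserving and idempotent), averaged per well, and divided by worms
per well (default design: 20 worms/well, 5 wells/condition).  Spare
respiratory capacity = maximal - basal, reported even when negative;
mitochondrial basal (basal - non-mitochondrial) is a secondary column.
Conditions are compared by one-way ANOVA with Tukey HSD.  A drug rescue is
declared when the mutant differs from the reference (Tukey-adjusted
p < 0.05) while the treated mutant does not; with fewer than three groups
the routine falls back to a plain pairwise comparison and leaves the
verdict undecided.  Default simulated levels (basal 20, maximal 30,
non-mito 4 raw units/well, noise SD 2) put a 1.5x basal elevation at ~100%
detection and a full rescue at ~97-98% declaration over 200 runs.

## Numerical and reproducibility choices

* All randomness flows from integer seeds through `SeedSequence.spawn`;
  generators are pure functions of (parameters, seed), and identical
  config + seed reproduce output tables byte-for-byte.
* Percentile interpolation is linear between order statistics; ties and
  permutations cannot change the result (sort-based).
* NCC peaks below 0.5 are treated as missing detections; nearest-neighbor
  matching beyond spacing/2 is rejected.
* Degenerate inputs fail loudly and specifically: overlapping lattices,
  worms wider than the lattice gap, phases shorter than their retention
  counts, empty masks, series shorter than the scoring window.
* Problem sizes in the test-suite benchmarks: 20 episodes x 225 frames for
  end-to-end recovery; 200-1,000 simulations for the assay Monte Carlos;
  10,000 simulations for test-size calibration.

## Known limitations

* The renderer's occlusion model (pillars always on top, worm a uniform
  tube) is idealized; real movies have focus drift, debris and
  illumination structure the segmentation has not been tuned for.
* Deep-contact classification leans on the displacement criterion; on
  arenas with much stiffer pillars (deflections below a pixel) contact
  detection would degrade toward the mask criterion alone.
* The split-plot paralysis ANOVA uses binary responses; its F-tests are
  approximate (they behave well at the cohort sizes used, as the
  calibration checks show, but are not exact).
* Strength results are per-episode independent samples; no repeated-
  measures modelling across days is attempted.
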