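# Methods

## The measurement problem

Breast cancer–related lymphoedema (BCRL) mixes two tissue responses in the
epifascial layer of the arm — the compartment between the skin and the
muscle fascia: accumulation of interstitial fluid (edema) and hypertrophy
of fat. Standard clinical assessment (tape, Perometer) measures only the
total size of the limb, so the composition of the swelling, which drives
treatment choice (compression and drainage address fluid; liposuction
addresses fat), is not quantified. `lymphmap` implements an automated MRI
post-processing method that measures six volumes per arm — total arm,
subfascial, epifascial, muscle (subfascial), fat (epifascial) and fluid
(epifascial) — and maps where the excess volume of the affected arm sits.

## Inputs and coordinate contract

Three co-registered 3D volumes per arm: a Dixon water image (muscle
bright), a Dixon fat image (fat bright) and a STIR image (fluid bright,
fat suppressed). All processing happens at 1 mm isotropic resolution, so
one voxel is 1 mm³ = 0.001 mL, and volumes are voxel counts. Axis 0 runs
wrist → shoulder; axes 1–2 are the transaxial plane. Slice indices are
0-based. The analysis extent is standardized anatomically: all slices from
the wrist (distal radioulnar joint) to the 65% upper-arm mark, defined as
`round(elbow + 0.65 × (shoulder_tip − elbow))` with half-away-from-zero
rounding (the rounding rule is our choice; both boundary slices are
included). Landmarks are supplied by the user in a JSON/YAML sidecar — the
method selects them anatomically and no automatic detection is attempted.

Resampling to isotropic spacing uses linear interpolation for intensity
volumes and nearest-neighbour for label volumes; output voxel *i* sits at
physical position *i* mm, preserving the physical extent to within one
voxel.

## Segmentation model

Each voxel contributes a point (water, fat, STIR) to a 3D feature space,
which is partitioned into k = 5 clusters by Lloyd's k-means: three tissue
clusters (muscle, fat, fluid), one for voxels contributing no signal
(image noise / background) and one for voxels of mixed composition at
tissue interfaces. Raw intensities are used (no scaling) by default, with
an optional per-channel standardization flag. Fitting is per arm; each
arm's combined analysis extent forms one feature space.

Implementation choices:

* k-means++ initialization with `n_init = 10` seeded restarts, keeping the
  lowest within-cluster sum of squares; max 300 iterations, relative
  tolerance 1e-4. Restarts matter: with four well-separated intensity
  populations and five clusters, the fifth centroid splits whichever
  population carries the largest mass × variance, and the best-inertia
  restart reliably puts that split in the (most populous) background
  rather than in a tissue.
* Volumes larger than 400 000 voxels are fitted on a seeded random
  subsample of that size; prediction always labels every voxel. At 1 mm
  resolution an arm extent has 2–3 million voxels, and centroid estimates
  from 400 k points are statistically indistinguishable for this task.
* Clusters map to tissues by centroid dominance, in fixed priority order:
  smallest channel sum → noise; largest fat value → fat; largest STIR →
  fluid; largest water → muscle; the remainder → mixed. Ties — including
  near-ties within a 1e-9 relative tolerance, which arise when an
  empty-cluster relocation duplicates a centroid up to floating-point
  rounding — resolve to the lower cluster index, and voxel labelling uses
  the same rule, so assignment and labelling can never disagree about a
  duplicated centroid.
* The model needs every tissue population actually present: an arm with
  essentially no fluid gives the fluid label to a background sub-cluster.
  Real arms, including unaffected ones, carry physiological interstitial
  fluid; the synthetic generators therefore include a baseline fluid
  pocket in both arms.

## Compartment separation

Per transaxial slice, two masks are built from the label map with binary
morphology and the compartments are their set differences:

* **external mask** — largest connected component of non-noise voxels
  after an opening (disk radius `r_open`, default 3 mm), then a closing
  (`r_close_external`, default 3 mm) and hole filling;
* **subfascial mask** — same construction from the muscle voxels with a
  wider closing (`r_close_fascia`, default 5 mm, so vessels and bone fall
  inside the fascial contour), constrained to the external mask;
* **epifascial = external ∖ subfascial**, so subfascial + epifascial voxel
  counts equal the external count exactly, per slice and globally.

The closing radii are package parameters (the method's description names
erosion/dilation but no sizes). The opening exists because, under noise,
the split background cluster labels roughly half the background as
"mixed": without it that salt-and-pepper scatter attaches to the arm
boundary and inflates the external mask. A residual fractional-voxel rim
remains — at noise equal to 10% of the minimum inter-tissue contrast it
inflates the total/epifascial volume by about 2–3.5% (tissue volumes are
unaffected); noise-free masks are exact. Slices with no muscle voxels get
an empty subfascial mask and a QC flag rather than an error. Contours are
extracted per slice as pixel-boundary polygons (exact area = voxel count);
mask areas and contour areas therefore agree identically.

Mixed-composition voxels count toward the compartment volumes (they are
tissue) but toward no single tissue volume. Fluid voxels found below the
fascia are counted in the subfascial volume, not in epifascial fluid, and
their count is reported as a diagnostic.

## Volumetry and paired metrics

Volumes are 0.001 mL × voxel counts; fat and fluid are counted only where
the compartment is epifascial, muscle only where subfascial. For an
affected/unaffected pair, both arms are first aligned at the elbow and
trimmed to a common extent of equal slice count; then per metric: excess =
affected − unaffected; percent change = excess / unaffected × 100
(reported missing, not infinite, when the unaffected volume is zero);
relative excesses divide the epifascial, fat and fluid excesses by the
unaffected arm's epifascial volume, normalizing arm size across subjects.
The epifascial share of excess is epifascial excess ÷ total-arm excess.

## Maps

* **Longitudinal profile** — per-slice mL of muscle, epifascial fat,
  epifascial fluid, epifascial and total; sums over slices equal the
  global volumes exactly.
* **Longitudinal excess map** — the forearm (aligned slices before the
  elbow index) is split into 6 contiguous segments and the upper arm
  (elbow onward) into 4; remainder slices are distributed one per segment
  from the distal end. Per segment: fluid excess (mL), fat excess (mL) and
  the epifascial increase (% of the unaffected volume; NaN for an empty
  unaffected segment). Segment sums equal the global excesses exactly.
  Each measure is normalized to its per-arm peak for display and the peak
  is stored with the map, so absolute values stay recoverable.
* **Radial excess map** — the epifascial layer is split into internal
  (above the muscle) and external (below the skin) sublayers at the
  midcontour, realized by per-slice Euclidean-distance comparison (an
  epifascial voxel is internal iff its distance to the subfascial region
  does not exceed its distance to the exterior; ties internal) — exactly
  equivalent to constructing the equidistant curve, and directly testable
  against brute-force nearest-voxel search. Each slice is cut into 8
  sectors by the horizontal, vertical and 45° lines through the
  subfascial centre of mass (computed per slice, tracking anatomical
  curvature; fallback to the whole-arm centre where the muscle mask is
  empty). Fluid volume accumulates into the 2 × 8 bins along the aligned
  extent, per arm, and the map is the per-bin affected − unaffected
  difference. A voxel centred exactly on a sector boundary is split half
  and half between the adjacent sectors, which removes a systematic
  diagonal-vs-axis bias while preserving the exact partition identity.
  Left arms are mirrored about the vertical axis so the torso-facing side
  renders on the right regardless of laterality.

## Cohort statistics

Per volume set: Shapiro–Wilk normality and a two-tailed paired t test
(significance at p < 0.05; zero-variance differences are flagged as
degenerate, not crashed). Fat vs fluid excess: Pearson correlation with a
least-squares line and the standard 95% confidence band. Rank
correlations use Spearman's rho; for n ≤ 8 without ties the two-sided
p-value is computed by exact permutation enumeration (8! orderings),
asymptotically otherwise — full enumeration at n = 9–10 costs far more
than the fidelity it adds. No multiple-testing correction is applied.

## The phantom generator

The generator defines the validation conditions: a tapered circular
cylinder (default wrist radius 32 mm → shoulder 48 mm over 200 slices,
120² in-plane) with a concentric muscle core (20 → 32 mm) whose boundary
is the fascia, fat filling the epifascial annulus, and fluid pockets
(spherical blobs or annulus-sectors, placed in the internal or external
sublayer; an optional honeycomb mode interleaves fluid with fat on a
period-2 lattice to mimic trabecular edema; subfascial pockets can be
injected to probe misclassification). Channel intensities are tissue mean
× optional smooth multiplicative bias field (random low-order polynomial,
amplitude default 0, emulating scanner-corrected data) + additive Gaussian
noise clipped at zero (a simplification of Rician magnitude noise).
Default tissue means (water, fat, STIR): background (30, 30, 30), muscle
(100, 10, 25), fat (15, 100, 10), fluid (60, 8, 100) — each tissue
dominates its characteristic channel, which construction validates. Noise
levels are expressed as a fraction of the minimum pairwise Euclidean
distance between tissue means (72.97 for the defaults); the validation
suite uses 10%.

Ground truth is the voxelized geometry itself: labels, compartments,
sublayers and the six volumes as exact voxel counts over the analysis
extent.

Excess injection is calibrated on the voxel grid: fat excess grows the
external radius per slice, fluid excess adds an annulus-sector pocket with
per-slice angular cuts, muscle excess grows the core; per-slice cut values
are chosen greedily on the sorted radius/angle values so the summed count
hits the target to within a few tens of voxels (≪ 1%), and the achieved
counts are what the truth tables report. Targets beyond geometric capacity
raise an error in `generate_pair`; the cohort generator instead clamps
rare extreme draws against conservative capacity estimates so cohort
generation is total for any seed.

Cohorts draw per-subject arm size (shoulder radius ~ N(36, 2) mm), fat
excess ~ N(120, 40) mL and fluid excess = fat/2.1 + N(0, 16.8) mL — the
slope mirrors a fat:fluid composition of 2.1 and the noise level sets the
population Pearson correlation to 0.75. Both arms carry a physiological
internal-layer fluid pocket (120° sector, ~25–30 mL).

## What the phantoms do and do not show

The phantoms share the contrast structure the method assumes (one dominant
channel per tissue, dark background) and its failure surface at the
geometric level (morphology radii vs. structure size, partial population
sizes, noise). They do **not** model: partial-volume mixing at tissue
interfaces (the "mixed" cluster is validated only as an escape class),
Rician noise statistics, uncorrected bias fields (amplitude defaults to
0), bone and vessels inside the fascia, non-circular cross-sections, or
fibrosis. Passing the suite therefore demonstrates the correctness of the
pipeline's geometry, accounting and statistics under the stated contrast
assumptions — not clinical accuracy on patient data, which would require
acquired images.

## Validation problem sizes

The volume-recovery suite runs a 200 × 120 × 120 phantom noise-free and at
10% contrast noise over 10 fixed seeds; excess recovery injects
(100 mL fat, 50 mL fluid) and a fat:fluid = 2.1 scenario at the same size;
the k-means oracle enumerates all 2-partitions of ≤ 12 points over 100
random instances (400 k-means++ restarts suffice for global optimality on
all of them); statistical calibration uses 1000 null paired tests at
n = 13 and a 200-subject truth table. Unit fixtures use 60–100-slice
phantoms to keep the default test run fast.

## Known limitations

* The external mask inflates by a fractional-voxel rim under heavy noise
  (see above); tissue volumes are unaffected.
* Arms whose fluid (or fat) population is negligible destabilize the
  five-cluster model; joint fitting of a pair or the standardization flag
  can help, but the supported regime is arms with all tissues present.
* The cluster→tissue assignment heuristic assumes the acquisition's
  contrast ordering; swapped or heavily scaled channels require the
  standardization flag and channel verification.
* Morphological radii (3/3/5 mm) suit adult arm geometry at 1 mm
  resolution; very thin structures (< ~6 mm) could be opened away.
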