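# Methods

## The problem and the model

Excitatory presynaptic boutons sometimes synapse onto two (or more)
postsynaptic partners at once — multisynaptic boutons (MSBs) — rather than
the usual one-bouton/one-spine arrangement. In dissociated hippocampal
cultures such MSB profiles can be identified in two-channel fluorescence
images as a presynaptic punctum abutting or overlapping two distinct
postsynaptic objects. This package implements the quantitative pipeline
around that observation:

1. **Profile census** (fixed images): a bouton contacting ≥ 2 postsynaptic
   objects is one MSB profile; exactly one contact is a single profile; one
   postsynaptic punctum contacted by ≥ 2 boutons is the converse "opposite"
   profile. "Contact" means segmented regions overlap by at least one voxel
   or their boundaries are within a gap of one pixel width (0.14 µm,
   configurable) — the numerical reading of "abutting".
2. **Pair geometry**: for a spine pair, the head distance is the Euclidean
   distance between the intensity-weighted head centres of mass in x-y-z;
   orientation is *towards* when heads are nearer than bases, *away* when
   further, *parallel* when equal within a tolerance. MSB pairs cluster
   near 1 µm head distance and point towards each other or parallel;
   random adjacent (control) pairs sit near 2.5 µm with no preferred
   orientation. That separation motivates the live-imaging identification
   rule: shared bouton, head distance < 1.3 µm, orientation towards or
   parallel.
3. **Dominance dynamics** (time lapse): each spine head's volume proxy is
   its integrated density IntDen (mean brightness × area = intensity sum).
   With the dominant spine preselected as the one with the higher mean
   IntDen over the analysis window,

       DiffIndex(t) = (IntDen_Dom − IntDen_Nondom) / (IntDen_Dom + IntDen_Nondom)

   is a per-frame, illumination-scale-invariant asymmetry index in [−1, 1].
   The slope of its ordinary-least-squares trend against time is the
   **dominance rate** (ΔDiffIndex/h); the squared Pearson correlation R²
   measures trend strength. Only the first 15 h from the first frame at
   which the synapse is discernable enter the fit (16 hourly frames), and
   frames where a spine is not measurable are treated as missing, not
   interpolated. MSB spine pairs show fast, strong trends (≈ 0.042/h) —
   one spine grows at its partner's expense — while single-bouton (SSB)
   spines paired with their nearest neighbors drift near zero (≈ 0.002/h).

The package reports these dynamics as descriptive statistics; it makes no
causal claim about competition.

## Statistics

The comparisons use one-tailed two-sample t tests (pooled variance by
default, Welch by flag; the direction of the alternative must always be
passed explicitly), a two-tailed Mann–Whitney U test, and χ² tests, all at
α = 0.05 and implemented from first principles so the small-sample behavior
is inspectable:

- **Mann–Whitney U**: for small samples (both n ≤ 10 or n·m ≤ 400) the
  exact null distribution of U is computed — by the standard counting
  recurrence N(m, n, u) = N(m−1, n, u−n) + N(m, n−1, u) when the pooled
  data has no ties (validated in the tests against full enumeration), or by
  full enumeration of group assignments when ties are present. Larger
  samples use the normal approximation with tie and continuity corrections.
  The result records which path ran. The two-tailed p is the null
  probability of a deviation |U − mn/2| at least as large as observed.
- **χ²**: both a goodness-of-fit variant (observed counts against expected
  proportions, df = k − 1) and a Pearson contingency variant
  (df = (r−1)(c−1), no continuity correction) are provided, because the
  orientation comparison can be read either way. For observed MSB
  orientation counts (14, 5, 3) against control-derived proportions
  (7, 9, 6)/22 the GOF variant gives χ² = 10.28, p = 0.0059 ≈ 0.006; the
  2×3 contingency reading of the same counts gives χ² = 4.48, p ≈ 0.11.
  The GOF variant is the one that reproduces the reference value.
- A caveat the package documents rather than hides: a pooled t on the
  printed head-distance summaries (0.98 ± 0.12 vs 2.53 ± 0.64 µm, n = 18
  each) gives p ≈ 1e-11, not the historically printed 4×10⁻⁵; summary
  statistics alone cannot reproduce that value, so no attempt is made to.

## The synthetic-data generator

Because no raw image data is distributable with the package, a generator
builds ground-truthed scenes whose *statistics* match the study regime; all
defaults are fixed in `SceneConfig`:

| parameter | default | meaning |
|---|---|---|
| `spine_density` | 0.75 /µm | spines per µm of dendrite |
| `dendrite_length` | 40 µm | one segment per scene |
| `msb_pair_fraction` | 0.08 | MSB share of synaptic profiles |
| `msb_head_distance_mean/sd` | 0.98 / 0.12 µm | MSB pair head distances |
| `control_head_distance_mean/sd` | 2.53 / 0.64 µm | adjacent control pairs |
| `orientation_probs_msb` | 14:5:3 / 22 | towards : parallel : away |
| `orientation_probs_control` | 7:9:6 / 22 | idem |
| `dominance_rate_mean/sd (msb)` | 0.042 / 0.004 /h | sampled pair trends |
| `dominance_rate_mean/sd (ssb)` | 0.002 / 0.007 /h | idem |
| `n_frames`, `frame_interval` | 16, 1 h | 15-h analysis window |
| `pixel_size_xy`, `z_step` | 0.14, 0.37 µm | acquisition calibration |
| `intensity_noise_sd` | 0.05 | relative measurement noise |

Design choices where the underlying numbers give no prescription:

- **Distance samplers** are normals truncated at 0.05 µm (a negative or
  zero distance is meaningless); truncation is by resampling and its effect
  on the means is far below sampling error.
- **Pair geometry** realises each sampled draw exactly: heads are placed
  `head_distance` apart along the dendrite axis, and the base distance is
  head distance ± 0.5 µm for towards/away (well beyond the 0.15 µm
  parallel tolerance) or equal for parallel.
- **Volume trajectories**: an MSB pair exchanges volume at constant total,
  so DiffIndex is exactly linear with the sampled slope; MSB pairs start
  with volume ratios in [0.9, 1.1] (competition starts from near-equal
  strength). The nondominant spine shrinks linearly to a floor of 5% of
  its initial volume and is then retracted (IntDen 0, DiffIndex 1); an
  `abrupt` mode keeps it constant until the retraction frame instead,
  since the true pre-retraction time course is not established.
- **Trend-sign consistency**: the initial asymmetry is set to
  max(ε, 0.03 − rate·t̄) so the spine carrying the sampled trend is also
  the one with the higher window-mean volume. Without this, mean-density
  preselection flips the sign of strongly negative sampled rates and the
  fitted SSB rate distribution would not converge to the configured one.
- **Rendering**: objects are anisotropic Gaussian blobs (σ_xy 0.2 µm,
  σ_z 0.5 µm) whose discrete sums match their truth volumes to ≪ 1%;
  the shaft is a uniform tube; multisynaptic boutons are elongated along
  the dendrite to span both spine heads. Noise is additive Gaussian with
  per-voxel s.d. proportional to the noise-free signal — the analysis is
  intensity-ratio based and insensitive to the specific noise model, which
  is deliberately simple and swappable. No photobleaching, stage drift,
  dendrite branching, or realistic PSF physics: passing tests demonstrate
  correctness of the measurement chain, not robustness to those real-data
  effects. Tabular pair series (`sample_pair_dynamics`) instead multiply
  each frame's IntDen by 1 + N(0, noise_sd), emulating measurement noise
  without rendering.
- **Coordinates**: physical µm, origin at the stack corner, voxel index =
  floor(position/size); the dendrite starts 1 µm into the field of view so
  no object's core is clipped at the border.

## Numerical and procedural choices

- Despeckling zeroes a pixel iff it is nonzero and all its 8- (2D) or
  26-connected (3D) neighbors are zero; the operation is idempotent and
  never increases a pixel.
- Z-projection is maximum-intensity by default (sum projection available).
- Segmentation normalizes each image so its maximum sits at the detector
  ceiling and thresholds relative to that ceiling (default 0.5 for puncta,
  0.25 for spine heads, which are dimmer relative to the global maximum),
  with full connectivity and a physical minimum component size. Spine
  heads are components off the (dilated) shaft mask; the shaft is the
  thresholded component with the largest x-extent; the base point is the
  shaft voxel nearest the head centroid. Dendrite length is the geodesic
  length of the projected shaft skeleton.
- Per-frame pair measurement uses a fixed spherical aperture (0.45 µm
  radius) at the tracked head position — the automated analogue of a
  manually traced head contour, and the same aperture every frame so the
  DiffIndex is unaffected by the captured-volume fraction.
- OLS fit: slope from centred sums; R² = 0 by convention for an exactly
  constant series (no trend explained, avoiding 0/0); < 2 valid frames or
  zero time variance raise errors rather than returning numbers.
- Dominance preselection ties break to the lexicographically smaller id,
  with a logged warning.
- Manual interactive steps of the original workflow (brightness/contrast
  adjustment, visual orientation calls, "first discernable frame"
  judgment) are replaced by recorded normalization, a 0.15 µm orientation
  tolerance (≈ one pixel), and an explicit per-pair start-frame argument.

## Problem sizes used in the checks

The automated checks run, per invocation: 10 000 sampled pairs per class
for the geometry statistics; 200 pairs per class (16 frames, 5% noise) for
rate recovery, with 100 meta-replicates for the separation test; one
rendered default scene (30 spines, 16 frames, ~4·10⁶ voxels) for the
end-to-end recovery scores; 2000 replicates for the type-I-error
calibration of each test; ≥ 100 randomized small instances per operation
for brute-force oracle equivalence.

## Known limitations

- The spine-head detector is a threshold/blob method, not a neurite
  reconstruction; it assumes a single unbranched shaft and heads standing
  clear of it, which the generator guarantees but dense real tissue does
  not.
- The live MSB identification rule rejects pairs angled away from each
  other by construction, so any truly away-angled MSB pair (≈ 3/22 of the
  fixed-image orientation distribution) is invisible to the live analysis;
  the recovered live-pair set is accordingly a biased subsample of all MSB
  pairs, in the synthetic scenes exactly as in the original procedure.
- Fold ratios of class means are reported without uncertainty; with a
  near-zero SSB denominator they are numerically unstable, which is why
  the class comparison also carries the t tests.
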