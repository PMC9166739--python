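# Methods

`synaptoscope` quantifies immunolabelled synaptosome particles — resealed
nerve-terminal particles of roughly 0.5–2 µm immobilized on coverslips and
imaged in two fluorescence channels — and screens sorted-vs-control
proteomes for enriched proteins. This note documents the models, the
parameters that matter, the synthetic data the test suite runs on, and the
numerical choices made where the design was genuinely open.

## Image model and detection

A frame is a set of co-registered 2-D channels with a physical pixel size
(default 0.1 µm/px, typical of wide-field imaging with a 40–63× objective).
Detection assumes that the two labels of interest lie close together on a
particle, so the channels are combined before particles are located:

1. each channel is standardized (mean subtracted, divided by its SD), so
   channels with different gain contribute on one scale;
2. the pixelwise maximum of the standardized channels forms one working
   image in which a particle present in *either* channel appears;
3. the working image is median-filtered (circular footprint, radius 3 px)
   and Gaussian-blurred; "blur radius 3 px" is interpreted as
   sigma = radius/2 = 1.5 px, the common blur-radius convention (the sigma
   is configurable and recorded in provenance output);
4. local maxima are retained by prominence: a maximum is kept only when
   its value exceeds the level at which its basin merges with a higher
   basin by at least the *noise tolerance* (default 3). Because the input
   is standardized, the tolerance is approximately in SD units.

The maxima finder is a union-find persistence sweep over pixels in
descending intensity order (8-connectivity). Equal-valued plateaus report
their centroid; among equal peaks the earliest in row-major order survives,
so results are deterministic. The output is invariant to adding a constant
to the image and equivariant to 90° rotations; the test suite cross-checks
it against the reconstruction-based h-maxima transform of scikit-image on
tie-free terrain (the two resolve equal-valued plateaus by different
conventions, so quantized images are not valid oracle ground).

Manual review of detections is replaced by two automatable rejection
rules: *border* (an event whose measurement circle plus background annulus
would exit the image cannot be quantified) and *competing particle*
(another candidate within twice the ROI radius, 48 px by default,
contaminates the measurement; both members of such a pair are rejected).
An optional spot-width filter (reject events whose fitted width exceeds a
cap) approximating "bad focus" rejection was considered and deliberately
left out of the default path: on synthetic scenes every spot is in focus,
so the filter would be dead code that the tests cannot exercise.

## Quantification

Accepted events are measured on the **raw** channel grids (standardization
and smoothing exist only to find particles). A circular ROI (radius 24 px)
is placed at the shared detection centre in both channels; local
background per pixel is estimated in a surrounding annulus (outer radius
30 px, ≈1 000 pixels); the corrected integrated intensity is

    I = sum(ROI) − background_per_pixel × N_ROI.

Two documented choices deviate from the most literal reading:

* **Background statistic = annulus mean** (median available via
  `QuantParams(background_statistic="median")`). The background error is
  multiplied by the ROI area (1 809 px), so estimator efficiency matters;
  the median inflates the error SD by ×1.253, which alone pushes the
  median relative intensity error at reference conditions from ~4% to ~6%.
  The usual argument for the median — robustness to a neighbouring
  particle leaking into the ring — does not apply to accepted events,
  because competing-particle QC guarantees a particle-free annulus.
* **Centroid localization** uses a moving-window refinement: an
  intensity-weighted centroid of background-subtracted, floored-at-zero
  pixels inside a small disc (radius 6 px ≈ 4 PSF sigma), seeded at the
  brightest ROI pixel and re-centred each iteration until convergence.
  A one-shot floored centroid over the full 24-px ROI is biased toward
  the ROI centre: clipped noise contributes ~N·sigma/sqrt(2π) of spurious
  mass spread symmetrically about the *detection* centre, which drags both
  channel centroids together and shrinks inter-signal distances (a 0.33 µm
  offset measured as ~0.12 µm under reference noise). With the moving
  window the spurious mass is symmetric about the running estimate, so the
  net pull vanishes; the empirical bias is ~0.001 µm over offsets
  0.1–1.0 µm. The one-shot rule remains available
  (`centroid_mode="full_roi"`).

The inter-signal distance is the Euclidean distance between the two
channel centroids, in µm. Whether to re-centre the measurement circle per
channel before integrating was an open design point; the default measures
both channels at the shared detection centre (the centroids themselves are
reported per channel), which keeps the two channel measurements on
identical pixels.

**Attainable accuracy.** With ROI radius 24 px the intensity error SD has
an irreducible floor of sqrt(1809)·sigma_noise from pixel noise plus
N_ROI·sigma_noise/sqrt(N_ring) from the background estimate — about 355
intensity units at the reference noise (SD 5), i.e. ~7% SD on a median
5 000-count spot, giving a median |relative error| of ~4.8%. A "5%-of-peak"
noise level would make 5% median error unattainable for *any* estimator
that sums the full circle; the recovery tests therefore run at the
reference noise, and claims about much noisier data should not be
extrapolated from them.

## Quadrant population analysis

Events are classified into four quadrants (A⁺B⁺, A⁺B⁻, A⁻B⁺, A⁻B⁻) by
per-channel thresholds on corrected integrated intensity. Positivity is
strict (`intensity > threshold`); an event exactly at a threshold is
negative. Thresholds may be supplied manually (mirroring gates placed by
eye on real data) or estimated: intensities are robust-scaled, a Gaussian
KDE is built, and the threshold is the minimum-density point between the
background mode and the next mode; for unimodal samples the fallback is
background mode + 3 robust SD (≈0.1% of a clean background called
positive). The estimator wants ≥50 events and both populations
represented; with very few events it degrades toward the fallback, which
is conservative (few or no positives). The method actually used is
recorded per channel.

Percentages are computed per frame (the frame/field-of-view is the unit of
replication) and summarized as mean ± SEM (SD/√n frames; a single frame
reports SEM 0 with a flag). Headline figures derive from two scale-invariant
operations: the conditional proportion `100·a/(a+b)` (of reference-positive
particles, the share also positive for the second marker) and the
enrichment ratio `post%/pre%` (fold-change of a population fraction through
sorting). Full precision is kept internally; headline values round to the
nearest integer (ratios to one decimal).

Subpopulation intensity comparisons use the two-sided Mann–Whitney U test
and the two-sample Kolmogorov–Smirnov test (scipy implementations; the
Mann–Whitney p is cross-checked against a permutation oracle in the
tests). Distance profiles per marker pair report mean ± SEM, median and
quartiles after robust outlier removal, with a Kruskal–Wallis omnibus
test across markers and Dunn's rank-based pairwise follow-up
(Bonferroni-adjusted; written in-package because no installed library
provides Dunn's test).

**Outlier removal** is an FDR-based univariate procedure in the spirit of
ROUT (the original is proprietary and regression-based): robust centre =
median, robust scale = 68.27th percentile of absolute deviations, per-point
two-tailed p from a t distribution with n−1 df, flagged by
Benjamini–Hochberg stepping at rate Q (default 1%). Below 10 values
nothing is removed and the profile is flagged; constant data (zero scale)
flags nothing. On clean normal samples of n = 1 000 it removes ≲1%.

## Association test (CSR null)

Two particles are associated when their centroid distance is strictly
below d (default 2 µm). The observed fraction is, per reference particle,
the share with ≥1 partner within d (a pooled symmetric variant is
available; outputs record which was used). Significance comes from a
Monte-Carlo randomization: the reference channel is fixed and the other is
replaced by complete spatial randomness — n i.i.d. uniform points over the
whole field, no edge correction, matching the null of "equal probability
everywhere" — for 10 000 iterations by default. The reported null is the
mean fraction over iterations; the empirical p uses the add-one estimator
(1 + #{null ≥ observed})/(iterations + 1), so it is never zero.

The closed-form null expectation, 100·(1 − (1 − πd²/A)^n), assumes points
at least d from the border; the Monte-Carlo null sits slightly below it
(bias bounded by perimeter·d/A times the value, ≈4% relative for a
200×200 µm field at d = 2). For 100 points in that field the null is
≈3.1%; at 15 points it is ≈0.47%, the sub-0.5% regime typical of sparse
real fields. Observed fractions of 10% and above against such nulls give
empirical p at the resolution floor of the iteration count.

## Proteome screen

Input is a long-format peptide table: three control (SYN) and three sorted
(FASS) replicates. Samples are normalized so all totals equal the
grand-mean total (equal protein loading). Each protein's ratio is the
median of all valid pairwise FASS_i/SYN_j peptide ratios (up to 9 per
peptide; missing or non-positive denominators skipped pairwise; even-count
median = midpoint). Proteins with no valid pair are dropped and counted;
proteins with fewer than 2 contributing peptides are reported but classed
`under_quantified`.

Significance uses a background-based robust z test built from the stated
assumption that most protein abundances do not change: centre = median of
log₂ ratios; scale = 68.27th percentile of absolute deviations inside an
iteratively trimmed central band (|z| ≤ 2.5, re-trimmed until stable,
never keeping fewer than half the proteins); two-sided normal p on the
robust z; Benjamini–Hochberg adjustment. This is a documented
reimplementation of the *idea* behind the vendor "background based
t-test", not the vendor statistic; every output carries a method tag
saying so. P-values are invariant to a common shift of all log-ratios, so
the normalization constant cannot create false calls.

Classification: `enriched` if ratio > 1.5 and adjusted p < 0.05;
`depleted` if ratio < fold_down and adjusted p < 0.05. The depletion
cutoff is genuinely ambiguous in the field (symmetric 1/1.5 ≈ 0.667 vs a
flat 0.75); the default is the symmetric 1/1.5, and 0.75 is one parameter
away (`ScreenParams(fold_down=0.75)`). Neither is asserted as "the" rule.

A one-sided planted-effect design (enrichment only) shifts all ratios
through total normalization: with 5% of proteins enriched 3-fold,
background ratios land near 0.91 and planted ones near 2.7. The screen is
robust to this because the background test centres itself and the planted
effects remain far above the 1.5 cutoff; the noiseless "ratio = fold
exactly" property holds for the ratio of enriched to background protein
ratios (scale invariance), and for `protein_ratio` on unnormalized data.

The Pearson correlation between imaging enrichment ratios (sorted %
divided by control % of marker-positive particles) and MS fold changes for
the six-marker validation panel is r² = 0.627 when recomputed from the
rounded published percentages (two-tailed t-transform p = 0.060); the
published figure rounds to 0.62 from unrounded inputs.

## Synthetic data

The generators define the conditions every stage is tested under.

* **Scenes** (`make_scene`): particles are isotropic 2-D Gaussian spots
  (PSF sigma 1.5 px ≈ 350 nm FWHM at 0.1 µm/px — wide-field imaging of
  sub-resolution ~0.5 µm particles). Spots are rendered by exact pixel
  integration (erf form), so a spot's rendered mass equals its true
  intensity to <10⁻⁸ relative (tail truncation at 6 sigma). Intensities
  are lognormal (log-mean 8.5 ≈ 5 000 counts, log-SD 0.3 — fluorescence
  is multiplicative); background is 100 counts with additive Gaussian
  camera noise of SD 5 (peak SNR ≈ 70). Classes: single-channel `A_only`
  and `B_only`, and double-channel `AB` whose two centroids are offset by
  a configurable law (default 0.3 ± 0.05 µm, the centre-to-centre range
  of co-assembled particles resolvable by wide-field imaging). Positions
  are uniform outside a 30-px margin so no ground-truth particle is
  border-rejected by construction; a minimum separation (dart throwing,
  explicit failure when the field is too small) puts reference scenes in
  the regime where the competing-particle rule does not fire.
* **Point sets** (`make_point_sets`): a planted fraction of B points at a
  fixed offset (uniform angle) from distinct A points, the rest CSR — the
  fixture for the association test, with the analytic null as oracle.
* **Peptide tables** (`make_peptide_table`): background proteins have
  equal expected intensity in all six samples; enriched proteins have
  FASS expectation = fold × SYN (depleted inverse); peptide count uniform
  1–6; multiplicative lognormal replicate noise with unit mean and
  configurable CV (default 0.2, typical label-free replicate scatter).

What the generators deliberately do **not** emulate: optical aberrations
and defocus, 3-D structure, aggregates, autofluorescence textures,
spectral bleed-through, missing peptide intensities, and
intensity-dependent MS noise. Passing tests therefore demonstrate the
correctness of the computations under the stated statistical model, not
robustness to every artefact of real data.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy.random.default_rng`; the
pipeline splits one master seed per stage via `SeedSequence` spawn keys),
and identical seeds give byte-identical outputs. The standing checks use:
4 scenes of 512² px (48 particles) for detection recall/precision; 400
scenes of 256² px (~3 200 channel measurements) for the intensity-error
median (a sample size chosen so the sampling noise of the median, ~0.15
percentage points, is small against its ~4.8% value); 7 offsets × 18
particles for distance bias; 10 000 Monte-Carlo iterations for single
association runs and 50 × 1 000 for null calibration; 1 000-protein tables
for the screen. A full pipeline run on the default configuration completes
in well under a minute on one CPU.

## Known limitations

* The prominence detector is O(N log N) in pixels but implemented in
  Python; very large mosaics (>4 MPx) take seconds per frame.
* The gate estimator assumes at most two intensity modes per channel and
  prefers false negatives when a sample is effectively single-population.
* The CSR null ignores edge effects by design (it reproduces the
  uniform-over-the-whole-field null); for fields not much larger than d
  the analytic oracle and the test both become approximate.
* The outlier and background tests are documented stand-ins for
  proprietary procedures; they control the same error rates but will not
  numerically reproduce vendor output.
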