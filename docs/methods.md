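# Methods

`fstloc` re-creates, end to end on synthetic data, a functional-MRI
procedure for localizing the putative human homolog of macaque area FST
(pFST) and distinguishing it from the neighboring hMT/MST motion complex.
No scanner data are read anywhere: the package generates the stimuli, a
ground-truth cortical sheet, and the vertex-wise BOLD responses, then runs
the full analysis chain (GLM contrasts → ROI delineation → pRF fitting →
validation statistics) against that ground truth. This note documents the
models, the defaults and why they were chosen, and what the synthetic
setting does and does not establish.

## Stimulus models

**2D-motion localizer.** 250 limited-lifetime dots (0.5 s) in a 10 deg
radius aperture, presented in a block design alternating moving and static
blocks of 15 s; the four motion conditions (radial in/out, clockwise/
counterclockwise rotation) each appear three times, giving 6 min of
stimulus plus a 15 s blank. Radial blocks scale dot speed with the square
root of eccentricity, `v(e) = 12·sqrt(e/10)` deg/s; rotational blocks use
one-eighth-power scaling, `v(e) = 12·(e/10)^(1/8)`, which keeps motion
visible near the fovea. Both profiles peak at 12 deg/s at the aperture
edge. Dots respawn uniformly over the aperture disk when their lifetime
expires or they leave the field (the uniform respawn distribution is a
choice; only "random location" is specified by the protocol). Dot ages are
initialized uniformly over the lifetime so respawns are asynchronous.

**3D-motion (stereomotion) localizer.** Two disparity-defined surfaces — a
central disk (within 6 deg eccentricity) and a surrounding annulus — move
in antiphase through depth. The disparity waveform is a triangle wave of
amplitude 18 arcmin and period 2 s (a direction reversal every second);
a triangle wave (constant speed in depth) was chosen over a sinusoid, the
protocol fixing only the ±18 arcmin endpoints and the 1 s reversals. The
temporally scrambled control permutes whole stereo frame pairs *within
each 1 s half-cycle segment*. Per-segment scrambling (rather than
run-wide) is deliberate: it conserves the disparity multiset and also
keeps every relative disparity level of the cycle on screen once per
second, so the control differs from the coherent condition only in the
temporal coherence of the disparity change. The schedule alternates
coherent/scrambled every 10 s, 15 repetitions each (5 min plus 15 s
blank).

**Opponent motion.** 300 dots per frame, 150 leftward and 150 rightward at
5 deg/s. In the paired condition dots form counterphase pairs sharing a
y-coordinate: members start 0.5 deg apart, cross once at mid-life and
annihilate at 0.5 deg on the far side, fixing the lifetime at
0.5 / (2·5) · 2 = 0.1 s. Pair phases are randomized so crossings are
asynchronous. The unpaired condition uses identical kinematics with
independent positions. Scans alternate the two conditions in 15 s blocks,
21 blocks = 315 s.

**pRF-mapping apertures.** Binary masks on a raster spanning ±12.2 deg
(default 101×101 cells), at TR resolution. The bar aperture translates
across the field in 8 positions per sweep, one sweep per direction
(right, up, left, down), each position held 3 TRs; the default bar width,
2·radius/n_steps, exactly tiles the field per sweep. Wedge (45 deg sector,
one rotation each way) and ring (expanding then contracting annulus)
apertures are provided for protocol completeness; the analysis and the
bias study use the bar, matching the simulated-stimulus choice of the
study being emulated. Exact sweep periods and duty cycles of the original
protocol are not restated in the source; the defaults here are round
numbers of the same order and are fully configurable.

## Synthetic hemisphere and forward model

The "hemisphere" is a flat 64×64 vertex sheet with 4-connectivity — real
cortical mesh topology, folding and vascular structure are out of scope.
Columns run posterior→anterior and rows dorsal→ventral. Three regions are
embedded:

| region | vertices | 2D gain (PSC) | 3D response | opponency idx | pRF σ (deg) | T1 (s) |
|---|---|---|---|---|---|---|
| V1-like | 160 | 1.2 | 0.05 | 0.1 | 0.8 | 1.30 |
| hMT/MST | 296 | 2.0 | 0.5 | 0.6 | 2.0 | 1.19 |
| pFST | 95 | 1.0 | 2.0 | 0.2 | 15 | 1.26 |
| background | rest | 0 | 0 | — | — | 1.331 |

Values are per-region means; vertices draw from Gaussians around them
(SDs 0.03–0.3 depending on the field). The orderings encode the study's
hypotheses: hMT/MST dominates the 2D contrast and opponency suppression;
pFST dominates the coherent-3D contrast (its 3D selectivity is 1.0, i.e.
the scrambled control drives it not at all, versus 0.5 for hMT/MST, which
is "somewhat responsive" to 3D motion — the 0.5 is a free modeling choice,
no quantitative value being reported); pFST receptive fields vastly exceed
those of hMT/MST, which exceed V1-like ones. T1 means put the R1 = 1/T1
myelin proxy at 0.840, 0.794 and 0.751 1/s for hMT/MST, pFST and average
cortex. Region sizes 296/95 reproduce the per-hemisphere degrees of
freedom of the vertex-level tests (one-sample df 295/94, pooled two-sample
df 389). pFST sits anterior and inferior to hMT/MST and adjacent to it.

A second label map stands in for an anatomical atlas: each region is
shifted by a seeded random offset (≤2 vertices) and then dilated or eroded
one step, emulating atlas-to-function misalignment. With jitter 0 the
atlas equals the truth and downstream Dice is 1.

The forward model is linear: each TR gets a neural amplitude from the
block condition (moving → 2D gain; paired → 2D gain × (1 − opponency);
coherent → 3D gain; scrambled → 3D gain × (1 − 3D selectivity); for pRF
runs, the Gaussian-overlap course scaled so its peak equals the vertex's
retinotopic gain), convolved with the hRF, plus a linear drift (default
0.5 PSC per run) and i.i.d. Gaussian noise per TR (default SD 0.5 PSC).
Temporally autocorrelated noise is not modeled. Simulated runs are wrapped
around a raw baseline of 100 so the analysis exercises its own
percent-signal-change conversion, psc = 100·(y − mean)/mean.

The hRF is a double-gamma kernel, gamma(shape 7) minus gamma(shape 17)/6,
sampled over 32 s and normalized to unit sum; its positive lobe peaks at
6 s. Peak time, undershoot delay and ratio are the conventional canonical
values.

## GLM and contrasts

Design matrices contain one hRF-convolved boxcar per condition (blank is
the implicit baseline), a constant, a linear drift ramp (normalized to
[−0.5, 0.5]) and optionally six motion-nuisance columns supplied by the
caller. Betas are `pinv(X) @ y` per vertex, estimated per run and averaged
with equal weights across runs. The three contrasts are motion2d =
mean(four moving betas) − static (the mean, not the sum, of the moving
betas is used; this affects scale only), motion3d = coherent − scrambled,
opponency = unpaired − paired. No prewhitening or multiple-testing
correction is applied, matching the emulated analysis.

## pRF model and fitting

A vertex's pRF is a 2D circular Gaussian with center (x0, y0) and size σ;
its neural response to an aperture is the mask overlap normalized by the
*untruncated* Gaussian integral (so σ and response scale stay separable;
truncation at the raster edge is accepted as model error), convolved with
the hRF. No compressive spatial-summation exponent is used. Fitting is
coarse-to-fine:

1. **Grid stage.** Exhaustive search over centers at 1 deg steps within
   ±radius and 20 log-spaced σ values in [0.25, 24] deg; scale and offset
   are solved in closed form, so the grid score reduces to a squared
   correlation. Ties resolve to the first maximum in row-major
   (x0, y0, σ) order.
2. **Refinement.** Nelder–Mead on (x0, y0, log σ) from the grid optimum
   (parameter tolerance 1e-4, ≤400 iterations), with the search clamped to
   the grid's region — centers within ±radius, σ within [0.25, 24]. The
   clamp matters: on noisy data an unconstrained simplex drifts to
   degenerate, arbitrarily large Gaussians whose predictions are almost
   flat. If refinement cannot beat the grid score, the grid optimum is
   returned (refinement never loses).

All-zero series return a flagged degenerate fit (r2 = 0, center at
fixation). Variance explained is 1 − SSE/SStot clipped to [0, 1], defined
as 0 for zero-variance data. The competing stimulus-contrast (ON/OFF)
model regresses the vertex on the hRF-convolved stimulated *area* course
(plus constant): it has no spatial selectivity, and the gap
r2(pRF) − r2(contrast) measures whether a vertex's position tuning is
resolvable within the aperture.

## Estimation-bias simulation

For each cell of a (size × eccentricity × noise) grid — defaults 1, 5, 10,
15, 20 deg sizes; 0, 3, 6, 9, 12 deg eccentricities; 50 voxels per cell —
voxels are placed at seeded uniform polar angles, their noiseless bar
responses scaled to a 1 PSC peak, Gaussian noise added, and the pRF model
refitted. Cell summaries are the mean and bootstrap SE (100 resamples of
voxels, SD of the resampled means) of estimated size and eccentricity.
Default noise SDs are 0.25, 0.5 and 2.0 PSC — low, medium and high noise
relative to the unit signal peak. All noise levels are strictly positive
by design: the fitted model is exactly the generative model, so at zero
noise recovery is exact and "bias" is pure floating-point jitter; zero
noise is retained in the tests only as a recovery oracle. The simulation
reproduces the qualitative phenomena of interest: sizes ≥ the aperture
radius are underestimated at every noise level, the underestimation grows
with noise, and eccentricity bias (toward the center) grows with true
size.

## ROI delineation

The manual drawing procedure is encoded as a deterministic heuristic so it
can be tested: threshold both contrast maps at a hemisphere-wide
percentile starting at the 95th; hMT/MST is the largest 4-connected
cluster of the 2D mask (drawn first); pFST candidates are clusters of the
3D mask outside hMT/MST that lie within 3 city-block steps of it; among
candidates the centroid score Δcol + Δrow (anterior/inferior relative to
the hMT/MST centroid) must be positive, the highest score winning and
larger clusters breaking ties. If no candidate qualifies, both thresholds
drop together in 1-percentile steps to the 90th (never below); failing
that, pFST is returned empty and flagged. When the 3D activation touches
hMT/MST on several sides the first-ranked candidate is taken and the
ambiguity recorded in the result's notes. An optional window mask stands
in for the anatomical restriction to the lateral-occipital/inferior
temporal cortex. Percentile thresholds use linear interpolation, so the
procedure is invariant to adding a constant to both maps; a constant map
passes everywhere by construction, which is documented behavior for
degenerate input.

One practical consequence of percentile thresholding: a mask at the 95th
percentile contains 5% of vertices, so when the true region holds ~7% of
the sheet the Dice ceiling against ground truth is below 1 regardless of
noise. Recovery tests therefore evaluate the procedure at the
size-matched percentile (100·(1 − region/hemisphere) ≈ 92.8 for the
default sheet), where clean recovery is exact; the shipped default start
remains the 95th, as in the emulated procedure.

Overlap metrics: Dice 2|A∩B|/(|A|+|B|) (0 when both sets are empty, by
convention), Euclidean centroid distance (optionally scaled to mm), and
surface area = vertex count × per-vertex area.

## Validation statistics

R1 = 1/T1 serves as the myelin proxy. Vertex-level comparisons use
one-sample t (df n−1) and pooled-variance Student two-sample t
(df n₁+n₂−2; Welch available behind a flag) — vertices are treated as
independent samples, mirroring the emulated analysis's degrees of freedom,
although real cortical data are spatially correlated; this caveat applies
to any interpretation of the vertex-level p values. Group comparisons are
two-sided paired t tests across hemispheres (18 hemispheres → df 17),
with per-hemisphere one-tailed two-sample tests counted at α = 0.05 in the
expected direction (hMT/MST > pFST for the 2D, opponency and R1 measures;
pFST ≥ hMT/MST for 3D). Decile profiles report the 10th–100th percentiles
of both ROI distributions with the sign of each decile's slope.

Group-level tests run on a lightweight measure-level cohort generator
(9 subjects × 2 hemispheres by default): per hemisphere and ROI, vertex
values are drawn around the region's expected contrast with vertex noise
(SD 0.3 PSC; 0.02 1/s for R1) plus a hemisphere-level offset shared by
both ROIs (SD 0.1 / 0.01), so paired comparisons stay calibrated. A null
mode removes all designed gaps for type-I-error checks; over 200 null
cohorts the paired test rejects at the nominal 5% rate within binomial
error.

## Reproducibility and problem sizes

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name (CRC-32 into a seed sequence, kept below
2³¹); running a stage twice with the same configuration produces
byte-identical outputs. The shipped default configuration holds every
default named above; tests exercise reduced problem sizes (61-cell
rasters, 6–10 voxels per bias cell, 10 seeds) chosen so the full suite
completes in a few minutes while leaving the default configuration at the
study-scale values.

## What the synthetic setting shows — and does not

Passing tests establish that the pipeline's machinery is faithful: the
stimulus arithmetic matches the protocol, the GLM recovers designed gains
to within convolution edge effects, the pRF fitter recovers parameters it
can in principle recover and exhibits the documented biases when it
cannot, the delineation heuristic recovers ground-truth regions under
moderate noise, and the statistics are calibrated. They do not establish
anything about real cortex: the synthetic sheet has no folding, no
spatially correlated noise, no inter-subject variability in region
geometry beyond seeded jitter, and its effect sizes are designed rather
than measured. Real-data quantities (the published t values, median R²,
per-subject overlap percentages) depend on scanner data and manual
drawing and are deliberately not reproduction targets.
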