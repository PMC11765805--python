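# Methods

## The measurement problem

During S phase, PCNA (the sliding clamp) and RPA (the ssDNA-binding
complex) concentrate in nuclear replication foci. Nucleotide depletion by
hydroxyurea (HU) stalls replication forks: PCNA leaves the foci within
minutes while RPA accumulates over tens of minutes on the ssDNA exposed by
continued unwinding; drug washout reverses both. Foci are too numerous,
variable and dynamic to segment and integrate reliably, so the package
quantifies the *freely diffusing* pool instead: protein leaving the foci
must appear in the diffuse pool and vice versa, and the diffuse pool is
spatially uniform, so a small foci-free patch of nucleoplasm reports it
cleanly.

## ROI photometry (formulas 1–6)

Per frame and channel, with region B a foci-free patch inside the nucleus
and region C camera background outside all cells:

* D_t = mean(B) − mean(C) — diffuse-pool intensity (formula 1);
* T_ref = mean of D_t over a *reference window* in which essentially the
  whole pool is diffuse — after focus dissolution for a decay channel,
  before drug addition for an accumulation channel;
* E_t = T_ref − D_t — bound intensity (formula 2);
* nE_t = E_t / max_t(smoothed E_t) — peak-normalized bound intensity
  (formula 3);
* F_t = E_t / T_ref — bound fraction of the total nuclear pool
  (formula 4).

Bound fractions convert to absolute numbers through HeLa proteome
constants: G_t = F_t · N_complexes / N_forks (formula 5) with
N = 865,300 PCNA homotrimers or 926,424 RPA heterotrimers and
N_forks = 4000 active forks, and H_t = 30 nt · G_t (formula 6) for the
ssDNA length covered by RPA. These constants are a versioned registry
(`StoichiometryConstants`) overridable per cell line. The tagged/endogenous
expression ratios of the fluorescent alleles are deliberately *not*
applied, matching the arithmetic that treats the tagged fraction as
representative of the whole pool.

Choices a user should know about:

* **Reference windows.** Decay channel: 15–25 min after drug addition;
  accumulation channel: the whole pre-treatment baseline. The decay window
  starts late on purpose: with a dissolution half-time of ~2 min, a window
  opening 10 min after treatment still contains ~2–4% undissolved protein,
  which biases T_ref low and every F_t value down by more than a
  percentage point; by 15–25 min the residual is < 0.3%.
* **Residual bound protein.** If a fraction of the decay channel never
  dissolves, T_ref underestimates the total pool by that fraction and
  F_t is compressed toward zero accordingly; an optional
  `total_correction` factor on T_ref (default 1.0) lets the user
  compensate a known residual. The simulator's decay channel defaults to
  full dissolution, which is the regime in which the reference-window
  definition is exact.
* **Negative E_t values are retained**, not clamped, so that averaging
  across cells and frames stays unbiased in the noise.
* The up-to-three B regions are averaged after background subtraction;
  the peak for nE_t is taken on a 5-frame moving average of E_t so a
  single noise spike cannot define the normalization (window 1 restores
  the raw maximum).
* Population curves report mean ± SD (not SEM) across cells.
* No photobleaching correction is applied by default (spinning-disk
  acquisition at these settings bleaches negligibly); the simulator can
  emulate bleaching, and nE_t/F_t are by construction invariant to gain
  and to shared offsets.

## Registration and automatic ROI placement

Each cell's stack is registered by translation against its first frame
(`skimage.registration.phase_cross_correlation`, 1/20-pixel resolution).
Two guards matter in practice: estimates below 0.3 px are treated as
correlation jitter — on a stationary cell, foci dissolving and appearing
move the correlation peak by a fraction of a pixel, and resampling the
frame for them only degrades the photometry — and single-frame estimates
that jump by more than 10 px are rejected as spurious peaks (the previous
frame's shift is carried over, with a warning).

Foci-free regions are placed automatically for the synthetic study: the
per-pixel temporal maximum of the (temporally smoothed) stack flags every
pixel that is ever bright, and three radius-5 px disks are placed greedily
to maximize distance from flagged pixels, at least 9 px inside the
segmented nucleus boundary. The temporal smoothing before the maximum is
not cosmetic: selecting pixels on their raw temporal maximum conditions
the selected pixels' noise to be low near their brightest epoch, which
imprints a small time-locked bias on D_t. Keeping the disks away from the
segmented boundary matters because Gaussian pre-smoothing makes Otsu
segmentation overshoot the true nuclear edge by a few pixels. On real
data, hand-drawn regions (as the measurement scheme assumes) can be
supplied instead; automatic placement is a convenience, not a claim.

## Kinetics

All transitions are single exponentials with offset — the minimal form
carrying a half-time, which is also what the reported half-times imply:
`y = r + (a − r)e^{−k(t−t0)}` for dissolution, `y = b + a(1 − e^{−k(t−t0)})`
for accumulation, t½ = ln2/k. Fits are unweighted least squares
(`scipy.optimize.curve_fit`) with endpoints as starting values and the
first half-crossing of the trace setting the initial rate; a flat trace is
returned flagged (R² = 0) rather than raised. Fits are per cell, then
summarized as mean ± SD, matching the ± notation across n cells.

Accumulation/removal *rates* are ambiguous without a stated window, so all
three definitions are computed and labeled: onset-to-half-maximum
regression slope (headline), net change over the phase divided by its
duration ("mean", an exact algebraic identity with the level change), and
the steepest 5-frame sliding-window slope. They differ by up to an order
of magnitude on a saturating trace — the output always records the mode.

Plateau onset is the earliest time after which the 5-frame moving average
stays within a tolerance (default 5% of dynamic range) of its final value
for a minimum span; for a clean saturating exponential this lands at
log2(1/0.05) ≈ 4.3 half-times.

## FRAP

Normalization follows four steps: (a) subtract the background-region trace
from the bleached and the reference focus; (b) scale each so its six
pre-bleach frames average 1; (c) divide bleached by reference, cancelling
acquisition photobleaching exactly (a shared multiplicative factor drops
out); (d) map affinely so the first post-bleach point is exactly 0 and the
pre-bleach mean exactly 1. Step (d) also cancels the diffuse pedestal
under the focus and the bleach depth, so on noise-free input the
normalized curve equals the underlying recovery function exactly.

The recovery is decomposed as A_f(1 − e^{−k_f t}) + A_s(1 − e^{−k_s t}):
a fast term (freely diffusing molecules re-entering the bleached spot), a
slow term (exchange of the bound pool) and an immobile remainder
1 − A_f − A_s. Two choices are ours rather than inherited: the
identifiability constraint k_f ≥ 10·k_s (without it the two terms swap
roles on noisy curves), and a model-selection rule that keeps the
single-exponential fit unless the two-component fit reduces the residual
by ≥ 5% (this is what routes single-step recoveries, like RPA's, to the
one-component branch). The bound-only curve subtracts the fitted fast
component and renormalizes by 1 − A_f; t½(bound) = ln2/k_s.

Exchange in absolute numbers multiplies the bound-curve gain over a window
by the number of bound complexes: windows default to 9 s for RPA-like and
60 s for PCNA-like records — the steepest part of each recovery. One
documented ambiguity: one part of the source protocol assigns the 9 s/1 min
windows to RPA without/with ATR inhibition, while the results apply 9 s to
RPA and 1 min to PCNA; the defaults follow the results usage, and both are
configurable.

## Single-focus validation (formula 7)

A hand-picked focus is tracked (brightest pixel within a search radius of
the previous position, refined twice by an intensity-weighted centroid —
the second pass removes the truncation bias of a window centered on the
peak pixel). Per frame a 7×7 crop around the rounded center is stitched
into a kymogram; the mean inside a radius-3.5 px circle around the
*unrounded* center minus a local background (default: 1 px annulus at
5–6 px) gives Q_t, normalized to peak 1 as nM_t. A pixel belongs to the
circle if its center is within the radius (37 pixels for an on-grid
center). Because circle and annulus both scale with the focus flux and
the diffuse pedestal cancels in the subtraction, nM_t is exactly
proportional to the focus's bound amount on noise-free input — which is
why nM_t and nE_t agree pointwise and the single-focus route validates
the diffuse-pool method.

## The synthetic-movie generator

The generator is the test-bed: a 2-D nucleus (ellipse — the analysis
consumes maximum-intensity projections, so the projected plane is rendered
directly) holding a fixed fluorophore budget per channel. The schedule's
bound fraction splits the budget across Gaussian foci (fixed per-focus
weights, default equal; optional per-focus width jitter) and the remainder
spreads uniformly over the nucleus, so total fluorescence is conserved by
construction. Camera model: background offset, then Poisson photon noise
(scale configurable), then Gaussian read noise. Defaults (budget 1.5×10⁵
a.u., background 10, photon scale 1, read σ 3, 20 foci of σ 1.5 px on a
128×128 frame) give a focus peak SNR ≈ 10. Stalling movies use minutes and
30 s frames; FRAP movies use seconds and 1 s frames, six pre-bleach frames
by default (five are accepted on input with a warning, but six are needed
for the normalization average).

Schedule defaults are the study conditions: decay channel f₀ = 0.27,
t½(stall) = 2.1 min, full dissolution, restart t½ = 5.1 min; accumulation
channel plateau f_max = 0.42 with t½(stall) = 23.9 min — the plateau is
set so the bound fraction *reaches ~35% after 60 min of treatment*, which
is the measured 1 h value, and is consistent with the ~40% plateau seen
under prolonged depletion; removal after washout with t½ = 2.5 min
(complete removal within ~12 min). The ATR-inhibited regime uses
t½ = 5.6 min, f_max = 0.70, and 16% of the plateau persisting after
restart. Focus count and weights are not constrained by any reported
value; 20 equal foci is a configurable convention.

FRAP rendering bleaches the focus component only, with the diffusing pool
treated as refilled within one 1 s frame (diffusion equilibrates in
milliseconds to seconds): persistently bleaching the diffuse pedestal
would double-count the fast recovery component that the ground-truth curve
already contains. The normalization steps then recover the ground-truth
recovery function exactly, which is what makes the FRAP stage testable
against truth.

What the generator does *not* emulate: 3-D optics and deconvolution,
chromatin texture, focus birth/death and merging, cell-cycle morphology,
shot-to-shot focus heterogeneity beyond width jitter, and detector
artifacts beyond the two-term noise model. Passing recovery tests on this
generator therefore demonstrates the correctness and calibration of the
*analysis chain*, not robustness to every property of real microscopy
data.

## Numerical conventions and degenerate inputs

Coordinates are 0-based pixel indices, x right / y down; crops use
half-open windows; kymogram crops round the center to the pixel grid while
photometry uses the unrounded center. Time is minutes for stalling
analysis and seconds for FRAP, converted explicitly at boundaries.
Segmentation of a constant image returns an empty labeling with a warning,
not an exception; registration of a flat stack assumes zero drift;
fitting a flat trace returns a flagged result; a FRAP record with no
detectable bleach raises. Simulations are deterministic given their seed
(identical seeds produce bit-identical movies), and batch seeds are
spawned from a single root seed.

## Problem sizes

The packaged study runs 10–16 cells per condition at 128×128 px and
151–241 frames, and 10 FRAP replicates per regime at 96×96 px and 306
frames. These sizes put the Monte-Carlo error of batch means well inside
the recovery tolerances while keeping a full run in tens of seconds;
larger batches change none of the conclusions.

## Known limitations

* The reference-window definition of T_ref is exact only when the decay
  channel dissolves completely; a residual bound pool compresses F_t
  (see `total_correction`).
* The accumulation channel's pre-treatment reference assumes no bound
  protein at baseline; invisible bound RPA at unperturbed forks would
  scale F_t down by that (unquantified) fraction.
* Rate estimates depend on the window mode; only the "mean" mode is
  parameter-free.
* The per-fork conversions apply one fork count uniformly across the
  S-phase stages captured in a movie.
* Tracking follows one focus and does not link across dissolution gaps;
  it coasts and flags instead.
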