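# Methods

## The measurement being modelled

A single protein labelled with a donor/acceptor dye pair is imaged at 10
frames per second in a dual-view geometry: the camera frame is split at the
horizontal midline, donor emission on the left half, acceptor on the right.
Energy transfer makes the two channels anti-correlated; the per-frame FRET
efficiency is

E = I_a / (I_a + γ·I_d),

with γ the detection-correction factor compensating the unequal quantum
yields and detection efficiencies of the two channels. When the acceptor
photobleaches, the donor stops losing energy to it and its intensity jumps
up; γ is measurable from exactly this event as |ΔI_a/ΔI_d|, and the same
event certifies that the spot is a genuine single-pair FRET molecule.
Efficiencies convert to inter-dye distances through r = R0·(1/E − 1)^(1/6),
with the dye size and orientation factor neglected.

## Synthetic data generator

The generator is a forward model of that measurement and is the package's
test bed: every estimator is validated by recovery of its hidden truth.

Per molecule:

1. a hidden state path is drawn from a continuous-time Markov chain with
   exponential dwells (mean `dwell_mean_s`, default 150 s) and uniform
   jumps among the other states — the data constrain only a single
   lifetime scale, so no structured rate matrix is imposed;
2. the per-frame efficiency is the state's Gaussian (mean/width from the
   config) truncated to [0, 1];
3. channels are built so the efficiency formula inverts exactly: with
   summed intensity T (`total_intensity`), acceptor = T·E and donor =
   T·(1−E)/γ_true;
4. the acceptor bleaches at an exponential time (mean
   `acceptor_bleach_mean_s`, default 5 s, which sets the ~5 s observable
   span); the donor survives an *additional* exponential time (mean
   `donor_bleach_mean_s`, default 5 s), so acceptor-before-donor ordering
   holds by construction. After the acceptor bleach the acceptor falls to
   background and the donor recovers to T/γ_true; after the donor bleach
   both sit at background;
5. additive Gaussian camera noise (`noise_sd`) per channel. Records have a
   fixed length `record_s` (default 60 s) so movie stacks are rectangular.

Movies render each molecule as a 2-D Gaussian spot (width `psf_sigma_px`)
whose integrated flux per frame equals the trace value; the acceptor spot
sits at the donor position translated by the half-frame width plus a
configurable sub-pixel offset (a pure translation — an affine map, which is
what the registration stage fits). Noise enters movies at the pixel level.

Condition presets encode the three experimental regimes as study
conditions: 2 emission states (0.54, 0.75) for monomeric actin with 312
(low salt) and 109 (high salt) molecules, 3 states (0.37, 0.54, 0.75) for
filamentous actin with 374 molecules. Component widths are not published;
σ = 0.08 is used for every state, a typical single-molecule peak width that
keeps the 0.17–0.21 peak separations resolvable. Weights are chosen so the
pooled mean efficiency reproduces the published condition averages —
low-salt G-actin (fg 0.24, g 0.76 → mean E 0.70), F-actin (f 0.45, fg 0.35,
g 0.20 → mean E ≈ 0.51) — with the high-salt preset fg-enriched
(0.45/0.55). Default total intensity 1000 with noise_sd 30 gives a ~3%
per-channel noise level.

What the generator does *not* emulate: EMCCD gain-register (excess) noise,
Poisson shot noise, spectral crosstalk and donor leakage, dye blinking,
polarization effects, stage drift. Passing recovery tests therefore shows
the estimators are correct under additive-Gaussian, crosstalk-free
conditions, not that they are robust to every camera artifact of real
recordings.

## Imaging

Spot detection band-passes each frame with a difference of Gaussians
(σ, 2σ), thresholds local maxima at median + `threshold_sd` × robust
(MAD-based) noise, refines positions with a sub-pixel 2-D Gaussian fit in a
3σ window, and merges detections closer than 2σ (brighter wins). View
registration pairs spots by nearest neighbour after removing the nominal
half-frame offset and fits an affine map by least squares with one round of
outlier rejection (residual > 3× median). Traces are read out by aperture
photometry — sum over a 3σ-radius disk minus the local background (median
of a 4–6σ annulus scaled by aperture area) — rather than per-frame PSF
fitting; aperture photometry is the robust choice at low photon counts. A
3σ aperture captures 98.9% of a Gaussian spot's flux, which is why the
noise-free round-trip guarantee is stated at 2%.

## Trace processing

Bleach steps are found on the **raw** channels (smoothing blurs edges) by
binary segmentation: the best least-squares change point of a
piecewise-constant fit is accepted when |step| exceeds `accept_k` (default
3) × the pooled within-segment standard deviation, recursing until
`max_steps` or no acceptable split. On pure-noise traces this accepts a
step in well under 5% of cases; a step 5× the noise is localized to ±2
frames in ≥95% of cases.

A molecule is accepted as a FRET pair when (i) exactly one acceptor step
drops to near background — a *bleach* is a negative step whose post level
falls below `bleach_frac` (default 25%) of the pre-step amplitude above
background, which distinguishes it from the partial anti-correlated steps
produced by conformational transitions (a literal single-negative-step rule
would silently discard every molecule showing a transition and with them
the kinetics signal); (ii) the donor shows a concurrent increase (±1 frame)
— the donor-recovery signature; (iii) at most one donor step falls to
background, and if present it is the donor's final step, after the acceptor
bleach. Everything else is rejected with a reason code.

γ is estimated per molecule from mean levels over `gamma_window_s`
(default 1 s) immediately before vs after the acceptor bleach frame
(excluding the frame itself, stopping before any donor bleach), and the
condition-level γ is the median over molecules — one γ per condition, not
per molecule. The estimator is exactly scale-invariant and recovers the
generating γ within 5% at 200 molecules and 5% channel noise.

Efficiencies are computed only on frames before the acceptor bleach.
Smoothing (centered moving average, default window 1 s = 10 frames at
10 fps; an even window extends one frame further forward than backward) is
applied *within the valid span only* — smoothing across the bleach edge
would drag post-bleach levels into the last ~window of valid frames and
bias the pooled distribution low. Frames with non-positive denominator are
invalid; E is clipped to [0, 1] with clipped frames recorded in a mask.

## State inference: two samples, one model

Pooled per-frame efficiencies are fit by a 1-D Gaussian-mixture EM written
for this purpose (restarts with quantile-spread initial means — the first
restart at the even quantiles (i+0.5)/K, later ones at sorted uniform
quantile positions; convergence at Δlog-likelihood < 1e-8, with restarts
ranked at a coarse tolerance and the winner polished to the full one;
components with width < 1e-4 are discarded as degenerate). Fitting is by
maximum likelihood on the un-binned sample; a histogram least-squares mode
(`fit_mixture_histogram`) exists for fidelity checks. The frame, not the
molecule, is the pooling unit.

Model order (2 vs 3 components, optionally 1) is chosen by BIC with ties
(ΔBIC < 2) broken toward the smaller K. Two different samples feed the two
questions:

* **selection** uses the **raw** per-frame efficiencies: raw frames are
  independent draws, so the BIC sample size is honest. Selecting on the
  smoothed sample demonstrably overfits — window autocorrelation inflates
  the evidence and the shrinking edge windows make each state a
  scale-mixture that BIC models with a spurious extra component;
* **parameter fitting** (and state assignment) uses the **smoothed**
  sample: the ~3× narrower, well-separated peaks give component means that
  are unbiased even for minor overlapping components, whereas fitting the
  raw sample biases a minor component's mean toward its dominant
  neighbour by up to ~0.06.

Reported widths therefore describe the smoothed-trace distribution, not
the raw emission width. Components are always reported sorted by ascending
mean and named by descending mean: g (highest E, most compact), fg
(intermediate), f (lowest E, filament-specific). Per-frame states are the
maximum-posterior components, ties broken toward the lower mean; fitted
mixture weights track the frame-weighted state occupancy of the *accepted*
molecules, which can deviate from the generating initial-state weights by
up to ~0.1 (random exponential spans plus mildly state-dependent
acceptance) — the condition-to-condition ordering of the fg weight, the
quantity of scientific interest, is unaffected.

## Kinetics and distances

A transition is a label change whose flanking runs both last
`min_dwell_frames` (default 10 = 1 s), suppressing assignment flicker. The
lifetime follows from the censored fraction: τ = T_obs / (k/n) with a
Clopper-Pearson 95% interval propagated through; zero transitions yield the
rule-of-three lower bound τ ≥ T_obs·n/3, flagged as such. Inside the
pipeline report T_obs is the *effective* observation window — the valid
span minus the 2·min_dwell − 1 edge frames in which a transition cannot
satisfy the run-length rule. Using the raw span would inflate the lifetime
by the inverse of the edge fraction (~2× at 5 s spans); the raw span is
reported alongside (`mean_observation_raw_s`). Per-state dwell fitting is
deliberately out of scope: spans (~5 s) are two orders of magnitude shorter
than the dwells (~150 s), so the censored-fraction argument is the only
estimator the data support.

Distances use r = R0·(1/E − 1)^(1/6). R0 defaults to 5.1 nm, the value
consistent with the published distance/efficiency pairs for this dye pair
(4.4 nm at E = 0.7) and with its literature Förster radius; it is
configurable. Condition-average efficiency is ambiguous between
frame-weighted and molecule-weighted; the report carries both, and both
distance conversions.

## Problem sizes and reproducibility

Recovery tests and the acceptance script run at the scale of the original
experiment: ensembles of 109–374 molecules, 10 fps, ~5 s observable spans,
with Monte-Carlo checks at 20–50 seeded replicates and model fits on
1.5–2×10⁴ pooled frames per ensemble. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical config + seed
reproduces every artifact byte for byte (the run manifest records SHA-256
checksums of all outputs).

## Known limitations

* The additive-Gaussian noise model understates low-count shot noise;
  detection thresholds on real EMCCD data will need recalibration.
* The uniform-jump Markov assumption is a modelling choice; the data do
  not constrain state-to-state connectivity (e.g. whether direct g↔f
  transitions occur).
* Registration is affine; strong field-dependent distortions between the
  views are not modelled.
* Pair selection assumes a single acceptor bleach within the record;
  molecules with acceptor blinking would be rejected as
  multiple-bleach candidates.
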